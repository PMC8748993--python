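"""Undersampling, boosting, thresholds, importances, odds ratios."""

import numpy as np
import pandas as pd
import pytest

from mapshb.features import FEATURE_COLUMNS, LABEL_COLUMN, LabeledDataset
from mapshb.model import (
    BoostingParams,
    classify,
    evaluate_thresholds,
    feature_importance,
    find_threshold_for_precision,
    load_model,
    member_probabilities,
    odds_ratio,
    precision_recall,
    predict,
    prior_correction,
    save_model,
    train_ensemble,
    train_member,
    tune_interaction_depth,
    undersample,
)
from mapshb.synthetic_data import GeneratorConfig, generate_feature_table

TINY = BoostingParams(n_trees=60, shrinkage=0.1, interaction_depth=2, cv_folds=3, seed=9)


def _constant_row(**overrides):
    row = {c: "UNK" for c in FEATURE_COLUMNS}
    row.update({
        "donor_res": "SER", "acceptor_res": "ASP", "donor_elem": "O",
        "acceptor_elem": "O", "donor_chg": "0", "acceptor_chg": "-1",
        "acceptor_loc": "side_chain", "donor_ss": "coil", "acceptor_ss": "coil",
    })
    row.update(overrides)
    return row


def _one_feature_dataset(n=400, seed=0, noise=0.0):
    """Label fully determined by donor_res (TYR=SHB, ARG=NHB) up to `noise`."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for _ in range(n):
        if rng.random() < 0.5:
            rows.append(_constant_row(donor_res="TYR"))
            labels.append("NHB" if rng.random() < noise else "SHB")
        else:
            rows.append(_constant_row(donor_res="ARG"))
            labels.append("SHB" if rng.random() < noise else "NHB")
    t = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    t[LABEL_COLUMN] = labels
    return LabeledDataset(t)


class TestBoostingParams:
    @pytest.mark.parametrize("bad", [
        dict(shrinkage=0.0), dict(shrinkage=1.5), dict(n_trees=0),
        dict(interaction_depth=0), dict(interaction_depth=16),
        dict(cv_folds=1), dict(bag_fraction=0.0), dict(cv_metric="auc"),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            BoostingParams(**bad)

    def test_profiles(self):
        paper = BoostingParams.paper_profile()
        assert (paper.shrinkage, paper.n_trees, paper.cv_folds) == (0.01, 5000, 10)
        assert paper.depth_grid == tuple(range(1, 16))
        fast = BoostingParams.fast_profile()
        assert fast.n_trees == 500 and fast.depth_grid == tuple(range(1, 7))


class TestUndersample:
    def test_balances_to_minority_count(self, prevalence_table_1200):
        n_shb, n_nhb = prevalence_table_1200.class_counts()
        assert n_nhb > n_shb
        balanced = undersample(prevalence_table_1200, seed=3)
        assert balanced.class_counts() == (n_shb, n_shb)

    def test_deterministic_given_seed(self, prevalence_table_1200):
        b1 = undersample(prevalence_table_1200, seed=7)
        b2 = undersample(prevalence_table_1200, seed=7)
        pd.testing.assert_frame_equal(b1.table, b2.table)
        b3 = undersample(prevalence_table_1200, seed=8)
        assert not b1.table.equals(b3.table)

    def test_already_balanced_keeps_all_rows(self, donor_only_balanced_1200):
        n_shb, n_nhb = donor_only_balanced_1200.class_counts()
        assert n_shb == n_nhb
        balanced = undersample(donor_only_balanced_1200, seed=0)
        assert len(balanced) == len(donor_only_balanced_1200)

    def test_minority_nhb_rejected(self):
        ds = _one_feature_dataset(n=100)
        t = ds.table.copy()
        t[LABEL_COLUMN] = np.where(np.arange(len(t)) < 80, "SHB", "NHB")
        with pytest.raises(ValueError, match="majority"):
            undersample(LabeledDataset(t), seed=0)


class TestTraining:
    def test_separable_one_feature_data_learns_positives(self):
        ds = _one_feature_dataset(n=400, seed=1, noise=0.0)
        member = train_member(ds, BoostingParams(
            n_trees=500, shrinkage=0.05, interaction_depth=1, seed=0))
        from mapshb.features import encode_categoricals
        X_enc, _ = encode_categoricals(ds.X)
        probs = member.booster.predict(X_enc)
        assert probs[ds.y == 1].min() >= 0.99
        assert probs[ds.y == 0].max() <= 0.01

    def test_pure_noise_probabilities_concentrate_near_half(self):
        rng = np.random.default_rng(4)
        cfg = GeneratorConfig.donor_only(
            n_records=2000, seed=4, marginal_mode="balanced",
            base_prob={d: 0.5 for d in GeneratorConfig().base_prob})
        ds = generate_feature_table(cfg)
        ens = train_ensemble(ds, TINY, n_members=2)
        holdout = generate_feature_table(
            GeneratorConfig.donor_only(
                n_records=500, seed=99, marginal_mode="balanced",
                base_prob={d: 0.5 for d in GeneratorConfig().base_prob}))
        probs = predict(ens, holdout.X)
        assert abs(probs.mean() - 0.5) <= 0.05

    def test_single_class_input_rejected(self):
        ds = _one_feature_dataset(n=50)
        t = ds.table.copy()
        t[LABEL_COLUMN] = "SHB"
        with pytest.raises(ValueError):
            train_member(LabeledDataset(t), TINY)

    def test_depth_must_be_fixed_before_member_fit(self, donor_only_balanced_1200):
        with pytest.raises(ValueError, match="interaction_depth"):
            train_member(donor_only_balanced_1200, BoostingParams(n_trees=10))


class TestTuneDepth:
    def test_single_feature_signal_prefers_depth_one(self):
        ds = _one_feature_dataset(n=600, seed=2, noise=0.15)
        p = BoostingParams(n_trees=120, shrinkage=0.1, cv_folds=3,
                           depth_grid=(1, 2, 3), seed=0)
        depth, cv = tune_interaction_depth(ds, p)
        # depth 1 must be within one standard error of the best depth
        best = cv["cv_score"].min()
        se = cv["cv_score"].std() / np.sqrt(len(cv))
        assert cv.loc[cv["depth"] == 1, "cv_score"].iloc[0] <= best + max(se, 0.01)

    def test_pure_interaction_needs_depth_at_least_two(self):
        cfg = GeneratorConfig(n_records=2500, seed=2, marginal_mode="balanced",
                              interaction_mode="crossed")
        ds = generate_feature_table(cfg)
        p = BoostingParams(n_trees=150, shrinkage=0.1, cv_folds=3,
                           depth_grid=(1, 2, 3, 4), seed=0)
        depth, cv = tune_interaction_depth(ds, p)
        assert depth >= 2
        # and the CV ordering shows depth 1 is genuinely worse
        assert (cv.loc[cv["depth"] == 1, "cv_score"].iloc[0]
                > cv.loc[cv["depth"] == depth, "cv_score"].iloc[0])

    def test_ties_break_to_smallest_depth(self):
        # a duplicated depth in the grid scores identically; argmin -> first
        ds = _one_feature_dataset(n=200, seed=3, noise=0.2)
        p = BoostingParams(n_trees=30, shrinkage=0.1, cv_folds=2,
                           depth_grid=(2, 2), seed=0)
        depth, cv = tune_interaction_depth(ds, p)
        assert depth == 2
        assert cv["cv_score"].iloc[0] == cv["cv_score"].iloc[1]


class TestEnsemble:
    def test_ensemble_probability_is_member_mean(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=3)
        X = donor_only_balanced_1200.X.head(50)
        mat = member_probabilities(ens, X)
        assert np.allclose(predict(ens, X), mat.mean(axis=0))

    def test_single_member_equals_one_undersampled_fit(self, prevalence_table_1200):
        ens = train_ensemble(prevalence_table_1200, TINY, n_members=1)
        from dataclasses import replace
        balanced = undersample(prevalence_table_1200, TINY.seed)
        member = train_member(balanced, replace(TINY, seed=TINY.seed))
        X = prevalence_table_1200.X.head(40)
        assert np.allclose(predict(ens, X), member_probabilities(ens, X)[0])
        from mapshb.features import encode_categoricals
        X_enc, _ = encode_categoricals(X)
        assert np.allclose(predict(ens, X), member.booster.predict(X_enc))

    def test_member_seeds_are_base_plus_index(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=3)
        assert ens.member_seeds == [9, 10, 11]

    def test_duplicate_rows_get_identical_probabilities(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=2)
        row = donor_only_balanced_1200.X.head(1)
        dup = pd.concat([row] * 5, ignore_index=True)
        probs = predict(ens, dup)
        assert np.all(probs == probs[0])
        assert np.all((probs >= 0) & (probs <= 1))

    def test_persistence_round_trip(self, tmp_path, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=2)
        path = tmp_path / "model.json"
        save_model(ens, path)
        back = load_model(path)
        X = donor_only_balanced_1200.X.head(30)
        assert np.allclose(predict(back, X), predict(ens, X), atol=0)
        assert back.member_seeds == ens.member_seeds
        assert back.depths == ens.depths


class TestThresholding:
    def test_classify_boundary_inclusive(self):
        assert classify(0.870, 0.870) == "SHB"
        assert classify(0.869, 0.870) == "NHB"
        assert np.all(classify(np.array([0.0, 0.5, 1.0]), 0.0) == "SHB")

    def test_precision_recall_arithmetic(self):
        probs = [0.9, 0.9, 0.9, 0.9, 0.1]
        labels = [1, 1, 1, 0, 1]  # TP=3 FP=1 FN=1 at threshold 0.5
        m = precision_recall(probs, labels, 0.5)
        assert m.precision == pytest.approx(75.0)
        assert m.recall == pytest.approx(75.0)
        assert m.n_predicted_shb == 4

    def test_threshold_zero_gives_full_recall(self):
        m = precision_recall([0.2, 0.8], [1, 1], 0.0)
        assert m.recall == 100.0

    def test_no_predictions_gives_undefined_precision(self):
        m = precision_recall([0.1, 0.2], [1, 0], 0.99)
        assert m.precision is None

    def test_recall_and_counts_non_increasing_in_threshold(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=2)
        probs = predict(ens, donor_only_balanced_1200.X)
        y = donor_only_balanced_1200.y
        sweep = [precision_recall(probs, y, t) for t in np.linspace(0, 1, 21)]
        recalls = [m.recall for m in sweep]
        counts = [m.n_predicted_shb for m in sweep]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_find_threshold_examples(self):
        m = find_threshold_for_precision([0.9, 0.8, 0.2], [1, 0, 0], 100.0)
        assert m.threshold == pytest.approx(0.9)
        assert m.recall == 100.0
        with pytest.raises(ValueError):
            find_threshold_for_precision([0.5], [1], 101.0)
        all_pos = find_threshold_for_precision([0.3, 0.6], [1, 1], 90.0)
        assert all_pos.threshold == pytest.approx(0.3)
        assert all_pos.precision == 100.0
        assert find_threshold_for_precision([0.9, 0.1], [0, 1], 99.0) is None


class TestImportanceAndOdds:
    def test_importance_sums_to_hundred(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=3)
        imp = feature_importance(ens)
        assert imp["importance_percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert set(imp["feature"]) == set(FEATURE_COLUMNS)

    def test_donor_signal_ranks_donor_residue_first(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=3)
        imp = feature_importance(ens)
        assert imp.iloc[0]["feature"] in ("donor_res", "donor_elem")

    def test_group_other_collapses_minor_features(self, donor_only_balanced_1200):
        ens = train_ensemble(donor_only_balanced_1200, TINY, n_members=2)
        imp = feature_importance(ens, group_other=True)
        assert imp["importance_percent"].sum() == pytest.approx(100.0, abs=0.1)
        if "other" in set(imp["feature"]):
            named = imp[imp["feature"] != "other"]
            assert (named["importance_percent"] > 1.0).all()

    @pytest.mark.parametrize("p1,p2,expected", [
        (0.32, 0.11, 3.8),
        (0.65, 0.23, 6.2),
        (0.4, 0.4, 1.0),
    ])
    def test_odds_ratio(self, p1, p2, expected):
        assert round(odds_ratio(p1, p2), 1) == expected

    def test_odds_ratio_boundary_rejected(self):
        for p1, p2 in [(0.0, 0.5), (0.5, 1.0)]:
            with pytest.raises(ValueError):
                odds_ratio(p1, p2)

    def test_prior_correction(self):
        # balanced output 0.5 maps to the true prevalence
        assert prior_correction(np.array([0.5]), 0.187)[0] == pytest.approx(0.187)
        with pytest.raises(ValueError):
            prior_correction(np.array([0.5]), 0.0)
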