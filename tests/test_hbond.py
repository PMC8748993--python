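"""Donor/acceptor enumeration, geometric classification, detection, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapshb import hbond
from mapshb.hbond import (
    classify_geometry,
    detect_hydrogen_bonds,
    enumerate_acceptors,
    enumerate_donors,
    pair_statistics,
    records_to_table,
    summarize_dataset,
)
from mapshb.structure_io import Atom, ProteinStructure, Residue, assign_secondary_structure
from mapshb.synthetic_data import ToyBondSpec, build_toy_structure


def _res(name, atoms, chain="A", seq=1, serial=0):
    return Residue(name=name, chain_id=chain, seq_index=seq, serial_index=serial,
                   atoms=atoms)


def _atom(name, elem, xyz):
    return Atom(name=name, element=elem, coords=np.array(xyz, float))


def _structure(residues):
    return ProteinStructure(structure_id="t", chains={"A": residues})


class TestEnumerateDonors:
    def test_protonated_tyr_hydroxyl_is_one_donor(self):
        tyr = _res("TYR", [
            _atom("OH", "O", (0, 0, 0)), _atom("HH", "H", (0.96, 0, 0)),
        ])
        donors = enumerate_donors(_structure([tyr]))
        assert len(donors) == 1
        assert donors[0].heavy_atom.name == "OH"
        assert donors[0].location == "side_chain"

    def test_gly_has_no_side_chain_donor(self):
        gly = _res("GLY", [
            _atom("N", "N", (0, 0, 0)), _atom("CA", "C", (1.4, 0, 0)),
            _atom("H", "H", (-0.5, 0.8, 0)),
        ])
        assert enumerate_donors(_structure([gly])) == []

    def test_fully_protonated_arg_gives_three_donor_groups(self):
        arg = _res("ARG", [
            _atom("NE", "N", (0, 0, 0)), _atom("HE", "H", (0, 1.0, 0)),
            _atom("NH1", "N", (2.2, 0, 0)), _atom("HH11", "H", (2.2, 1.0, 0)),
            _atom("HH12", "H", (3.0, -0.5, 0)),
            _atom("NH2", "N", (1.2, -2.0, 0)), _atom("HH21", "H", (1.2, -3.0, 0)),
        ])
        donors = enumerate_donors(_structure([arg]))
        assert sorted(d.heavy_atom.name for d in donors) == ["NE", "NH1", "NH2"]
        assert all(d.group_charge == 1 for d in donors)
        assert len(donors[1].hydrogens) + len(donors[0].hydrogens) + len(donors[2].hydrogens) == 4

    def test_unprotonated_donor_warns_and_is_skipped(self):
        ser = _res("SER", [_atom("OG", "O", (0, 0, 0))])
        with pytest.warns(UserWarning, match="no hydrogen"):
            assert enumerate_donors(_structure([ser])) == []

    def test_backbone_n_never_donates(self):
        ala = _res("ALA", [
            _atom("N", "N", (0, 0, 0)), _atom("H", "H", (0, 1.0, 0)),
        ])
        assert enumerate_donors(_structure([ala])) == []


class TestEnumerateAcceptors:
    def test_asp_contributes_backbone_o_and_both_carboxylate_oxygens(self):
        asp = _res("ASP", [
            _atom("O", "O", (0, 0, 0)), _atom("OD1", "O", (3, 0, 0)),
            _atom("OD2", "O", (4, 1, 0)),
        ])
        acc = enumerate_acceptors(_structure([asp]))
        names = sorted((a.heavy_atom.name, a.location, a.group_charge) for a in acc)
        assert names == [("O", "backbone", 0), ("OD1", "side_chain", -1),
                         ("OD2", "side_chain", -1)]

    def test_ala_contributes_backbone_o_only(self):
        ala = _res("ALA", [_atom("O", "O", (0, 0, 0)), _atom("CB", "C", (2, 0, 0))])
        acc = enumerate_acceptors(_structure([ala]))
        assert [(a.heavy_atom.name, a.location) for a in acc] == [("O", "backbone")]

    def test_his_tautomer_unprotonated_n_accepts(self):
        his = _res("HIS", [
            _atom("ND1", "N", (0, 0, 0)),
            _atom("NE2", "N", (2.2, 0, 0)), _atom("HE2", "H", (2.2, 1.0, 0)),
        ])
        acc = enumerate_acceptors(_structure([his]))
        assert [a.heavy_atom.name for a in acc] == ["ND1"]


class TestClassifyGeometry:
    @pytest.mark.parametrize(
        "r,angle,expected",
        [
            (2.65, 160.0, "SHB"),       # canonical short bond
            (2.75, 160.0, "unlabeled"), # the deliberate 2.7-2.8 gap
            (2.60, 134.9, "unlabeled"), # just below the angle cut
            (2.3, 135.0, "SHB"),        # both lower boundaries inclusive
            (2.7, 135.0, "SHB"),
            (2.8, 135.0, "NHB"),
            (3.2, 135.0, "NHB"),
            (2.2999, 170.0, "unlabeled"),
            (3.2001, 170.0, "unlabeled"),
        ],
    )
    def test_window_boundaries(self, r, angle, expected):
        assert classify_geometry(r, angle) == expected

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_geometry(0.0, 150.0)

    @given(r=st.floats(0.01, 6.0), angle=st.floats(0.0, 180.0))
    @settings(derandomize=True, max_examples=200)
    def test_partitions_the_domain(self, r, angle):
        """Every (R, angle) maps to exactly one of the three classes."""
        assert classify_geometry(r, angle) in ("SHB", "NHB", "unlabeled")


class TestDetection:
    @pytest.mark.parametrize("r,angle", [(2.3, 135.0), (2.65, 165.0), (3.0, 150.0), (3.2, 140.0)])
    def test_grid_detection_equals_brute_force(self, r, angle):
        s = build_toy_structure(ToyBondSpec(r=r, angle=angle))
        fast = detect_hydrogen_bonds(s, use_index=True)
        slow = detect_hydrogen_bonds(s, use_index=False)
        key = lambda recs: [(x.sort_key(), round(x.R, 9), round(x.angle, 9), x.label) for x in recs]
        assert key(fast) == key(slow)

    def test_beyond_cutoff_yields_nothing(self):
        s = build_toy_structure(ToyBondSpec(r=3.5, angle=165.0))
        assert detect_hydrogen_bonds(s) == []

    def test_bidentate_geometry_gives_two_records(self):
        # Arg-Asp-like: one donor N-H seeing both carboxylate oxygens in range
        arg = _res("ARG", [
            _atom("NE", "N", (0, 0, 0)), _atom("HE", "H", (1.01, 0, 0)),
        ], seq=1, serial=0)
        asp = _res("ASP", [
            _atom("OD1", "O", (2.79, 0.3, 0)), _atom("OD2", "O", (2.85, -0.9, 0)),
        ], seq=5, serial=1)
        recs = detect_hydrogen_bonds(_structure([arg, asp]))
        assert len(recs) == 2
        assert {x.acceptor.heavy_atom.name for x in recs} == {"OD1", "OD2"}

    def test_same_residue_pairs_excluded(self):
        ser = _res("SER", [
            _atom("OG", "O", (0, 0, 0)), _atom("HG", "H", (0.96, 0, 0)),
            _atom("O", "O", (2.9, 0.5, 0)),
        ])
        assert detect_hydrogen_bonds(_structure([ser])) == []

    def test_no_hydrogens_anywhere_raises(self):
        ser = _res("SER", [_atom("OG", "O", (0, 0, 0)), _atom("O", "O", (5, 0, 0))])
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            with pytest.raises(ValueError, match="no donors usable"):
                detect_hydrogen_bonds(_structure([ser]))

    def test_best_angle_hydrogen_defines_record(self):
        lys = _res("LYS", [
            _atom("NZ", "N", (0, 0, 0)),
            _atom("HZ1", "H", (1.01, 0, 0)),           # points at the acceptor
            _atom("HZ2", "H", (-0.5, 0.87, 0)),
            _atom("HZ3", "H", (-0.5, -0.87, 0)),
        ], serial=0)
        asn = _res("ASN", [_atom("OD1", "O", (3.0, 0, 0))], seq=9, serial=1)
        recs = detect_hydrogen_bonds(_structure([lys, asn]))
        assert len(recs) == 1
        assert recs[0].h_used.name == "HZ1"
        assert recs[0].angle == pytest.approx(180.0, abs=0.5)

    def test_deterministic_sorted_output(self, tyr_asp_structure):
        t1 = records_to_table(detect_hydrogen_bonds(tyr_asp_structure))
        t2 = records_to_table(detect_hydrogen_bonds(tyr_asp_structure))
        assert t1.to_csv(sep="\t") == t2.to_csv(sep="\t")


class TestSummarize:
    @pytest.mark.parametrize(
        "counts,expected",
        [((6181, 26929), 18.7), ((3980, 17942), 18.2), ((0, 100), 0.0)],
    )
    def test_shb_percentage_from_counts(self, counts, expected):
        table = summarize_dataset(counts)
        assert table.loc[0, "shb_percent"] == pytest.approx(expected)

    def test_zero_labeled_records_is_undefined_not_zero(self):
        table = summarize_dataset((0, 0))
        assert table.loc[0, "shb_percent"] is None or np.isnan(table.loc[0, "shb_percent"])

    def test_grouped_by_acceptor_location(self, tyr_asp_structure):
        recs = detect_hydrogen_bonds(tyr_asp_structure)
        table = summarize_dataset(recs)
        assert set(table["group"]) == {"overall", "side_chain"}
        overall = table[table["group"] == "overall"].iloc[0]
        assert overall["n_shb"] == 1 and overall["shb_percent"] == 100.0


class TestPairStatistics:
    def test_monte_carlo_recovers_generating_probability(self):
        # synthetic Tyr-Asp record table at the configured 96% SHB rate
        rng = np.random.default_rng(123)
        n, p_true = 2000, 0.96
        labels = np.where(rng.random(n) < p_true, "SHB", "NHB")
        table = pd.DataFrame({
            "resn_d": "TYR", "resn_a": "ASP",
            "label": labels,
            "R": np.where(labels == "SHB", 2.6, 2.9),
            "chain_d": "A", "chain_a": "A",
            "resi_d": "1", "resi_a": "50",
            "seq_sep": np.nan,
        })
        stats = pair_statistics(table)
        row = stats.iloc[0]
        sigma = 100 * np.sqrt(p_true * (1 - p_true) / n)
        assert abs(row["shb_prob"] - 96.0) <= 3 * sigma
        assert row["n"] == n
        assert row["median_r_shb"] == pytest.approx(2.6)
        assert row["median_r_nhb"] == pytest.approx(2.9)

    def test_empty_input_gives_empty_table(self):
        assert pair_statistics([]).empty

    def test_half_shb_single_pair(self):
        table = pd.DataFrame({
            "resn_d": "SER", "resn_a": "ASP",
            "label": ["SHB", "NHB"] * 10,
            "R": [2.5, 3.0] * 10,
            "seq_sep": [2.0] * 20,
        })
        stats = pair_statistics(table)
        row = stats.iloc[0]
        assert row["shb_prob"] == 50.0 and row["n"] == 20
        assert row["n_motif"] == 20 and row["shb_prob_motif"] == 50.0

    def test_motif_column_flags_sequence_separation_two(self, tyr_asp_structure):
        recs = detect_hydrogen_bonds(tyr_asp_structure)
        stats = pair_statistics(recs)
        # donor chain A, acceptor chain B: no same-chain pair, no motif rows
        assert stats.iloc[0]["n_motif"] == 0
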