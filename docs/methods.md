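# Methods

This note records the models implemented in `mapshb`, the parameter
choices that matter, and what the synthetic generators do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Geometric definition of a hydrogen bond

A candidate is any (side-chain donor heavy atom, N/O acceptor heavy atom)
pair with heavy-atom separation R ≤ 3.2 Å, excluding same-residue pairs.
Donor atoms are the protonated side-chain sites Ser OG, Thr OG1, Tyr OH,
Trp NE1, His ND1/NE2 (whichever carries the hydrogen), Lys NZ,
Arg NE/NH1/NH2, Asn ND2 and Gln NE2; S- and C-mediated contacts and
backbone amide donors are out of scope (backbone donors form short bonds so
rarely that including them only dilutes the classes). Acceptors are every
backbone carbonyl O plus Asp OD1/OD2, Glu OE1/OE2, Asn OD1, Gln OE1,
Ser OG, Thr OG1, Tyr OH and unprotonated His ring nitrogens.

Classification is purely geometric: SHB for 2.3 ≤ R ≤ 2.7 Å, NHB for
2.8 ≤ R ≤ 3.2 Å, both with the A–H–B angle at the hydrogen ≥ 135°; every
boundary is inclusive; everything else — including the intentional
2.7–2.8 Å buffer that keeps the two classes geometrically separated — is
reported as `unlabeled` and excluded from training and evaluation.

Choices where the design was genuinely open:

* For donors with several hydrogens, the hydrogen maximizing the A–H–B
  angle defines the record (one geometry per atom pair).
* A residue pair may contribute several records (bidentate contacts such
  as a guanidinium facing both carboxylate oxygens give two).
* Bifurcated bonds (one H within range of two acceptors) keep both
  records; no deduplication.
* Group charges use pH-7 conventions: Asp/Glu carboxylates −1, Lys/Arg
  side chains +1, His and everything else 0. There is no pKa model.
* Candidate pairs come from a KD-tree spatial index; an all-pairs scan is
  available (`use_index=False`) and the test suite asserts the two are
  record-for-record identical.
* Distances and angles are rounded to 9 decimals before the window test so
  that exactly-boundary geometries classify inclusively instead of falling
  to float dust.

## Structure preparation

Parsing is delegated to gemmi. Only the first MODEL is kept; for alternate
locations the highest-occupancy conformer wins, ties toward altLoc 'A';
crystallographic waters are removed; HETATM ligands are retained outside
the residue chains. Resolution and R-factors come from the header
(REMARK 2/3); missing quality metadata warns but never fails, because
minimized or edited files routinely lack headers. The dataset-quality
filter is resolution ≤ 1.1 Å, R-factor ≤ 0.20 (0.28 in permissive mode,
for the tail of otherwise-good structures) and R-free − R-factor ≤ 0.07.

Secondary structure is assigned from backbone N–H···O=C bonds scored with
the Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, accepted below
−0.5 kcal/mol, with the amide hydrogen idealized along the preceding
C=O direction when absent. The 8-letter alphabet is collapsed to 4 classes
(helix = 3₁₀/α/π ladders, sheet = bridge patterns, turn = isolated turns,
coil = default) because the downstream feature only needs coarse classes —
in the trained models all secondary-structure features together contribute
on the order of a percent.

Polar-hydrogen placement is **opt-in** (`--place-h`), not default. O–H
bonds are built at 0.96 Å and N–H at 1.01 Å; sp² NH/NH₂ in the plane of
the attached group; Lys NH₃⁺ tetrahedral and staggered; His is protonated
on NE2 (the common neutral tautomer) unless HD1 already exists. Rotatable
hydroxyls (Ser/Thr/Tyr) are oriented by scanning the C–O torsion in 10°
steps and keeping the rotamer that maximizes the best A–H–B angle to any
N/O within 3.5 Å. That scan deliberately biases planted hydrogens toward
hydrogen-bond acceptance — good for recovering donors in stripped files,
wrong as a default for survey statistics, hence opt-in. Existing hydrogens
and heavy atoms are never moved.

## The 21 features

Nine bond-level fields (donor/acceptor residue, element, charge, acceptor
location, two secondary structures) plus twelve sequence-context fields
(residues at offsets −3…−1, +1…+3 around donor and acceptor). Context
offsets walk the chain's *serial* ordering, not author numbering, so
insertion codes and numbering gaps cannot shift the window; chain termini
pad with `TER`, non-standard residues map to `UNK` (distinct tokens:
terminus ≠ unknown). Donor and acceptor each use their own chain's
context. R and the angle are never features — they define the label, and
the model must predict shortness without seeing them.

Encoding is native-categorical (one integer-coded column per feature with
a fixed vocabulary persisted alongside the model). This keeps the tree
learner's split-gain importances attributable 1:1 to the 21 parent
features with no one-hot aggregation. Unseen categories at prediction time
map to `UNK` with a warning.

## The undersampling boosted ensemble

With ~19% SHBs, a model trained on raw data drifts toward "normal". The
remedy: for member i (i = 0…9), draw all SHBs plus a uniform
without-replacement NHB sample of equal size (seed = base seed + i, so
every member's subsample is reproducible), tune the tree depth, fit, and
average the ten predicted probabilities with equal weights.

The stagewise fit is delegated to LightGBM configured as classical
gradient boosting on binomial deviance: `n_trees` stages at learning rate
`shrinkage`, per-stage row subsampling `bag_fraction` = 0.5, and trees
limited to `interaction_depth` splits (`num_leaves = depth + 1`, grown
best-first). Determinism is forced (single thread, fixed seed,
row-wise histograms). Depth is tuned per member over a grid by stratified
k-fold cross-validation on held-out binomial deviance (misclassification
rate is a config alternative), argmin with ties to the smallest depth;
degenerate single-class folds are re-drawn with an incremented seed.

Two profiles:

* **paper** — shrinkage 0.01, 5000 stages, depths 1–15, 10 folds. This is
  the reference configuration.
* **fast** (default) — 500 stages, depths 1–6, 5 folds, shrinkage **0.05**.
  At 500 stages a 0.01 learning rate leaves the logits visibly
  under-converged (per-donor mean predicted probabilities off by up to
  0.07 on the balanced n=5000 recovery benchmark); raising the rate to
  0.05 restores a total learning budget of 25 (vs 50 for the full
  profile) and converges (max error 0.035 on the same benchmark). The
  fast profile is a desk-scale surrogate, not the reference.

Probabilities are calibrated to the balanced (50/50) prior by
construction. An optional prior correction
p′ = pπ/(pπ + (1−p)(1−π)) to a true prevalence π is provided but off by
default — the published threshold grid (0.996, 0.979, 0.943, 0.870,
0.740, 0.555, 0.062) is defined on uncorrected outputs, with 0.870 as the
recommended operating point.

Feature importances: per member, split-gain totals per feature normalized
to 100%; then an unweighted mean across members (no member weighting —
nothing suggests unequal member quality). The reporting option
`group_other=True` collapses features at ≤ 1% into a single "other" row.

## The synthetic generators

**Feature tables.** Rows are drawn independently: donor from a categorical
(uniform by default over the nine donors), acceptor backbone-vs-side-chain
(50/50 by default) and type, contexts uniform over the twenty residues,
secondary structure uniform. The SHB probability of a row is

    p = logistic( logit(base_prob[donor]) + shift · 1[anionic side-chain acceptor] )

with defaults taken from the published per-donor values — Tyr 0.86,
Ser 0.53, Thr 0.40, His 0.29, and the five N-donors at 0.10–0.13 ("below
15%"); shift = logit(0.738) − logit(0.40) ≈ 1.442 so a Thr donor facing
Asp/Glu hits its published 73.8%. Ser/Thr→Asp side-chain pairs enter the
donor–Xxx–acceptor sequence motif with rate 0.364, which overrides p to
0.825 and writes the partner's identity into the ±2 context slot. Labels
are Bernoulli draws from p.

*Class marginals without distorting conditionals.* A quota-style rejection
on (row, label) pairs would change P(SHB | donor) — under the default
table, balancing that way would inflate Tyr from 0.86 to ≈ 0.94 — so the
generator instead tilts *which rows are generated*: a candidate row is
accepted with probability ∝ p^k (k ≥ 0) or (1−p)^{−k} (k < 0), with k
solved by bisection so the expected label marginal hits the target (50/50
in balanced mode, 18.7% in prevalence mode). Acceptance never looks at the
drawn label, so P(label | row) stays exactly at the configured value; a
final trim of the over-full class (exchangeable rows, so an unbiased
subsample) gives the exact requested counts. Degenerate configurations
whose marginal cannot reach the target (e.g. all base probabilities near
zero) fall back to natural sampling with a warning.

*Interactions.* The additive log-odds shift is, by construction,
representable by an additive-in-logit model: depth-1 boosted stumps
reproduce it exactly through the `acceptor_chg` feature, and measured CV
correctly prefers depth 1 on such data. The motif override is both rare
and numerically almost identical to the additive prediction for Ser
(0.825 vs 0.827), so it cannot drive depth selection either. To exercise
depth tuning the generator therefore offers
`interaction_mode="crossed"`: p = 0.85 when exactly one of {hydroxyl/
imidazole donor, anionic acceptor} holds and 0.15 otherwise — a pure XOR
that no additive model can represent; measured CV depth on such data is
≥ 2. This is the mode the depth-tuning acceptance check uses.

**Toy structures.** A host peptide (flanking residues, the donor residue,
flanking residues) is built on an idealized backbone (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å, ω = 180°, default φ/ψ = −120°/130°; the
builder also produces α-helices for the secondary-structure tests) with a
table-driven side chain for the donor; the acceptor is a free amino acid
(chain B) whose acceptor atom is placed so the *written, 3-decimal* PDB
coordinates realize the requested R and A–H–B angle. Because rounding to
PDB precision can push an exactly-boundary geometry across its window
edge, coordinates are quantized during construction and the acceptor
fragment is shifted over a candidate grid to land R on the window side of
the edge (bias ≤ 0.004 Å, far below the 0.01 Å recovery tolerance; the
135° angle case is biased by +0.08°, far below the 0.5° tolerance).
Reverse donation from hydroxyl-acceptor fragments is suppressed by
torsion-scanning their H away from the donor; the toy Arg side chain omits
the (H-less) NH1/NH2 so no spurious donor warnings arise. Toy structures
are valid inputs to the full pipeline — read, secondary structure,
detection, featurization — with zero warnings.

What the generators do **not** emulate: realistic folds or rotamer
statistics, crystallographic noise and occupancy disorder, correlated
sequence context, water- or ligand-mediated bonds, and any energetics.
Passing the recovery tests therefore certifies the *machinery* (feature
plumbing, balancing, boosting, aggregation, thresholds) — not performance
on real structures, which depends on a curated PDB-derived training set.

## Problem sizes in the test suite

The statistical checks run at deliberately modest sizes chosen once:
parameter recovery on a balanced n = 5000 table with the full 10-member
fast-profile ensemble (tolerance ±0.05 per donor); depth detection on a
crossed-signal n = 4000 table; ranking concordance (> 0.9) at the 18.7%
prevalence on n = 3000; end-to-end determinism on n = 800 plus two toy
structures. Generator-fidelity checks use n = 10000–30000 with 3σ binomial
bands.

## Known limitations

* PDB format only (no mmCIF); fixed-width conventions; insertion codes
  kept as part of residue identity.
* No force-field minimization, no pKa prediction, no ligand protonation;
  His tautomer defaults to NE2-H when placing hydrogens.
* The 4-class secondary structure is a coarse collapse; π-helix vs 3₁₀ is
  not distinguished (nor needed downstream).
* Inter-chain bonds use each partner's own chain context; the |Δseq| = 2
  motif flag applies only within one chain.
* Published headline performance (precision/recall at the recommended
  threshold on the authors' test pool) requires the original PDB-derived
  dataset and is not reproducible from synthetic data; the pipeline
  reports those metrics for whatever labeled data it is given.
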