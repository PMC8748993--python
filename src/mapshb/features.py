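"""Encoding of hydrogen bonds as 21 categorical predictors.

Each bond is described by nine bond-level fields — donor and acceptor
residue types, heteroatom elements (N/O), group charges, acceptor location
(backbone/side chain), donor and acceptor secondary structure — plus the
residue identities at sequence offsets -3..-1 and +1..+3 around the donor
and around the acceptor (twelve context fields). Positions beyond a chain
terminus are padded with the token TER; non-standard residues map to UNK.
The bond geometry (R, angle) defines the label and is deliberately never a
predictor: the model must infer shortness from chemistry and sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .hbond import HBondRecord, detect_hydrogen_bonds
from .structure_io import STANDARD_RESIDUES, ProteinStructure, Residue

logger = logging.getLogger(__name__)

TER = "TER"  # chain-terminus padding token
UNK = "UNK"  # unknown / non-standard residue token

AA3 = sorted(STANDARD_RESIDUES)

BOND_FIELDS = [
    "donor_res", "acceptor_res", "donor_elem", "acceptor_elem",
    "donor_chg", "acceptor_chg", "acceptor_loc", "donor_ss", "acceptor_ss",
]
DONOR_CTX = ["d_m3", "d_m2", "d_m1", "d_p1", "d_p2", "d_p3"]
ACCEPTOR_CTX = ["a_m3", "a_m2", "a_m1", "a_p1", "a_p2", "a_p3"]
FEATURE_COLUMNS = BOND_FIELDS + DONOR_CTX + ACCEPTOR_CTX
LABEL_COLUMN = "label"

assert len(FEATURE_COLUMNS) == 21

RESIDUE_VOCAB = AA3 + [UNK]
CONTEXT_VOCAB = AA3 + [TER, UNK]

VOCABULARIES: dict[str, list[str]] = {
    "donor_res": RESIDUE_VOCAB,
    "acceptor_res": RESIDUE_VOCAB,
    "donor_elem": ["N", "O", UNK],
    "acceptor_elem": ["N", "O", UNK],
    "donor_chg": ["-1", "0", "+1", UNK],
    "acceptor_chg": ["-1", "0", "+1", UNK],
    "acceptor_loc": ["backbone", "side_chain", UNK],
    "donor_ss": ["helix", "sheet", "turn", "coil", UNK],
    "acceptor_ss": ["helix", "sheet", "turn", "coil", UNK],
    **{c: CONTEXT_VOCAB for c in DONOR_CTX + ACCEPTOR_CTX},
}


class EncodingError(ValueError):
    """Raised when a record cannot be featurized or violates the schema."""


@dataclass
class FeatureVector:
    """The 21 categorical predictors for one hydrogen bond."""

    values: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.values]
        extra = [c for c in self.values if c not in FEATURE_COLUMNS]
        if missing or extra:
            raise EncodingError(
                f"feature vector must have exactly the 21 fields; "
                f"missing={missing} extra={extra}"
            )

    def __getitem__(self, key: str) -> str:
        return self.values[key]

    def as_row(self) -> dict[str, str]:
        return {c: self.values[c] for c in FEATURE_COLUMNS}


@dataclass
class LabeledDataset:
    """Feature rows plus binary labels (SHB=1, NHB=0) and provenance."""

    table: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols != FEATURE_COLUMNS + [LABEL_COLUMN]:
            raise EncodingError(
                f"dataset columns must be the 21 features + '{LABEL_COLUMN}', got {cols}"
            )
        bad = set(self.table[LABEL_COLUMN].unique()) - {"SHB", "NHB"}
        if bad:
            raise EncodingError(f"unlabeled or invalid labels in dataset: {sorted(bad)}")
        for col in FEATURE_COLUMNS:
            vocab = set(VOCABULARIES[col])
            seen = set(self.table[col].astype(str).unique())
            offending = seen - vocab
            if offending:
                raise EncodingError(
                    f"column {col} contains out-of-vocabulary value(s) {sorted(offending)}"
                )

    @property
    def X(self) -> pd.DataFrame:
        return self.table[FEATURE_COLUMNS]

    @property
    def y(self) -> np.ndarray:
        return (self.table[LABEL_COLUMN] == "SHB").to_numpy(dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(n_shb, n_nhb)."""
        y = self.y
        return int(y.sum()), int(len(y) - y.sum())

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, provenance: Optional[list[str]] = None) -> "LabeledDataset":
        table = pd.read_csv(path, sep="\t", dtype=str)
        n_unlabeled = int((~table[LABEL_COLUMN].isin(["SHB", "NHB"])).sum())
        if n_unlabeled:
            logger.info("%d unlabeled row(s) dropped", n_unlabeled)
            table = table[table[LABEL_COLUMN].isin(["SHB", "NHB"])]
        return cls(table.reset_index(drop=True), provenance or [str(path)])


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _context(chain: Sequence[Residue], serial: int, offset: int) -> str:
    pos = serial + offset
    if pos < 0 or pos >= len(chain):
        return TER
    name = chain[pos].name
    return name if name in STANDARD_RESIDUES else UNK


def extract_features(rec: HBondRecord, s: ProteinStructure) -> FeatureVector:
    """Build the 21-feature vector for one detected hydrogen bond.

    Context offsets walk the chain's serial ordering (not author numbering),
    so numbering gaps and insertion codes cannot shift the window; donor and
    acceptor each use their own chain.
    """
    d_res, a_res = rec.donor.residue, rec.acceptor.residue
    d_chain = s.chains.get(d_res.chain_id)
    a_chain = s.chains.get(a_res.chain_id)
    if (
        d_chain is None or a_chain is None
        or d_res.serial_index < 0 or a_res.serial_index < 0
        or d_res.serial_index >= len(d_chain) or a_res.serial_index >= len(a_chain)
        or d_chain[d_res.serial_index] is not d_res
        or a_chain[a_res.serial_index] is not a_res
    ):
        raise EncodingError(
            f"record {d_res.label}->{a_res.label} does not resolve in "
            f"structure {s.structure_id}"
        )
    if d_res.secondary_structure is None or a_res.secondary_structure is None:
        raise EncodingError(
            f"record {d_res.label}->{a_res.label}: secondary structure not assigned"
        )

    values = {
        "donor_res": d_res.name if d_res.name in STANDARD_RESIDUES else UNK,
        "acceptor_res": a_res.name if a_res.name in STANDARD_RESIDUES else UNK,
        "donor_elem": rec.donor.heavy_atom.element,
        "acceptor_elem": rec.acceptor.heavy_atom.element,
        "donor_chg": _fmt_charge(rec.donor.group_charge),
        "acceptor_chg": _fmt_charge(rec.acceptor.group_charge),
        "acceptor_loc": rec.acceptor.location,
        "donor_ss": d_res.secondary_structure,
        "acceptor_ss": a_res.secondary_structure,
    }
    for col, off in zip(DONOR_CTX, (-3, -2, -1, 1, 2, 3)):
        values[col] = _context(d_chain, d_res.serial_index, off)
    for col, off in zip(ACCEPTOR_CTX, (-3, -2, -1, 1, 2, 3)):
        values[col] = _context(a_chain, a_res.serial_index, off)
    return FeatureVector(values)


def _fmt_charge(c: int) -> str:
    return {-1: "-1", 0: "0", 1: "+1"}[c]


def build_dataset(
    structures: Iterable[ProteinStructure],
    records_per_structure: Optional[dict[str, list[HBondRecord]]] = None,
) -> LabeledDataset:
    """Featurize all labeled hydrogen bonds of the given structures.

    Detection is run on the fly unless pre-computed records are supplied.
    Unlabeled (gap or bad-angle) records are dropped with a logged count;
    row order follows the sorted detection order, so the result is
    deterministic for identical inputs.
    """
    rows: list[dict[str, str]] = []
    provenance: list[str] = []
    n_unlabeled = 0
    for s in structures:
        provenance.append(s.structure_id)
        if records_per_structure is not None:
            records = records_per_structure.get(s.structure_id, [])
        else:
            records = detect_hydrogen_bonds(s)
        for rec in records:
            if rec.label not in ("SHB", "NHB"):
                n_unlabeled += 1
                continue
            row = extract_features(rec, s).as_row()
            row[LABEL_COLUMN] = rec.label
            rows.append(row)
    if n_unlabeled:
        logger.info("%d unlabeled record(s) dropped during dataset build", n_unlabeled)
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS + [LABEL_COLUMN])
    return LabeledDataset(table, provenance)


# ---------------------------------------------------------------------------
# categorical encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodingMap:
    """Fixed vocabulary order per feature; persists with trained models."""

    categories: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {"categories": self.categories}

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingMap":
        return cls(categories={k: list(v) for k, v in d["categories"].items()})


def default_encoding_map() -> EncodingMap:
    return EncodingMap(categories={c: list(VOCABULARIES[c]) for c in FEATURE_COLUMNS})


def encode_categoricals(
    X: pd.DataFrame, encoding: Optional[EncodingMap] = None
) -> tuple[pd.DataFrame, EncodingMap]:
    """Encode feature columns as ordered pandas categoricals.

    Native categorical codes (one column per parent feature) keep the tree
    learner's split-gain importances directly attributable to the 21
    features, with no one-hot aggregation step. Values outside a column's
    vocabulary are mapped to UNK with a warning (prediction-time safety
    valve); encode -> decode is the identity for in-vocabulary rows.
    """
    encoding = encoding or default_encoding_map()
    out = {}
    for col in FEATURE_COLUMNS:
        cats = encoding.categories[col]
        series = X[col].astype(str)
        unseen = set(series.unique()) - set(cats)
        if unseen:
            warnings.warn(
                f"column {col}: unseen categorie(s) {sorted(unseen)} mapped to {UNK}"
            )
            series = series.where(series.isin(cats), UNK)
        out[col] = pd.Categorical(series, categories=cats)
    return pd.DataFrame(out, index=X.index), encoding


def decode_categoricals(X_enc: pd.DataFrame) -> pd.DataFrame:
    return X_enc.astype(str)
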