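"""Hydrogen-bond detection and geometric SHB/NHB classification.

A short hydrogen bond (SHB) is a donor-acceptor contact with heavy-atom
separation R between 2.3 and 2.7 A; a normal hydrogen bond (NHB) has R
between 2.8 and 3.2 A; both require the donor-H-acceptor angle (vertex at
the hydrogen) to be at least 135 degrees, and both heteroatoms to be N or
O. The 2.7-2.8 A gap is deliberate and such contacts stay unlabeled.

Donors are side-chain N/O groups only (backbone amides form short bonds so
rarely that they are excluded from the problem); acceptors are backbone
carbonyl oxygens and side-chain N/O groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import angle_at, distance
from .structure_io import Atom, ProteinStructure, Residue

__all__ = [
    "DonorGroup",
    "AcceptorGroup",
    "HBondRecord",
    "SHB_R_MIN", "SHB_R_MAX", "NHB_R_MIN", "NHB_R_MAX", "MIN_ANGLE",
    "enumerate_donors",
    "enumerate_acceptors",
    "classify_geometry",
    "detect_hydrogen_bonds",
    "records_to_table",
    "summarize_dataset",
    "pair_statistics",
]

SHB_R_MIN, SHB_R_MAX = 2.3, 2.7
NHB_R_MIN, NHB_R_MAX = 2.8, 3.2
MIN_ANGLE = 135.0
DETECT_CUTOFF = NHB_R_MAX  # heavy-atom pair screen, also the grid cell size

# side-chain donor heavy atoms and the hydrogen names that ride on them
SIDE_CHAIN_DONORS: dict[tuple[str, str], tuple[str, ...]] = {
    ("SER", "OG"): ("HG",),
    ("THR", "OG1"): ("HG1",),
    ("TYR", "OH"): ("HH",),
    ("TRP", "NE1"): ("HE1",),
    ("HIS", "ND1"): ("HD1",),
    ("HIS", "NE2"): ("HE2",),
    ("LYS", "NZ"): ("HZ1", "HZ2", "HZ3"),
    ("ARG", "NE"): ("HE",),
    ("ARG", "NH1"): ("HH11", "HH12"),
    ("ARG", "NH2"): ("HH21", "HH22"),
    ("ASN", "ND2"): ("HD21", "HD22"),
    ("GLN", "NE2"): ("HE21", "HE22"),
}

# side-chain acceptor heavy atoms; His N acceptors require the unprotonated N
SIDE_CHAIN_ACCEPTORS: dict[tuple[str, str], int] = {
    ("ASP", "OD1"): -1,
    ("ASP", "OD2"): -1,
    ("GLU", "OE1"): -1,
    ("GLU", "OE2"): -1,
    ("ASN", "OD1"): 0,
    ("GLN", "OE1"): 0,
    ("SER", "OG"): 0,
    ("THR", "OG1"): 0,
    ("TYR", "OH"): 0,
    ("HIS", "ND1"): 0,
    ("HIS", "NE2"): 0,
}

_DONOR_CHARGE = {"LYS": +1, "ARG": +1}


@dataclass(frozen=True)
class DonorGroup:
    residue: Residue
    heavy_atom: Atom
    hydrogens: tuple[Atom, ...]
    group_charge: int = 0
    location: str = "side_chain"


@dataclass(frozen=True)
class AcceptorGroup:
    residue: Residue
    heavy_atom: Atom
    location: str  # backbone | side_chain
    group_charge: int = 0


@dataclass
class HBondRecord:
    donor: DonorGroup
    acceptor: AcceptorGroup
    R: float
    angle: float
    h_used: Atom
    label: str  # SHB | NHB | unlabeled
    structure_id: str

    def sort_key(self):
        d, a = self.donor.residue, self.acceptor.residue
        return (
            self.structure_id, d.chain_id, d.serial_index, self.donor.heavy_atom.name,
            a.chain_id, a.serial_index, self.acceptor.heavy_atom.name,
        )


def _attached_h(res: Residue, heavy: Atom, names: Sequence[str]) -> list[Atom]:
    """Hydrogens bonded to `heavy`: canonical names first, else any H within 1.3 A."""
    out = [a for n in names for a in res.atoms if a.name == n and a.is_hydrogen]
    if not out:
        out = [
            a for a in res.atoms
            if a.is_hydrogen and distance(a.coords, heavy.coords) <= 1.3
        ]
    return out


def enumerate_donors(s: ProteinStructure) -> list[DonorGroup]:
    """List all usable side-chain donor groups (protonated N/O side chains).

    Covers Ser OG, Thr OG1, Tyr OH, Trp NE1, His ND1/NE2 (whichever carries
    a hydrogen), Lys NZ, Arg NE/NH1/NH2, Asn ND2 and Gln NE2. Donor atoms
    without any attached hydrogen are skipped with a warning. Cys SG and
    C-H groups never donate; the backbone N is never a donor.
    """
    donors: list[DonorGroup] = []
    for res in s.standard_residues():
        for (resname, atom_name), h_names in SIDE_CHAIN_DONORS.items():
            if res.name != resname:
                continue
            heavy = res.atom(atom_name)
            if heavy is None:
                continue
            hydrogens = _attached_h(res, heavy, h_names)
            if not hydrogens:
                # an unprotonated His ring nitrogen is simply the acceptor
                # side of the tautomer, not a defective donor
                if resname != "HIS":
                    warnings.warn(
                        f"{res.label}: donor atom {atom_name} has no hydrogen; skipped"
                    )
                continue
            donors.append(
                DonorGroup(
                    residue=res,
                    heavy_atom=heavy,
                    hydrogens=tuple(hydrogens),
                    group_charge=_DONOR_CHARGE.get(resname, 0),
                )
            )
    return donors


def enumerate_acceptors(s: ProteinStructure) -> list[AcceptorGroup]:
    """List all N/O acceptor groups: backbone carbonyl O plus side-chain sites.

    Carboxylate oxygens of Asp/Glu carry charge -1; His ring nitrogens
    accept only when unprotonated; all other acceptors are neutral.
    """
    acceptors: list[AcceptorGroup] = []
    for res in s.standard_residues():
        bb_o = res.atom("O")
        if bb_o is not None:
            acceptors.append(
                AcceptorGroup(residue=res, heavy_atom=bb_o, location="backbone")
            )
        for (resname, atom_name), charge in SIDE_CHAIN_ACCEPTORS.items():
            if res.name != resname:
                continue
            heavy = res.atom(atom_name)
            if heavy is None:
                continue
            if resname == "HIS" and _attached_h(res, heavy, ()):
                continue  # protonated ring N donates, does not accept
            acceptors.append(
                AcceptorGroup(
                    residue=res,
                    heavy_atom=heavy,
                    location="side_chain",
                    group_charge=charge,
                )
            )
    return acceptors


def classify_geometry(R: float, angle: float) -> str:
    """Classify a contact as 'SHB', 'NHB' or 'unlabeled' from (R, angle).

    All window boundaries are inclusive; the 2.7 < R < 2.8 A gap and any
    angle below 135 degrees yield 'unlabeled'.
    """
    if R <= 0:
        raise ValueError(f"donor-acceptor distance must be positive, got {R}")
    if angle >= MIN_ANGLE:
        if SHB_R_MIN <= R <= SHB_R_MAX:
            return "SHB"
        if NHB_R_MIN <= R <= NHB_R_MAX:
            return "NHB"
    return "unlabeled"


def detect_hydrogen_bonds(
    s: ProteinStructure, use_index: bool = True
) -> list[HBondRecord]:
    """Detect all side-chain-donor hydrogen bonds in a structure.

    Every donor/acceptor heavy-atom pair with R <= 3.2 A is evaluated
    (same-residue pairs excluded); candidate pairs come from a KD-tree
    spatial index unless ``use_index`` is False, in which case all pairs
    are scanned (the two are record-for-record equivalent). For donors with
    several hydrogens the hydrogen maximizing the donor-H-acceptor angle
    defines the record. Output is sorted by structure, donor and acceptor.
    """
    donors = enumerate_donors(s)
    acceptors = enumerate_acceptors(s)
    if not donors:
        has_any_h = any(a.is_hydrogen for _, a in s.atoms())
        if not has_any_h:
            raise ValueError(
                "no donors usable: structure has no hydrogens "
                "(add explicit hydrogens or enable placement)"
            )
        return []
    if not acceptors:
        return []

    if use_index and acceptors:
        tree = cKDTree(np.array([a.heavy_atom.coords for a in acceptors]))
        d_coords = np.array([d.heavy_atom.coords for d in donors])
        # epsilon keeps pairs at exactly the cutoff (inclusive boundary)
        neighbor_lists = tree.query_ball_point(d_coords, DETECT_CUTOFF + 1e-6)
    else:
        neighbor_lists = [range(len(acceptors))] * len(donors)

    records: list[HBondRecord] = []
    for d, neigh in zip(donors, neighbor_lists):
        for ai in neigh:
            a = acceptors[ai]
            if a.residue is d.residue:
                continue
            # round away float dust so exact window boundaries stay inclusive
            r = round(distance(d.heavy_atom.coords, a.heavy_atom.coords), 9)
            if r > DETECT_CUTOFF or r < 1e-6:
                continue
            best_h, best_angle = None, -1.0
            for h in d.hydrogens:
                ang = round(
                    angle_at(d.heavy_atom.coords, h.coords, a.heavy_atom.coords), 9
                )
                if ang > best_angle:
                    best_h, best_angle = h, ang
            records.append(
                HBondRecord(
                    donor=d,
                    acceptor=a,
                    R=r,
                    angle=best_angle,
                    h_used=best_h,
                    label=classify_geometry(r, best_angle),
                    structure_id=s.structure_id,
                )
            )
    records.sort(key=HBondRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# tabulation and statistics
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "structure_id", "chain_d", "resi_d", "resn_d", "atom_d",
    "chain_a", "resi_a", "resn_a", "atom_a",
    "acceptor_location", "R", "angle", "label",
]


def records_to_table(records: Iterable[HBondRecord]) -> pd.DataFrame:
    """Flatten records to the TSV schema (R to 3 decimals, angle to 1)."""
    rows = []
    for r in records:
        d, a = r.donor.residue, r.acceptor.residue
        rows.append(
            {
                "structure_id": r.structure_id,
                "chain_d": d.chain_id,
                "resi_d": f"{d.seq_index}{d.insertion_code}",
                "resn_d": d.name,
                "atom_d": r.donor.heavy_atom.name,
                "chain_a": a.chain_id,
                "resi_a": f"{a.seq_index}{a.insertion_code}",
                "resn_a": a.name,
                "atom_a": r.acceptor.heavy_atom.name,
                "acceptor_location": r.acceptor.location,
                "R": round(r.R, 3),
                "angle": round(r.angle, 1),
                "label": r.label,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _shb_fraction(n_shb: int, n_nhb: int) -> Optional[float]:
    total = n_shb + n_nhb
    if total == 0:
        return None
    return round(100.0 * n_shb / total, 1)


def summarize_dataset(records_or_counts) -> pd.DataFrame:
    """Count SHBs/NHBs and the SHB percentage, overall and per acceptor location.

    Accepts either an iterable of :class:`HBondRecord` / a records table,
    or a plain ``(n_shb, n_nhb)`` tuple. The SHB fraction is
    nSHB/(nSHB+nNHB) as a percentage rounded to one decimal; with no
    labeled records it is reported as missing (NaN), never as zero.
    """
    if (
        isinstance(records_or_counts, tuple)
        and len(records_or_counts) == 2
        and all(isinstance(x, (int, np.integer)) for x in records_or_counts)
    ):
        n_shb, n_nhb = records_or_counts
        rows = [
            {"group": "overall", "n_shb": n_shb, "n_nhb": n_nhb,
             "shb_percent": _shb_fraction(n_shb, n_nhb)}
        ]
        return pd.DataFrame(rows)

    if isinstance(records_or_counts, pd.DataFrame):
        table = records_or_counts
    else:
        table = records_to_table(records_or_counts)
    rows = []
    def _row(group: str, sub: pd.DataFrame):
        n_shb = int((sub["label"] == "SHB").sum())
        n_nhb = int((sub["label"] == "NHB").sum())
        rows.append(
            {"group": group, "n_shb": n_shb, "n_nhb": n_nhb,
             "shb_percent": _shb_fraction(n_shb, n_nhb)}
        )
    _row("overall", table)
    for loc, sub in table.groupby("acceptor_location"):
        _row(loc, sub)
    return pd.DataFrame(rows)


def pair_statistics(records_or_table) -> pd.DataFrame:
    """Per donor-residue/acceptor-residue statistics of SHB propensity.

    For each (donor residue type, acceptor residue type): the number of
    hydrogen bonds, the SHB probability among labeled bonds, and the
    median R of the SHBs and of the NHBs. A separate ``motif`` block
    reports the same-chain |dseq| = 2 pairs (donor-Xxx-acceptor sequence
    motif) and their SHB probability.
    """
    if isinstance(records_or_table, pd.DataFrame):
        table = records_or_table.copy()
        if "seq_sep" not in table.columns:
            table["seq_sep"] = np.where(
                table["chain_d"] == table["chain_a"],
                pd.to_numeric(table["resi_d"], errors="coerce")
                - pd.to_numeric(table["resi_a"], errors="coerce"),
                np.nan,
            )
    else:
        records = list(records_or_table)
        table = records_to_table(records)
        seps = []
        for r in records:
            d, a = r.donor.residue, r.acceptor.residue
            seps.append(
                d.serial_index - a.serial_index if d.chain_id == a.chain_id else np.nan
            )
        table["seq_sep"] = seps

    if table.empty:
        return pd.DataFrame(
            columns=["resn_d", "resn_a", "n", "shb_prob", "median_r_shb",
                     "median_r_nhb", "n_motif", "shb_prob_motif"]
        )

    labeled = table[table["label"].isin(["SHB", "NHB"])]
    out = []
    for (dn, an), sub in labeled.groupby(["resn_d", "resn_a"]):
        n = len(sub)
        n_shb = int((sub["label"] == "SHB").sum())
        shb = sub[sub["label"] == "SHB"]["R"]
        nhb = sub[sub["label"] == "NHB"]["R"]
        motif = sub[np.abs(sub["seq_sep"]) == 2]
        out.append(
            {
                "resn_d": dn,
                "resn_a": an,
                "n": n,
                "shb_prob": round(100.0 * n_shb / n, 1),
                "median_r_shb": round(float(shb.median()), 3) if len(shb) else np.nan,
                "median_r_nhb": round(float(nhb.median()), 3) if len(nhb) else np.nan,
                "n_motif": int(len(motif)),
                "shb_prob_motif": (
                    round(100.0 * float((motif["label"] == "SHB").mean()), 1)
                    if len(motif) else np.nan
                ),
            }
        )
    return (
        pd.DataFrame(out)
        .sort_values(["resn_d", "resn_a"])
        .reset_index(drop=True)
    )
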