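"""Reading, validation and preparation of protein structures in PDB format.

This module turns a PDB file into a lightweight :class:`ProteinStructure`
(chains of residues of atoms), applies the crystallographic quality filters
used to assemble high-resolution hydrogen-bond datasets, optionally places
idealized polar hydrogens on side-chain donor groups, and assigns a coarse
four-state secondary structure (helix / sheet / turn / coil) from backbone
hydrogen-bond patterns.

Parsing is delegated to :mod:`gemmi`; only the first MODEL is kept, the
highest-occupancy alternate conformer wins (ties go to altLoc 'A'), and
crystallographic waters are dropped.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from ._geometry import angle_at, distance, place_atom, unit

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

KNOWN_ELEMENTS = {
    "H", "D", "C", "N", "O", "S", "P", "SE", "F", "CL", "BR", "I",
    "FE", "ZN", "MG", "MN", "CA", "NA", "K", "CU", "NI", "CO", "X",
}

SS_CLASSES = ("helix", "sheet", "turn", "coil")

# Kabsch-Sander electrostatic H-bond model: partial charges +-0.20e / +-0.42e,
# dimensional factor 332 kcal*A/mol, bond accepted below -0.5 kcal/mol.
_KS_Q1Q2_F = 0.084 * 332.0
_KS_CUTOFF = -0.5


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


@dataclass
class Atom:
    """One atom: PDB name, element symbol, coordinates in Angstroms."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        self.element = self.element.upper()
        if self.element not in KNOWN_ELEMENTS:
            raise ValueError(f"atom {self.name}: unknown element {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """One residue with author numbering preserved and a serial index."""

    name: str
    chain_id: str
    seq_index: int              # author residue number
    insertion_code: str = ""
    serial_index: int = -1      # 0-based position within the chain
    atoms: list[Atom] = field(default_factory=list)
    secondary_structure: Optional[str] = None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_index}{self.insertion_code}"


@dataclass
class QualityMetadata:
    """Crystallographic quality descriptors parsed from PDB header remarks."""

    resolution: Optional[float] = None
    r_factor: Optional[float] = None
    r_free: Optional[float] = None

    def __post_init__(self) -> None:
        for f in ("resolution", "r_factor", "r_free"):
            v = getattr(self, f)
            if v is not None and v <= 0 and not (f == "r_free" and v == 0):
                raise ValueError(f"{f} must be positive, got {v}")


@dataclass
class ProteinStructure:
    """Parsed single-model protein structure."""

    structure_id: str
    chains: dict[str, list[Residue]]
    quality: QualityMetadata = field(default_factory=QualityMetadata)
    source_experiment: str = "other"
    molecule_name: str = ""
    hetero_residues: list[Residue] = field(default_factory=list)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def standard_residues(self) -> Iterator[Residue]:
        for r in self.residues():
            if r.is_standard:
                yield r

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a


@dataclass
class QualityReport:
    passed: bool
    reasons: list[str]
    warnings: list[str]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_RE_RWORK = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")
_RE_RALL = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING \+ TEST SET\)\s*:\s*([0-9.]+)")
_RE_RFREE = re.compile(r"REMARK   3\s+FREE R VALUE\s+:\s*([0-9.]+)")


def _pick_conformers(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken by altLoc 'A' first."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc if a.altloc != "\0" else ""))
        kept.append(group[0])
    return kept


def read_structure(path: str | Path, structure_id: Optional[str] = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only the first MODEL is used; for alternate locations the
    highest-occupancy conformer is kept (ties resolved toward altLoc 'A');
    crystallographic waters (HOH/DOD/WAT) are removed; HETATM ligand records
    are retained separately in ``hetero_residues`` and never enter the
    residue chains. Resolution and R-factors are read from REMARK 2/3 when
    present.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")

    st.setup_entities()
    quality = _parse_quality(st)
    expt = _experiment_kind(st)
    try:
        title = st.info["_struct.title"]
    except (KeyError, TypeError):
        title = ""
    name = " ".join(str(title).lower().split())

    chains: dict[str, list[Residue]] = {}
    hetero: list[Residue] = []
    model = st[0]
    for gchain in model:
        chain_id = gchain.name or "A"
        for gres in gchain:
            resname = gres.name.strip().upper()
            if resname in ("HOH", "DOD", "WAT"):
                continue
            atoms = []
            for ga in _pick_conformers(gres):
                elem = ga.element.name.upper() or "X"
                if elem not in KNOWN_ELEMENTS:
                    elem = "X"
                altloc = "" if ga.altloc in ("\0", " ") else ga.altloc
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=elem,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        alt_loc=altloc,
                    )
                )
            residue = Residue(
                name=resname,
                chain_id=chain_id,
                seq_index=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                atoms=atoms,
            )
            if resname in STANDARD_RESIDUES:
                chains.setdefault(chain_id, []).append(residue)
            else:
                hetero.append(residue)

    for chain_id, residues in chains.items():
        for i, r in enumerate(residues):
            r.serial_index = i

    n_std = sum(len(c) for c in chains.values())
    if n_std == 0:
        raise StructureError(f"{path}: structure contains no standard amino-acid residues")

    sid = structure_id or (st.name.strip() if st.name.strip() else path.stem)
    return ProteinStructure(
        structure_id=sid.lower(),
        chains=chains,
        quality=quality,
        source_experiment=expt,
        molecule_name=name,
        hetero_residues=hetero,
    )


def _parse_quality(st: gemmi.Structure) -> QualityMetadata:
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    r_factor = r_free = None
    for ref in st.meta.refinement:
        if ref.r_work == ref.r_work and ref.r_work > 0:  # not NaN
            r_factor = ref.r_work
        if ref.r_free == ref.r_free and ref.r_free > 0:
            r_free = ref.r_free
    if r_factor is None or r_free is None:
        remarks = "\n".join(st.raw_remarks)
        if r_factor is None:
            m = _RE_RWORK.search(remarks) or _RE_RALL.search(remarks)
            if m:
                r_factor = float(m.group(1))
        if r_free is None:
            m = _RE_RFREE.search(remarks)
            if m:
                r_free = float(m.group(1))
    return QualityMetadata(resolution=resolution, r_factor=r_factor, r_free=r_free)


def _experiment_kind(st: gemmi.Structure) -> str:
    raw = ""
    try:
        raw = st.info["_exptl.method"]
    except (KeyError, TypeError):
        pass
    raw = (raw or "").upper()
    if "X-RAY" in raw:
        return "xray"
    if "NEUTRON" in raw:
        return "neutron"
    return "other"


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_structure(s: ProteinStructure, path: str | Path) -> None:
    """Write the structure back out as fixed-width PDB ATOM records."""
    path = Path(path)
    lines = []
    if s.molecule_name:
        lines.append(f"TITLE     {s.molecule_name.upper():<60s}")
    serial = 0
    for chain_id in s.chains:
        for res in s.chains[chain_id]:
            for a in res.atoms:
                serial += 1
                lines.append(_atom_line(serial, a, res, "ATOM"))
        lines.append(f"TER   {serial + 1:5d}")
    for res in s.hetero_residues:
        for a in res.atoms:
            serial += 1
            lines.append(_atom_line(serial, a, res, "HETATM"))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _atom_line(serial: int, a: Atom, res: Residue, record: str) -> str:
    name = a.name
    # PDB rule: 1-letter elements start in column 14 unless the name is 4 chars
    if len(name) < 4:
        name = (" " + name) if len(a.element) == 1 else name
    elem = a.element if a.element != "D" else "H"
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{'':1s}{res.name:<3s} {res.chain_id[:1]}"
        f"{res.seq_index:4d}{res.insertion_code[:1] or ' ':1s}   "
        f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
        f"{a.occupancy:6.2f}{0.0:6.2f}          {elem:>2s}"
    )


# ---------------------------------------------------------------------------
# quality validation
# ---------------------------------------------------------------------------

def validate_quality(
    q: QualityMetadata,
    max_resolution: float = 1.1,
    max_r_factor: float = 0.20,
    max_r_gap: float = 0.07,
    permissive: bool = False,
) -> QualityReport:
    """Check a structure's crystallographic quality against dataset filters.

    Pass requires resolution <= ``max_resolution`` (default 1.1 A),
    R-factor <= ``max_r_factor`` (default 0.20; 0.28 in permissive mode) and
    R-free - R-factor <= ``max_r_gap`` (default 0.07). Missing fields yield
    warnings, never failures.
    """
    if max_resolution <= 0 or max_r_factor <= 0 or max_r_gap <= 0:
        raise ValueError("quality thresholds must be positive")
    if permissive:
        max_r_factor = max(max_r_factor, 0.28)
    reasons: list[str] = []
    warns: list[str] = []
    if q.resolution is None:
        warns.append("resolution missing")
    elif q.resolution > max_resolution:
        reasons.append(f"resolution {q.resolution:.2f} A > {max_resolution:.2f} A")
    if q.r_factor is None:
        warns.append("r_factor missing")
    elif q.r_factor > max_r_factor:
        reasons.append(f"r_factor {q.r_factor:.3f} > {max_r_factor:.2f}")
    if q.r_free is None:
        warns.append("r_free missing")
    elif q.r_factor is not None and (q.r_free - q.r_factor) > max_r_gap:
        reasons.append(
            f"r_free - r_factor gap {q.r_free - q.r_factor:.3f} > {max_r_gap:.2f}"
        )
    return QualityReport(passed=not reasons, reasons=reasons, warnings=warns)


# ---------------------------------------------------------------------------
# polar hydrogen placement
# ---------------------------------------------------------------------------

OH_BOND = 0.96
NH_BOND = 1.01

# donor heavy atom -> (hydrogen names, geometry kind, reference atoms)
_PLACEMENT_RULES: dict[tuple[str, str], dict] = {
    ("SER", "OG"): {"h": ["HG"], "kind": "hydroxyl", "refs": ("CB", "CA")},
    ("THR", "OG1"): {"h": ["HG1"], "kind": "hydroxyl", "refs": ("CB", "CA")},
    ("TYR", "OH"): {"h": ["HH"], "kind": "hydroxyl", "refs": ("CZ", "CE1")},
    ("TRP", "NE1"): {"h": ["HE1"], "kind": "sp2_bisector", "refs": ("CD1", "CE2")},
    ("HIS", "NE2"): {"h": ["HE2"], "kind": "sp2_bisector", "refs": ("CD2", "CE1")},
    ("LYS", "NZ"): {"h": ["HZ1", "HZ2", "HZ3"], "kind": "sp3_nh3", "refs": ("CE", "CD")},
    ("ARG", "NE"): {"h": ["HE"], "kind": "sp2_bisector", "refs": ("CD", "CZ")},
    ("ARG", "NH1"): {"h": ["HH11", "HH12"], "kind": "sp2_nh2", "refs": ("CZ", "NE")},
    ("ARG", "NH2"): {"h": ["HH21", "HH22"], "kind": "sp2_nh2", "refs": ("CZ", "NE")},
    ("ASN", "ND2"): {"h": ["HD21", "HD22"], "kind": "sp2_nh2", "refs": ("CG", "OD1")},
    ("GLN", "NE2"): {"h": ["HE21", "HE22"], "kind": "sp2_nh2", "refs": ("CD", "OE1")},
}


def place_polar_hydrogens(s: ProteinStructure) -> ProteinStructure:
    """Add idealized hydrogens to side-chain donor heavy atoms lacking them.

    O-H bonds are built at 0.96 A and N-H at 1.01 A. Hydrogens on sp2
    nitrogens are placed in the plane of the attached group; Lys NZ gets a
    tetrahedral NH3+. Rotatable hydroxyls (Ser OG, Thr OG1, Tyr OH) are
    oriented by scanning the hydroxyl torsion in 10 degree steps and keeping
    the rotamer that maximizes the best donor-H-acceptor angle to any N/O
    atom within 3.5 A. Existing hydrogens and all heavy atoms are left
    untouched. His is protonated on NE2 only (the common neutral tautomer)
    unless the file already carries HD1.

    The torsion scan biases planted geometries toward hydrogen-bond
    acceptance, which is why the detection pipeline treats placement as
    opt-in rather than default.
    """
    heavy_positions = [
        (r, a.coords)
        for r, a in s.atoms()
        if a.element in ("N", "O")
    ]
    for res in s.standard_residues():
        for (resname, heavy_name), rule in _PLACEMENT_RULES.items():
            if res.name != resname:
                continue
            if resname == "HIS" and heavy_name == "NE2" and res.has_atom("HD1"):
                continue  # ND1-protonated tautomer already present
            heavy = res.atom(heavy_name)
            if heavy is None:
                continue
            existing = _attached_hydrogens(res, heavy)
            if len(existing) >= len(rule["h"]):
                continue
            refs = [res.atom(n) for n in rule["refs"]]
            if any(r is None for r in refs):
                warnings.warn(
                    f"{res.label}: missing parent atom for {heavy_name}; donor skipped"
                )
                continue
            new_h = _build_hydrogens(heavy, refs, rule, heavy_positions, res)
            wanted = [h for h in rule["h"] if not res.has_atom(h)]
            for name, pos in zip(wanted, new_h[: len(wanted)]):
                res.atoms.append(Atom(name=name, element="H", coords=pos))
    return s


def _attached_hydrogens(res: Residue, heavy: Atom, max_dist: float = 1.3) -> list[Atom]:
    return [
        a for a in res.atoms
        if a.is_hydrogen and distance(a.coords, heavy.coords) <= max_dist
    ]


def _build_hydrogens(heavy, refs, rule, heavy_positions, residue) -> list[np.ndarray]:
    kind = rule["kind"]
    x = heavy.coords
    r1, r2 = refs[0].coords, refs[1].coords
    bond = OH_BOND if heavy.element == "O" else NH_BOND
    if kind == "sp2_bisector":
        d = -(unit(r1 - x) + unit(r2 - x))
        return [x + bond * unit(d)]
    if kind == "sp2_nh2":
        # two in-plane H at ~120 deg from the parent bond
        return [
            place_atom(x, r1, r2, bond, 120.0, 0.0),
            place_atom(x, r1, r2, bond, 120.0, 180.0),
        ]
    if kind == "sp3_nh3":
        return [
            place_atom(x, r1, r2, bond, 109.5, t) for t in (60.0, 180.0, 300.0)
        ]
    if kind == "hydroxyl":
        return [_best_hydroxyl_h(x, r1, r2, bond, heavy_positions, residue)]
    raise AssertionError(f"unknown placement kind {kind}")


def _best_hydroxyl_h(o, c, c2, bond, heavy_positions, residue) -> np.ndarray:
    """Scan the H-O-C torsion in 10 deg steps; keep the acceptance-maximizing H.

    Candidate acceptors are N/O atoms of *other* residues within 3.5 A; a
    hydroxyl cannot hydrogen-bond to its own side chain or amide group.
    """
    acceptors = [
        p for r, p in heavy_positions
        if r is not residue and 0.5 < distance(p, o) <= 3.5
    ]
    best_pos, best_score = None, -1.0
    for t in range(0, 360, 10):
        h = place_atom(o, c, c2, bond, 109.5, float(t))
        if acceptors:
            score = max(angle_at(o, h, b) for b in acceptors)
        else:
            score = 0.0 if t != 180 else 1.0  # no acceptor nearby: anti rotamer
        if score > best_score:
            best_score, best_pos = score, h
    return best_pos


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def assign_secondary_structure(s: ProteinStructure) -> ProteinStructure:
    """Assign helix / sheet / turn / coil per residue from backbone H-bonds.

    Backbone N-H...O=C hydrogen bonds are scored with the Kabsch-Sander
    electrostatic energy E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN)
    kcal/mol and accepted below -0.5 kcal/mol; the amide hydrogen is
    idealized from the preceding peptide unit when absent. The eight-state
    pattern alphabet is collapsed to four classes: n-turn ladders become
    helix, bridge patterns sheet, isolated turns turn, everything else coil.
    """
    for chain_id, residues in s.chains.items():
        n = len(residues)
        bb = [_backbone(r) for r in residues]
        for r, atoms in zip(residues, bb):
            if atoms is None and r.is_standard:
                warnings.warn(f"{r.label}: missing backbone atoms; labeled coil")
        hbond = _backbone_hbond_matrix(residues, bb)
        labels = ["coil"] * n

        # n-turns: donor NH of residue i+k accepts from CO of residue i
        turn = {k: [False] * n for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for i in range(n - k):
                if hbond[i + k].get(i, False):
                    turn[k][i] = True

        # helices: two consecutive k-turns cover residues i..i+k
        is_helix = [False] * n
        for k in (3, 4, 5):
            for i in range(1, n - k):
                if turn[k][i] and turn[k][i - 1]:
                    for j in range(i, i + k):
                        is_helix[j] = True

        # bridges (parallel / antiparallel), Kabsch-Sander patterns
        is_sheet = [False] * n
        for i in range(n):
            for j in range(n):
                if abs(i - j) < 3:
                    continue
                para = (
                    (0 < i and i + 1 < n and hbond[j].get(i - 1, False) and hbond[i + 1].get(j, False))
                    or (0 < j and j + 1 < n and hbond[i].get(j - 1, False) and hbond[j + 1].get(i, False))
                )
                anti = (
                    (hbond[i].get(j, False) and hbond[j].get(i, False))
                    or (0 < i and i + 1 < n and 0 < j and j + 1 < n
                        and hbond[j + 1].get(i - 1, False) and hbond[i + 1].get(j - 1, False))
                )
                if para or anti:
                    is_sheet[i] = True

        is_turn = [False] * n
        for k in (3, 4, 5):
            for i in range(n - k):
                if turn[k][i]:
                    for j in range(i, i + k + 1):
                        is_turn[j] = True

        for i in range(n):
            if is_helix[i]:
                labels[i] = "helix"
            elif is_sheet[i]:
                labels[i] = "sheet"
            elif is_turn[i]:
                labels[i] = "turn"
        for r, lab in zip(residues, labels):
            r.secondary_structure = lab
    return s


def _backbone(res: Residue):
    atoms = {n: res.atom(n) for n in ("N", "CA", "C", "O")}
    if any(a is None for a in atoms.values()):
        return None
    return {k: a.coords for k, a in atoms.items()}


def _amide_h(residues: Sequence[Residue], bb, i: int) -> Optional[np.ndarray]:
    res = residues[i]
    if res.name == "PRO":
        return None
    h = res.atom("H") or res.atom("HN") or res.atom("H1")
    if h is not None:
        return h.coords
    if i == 0 or bb[i] is None or bb[i - 1] is None:
        return None
    # idealize: H along the C(i-1)=O(i-1) direction mirrored onto N(i)
    prev = bb[i - 1]
    return bb[i]["N"] + unit(prev["C"] - prev["O"]) * 1.01


def _backbone_hbond_matrix(residues, bb) -> list[dict[int, bool]]:
    """hbond[d][a] is True when donor NH of residue d bonds acceptor CO of a."""
    n = len(residues)
    out: list[dict[int, bool]] = [dict() for _ in range(n)]
    for d in range(n):
        if bb[d] is None:
            continue
        h = _amide_h(residues, bb, d)
        if h is None:
            continue
        npos = bb[d]["N"]
        for a in range(n):
            if a == d or abs(a - d) < 1 or bb[a] is None:
                continue
            opos, cpos = bb[a]["O"], bb[a]["C"]
            r_on = distance(opos, npos)
            if r_on > 5.2:  # beyond any plausible backbone H-bond
                continue
            e = _KS_Q1Q2_F * (
                1.0 / r_on
                + 1.0 / distance(cpos, h)
                - 1.0 / distance(opos, h)
                - 1.0 / distance(cpos, npos)
            )
            if e < _KS_CUTOFF:
                out[d][a] = True
    return out


# ---------------------------------------------------------------------------
# train/test split by molecule name
# ---------------------------------------------------------------------------

def split_by_name(
    structures: Iterable[ProteinStructure],
) -> tuple[list[str], list[str]]:
    """Split structure ids into (training, test) pools by unique molecule name.

    One representative per unique normalized name (first by sorted
    structure_id) enters the training pool; all remaining entries form the
    test pool. Structures without a name are excluded with a warning.
    """
    named: dict[str, list[str]] = {}
    for s in structures:
        name = " ".join(s.molecule_name.lower().split())
        if not name:
            warnings.warn(f"{s.structure_id}: no molecule name; excluded from split")
            continue
        named.setdefault(name, []).append(s.structure_id)
    train: list[str] = []
    test: list[str] = []
    for name in sorted(named):
        ids = sorted(named[name])
        train.append(ids[0])
        test.extend(ids[1:])
    return sorted(train), sorted(test)
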