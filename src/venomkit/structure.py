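"""Geometry-level structural analysis of disulfide-rich peptides.

Covers disulfide detection from S-gamma distances, beta/gamma turn
classification from backbone dihedrals, inhibitor-cystine-knot (ICK)
topology classification, rigid-body superposition (Kabsch), the PDBeFold
Q-score, NOE r^-6 distance calibration, annealing-style disulfide
restraints, and a Wimley-White hydrophobicity profile.

The ICK core is the hallmark abcabc connectivity: ranking the six cysteines
of a three-bond subset by sequence order, the bonds must connect 1-4, 2-5
and 3-6, so that the third bond threads the macrocycle closed by the first
two.  Additional bonds are labeled by their role: a "C-terminal clamp"
protects the C-terminal segment (one partner is the last cysteine) and a
"hairpin staple" pins a protruding loop (both partners strictly between the
4th- and 6th-ranked core cysteines).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ._tables import WHITE_WIMLEY_INTERFACE

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Residue:
    index: int
    aa: str
    atoms: dict  # atom name -> np.ndarray(3), Angstrom


@dataclass(frozen=True)
class StructureModel:
    residues: tuple

    def __post_init__(self):
        indices = [r.index for r in self.residues]
        if indices != sorted(set(indices)):
            raise ValueError("residue indices must be strictly increasing")
        for r in self.residues:
            missing = [a for a in BACKBONE_ATOMS if a not in r.atoms]
            if missing:
                raise ValueError(
                    f"residue {r.index} missing backbone atoms {missing}")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atom(self, index: int, name: str) -> np.ndarray:
        for r in self.residues:
            if r.index == index:
                return r.atoms[name]
        raise KeyError(index)


@dataclass(frozen=True)
class DisulfideBond:
    i: int
    j: int
    distance: float

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("disulfide residue pair must have i < j")


@dataclass(frozen=True)
class AlignmentStats:
    nres1: int
    nres2: int
    nalgn: int
    rmsd: float

    def __post_init__(self):
        if self.nres1 < 1 or self.nres2 < 1:
            raise ValueError("Nres must be positive")
        if self.nalgn > min(self.nres1, self.nres2):
            raise ValueError("Nalgn cannot exceed min(Nres1, Nres2)")
        if self.rmsd < 0:
            raise ValueError("RMSD must be non-negative")


@dataclass(frozen=True)
class Restraint:
    atom1: str
    atom2: str
    lower: float
    upper: float
    kind: str

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("restraint lower bound exceeds upper bound")


def detect_disulfides(model: StructureModel, max_ss_dist: float = 2.5,
                      ) -> list[DisulfideBond]:
    """Pair cysteine S-gamma atoms within ``max_ss_dist``, greedily by
    shortest distance first, each cysteine in at most one bond.  Cysteines
    without an SG atom are skipped with a warning."""
    import warnings
    cys = []
    for r in model.residues:
        if r.aa != "C":
            continue
        if "SG" not in r.atoms:
            warnings.warn(f"Cys {r.index} has no SG atom; skipped")
            continue
        cys.append((r.index, r.atoms["SG"]))
    pairs = []
    for (i, a), (j, b) in itertools.combinations(cys, 2):
        d = float(np.linalg.norm(a - b))
        if d <= max_ss_dist:
            pairs.append((d, i, j))
    pairs.sort()
    used = set()
    bonds = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(DisulfideBond(min(i, j), max(i, j), d))
    bonds.sort(key=lambda b: (b.i, b.j))
    return bonds


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(model: StructureModel):
    """(phi, psi) per residue; None at chain termini."""
    res = model.residues
    out = []
    for i, r in enumerate(res):
        phi = psi = None
        if i > 0:
            phi = dihedral(res[i - 1].atoms["C"], r.atoms["N"],
                           r.atoms["CA"], r.atoms["C"])
        if i < len(res) - 1:
            psi = dihedral(r.atoms["N"], r.atoms["CA"], r.atoms["C"],
                           res[i + 1].atoms["N"])
        out.append((phi, psi))
    return out


#: Canonical (phi, psi) at positions i+1 and i+2 of each beta-turn type
#: (Hutchinson-Thornton convention).
BETA_TURN_TYPES = {
    "I": ((-60.0, -30.0), (-90.0, 0.0)),
    "I'": ((60.0, 30.0), (90.0, 0.0)),
    "II": ((-60.0, 120.0), (80.0, 0.0)),
    "II'": ((60.0, -120.0), (-80.0, 0.0)),
    "VIII": ((-60.0, -30.0), (-120.0, 120.0)),
}

#: Canonical (phi, psi) at the central residue of gamma turns.
GAMMA_TURN_TYPES = {
    "gamma": (75.0, -65.0),
    "inverse-gamma": (-79.0, 69.0),
}

_HELIX = (-60.0, -45.0)


def _angle_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def _fits(observed, canonical, tol: float = 30.0, loose: float = 45.0) -> bool:
    """All angles within tol, with a single angle allowed out to ``loose``."""
    diffs = [_angle_diff(o, c) for o, c in zip(observed, canonical)]
    if any(d > loose for d in diffs):
        return False
    return sum(d > tol for d in diffs) <= 1


def classify_turns(model: StructureModel):
    """Classify beta turns (4 residues) and gamma turns (3 residues).

    A beta turn requires CA(i)-CA(i+3) <= 7 A with the two central residues
    not continuing a helix; the type is assigned from the canonical
    (phi, psi) table with +-30 deg tolerance (+-45 deg on one angle), type
    IV when no canonical type fits.  A gamma turn is typed from (phi, psi)
    of the central residue alone.  Returns a list of
    ((start index, end index), type) tuples.
    """
    res = model.residues
    if len(res) < 3:
        return []
    dihedrals = backbone_dihedrals(model)
    turns = []
    for i in range(len(res) - 3):
        window = [res[i + k] for k in range(4)]
        if any(r2.index - r1.index != 1
               for r1, r2 in zip(window, window[1:])):
            continue
        try:
            d = float(np.linalg.norm(window[0].atoms["CA"]
                                     - window[3].atoms["CA"]))
        except KeyError:
            continue
        if d > 7.0:
            continue
        angles = []
        ok = True
        for k in (1, 2):
            phi, psi = dihedrals[i + k]
            if phi is None or psi is None:
                ok = False
                break
            angles.extend((phi, psi))
        if not ok:
            continue
        helical = all(
            _fits(angles[k:k + 2], _HELIX, tol=30.0, loose=30.0)
            for k in (0, 2))
        if helical:
            continue
        turn_type = "IV"
        for name, ((phi1, psi1), (phi2, psi2)) in BETA_TURN_TYPES.items():
            if _fits(angles, (phi1, psi1, phi2, psi2)):
                turn_type = name
                break
        turns.append(((window[0].index, window[3].index), turn_type))
    for i in range(len(res) - 2):
        window = [res[i + k] for k in range(3)]
        if any(r2.index - r1.index != 1
               for r1, r2 in zip(window, window[1:])):
            continue
        phi, psi = dihedrals[i + 1]
        if phi is None or psi is None:
            continue
        for name, canonical in GAMMA_TURN_TYPES.items():
            if _fits((phi, psi), canonical):
                turns.append(((window[0].index, window[2].index), name))
                break
    return turns


def q_score(a: AlignmentStats, r0: float = 3.0) -> float:
    """Structure-similarity Q-score.

    Q = Nalgn^2 / ((1 + (RMSD/R0)^2) * Nres1 * Nres2), with R0 = 3 A;
    1.0 for a perfect full-length zero-RMSD self match.
    """
    return (a.nalgn * a.nalgn
            / ((1.0 + (a.rmsd / r0) ** 2) * a.nres1 * a.nres2))


def superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares rigid superposition of B onto A (Kabsch).

    ``coords_a`` and ``coords_b`` are (n, 3) arrays of corresponding atoms,
    n >= 3 and not collinear.  Returns (rotation matrix, translation,
    RMSD) such that coords_b @ R.T + t approximates coords_a.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 corresponding pairs")
    for pts in (a, b):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) coordinate set")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    rmsd = rssd / math.sqrt(a.shape[0])
    matrix = rot.as_matrix()
    translation = ca - matrix @ cb
    return matrix, translation, float(rmsd)


def classify_ick(bonds: list[DisulfideBond], cys_positions):
    """Find the ICK core among a set of disulfide bonds.

    Returns a dict with ``core`` (tuple of three bonds or None) and
    ``extra_roles`` mapping each non-core bond to "C-terminal clamp",
    "hairpin staple" or "other".  Every bond must use distinct cysteines
    from ``cys_positions``.
    """
    cys_positions = tuple(cys_positions)
    cys_set = set(cys_positions)
    seen = set()
    for bond in bonds:
        for p in (bond.i, bond.j):
            if p not in cys_set:
                raise ValueError(f"bond residue {p} not in cysteine list")
            if p in seen:
                raise ValueError(f"cysteine {p} used by more than one bond")
            seen.add(p)
    core = None
    for subset in itertools.combinations(sorted(bonds, key=lambda b: (b.i, b.j)), 3):
        six = sorted({p for b in subset for p in (b.i, b.j)})
        rank = {p: r + 1 for r, p in enumerate(six)}
        connectivity = sorted(tuple(sorted((rank[b.i], rank[b.j])))
                              for b in subset)
        if connectivity == [(1, 4), (2, 5), (3, 6)]:
            core = subset
            break
    if core is None:
        return {"core": None, "extra_roles": {}}
    core_six = sorted({p for b in core for p in (b.i, b.j)})
    rank4, rank6 = core_six[3], core_six[5]
    last_cys = max(cys_positions)
    roles = {}
    for bond in bonds:
        if bond in core:
            continue
        if bond.j == last_cys or bond.i == last_cys:
            roles[bond] = "C-terminal clamp"
        elif rank4 < bond.i < rank6 and rank4 < bond.j < rank6:
            roles[bond] = "hairpin staple"
        else:
            roles[bond] = "other"
    return {"core": core, "extra_roles": roles}


def noe_calibrate(intensity: float, ref_intensity: float,
                  ref_distance: float, clip=(2.0, 6.0)) -> float:
    """Upper distance limit from r^-6 NOE calibration.

    d = ref_distance * (ref_intensity / intensity)^(1/6), clipped to the
    physically sensible [2, 6] A window used for annealing restraints.
    """
    if intensity <= 0 or ref_intensity <= 0 or ref_distance <= 0:
        raise ValueError("NOE calibration inputs must be positive")
    d = ref_distance * (ref_intensity / intensity) ** (1.0 / 6.0)
    return min(max(d, clip[0]), clip[1])


def disulfide_restraints(bonds: list[DisulfideBond]) -> list[Restraint]:
    """Annealing-convention disulfide restraints: per bond, three atom
    pairs each with an upper and a lower bound — SG(i)-SG(j) in [2.0, 2.1],
    CB(i)-SG(j) and SG(i)-CB(j) in [3.0, 3.1] A."""
    if not bonds:
        raise ValueError("no disulfide bonds given")
    restraints = []
    for b in bonds:
        restraints.append(Restraint(f"SG {b.i}", f"SG {b.j}", 2.0, 2.1,
                                    "disulfide"))
        restraints.append(Restraint(f"CB {b.i}", f"SG {b.j}", 3.0, 3.1,
                                    "disulfide"))
        restraints.append(Restraint(f"SG {b.i}", f"CB {b.j}", 3.0, 3.1,
                                    "disulfide"))
    return restraints


def restraint_text(restraints: list[Restraint], bound: str = "upper") -> str:
    """CYANA-like 3-column restraint layout (atom1, atom2, bound)."""
    lines = []
    for r in restraints:
        value = r.upper if bound == "upper" else r.lower
        lines.append(f"{r.atom1}\t{r.atom2}\t{value:.2f}")
    return "\n".join(lines) + "\n"


def hydrophobicity_profile(seq: str, window: int = 5) -> list[float]:
    """Sliding-window mean of the Wimley-White interface scale.

    The scale is in kcal/mol for transfer from water to the bilayer
    interface; more negative means more hydrophobic.  Windows are centered;
    edge positions use the truncated window.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    values = [WHITE_WIMLEY_INTERFACE[a] for a in seq]
    half = window // 2
    profile = []
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        profile.append(sum(values[lo:hi]) / (hi - lo))
    return profile


def find_sheets(model: StructureModel, max_no_dist: float = 3.5):
    """Simplified antiparallel beta-sheet detection.

    Two residues are H-bond partners when backbone N(i)-O(j) or O(i)-N(j)
    is within ``max_no_dist`` A and |i - j| > 2; maximal runs of partnered
    residues are reported as strand intervals.  This is a deliberately
    approximate stand-in for a full secondary-structure assignment.
    """
    res = model.residues
    partnered = set()
    for a, b in itertools.combinations(res, 2):
        if abs(a.index - b.index) <= 2:
            continue
        dno = float(np.linalg.norm(a.atoms["N"] - b.atoms["O"]))
        don = float(np.linalg.norm(a.atoms["O"] - b.atoms["N"]))
        if min(dno, don) <= max_no_dist:
            partnered.update((a.index, b.index))
    strands = []
    run = []
    for r in res:
        if r.index in partnered and (not run or r.index == run[-1] + 1):
            run.append(r.index)
        else:
            if len(run) >= 2:
                strands.append((run[0], run[-1]))
            run = [r.index] if r.index in partnered else []
    if len(run) >= 2:
        strands.append((run[0], run[-1]))
    return strands
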