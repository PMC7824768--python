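"""Simplified bottom-up search engine with target-decoy FDR control.

The database holds propeptide and mature sequences predicted from the
transcriptome, plus an equal number of full sequence reversals as decoys.
Spectra are matched against digest peptidoforms whose theoretical precursor
mass lies within a ppm tolerance of the observed one; fragment matching is
greedy one-peak-one-fragment in m/z order at an absolute Da tolerance.

The score is a hyperscore variant:

    score = log(n_b! * n_y!) + log(I_matched / I_total + eps)

with n_b / n_y the numbers of matched b / y ions, I the summed peak
intensities, and eps = 1e-6.  It is invariant to peak order and to uniform
intensity scaling.  This scoring is this package's own; the false-discovery
behavior is validated by simulation with known ground truth, not by
replicating any particular production engine.

PSM-level q-values follow the classic target-decoy estimator
q(s) = min over thresholds t <= s of  #decoys(score >= t) / #targets(score >= t),
monotonized from the bottom of the ranking.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

from ._tables import CAM_DELTA_MASS
from .annotate import PrecursorModel
from .digest import Peptidoform, Proteoform, apply_modifications, digest, fragment_ions
from .masses import neutral_mass_from_mz

_EPS = 1e-6

FIXED_CAM = {"C": (CAM_DELTA_MASS, "cam")}
VARIABLE_CAM = {aa: (CAM_DELTA_MASS, "cam") for aa in "MHKW"}


@dataclass(frozen=True)
class DatabaseEntry:
    accession: str
    sequence: str
    kind: str              # "propeptide" | "mature"
    is_decoy: bool


@dataclass(frozen=True)
class SearchDatabase:
    entries: tuple

    @property
    def n_targets(self) -> int:
        return sum(not e.is_decoy for e in self.entries)

    @property
    def n_decoys(self) -> int:
        return sum(e.is_decoy for e in self.entries)


@dataclass(frozen=True)
class Spectrum:
    id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple  # ((mz, intensity), ...) sorted by m/z

    def __post_init__(self):
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks",
                               tuple(sorted(self.peaks, key=lambda p: p[0])))
        for m, inten in self.peaks:
            if not (math.isfinite(m) and math.isfinite(inten)) or inten < 0:
                raise ValueError(f"{self.id}: bad peak ({m}, {inten})")


@dataclass
class PSM:
    spectrum_id: str
    accession: str
    peptidoform: Peptidoform
    score: float
    n_matched_fragments: int
    is_decoy: bool
    q_value: float | None = None


def build_search_db(precursors: list[PrecursorModel]) -> SearchDatabase:
    """Targets = every propeptide and mature sequence; decoys = reversals.

    Two target entries per precursor with a non-empty propeptide, one
    otherwise; decoys are appended 1:1, each the full reversal of its target.
    """
    entries = []
    seen = set()
    for i, prec in enumerate(precursors):
        parts = []
        if prec.propeptide is not None and prec.propeptide_seq:
            parts.append(("propeptide", prec.propeptide_seq))
        parts.append(("mature", prec.mature_seq))
        for kind, seq in parts:
            acc = f"tx{i:04d}|{kind}"
            if acc in seen:
                raise ValueError(f"duplicate accession {acc}")
            seen.add(acc)
            entries.append(DatabaseEntry(acc, seq, kind, False))
    decoys = [DatabaseEntry("DECOY_" + e.accession, e.sequence[::-1],
                            e.kind, True) for e in entries]
    return SearchDatabase(tuple(entries + decoys))


def enumerate_peptidoforms(entry: DatabaseEntry, enzyme: str, max_missed: int,
                           fixed: dict | None = FIXED_CAM,
                           variable: dict | None = None,
                           max_variable: int = 0,
                           consider_amidation: bool = True
                           ) -> list[tuple[Peptidoform, float]]:
    """Digest one database entry and enumerate (peptidoform, neutral mass).

    Protein-level C-terminal amidation is a variable hypothesis for the
    C-terminal peptides of mature entries only (decoys of mature entries
    are treated identically so the decoy model stays unbiased).
    """
    amid_states = [False]
    if consider_amidation and entry.kind == "mature":
        amid_states.append(True)
    forms = []
    for amidated in amid_states:
        parent = Proteoform(entry.sequence, c_amidated=amidated)
        for pep in digest(parent, enzyme, max_missed):
            if amidated and not pep.c_amidated:
                continue  # only the C-terminal peptide differs
            if len(pep) < 2:
                continue
            for form in apply_modifications(pep, fixed, variable, max_variable):
                forms.append((form, form.neutral_mass()))
    return forms


class PeptidoformIndex:
    """Mass-sorted index of all digest peptidoforms of a database."""

    def __init__(self, db: SearchDatabase, enzyme: str, max_missed: int,
                 fixed=FIXED_CAM, variable=None, max_variable: int = 0):
        records = []
        for entry in db.entries:
            for form, mass in enumerate_peptidoforms(
                    entry, enzyme, max_missed, fixed, variable, max_variable):
                records.append((mass, entry.accession, entry.is_decoy, form))
        records.sort(key=lambda r: r[0])
        self._records = records
        self._masses = [r[0] for r in records]

    def candidates(self, neutral_mass: float, tol_ppm: float):
        delta = neutral_mass * tol_ppm * 1e-6
        lo = bisect_left(self._masses, neutral_mass - delta)
        hi = bisect_right(self._masses, neutral_mass + delta)
        return self._records[lo:hi]


def _greedy_match(peaks, theo_mzs, frag_tol: float):
    """One-peak-one-fragment greedy matching in ascending m/z order.

    Returns (matched fragment indices, summed matched intensity).
    """
    matched = []
    intensity = 0.0
    i = j = 0
    order = sorted(range(len(theo_mzs)), key=lambda t: theo_mzs[t])
    while i < len(peaks) and j < len(order):
        pm = peaks[i][0]
        tm = theo_mzs[order[j]]
        if pm < tm - frag_tol:
            i += 1
        elif pm > tm + frag_tol:
            j += 1
        else:
            matched.append(order[j])
            intensity += peaks[i][1]
            i += 1
            j += 1
    return matched, intensity


def score_match(spectrum: Spectrum, form: Peptidoform, frag_tol: float
                ) -> tuple[float, int]:
    """Hyperscore-style score and matched-fragment count for one candidate."""
    ions = fragment_ions(form, charges=(1,))
    theo = [(ion.mz, ion.series) for ion in ions]
    matched_idx, matched_intensity = _greedy_match(
        spectrum.peaks, [t[0] for t in theo], frag_tol)
    if not matched_idx:
        return float("-inf"), 0
    n_b = sum(theo[i][1] == "b" for i in matched_idx)
    n_y = sum(theo[i][1] == "y" for i in matched_idx)
    total_intensity = sum(p[1] for p in spectrum.peaks)
    frac = matched_intensity / total_intensity if total_intensity > 0 else 0.0
    score = (math.lgamma(n_b + 1) + math.lgamma(n_y + 1)
             + math.log(frac + _EPS))
    return score, n_b + n_y


def match_spectrum(spectrum: Spectrum, index: PeptidoformIndex,
                   prec_tol_ppm: float = 10.0, frag_tol_da: float = 0.02,
                   min_matched: int = 2) -> list[PSM]:
    """Best PSM for one spectrum (empty list when nothing matches).

    Candidates with fewer than ``min_matched`` matched fragments are
    discarded — a single chance peak carries no sequence evidence and is
    invisible to the decoy model.  Ties are broken by fewer modifications,
    then lexicographic peptide.
    """
    if prec_tol_ppm <= 0 or frag_tol_da <= 0:
        raise ValueError("tolerances must be positive")
    if not spectrum.peaks:
        return []
    observed = neutral_mass_from_mz(spectrum.precursor_mz,
                                    spectrum.precursor_charge)
    best = None
    for mass, accession, is_decoy, form in index.candidates(
            observed, prec_tol_ppm):
        score, n_matched = score_match(spectrum, form, frag_tol_da)
        if n_matched < min_matched:
            continue
        key = (-score, len(form.mods), form.sequence)
        if best is None or key < best[0]:
            best = (key, PSM(spectrum.id, accession, form, score,
                             n_matched, is_decoy))
    return [best[1]] if best else []


def target_decoy_fdr(psms: list[PSM], alpha: float) -> list[PSM]:
    """Assign q-values and return the target PSMs accepted at level alpha."""
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    if not psms:
        return []
    ranked = sorted(psms, key=lambda p: -p.score)
    # tied scores share one threshold: count the whole tie group first
    n_decoy = n_target = 0
    raw = []
    i = 0
    while i < len(ranked):
        j = i
        while j < len(ranked) and ranked[j].score == ranked[i].score:
            if ranked[j].is_decoy:
                n_decoy += 1
            else:
                n_target += 1
            j += 1
        raw.extend([n_decoy / max(1, n_target)] * (j - i))
        i = j
    # monotonize: q at a score is the minimum FDR at any lower threshold
    q = raw[:]
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    for psm, qv in zip(ranked, q):
        psm.q_value = qv
    return [p for p in ranked if not p.is_decoy and p.q_value <= alpha]


def sequence_coverage(psms: list[PSM], protein: str):
    """Union of covered intervals and per-peptide PSM counts.

    Returns (intervals, counts) where intervals is a list of (start, end)
    1-based inclusive merged intervals and counts maps
    (sequence, start, end) -> number of PSMs.
    """
    counts: dict[tuple, int] = {}
    spans = []
    for psm in psms:
        pep = psm.peptidoform.peptide
        if pep.start < 1 or pep.end > len(protein):
            raise ValueError(f"PSM coordinates {pep.start}-{pep.end} outside "
                             f"protein of length {len(protein)}")
        key = (pep.sequence, pep.start, pep.end)
        counts[key] = counts.get(key, 0) + 1
        spans.append((pep.start, pep.end))
    merged = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged, counts


def coverage_table(psms: list[PSM], protein: str, enzyme: str) -> str:
    """Tab-separated PSM report mirroring the bottom-up results layout."""
    _, counts = sequence_coverage(psms, protein)
    lines = ["Enzyme\tPSMs\tPeptide\tAA-from\tAA-to\tMissed Cleavages"]
    by_count = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][1]))
    missed = {}
    for psm in psms:
        pep = psm.peptidoform.peptide
        missed[(pep.sequence, pep.start, pep.end)] = pep.missed_cleavages
        if psm.peptidoform.c_amidated:
            key = (pep.sequence, pep.start, pep.end)
            missed[key] = pep.missed_cleavages
    for (seq, start, end), n in by_count:
        lines.append(f"{enzyme}\t{n}\t{seq}\t{start}\t{end}\t"
                     f"{missed[(seq, start, end)]}")
    return "\n".join(lines) + "\n"
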