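"""Isotope-cluster detection in MS1 peak lists and intact-proteoform matching.

A cluster is a run of peaks spaced by 1.00336/z (the 13C spacing at charge
z); charge is assigned from the spacing and the monoisotopic m/z is the
first peak of the run.  Detected clusters are matched to a hypothesis grid
per candidate sequence — every disulfide count from 0 to floor(nCys/2)
crossed with amidation true/false — and the best hypothesis is the one with
the smallest absolute ppm error on the neutral monoisotopic mass.  A
sequence with no hypothesis inside tolerance is reported unmatched, which
is a result, not an error (an undetected propeptide is informative).
"""

from __future__ import annotations

from dataclasses import dataclass

from ._tables import C13_SPACING, PROTON
from .masses import Proteoform, monoisotopic_mass, neutral_mass_from_mz


@dataclass(frozen=True)
class IsotopeCluster:
    charge: int
    monoisotopic_mz: float
    peaks: tuple        # ((mz, intensity), ...) consecutive isotopologues
    apex_index: int     # index of the most abundant peak in ``peaks``

    @property
    def neutral_mass(self) -> float:
        return neutral_mass_from_mz(self.monoisotopic_mz, self.charge)


@dataclass(frozen=True)
class IntactMatch:
    sequence_id: str
    sequence: str
    n_disulfides: int
    c_amidated: bool
    theoretical_mass: float
    observed_mass: float    # intensity-weighted mean over charge states
    error_ppm: float
    charge_states: tuple
    matched: bool


def detect_clusters(peaks, min_peaks: int = 3, spacing_tol: float = 0.01,
                    charge_range=range(1, 9)) -> list[IsotopeCluster]:
    """Greedy longest-run-first grouping of MS1 peaks into isotope clusters.

    ``peaks`` is a sequence of (mz, intensity) sorted by m/z.  For every
    charge, maximal runs of peaks with consecutive spacing 1.00336/z within
    ``spacing_tol`` are collected; runs are then claimed longest-first, each
    peak belonging to at most one cluster.  Runs shorter than ``min_peaks``
    are discarded.
    """
    peaks = list(peaks)
    if any(peaks[i][0] > peaks[i + 1][0] for i in range(len(peaks) - 1)):
        raise ValueError("MS1 peaks must be sorted by m/z")
    runs = []
    for z in charge_range:
        step = C13_SPACING / z
        for start in range(len(peaks)):
            run = [start]
            current = start
            while True:
                target = peaks[current][0] + step
                nxt = None
                for j in range(current + 1, len(peaks)):
                    if peaks[j][0] > target + spacing_tol:
                        break
                    if abs(peaks[j][0] - target) <= spacing_tol:
                        nxt = j
                        break
                if nxt is None:
                    break
                run.append(nxt)
                current = nxt
            if len(run) >= min_peaks:
                runs.append((z, run))
    runs.sort(key=lambda r: (-len(r[1]), r[1][0], r[0]))
    used = set()
    clusters = []
    for z, run in runs:
        if any(i in used for i in run):
            continue
        used.update(run)
        cluster_peaks = tuple(peaks[i] for i in run)
        apex = max(range(len(cluster_peaks)),
                   key=lambda i: cluster_peaks[i][1])
        clusters.append(IsotopeCluster(z, cluster_peaks[0][0],
                                       cluster_peaks, apex))
    clusters.sort(key=lambda c: c.monoisotopic_mz)
    return clusters


def hypothesis_grid(sequence: str, allow_amidation: bool = True):
    """All (n_disulfides, amidated) PTM hypotheses for a sequence."""
    n_cys = sequence.count("C")
    states = (False, True) if allow_amidation else (False,)
    return [(n_ss, amidated)
            for n_ss in range(n_cys // 2 + 1)
            for amidated in states]


def match_intact(clusters: list[IsotopeCluster],
                 candidates: list[tuple[str, str]],
                 tol_ppm: float = 5.0,
                 group_tol_ppm: float = 10.0,
                 allow_amidation: bool = True) -> list[IntactMatch]:
    """Match detected clusters to intact-proteoform hypotheses.

    ``candidates`` is a list of (sequence id, sequence).  Clusters whose
    neutral masses agree within ``group_tol_ppm`` are treated as charge
    states of one species.  For each candidate the exhaustive hypothesis
    grid is scanned and the hypothesis with the smallest |ppm error| against
    the species mass is kept; candidates without a hypothesis within
    ``tol_ppm`` are reported with ``matched=False``.
    """
    if tol_ppm > 20:
        raise ValueError("tol_ppm must be <= 20")
    # group clusters into species by neutral mass agreement
    species = []  # list of [clusters]
    for cluster in sorted(clusters, key=lambda c: c.neutral_mass):
        placed = False
        for group in species:
            ref = group[0].neutral_mass
            if abs(cluster.neutral_mass - ref) / ref * 1e6 <= group_tol_ppm:
                group.append(cluster)
                placed = True
                break
        if not placed:
            species.append([cluster])
    results = []
    for seq_id, seq in candidates:
        best = None
        for n_ss, amidated in hypothesis_grid(seq, allow_amidation):
            theo = monoisotopic_mass(Proteoform(seq, n_ss, amidated))
            for group in species:
                weights = [sum(p[1] for p in c.peaks) for c in group]
                observed = (sum(w * c.neutral_mass
                                for w, c in zip(weights, group))
                            / sum(weights))
                err = (observed - theo) / theo * 1e6
                cand = (abs(err), n_ss, amidated, theo, observed,
                        tuple(sorted(c.charge for c in group)))
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None or best[0] > tol_ppm:
            matched = False
            if best is None:
                results.append(IntactMatch(seq_id, seq, 0, False,
                                           float("nan"), float("nan"),
                                           float("nan"), (), False))
                continue
        else:
            matched = True
        abs_err, n_ss, amidated, theo, observed, charges = best
        err = (observed - theo) / theo * 1e6
        results.append(IntactMatch(seq_id, seq, n_ss, amidated, theo,
                                   observed, err, charges, matched))
    return results


def intact_table(matches: list[IntactMatch]) -> str:
    """Tab-separated intact-match report."""
    lines = ["id\tmatched\tn_disulfides\tamidated\ttheoretical_mass\t"
             "observed_mass\terror_ppm\tcharge_states"]
    for m in matches:
        charges = ",".join(str(z) for z in m.charge_states)
        lines.append(f"{m.sequence_id}\t{m.matched}\t{m.n_disulfides}\t"
                     f"{m.c_amidated}\t{m.theoretical_mass:.4f}\t"
                     f"{m.observed_mass:.4f}\t{m.error_ppm:.2f}\t{charges}")
    return "\n".join(lines) + "\n"
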