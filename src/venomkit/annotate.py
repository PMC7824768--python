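"""Annotation of venom-gland transcripts into toxin precursor models.

Spider toxin precursors are prepropeptides: an N-terminal signal peptide, an
optional acidic propeptide ending in a processing motif, a cysteine-rich
mature toxin, and sometimes a short C-terminal tail (Gly plus up to two basic
residues) that is cleaved off during amidation of the mature C-terminus.

The segmentation here is heuristic by design:

* the signal peptide boundary ``k`` is chosen in a configurable window to
  maximize the mean Kyte-Doolittle hydropathy of the core (residues 5..k-5),
  requiring a run of at least 8 consecutive hydrophobic residues and small
  residues (A/G/S/C) at the -1 and -3 positions of the cleavage site (the
  von Heijne rule).  This approximates a dedicated signal-peptide predictor
  and is documented as such.
* the propeptide ends at the last residue of a processing quadruplet motif:
  three residues enriched in Asp/Glu followed by Arg, with cleavage after
  the Arg, searched before the first cysteine of the downstream region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from ._tables import KYTE_DOOLITTLE

_DNA_RE = re.compile(r"^[ACGTN]+$")
_STOP = "*"

SMALL_RESIDUES = frozenset("AGSC")


class AnnotationError(ValueError):
    """Raised when a record cannot be annotated; carries a reason code."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise AnnotationError("empty_sequence", f"{self.id}: empty sequence")
        if not _DNA_RE.match(self.sequence.upper()):
            bad = sorted(set(self.sequence.upper()) - set("ACGTN"))
            raise AnnotationError(
                "non_dna_alphabet",
                f"{self.id}: non-DNA characters {bad} (only A/C/G/T/N accepted)")


@dataclass(frozen=True)
class OpenReadingFrame:
    transcript_id: str
    frame: int
    start_nt: int  # 1-based inclusive, start of ATG
    end_nt: int    # 1-based inclusive, last base of the codon before the stop
    aa_sequence: str


@dataclass(frozen=True)
class Interval:
    """1-based inclusive residue interval; (0, -1)-style empties disallowed,
    use ``None`` for absent regions instead."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}..{self.end}")

    def __len__(self):
        return self.end - self.start + 1


@dataclass(frozen=True)
class PrecursorModel:
    aa_sequence: str
    signal: Interval
    propeptide: Interval | None
    mature: Interval
    amidation_tail: Interval | None
    amidated: bool

    @property
    def signal_seq(self) -> str:
        return self.aa_sequence[self.signal.start - 1:self.signal.end]

    @property
    def propeptide_seq(self) -> str:
        if self.propeptide is None:
            return ""
        return self.aa_sequence[self.propeptide.start - 1:self.propeptide.end]

    @property
    def mature_seq(self) -> str:
        return self.aa_sequence[self.mature.start - 1:self.mature.end]


@dataclass(frozen=True)
class CysteineFramework:
    positions: tuple   # 1-based indices within the mature peptide
    pattern: str       # canonical inter-cysteine gap encoding, "" if linear
    linear: bool = False


@dataclass(frozen=True)
class ToxinFamily:
    members: tuple
    representative: str
    framework: CysteineFramework


@dataclass
class SegmentationConfig:
    """Tunables of the precursor segmentation heuristics."""

    signal_min_len: int = 15
    signal_max_len: int = 30
    core_hydropathy_threshold: float = 1.5
    core_min_run: int = 8
    scan_reverse_frames: bool = False
    max_tail_basics: int = 2


def find_orfs(transcript: TranscriptRecord, min_aa_len: int,
              scan_reverse: bool = False) -> list[OpenReadingFrame]:
    """Enumerate Met-initiated, stop-terminated ORFs in the forward frames.

    Every ATG that runs to an in-frame stop codon yields one ORF (nested
    starts included).  cDNA libraries sequenced 5'->3' are oriented, so only
    forward frames are scanned unless ``scan_reverse`` is set.  Candidate
    ORFs containing an N are dropped (the residue would be unknown).
    """
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    seq = transcript.sequence.upper()
    strands = [(seq, +1)]
    if scan_reverse:
        strands.append((str(Seq(seq).reverse_complement()), -1))
    orfs = []
    for strand_seq, sense in strands:
        n = len(strand_seq)
        for frame in range(3):
            stop_positions = []
            for pos in range(frame, n - 2, 3):
                if str(Seq(strand_seq[pos:pos + 3]).translate()) == _STOP:
                    stop_positions.append(pos)
            for pos in range(frame, n - 2, 3):
                if strand_seq[pos:pos + 3] != "ATG":
                    continue
                stop = next((s for s in stop_positions if s > pos), None)
                if stop is None:
                    continue
                coding = strand_seq[pos:stop]
                if "N" in coding:
                    continue
                aa = str(Seq(coding).translate())
                if len(aa) < min_aa_len:
                    continue
                start_nt, end_nt = pos + 1, stop
                if sense < 0:
                    start_nt, end_nt = n - stop + 1, n - pos
                orfs.append(OpenReadingFrame(
                    transcript.id, frame, start_nt, end_nt, aa))
    return orfs


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def assemble_overlaps(fragments: list[str], min_overlap: int = 10) -> str:
    """Merge oriented DNA fragments by maximal suffix-prefix overlap.

    Emulates overlap-extension assembly of synthetic oligonucleotides into
    one amplicon; fragments must already be on the sense strand and given
    5'->3' in order.  Raises when adjacent fragments share less than
    ``min_overlap`` bases.
    """
    contig = fragments[0]
    for frag in fragments[1:]:
        best = 0
        for k in range(min(len(contig), len(frag)), min_overlap - 1, -1):
            if contig.endswith(frag[:k]):
                best = k
                break
        if not best:
            raise ValueError(
                f"no overlap of >= {min_overlap} nt with fragment {frag!r}")
        contig += frag[best:]
    return contig


def detect_amidation_tail(mature_candidate: str, max_basics: int = 2
                          ) -> tuple[str, bool, int]:
    """Trim a C-terminal amidation donor tail: X-Gly-(Lys|Arg){0,max}.

    The glycine donates the amide nitrogen to the preceding residue X and is
    removed together with any trailing basic residues.  Returns
    (trimmed sequence, amidated flag, tail length).
    """
    if len(mature_candidate) < 5:
        raise ValueError("mature candidate shorter than 5 residues")
    m = re.search(r"G[KR]{0,%d}$" % max_basics, mature_candidate)
    if m is None or m.start() == 0:
        return mature_candidate, False, 0
    return mature_candidate[:m.start()], True, len(mature_candidate) - m.start()


def _signal_boundary(aa: str, cfg: SegmentationConfig) -> int | None:
    """Pick the signal-peptide length k, or None if no k is plausible."""
    best_k, best_score = None, None
    kd = [KYTE_DOOLITTLE.get(a, 0.0) for a in aa]
    hi = min(cfg.signal_max_len, len(aa) - 10)
    for k in range(cfg.signal_min_len, hi + 1):
        core = kd[4:k - 5]  # residues 5..k-5, 0-based slice
        if len(core) < cfg.core_min_run:
            continue
        if aa[k - 1] not in SMALL_RESIDUES or aa[k - 3] not in SMALL_RESIDUES:
            continue
        run = best_run = 0
        for v in core:
            run = run + 1 if v > cfg.core_hydropathy_threshold else 0
            best_run = max(best_run, run)
        if best_run < cfg.core_min_run:
            continue
        score = sum(core) / len(core)
        if best_score is None or score > best_score:
            best_k, best_score = k, score
    return best_k


_PQM_RE = re.compile(r"(?=([A-Z]{3}R))")


def _propeptide_end(after_signal: str) -> int | None:
    """Offset (1-based, within ``after_signal``) of the last residue of the
    last processing quadruplet motif before the first cysteine, or None."""
    first_cys = after_signal.find("C")
    search_region = after_signal if first_cys < 0 else after_signal[:first_cys]
    last = None
    for m in _PQM_RE.finditer(search_region):
        triplet = m.group(1)[:3]
        if sum(c in "DE" for c in triplet) >= 1:
            last = m.start() + 4
    return last


def segment_precursor(orf: OpenReadingFrame | str,
                      config: SegmentationConfig | None = None
                      ) -> PrecursorModel:
    """Segment a precursor protein into signal / propeptide / mature / tail.

    Raises :class:`AnnotationError` (reason ``"no_signal"``) when no
    plausible signal region exists; a missing processing motif yields an
    empty propeptide with the mature region starting right after the signal.
    """
    cfg = config or SegmentationConfig()
    aa = orf if isinstance(orf, str) else orf.aa_sequence
    if len(aa) < 30:
        raise AnnotationError("too_short", f"precursor of {len(aa)} aa (< 30)")
    if not aa.startswith("M"):
        raise AnnotationError("no_initiator_met", "precursor must start with Met")
    k = _signal_boundary(aa, cfg)
    if k is None:
        raise AnnotationError("no_signal", "no plausible signal peptide region")
    after_signal = aa[k:]
    pro_end = _propeptide_end(after_signal)
    propeptide = None
    mature_start = k + 1
    if pro_end is not None:
        propeptide = Interval(k + 1, k + pro_end)
        mature_start = k + pro_end + 1
    mature_candidate = aa[mature_start - 1:]
    if len(mature_candidate) < 10:
        raise AnnotationError("mature_too_short",
                              f"mature region of {len(mature_candidate)} aa")
    trimmed, amidated, tail_len = detect_amidation_tail(
        mature_candidate, cfg.max_tail_basics)
    if len(trimmed) < 10:  # do not trim into a too-short mature peptide
        trimmed, amidated, tail_len = mature_candidate, False, 0
    mature = Interval(mature_start, mature_start + len(trimmed) - 1)
    tail = Interval(mature.end + 1, len(aa)) if amidated else None
    return PrecursorModel(aa, Interval(1, k), propeptide, mature, tail, amidated)


def cys_framework(mature: str) -> CysteineFramework:
    """Ordered cysteine positions and the canonical gap-pattern string.

    The pattern writes inter-cysteine gap lengths between "C" letters, with
    adjacent cysteines (gap 0) rendered as "CC"; e.g. positions [1, 8, 14]
    in a mature peptide give "C6C5C".  Fewer than two cysteines flags the
    peptide as linear with an empty pattern.
    """
    positions = tuple(i + 1 for i, a in enumerate(mature) if a == "C")
    if len(positions) < 2:
        return CysteineFramework(positions, "", linear=True)
    parts = ["C"]
    for prev, cur in zip(positions, positions[1:]):
        gap = cur - prev - 1
        parts.append(("%d" % gap if gap else "") + "C")
    return CysteineFramework(positions, "".join(parts))


def framework_positions(pattern: str, first_position: int = 1) -> tuple:
    """Invert :func:`cys_framework`: recover positions from a gap pattern."""
    positions = []
    pos = first_position
    for token in re.findall(r"C|\d+", pattern):
        if token == "C":
            positions.append(pos)
            pos += 1
        else:
            pos += int(token)
    return tuple(positions)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None
                      ) -> float:
    """Global-alignment identity: matches / alignment length."""
    aligner = aligner or _make_aligner()
    alignment = aligner.align(a, b)[0]
    return alignment.counts().identities / alignment.length


def group_families(matures: list[str], identity_threshold: float
                   ) -> list[ToxinFamily]:
    """Single-linkage clustering of mature toxins into homologous families.

    Linkage requires equal cysteine counts and pairwise global identity at
    or above the threshold.  Deterministic: sequences are processed in
    lexicographic order and each family's representative is its
    lexicographically smallest member.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    if not matures:
        return []
    seqs = sorted(matures)
    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _make_aligner()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if seqs[i].count("C") != seqs[j].count("C"):
                continue
            if pairwise_identity(seqs[i], seqs[j], aligner) >= identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[str]] = {}
    for i, s in enumerate(seqs):
        clusters.setdefault(find(i), []).append(s)
    families = []
    for root in sorted(clusters):
        members = tuple(clusters[root])
        representative = members[0]
        families.append(ToxinFamily(members, representative,
                                    cys_framework(representative)))
    return families
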