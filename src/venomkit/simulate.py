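"""Synthetic data generators with machine-readable ground truth.

Every generator is a pure function of its parameters and seed, with an
independent random stream per call, so fixtures for one pipeline stage are
stable under changes to another.  Each generated dataset carries a ground
truth structure sufficient to score the corresponding pipeline stage
exactly (region boundaries, spectrum assignments, proteoform identities,
disulfide pairings).

The precursor generator emulates the architecture of spider-toxin
prepropeptides: a signal peptide with a strongly hydrophobic core and small
residues at the -1/-3 cleavage positions, an acidic propeptide ending in a
processing quadruplet motif (acidic-enriched triplet + Arg), a
cysteine-rich mature region built on a fixed cysteine framework with
randomized loop residues, and an optional C-terminal Gly + basic-residue
amidation tail.  Reverse translation uses one fixed codon per residue;
codon optimization is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._tables import CODON
from .digest import Peptidoform
from .masses import Proteoform, isotope_envelope, monoisotopic_mass, mz
from .search import Spectrum
from .structure import Residue, StructureModel

#: The 10-cysteine framework of the flagship insectotoxin: positions within
#: the 39-residue mature peptide.
TBO_IT2_FRAMEWORK_POSITIONS = (1, 8, 14, 15, 17, 20, 22, 29, 31, 39)
TBO_IT2_MATURE = "CIQRHRSCRKSSECCGCSVCQCNLFGQNCQCKSGGLIAC"


@dataclass(frozen=True)
class FrameworkTemplate:
    """A cysteine framework to build synthetic mature toxins on."""

    name: str
    cys_positions: tuple
    mature_length: int

    def __post_init__(self):
        if not self.cys_positions:
            raise ValueError("framework needs at least one cysteine")
        if max(self.cys_positions) > self.mature_length:
            raise ValueError("cysteine position beyond mature length")


TBO_IT2_TEMPLATE = FrameworkTemplate(
    "tbo-it2-like", TBO_IT2_FRAMEWORK_POSITIONS, 39)


# Alphabets chosen so that precursor segmentation has a unique solution:
# the hydrophobic signal core avoids small residues (A/G/S/C), the regions
# after the signal avoid small residues entirely, and Arg occurs only as
# the final residue of the processing motif.
_CORE_AA = "LIVF"
_PRE_CORE_AA = "KNQT"
_SMALL_AA = "AGS"
_PRO_AA = "DENQT"
_LOOP_AA = "ADEFHIKLNPQSTVWY"
_LOOP_AA_SAFE = "DEFHILNPQTVWY"  # no A/G/S/K/R: used around sensitive spots


def _choice(rng, alphabet: str, n: int = 1) -> str:
    return "".join(alphabet[int(i)] for i in
                   rng.integers(0, len(alphabet), size=n))


def _gen_signal(rng) -> str:
    """Signal of length k with small residues exactly at k-2 and k."""
    k = int(rng.integers(18, 27))
    parts = ["M", _choice(rng, _PRE_CORE_AA, 3),
             _choice(rng, _CORE_AA, k - 9),        # positions 5..k-5
             _choice(rng, _CORE_AA, 2),            # k-4, k-3
             _choice(rng, _SMALL_AA),              # k-2
             _choice(rng, _CORE_AA),               # k-1
             _choice(rng, _SMALL_AA)]              # k
    signal = "".join(parts)
    assert len(signal) == k
    return signal


def _gen_propeptide(rng) -> str:
    interior = int(rng.integers(1, 22))  # total length 5..25
    triplet = _choice(rng, "ED", 3)
    return _choice(rng, _PRO_AA, interior) + triplet + "R"


def _gen_mature(rng, template: FrameworkTemplate) -> str:
    first_c, last_c = min(template.cys_positions), max(template.cys_positions)
    out = []
    for pos in range(1, template.mature_length + 1):
        if pos in template.cys_positions:
            out.append("C")
        elif pos < first_c or pos > last_c:
            # no K/R before the first Cys (would mimic a processing motif)
            # and no A/G/S/K/R after the last (would mimic an amidation tail)
            out.append(_choice(rng, _LOOP_AA_SAFE))
        else:
            out.append(_choice(rng, _LOOP_AA))
    return "".join(out)


def _strip_atg(dna: str) -> str:
    out = list(dna)
    for i in range(len(out) - 2):
        while "".join(out[i:i + 3]) == "ATG":
            out[i + 2] = "C"
    return "".join(out)


def reverse_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


@dataclass
class PrecursorTruth:
    transcript_id: str
    aa_sequence: str
    signal: tuple
    propeptide: tuple | None
    mature: tuple
    amidation_tail: tuple | None
    amidated: bool
    mature_seq: str
    orf_start_nt: int
    orf_end_nt: int
    frame: int

    def to_json(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "aa_sequence": self.aa_sequence,
            "signal": list(self.signal),
            "propeptide": list(self.propeptide) if self.propeptide else None,
            "mature": list(self.mature),
            "amidation_tail": (list(self.amidation_tail)
                               if self.amidation_tail else None),
            "amidated": self.amidated,
            "mature_seq": self.mature_seq,
            "orf_start_nt": self.orf_start_nt,
            "orf_end_nt": self.orf_end_nt,
            "frame": self.frame,
        }


def gen_precursor_library(n: int, seed: int,
                          frameworks: list[FrameworkTemplate] | None = None,
                          amidation_prob: float = 0.75,
                          ) -> tuple[list, list]:
    """Generate a synthetic transcript library with full ground truth.

    Returns (transcripts, truths): transcripts as (id, DNA) tuples ready
    for FASTA output and one :class:`PrecursorTruth` per record.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if frameworks is not None and not frameworks:
        raise ValueError("framework list must not be empty")
    frameworks = frameworks or [TBO_IT2_TEMPLATE]
    rng = np.random.default_rng(seed)
    transcripts, truths = [], []
    for i in range(n):
        template = frameworks[int(rng.integers(0, len(frameworks)))]
        signal = _gen_signal(rng)
        propeptide = _gen_propeptide(rng)
        mature = _gen_mature(rng, template)
        amidated = bool(rng.random() < amidation_prob)
        tail = "G" + _choice(rng, "KR", 2) if amidated else ""
        aa = signal + propeptide + mature + tail
        cds = reverse_translate(aa) + "TAA"
        utr5 = _strip_atg(_choice(rng, "ACGT", int(rng.integers(20, 61))))
        utr3 = _strip_atg(_choice(rng, "ACGT", int(rng.integers(20, 61))))
        dna = utr5 + cds + utr3
        tid = f"syn{i:04d}"
        k = len(signal)
        p0 = k + 1
        m0 = k + len(propeptide) + 1
        truth = PrecursorTruth(
            transcript_id=tid,
            aa_sequence=aa,
            signal=(1, k),
            propeptide=(p0, m0 - 1),
            mature=(m0, m0 + len(mature) - 1),
            amidation_tail=((m0 + len(mature), len(aa)) if amidated else None),
            amidated=amidated,
            mature_seq=mature,
            orf_start_nt=len(utr5) + 1,
            orf_end_nt=len(utr5) + 3 * len(aa),
            frame=len(utr5) % 3,
        )
        transcripts.append((tid, dna))
        truths.append(truth)
    return transcripts, truths


def gen_msms_run(peptidoforms: list[Peptidoform], seed: int,
                 ppm_error_sd: float = 3.0, frag_noise_peaks: int = 10,
                 dropout: float = 0.0, frag_mz_sd: float = 0.004,
                 precursor_charge: int = 2) -> tuple[list[Spectrum], dict]:
    """One MS/MS spectrum per peptidoform, with ground-truth assignments.

    Precursor m/z carries a Gaussian ppm error (sd ``ppm_error_sd``); all
    singly charged b/y ions are emitted minus a ``dropout`` fraction, with
    Gaussian m/z jitter and log-normal intensities, plus uniform-random
    noise peaks.  Returns (spectra, truth) with truth mapping spectrum id
    to (peptide sequence, modification label, amidated flag).
    """
    if not 0 <= dropout <= 0.9:
        raise ValueError("dropout must be in [0, 0.9]")
    from .digest import fragment_ions
    rng = np.random.default_rng(seed)
    spectra, truth = [], {}
    for i, form in enumerate(peptidoforms):
        neutral = form.neutral_mass()
        pmz = mz(neutral, precursor_charge)
        pmz *= 1.0 + rng.normal(0.0, ppm_error_sd) * 1e-6
        ions = fragment_ions(form, charges=(1,))
        peaks = []
        for ion in ions:
            if dropout and rng.random() < dropout:
                continue
            peaks.append((ion.mz + rng.normal(0.0, frag_mz_sd),
                          float(rng.lognormal(10.0, 0.5))))
        if ions:
            lo = min(ion.mz for ion in ions) - 50.0
            hi = max(ion.mz for ion in ions) + 50.0
        else:
            lo, hi = 100.0, 1500.0
        for _ in range(frag_noise_peaks):
            peaks.append((float(rng.uniform(lo, hi)),
                          float(rng.lognormal(9.0, 0.5))))
        sid = f"synspec{i:05d}"
        spectra.append(Spectrum(sid, pmz, precursor_charge,
                                tuple(sorted(peaks))))
        truth[sid] = (form.sequence, form.mod_label(), form.c_amidated)
    return spectra, truth


def gen_noise_spectra(target_masses: list[float], seed: int,
                      n_peaks: int = 60, precursor_charge: int = 2,
                      mz_range: tuple = (150.0, 1500.0)) -> list[Spectrum]:
    """Pure-noise spectra whose precursors sit on plausible peptide masses.

    One spectrum per target mass, each with ``n_peaks`` uniform-random
    peaks; used for null (false-discovery) simulations where candidate
    peptides exist but no true fragment evidence does.
    """
    rng = np.random.default_rng(seed)
    spectra = []
    for i, mass in enumerate(target_masses):
        pmz = mz(mass, precursor_charge) * (1.0 + rng.normal(0, 2e-6))
        mzs = np.sort(rng.uniform(mz_range[0], mz_range[1], size=n_peaks))
        intens = rng.lognormal(9.0, 0.5, size=n_peaks)
        peaks = tuple((float(m), float(h)) for m, h in zip(mzs, intens))
        spectra.append(Spectrum(f"noise{i:05d}", pmz, precursor_charge,
                                peaks))
    return spectra


def gen_ms1_run(proteoforms: list[tuple[str, Proteoform]],
                charge_range=range(4, 8), seed: int = 0,
                noise_peaks: int = 50, prune: float = 2e-3,
                mz_range: tuple = (400.0, 1600.0)) -> tuple[list, dict]:
    """Synthetic MS1 peak table with isotope clusters of intact proteoforms.

    Returns (rows, truth): rows are (scan, mz, intensity) sorted by m/z
    within the single simulated scan, truth maps proteoform id to
    (neutral monoisotopic mass, n_disulfides, amidated, charge list).
    """
    if min(charge_range) < 1 or max(charge_range) > 8:
        raise ValueError("charge_range must lie within 1..8")
    rng = np.random.default_rng(seed)
    rows = []
    truth = {}
    for pid, form in proteoforms:
        envelope = isotope_envelope(form.composition(), prune=prune)
        mono = monoisotopic_mass(form)
        for z in charge_range:
            scale = float(rng.lognormal(13.0, 0.3))
            for k, mass_k, abundance in envelope.peaks:
                # offset the convolved mass so the envelope sits on the
                # printed-value mass scale of the proteoform
                mass = mono + (mass_k - envelope.mass_at(0))
                rows.append((1, mz(mass, z), abundance * scale))
        truth[pid] = (mono, form.n_disulfides, form.c_amidated,
                      list(charge_range))
    for _ in range(noise_peaks):
        rows.append((1, float(rng.uniform(*mz_range)),
                     float(rng.lognormal(9.0, 0.8))))
    rows.sort(key=lambda r: r[1])
    return rows, truth


# ---------------------------------------------------------------------------
# Toy 3D structures

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.53, "CB-SG": 1.81}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "N-CA-CB": 110.4, "CA-CB-SG": 114.0}


def place_atom(a, b, c, length: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = length, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-length * math.cos(angle),
                        length * math.sin(angle) * math.cos(torsion),
                        length * math.sin(angle) * math.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_from_torsions(seq: str, torsions, omega: float = 180.0
                           ) -> StructureModel:
    """Build an ideal-geometry backbone from (phi, psi) per residue.

    ``torsions[i]`` supplies (phi_i, psi_i); phi of the first residue and
    psi of the last are ignored.  Adds carbonyl O (in the peptide plane,
    anti to the next N), CB for non-Gly residues, and an SG stub for
    cysteines.
    """
    n_res = len(seq)
    if len(torsions) != n_res:
        raise ValueError("need one (phi, psi) pair per residue")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND["N-CA"], 0.0, 0.0])]
    theta = math.radians(_ANGLE["N-CA-C"])
    C = [CA[0] + _BOND["CA-C"] * np.array([-math.cos(theta),
                                           math.sin(theta), 0.0])]
    for i in range(n_res - 1):
        psi = torsions[i][1]
        N.append(place_atom(N[i], CA[i], C[i], _BOND["C-N"],
                            _ANGLE["CA-C-N"], psi))
        CA.append(place_atom(CA[i], C[i], N[i + 1], _BOND["N-CA"],
                             _ANGLE["C-N-CA"], omega))
        phi = torsions[i + 1][0]
        C.append(place_atom(C[i], N[i + 1], CA[i + 1], _BOND["CA-C"],
                            _ANGLE["N-CA-C"], phi))
    residues = []
    for i in range(n_res):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        if i < n_res - 1:
            u = N[i + 1] - C[i]
            v = CA[i] - C[i]
            direction = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
        else:
            virtual_n = place_atom(N[i], CA[i], C[i], _BOND["C-N"],
                                   _ANGLE["CA-C-N"], torsions[i][1])
            u = virtual_n - C[i]
            v = CA[i] - C[i]
            direction = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
        atoms["O"] = C[i] + _BOND["C-O"] * direction / np.linalg.norm(direction)
        if seq[i] != "G":
            atoms["CB"] = place_atom(C[i], N[i], CA[i], _BOND["CA-CB"],
                                     _ANGLE["N-CA-CB"], -122.0)
            if seq[i] == "C":
                atoms["SG"] = place_atom(N[i], CA[i], atoms["CB"],
                                         _BOND["CB-SG"],
                                         _ANGLE["CA-CB-SG"], 180.0)
        residues.append(Residue(i + 1, seq[i], atoms))
    return StructureModel(tuple(residues))


def gen_toy_structure(seq: str, disulfide_pairs, seed: int,
                      ss_bond_length: float = 2.03,
                      max_tries: int = 50) -> StructureModel:
    """Toy coordinates with known disulfide pairings (synthetic geometry).

    An extended-like backbone with randomized torsions is built, then the
    S-gamma atoms of each requested cysteine pair are repositioned
    symmetrically about the midpoint of their CB atoms, 2.03 A apart.
    Coordinates are a synthetic fixture: chemically plausible locally, not
    a physically folded chain.
    """
    pairs = [tuple(sorted(p)) for p in disulfide_pairs]
    for i, j in pairs:
        for p in (i, j):
            if p < 1 or p > len(seq) or seq[p - 1] != "C":
                raise ValueError(f"disulfide partner {p} is not a cysteine")
    flat = [p for pair in pairs for p in pair]
    if len(flat) != len(set(flat)):
        raise ValueError("a cysteine may appear in at most one pair")
    rng = np.random.default_rng(seed)
    paired = set(flat)
    for _ in range(max_tries):
        torsions = [(float(rng.normal(-120.0, 25.0)),
                     float(rng.normal(130.0, 25.0))) for _ in seq]
        model = backbone_from_torsions(seq, torsions)
        residues = {r.index: dict(r.atoms) for r in model.residues}
        for i, j in pairs:
            cb_i, cb_j = residues[i]["CB"], residues[j]["CB"]
            mid = (cb_i + cb_j) / 2.0
            u = cb_j - cb_i
            norm = np.linalg.norm(u)
            u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
            residues[i]["SG"] = mid - u * ss_bond_length / 2.0
            residues[j]["SG"] = mid + u * ss_bond_length / 2.0
        new_model = StructureModel(tuple(
            Residue(r.index, r.aa, residues[r.index])
            for r in model.residues))
        # reject conformers where unrelated S-gamma atoms collide
        sg = {r.index: r.atoms["SG"] for r in new_model.residues
              if r.aa == "C" and "SG" in r.atoms}
        ok = True
        for a in sg:
            for b in sg:
                if a >= b or tuple(sorted((a, b))) in pairs:
                    continue
                if np.linalg.norm(sg[a] - sg[b]) <= 3.0:
                    ok = False
        if ok:
            return new_model
    raise RuntimeError("could not place disulfides without collisions")
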