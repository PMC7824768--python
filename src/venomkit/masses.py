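"""Elemental compositions, masses, isotope envelopes and m/z arithmetic.

A :class:`Proteoform` is a mature peptide together with its PTM state — the
number of disulfide bonds, C-terminal amidation, and fixed residue
modifications.  Its elemental composition is the sum of the residue formulas
plus one water, minus two hydrogens per disulfide bond, with the amide delta
(-O +N +H) when amidated, plus any fixed-modification deltas.

Isotope envelopes are computed by exact polynomial convolution of the
per-element isotope distributions, aggregated at unit (nominal) resolution,
which is how peaks of an MS1 isotope cluster are read out.  Fine isotopic
structure is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._tables import (
    AA20,
    AMIDE_DELTA_COMP,
    AMIDE_DELTA_MASS,
    AVERAGE,
    ISOTOPES,
    MONO,
    PROTON,
    RESIDUE_FORMULA,
    WATER,
)

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class Composition:
    """CHNOS elemental composition with non-negative counts."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self):
        for el in _ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition: {self}")

    def __add__(self, other: "Composition") -> "Composition":
        return Composition(**{el: getattr(self, el) + getattr(other, el)
                              for el in _ELEMENTS})

    def __sub__(self, other: "Composition") -> "Composition":
        return Composition(**{el: getattr(self, el) - getattr(other, el)
                              for el in _ELEMENTS})

    def items(self):
        return [(el, getattr(self, el)) for el in _ELEMENTS if getattr(self, el)]

    @property
    def total_atoms(self) -> int:
        return sum(getattr(self, el) for el in _ELEMENTS)

    def monoisotopic(self) -> float:
        return sum(n * MONO[el] for el, n in self.items())

    def average(self) -> float:
        return sum(n * AVERAGE[el] for el, n in self.items())


def _shifted(delta: dict) -> tuple[Composition, Composition]:
    """Split a possibly-negative element delta into (plus, minus) parts."""
    plus = {el: n for el, n in delta.items() if n > 0}
    minus = {el: -n for el, n in delta.items() if n < 0}
    return Composition(**plus), Composition(**minus)


@dataclass(frozen=True)
class Proteoform:
    """A peptide sequence with its post-translational modification state.

    Parameters
    ----------
    sequence : str
        Canonical one-letter amino-acid sequence.
    n_disulfides : int
        Number of intramolecular disulfide bonds (each removes 2 H).
    c_amidated : bool
        Whether the C-terminal carboxyl is converted to an amide.
    fixed_mods : tuple of (residue, mass delta, composition delta dict)
        Applied to every occurrence of the residue.
    """

    sequence: str
    n_disulfides: int = 0
    c_amidated: bool = False
    fixed_mods: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for i, aa in enumerate(self.sequence):
            if aa not in AA20:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i + 1}")
        n_cys = self.sequence.count("C")
        if self.n_disulfides < 0 or 2 * self.n_disulfides > n_cys:
            raise ValueError(
                f"{self.n_disulfides} disulfides impossible with {n_cys} Cys")

    def composition(self) -> Composition:
        comp = Composition(**WATER)
        for aa in self.sequence:
            comp = comp + Composition(**RESIDUE_FORMULA[aa])
        comp = comp - Composition(H=2 * self.n_disulfides)
        if self.c_amidated:
            plus, minus = _shifted(AMIDE_DELTA_COMP)
            comp = comp + plus - minus
        for residue, _dm, dcomp in self.fixed_mods:
            n = self.sequence.count(residue)
            plus, minus = _shifted(dcomp)
            for _ in range(n):
                comp = comp + plus - minus
        return comp


def residue_mass(aa: str) -> float:
    """Monoisotopic residue (amino acid minus water) mass, Da."""
    return Composition(**RESIDUE_FORMULA[aa]).monoisotopic()


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of an unmodified peptide, Da."""
    return Proteoform(sequence).composition().monoisotopic()


def monoisotopic_mass(p: Proteoform) -> float:
    """Neutral monoisotopic mass of a proteoform, Da.

    Equivalent to the composition route, but computed as residue-mass sum so
    the disulfide and amide deltas enter with their conventional printed
    values rather than through integer element counts.
    """
    mass = sum(residue_mass(aa) for aa in p.sequence)
    mass += Composition(**WATER).monoisotopic()
    mass -= 2 * p.n_disulfides * 1.0078250319
    if p.c_amidated:
        mass += AMIDE_DELTA_MASS
    for residue, dm, _dc in p.fixed_mods:
        mass += dm * p.sequence.count(residue)
    return mass


def average_mass(p: Proteoform) -> float:
    """Neutral average mass of a proteoform, Da."""
    return p.composition().average()


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Unit-resolution isotopologue distribution.

    ``peaks`` is a tuple of (nominal offset k, exact mass Da, relative
    abundance); offset 0 is the monoisotopic peak.  Exact masses are
    abundance-weighted means within each nominal bin.
    """

    peaks: tuple

    @property
    def offsets(self):
        return [k for k, _, _ in self.peaks]

    @property
    def apex_offset(self) -> int:
        """Nominal offset of the most abundant isotopologue."""
        return max(self.peaks, key=lambda p: p[2])[0]

    def mass_at(self, offset: int) -> float:
        for k, m, _ in self.peaks:
            if k == offset:
                return m
        raise KeyError(offset)

    def abundance_at(self, offset: int) -> float:
        for k, _, a in self.peaks:
            if k == offset:
                return a
        raise KeyError(offset)


def _single_element_distribution(element: str):
    """Distribution for one atom: dict nominal offset -> (abundance, mass)."""
    iso = ISOTOPES[element]
    base_nominal = round(iso[0][0])
    dist = {}
    for mass, abundance in iso:
        k = round(mass) - base_nominal
        a0, m0 = dist.get(k, (0.0, 0.0))
        a = a0 + abundance
        dist[k] = (a, (m0 * a0 + mass * abundance) / a)
    return dist


def _convolve(d1: dict, d2: dict, floor: float = 1e-15) -> dict:
    out = {}
    for k1, (a1, m1) in d1.items():
        for k2, (a2, m2) in d2.items():
            a = a1 * a2
            if a < floor:
                continue
            k = k1 + k2
            a0, m0 = out.get(k, (0.0, 0.0))
            anew = a0 + a
            out[k] = (anew, (m0 * a0 + (m1 + m2) * a) / anew)
    return out


def _element_power(element: str, n: int) -> dict:
    """Distribution of n atoms of one element, by binary exponentiation."""
    result = {0: (1.0, 0.0)}
    base = _single_element_distribution(element)
    while n:
        if n & 1:
            result = _convolve(result, base)
        base = _convolve(base, base)
        n >>= 1
    return result


def isotope_envelope(c: Composition, prune: float = 1e-4) -> IsotopeEnvelope:
    """Exact unit-resolution isotope envelope of a composition.

    Parameters
    ----------
    c : Composition
        Elemental composition; must be non-empty.
    prune : float
        Final relative-abundance floor, in (0, 0.01].

    Returns
    -------
    IsotopeEnvelope
        Peaks sorted by nominal offset, abundances each in [0, 1] and
        summing to at most 1.
    """
    if c.total_atoms == 0:
        raise ValueError("empty composition has no isotope envelope")
    if not 0 < prune <= 0.01:
        raise ValueError("prune floor must be in (0, 0.01]")
    dist = {0: (1.0, 0.0)}
    for el, n in c.items():
        dist = _convolve(dist, _element_power(el, n))
    peaks = sorted((k, m, a) for k, (a, m) in dist.items() if a >= prune)
    return IsotopeEnvelope(tuple(peaks))


def mz(neutral_mass: float, z: int) -> float:
    """m/z of a positive ion: (M + z * m_proton) / z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON) / z


def neutral_mass_from_mz(observed_mz: float, z: int) -> float:
    """Invert :func:`mz`: neutral mass from an observed m/z and charge."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return observed_mz * z - z * PROTON
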