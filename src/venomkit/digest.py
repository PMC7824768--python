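"""In-silico protease digestion and theoretical b/y fragment ions.

Supported enzymes: trypsin (cleaves C-terminal to Lys/Arg; the classic
"not before Pro" exception is available behind a flag and off by default)
and endoproteinase GluC in bicarbonate buffer (cleaves C-terminal to Glu
and Asp).

A C-terminally amidated parent propagates its amide only to the digest
peptide that contains the parent C-terminus, and within fragment series only
to y-ions (which contain the peptide C-terminus).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._tables import PROTON, WATER
from .masses import Composition, Proteoform, residue_mass

_WATER_MASS = Composition(**WATER).monoisotopic()

ENZYMES = {
    "trypsin": "KR",
    "gluc": "ED",
}


@dataclass(frozen=True)
class ProteolyticPeptide:
    sequence: str
    start: int  # 1-based inclusive in parent
    end: int
    missed_cleavages: int
    c_amidated: bool = False

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class Peptidoform:
    """A proteolytic peptide with a concrete modification assignment.

    ``mods`` is a tuple of (1-based position in peptide, mass delta, label).
    """

    peptide: ProteolyticPeptide
    mods: tuple = field(default_factory=tuple)

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def c_amidated(self) -> bool:
        return self.peptide.c_amidated

    def neutral_mass(self) -> float:
        from ._tables import AMIDE_DELTA_MASS
        mass = sum(residue_mass(a) for a in self.sequence) + _WATER_MASS
        mass += sum(dm for _, dm, _ in self.mods)
        if self.c_amidated:
            mass += AMIDE_DELTA_MASS
        return mass

    def mod_label(self) -> str:
        if not self.mods:
            return ""
        return ";".join(f"{label}@{pos}" for pos, _, label in self.mods)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    index: int   # 1..L-1
    charge: int
    mz: float


def cleavage_sites(sequence: str, enzyme: str,
                   proline_rule: bool = False) -> list[int]:
    """0-based positions after which the enzyme cleaves."""
    if enzyme not in ENZYMES:
        raise ValueError(
            f"unknown enzyme {enzyme!r}; supported: {sorted(ENZYMES)}")
    targets = ENZYMES[enzyme]
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in targets:
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(parent: Proteoform, enzyme: str, max_missed: int,
           proline_rule: bool = False) -> list[ProteolyticPeptide]:
    """All digestion products with up to ``max_missed`` missed cleavages.

    Peptide coordinates are 1-based inclusive in the parent sequence; the
    parent-C-terminal peptide inherits the parent's amidation state.
    """
    if not 0 <= max_missed <= 6:
        raise ValueError("max_missed must be in 0..6")
    seq = parent.sequence
    sites = cleavage_sites(seq, enzyme, proline_rule)
    # boundaries as 0-based exclusive ends of peptides
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_missed + 2, len(bounds))):
            start, end = bounds[a], bounds[b]
            peptides.append(ProteolyticPeptide(
                sequence=seq[start:end],
                start=start + 1,
                end=end,
                missed_cleavages=b - a - 1,
                c_amidated=parent.c_amidated and end == len(seq),
            ))
    return peptides


def apply_modifications(pep: ProteolyticPeptide,
                        fixed: dict | None,
                        variable: dict | None,
                        max_variable: int = 0) -> list[Peptidoform]:
    """Enumerate peptidoforms of a peptide under fixed + variable mods.

    ``fixed`` and ``variable`` map residue letter -> (mass delta, label).
    Fixed mods apply to every matching residue; variable mods are enumerated
    combinatorially with at most ``max_variable`` per peptide.  A site
    already carrying a fixed mod is not considered for variable ones.
    """
    if not 0 <= max_variable <= 4:
        raise ValueError("max_variable must be in 0..4")
    fixed = fixed or {}
    variable = variable or {}
    base = []
    fixed_positions = set()
    for i, aa in enumerate(pep.sequence):
        if aa in fixed:
            dm, label = fixed[aa]
            base.append((i + 1, dm, label))
            fixed_positions.add(i + 1)
    var_sites = [(i + 1, variable[aa]) for i, aa in enumerate(pep.sequence)
                 if aa in variable and (i + 1) not in fixed_positions]
    forms = []
    for k in range(0, max_variable + 1):
        for combo in itertools.combinations(var_sites, k):
            mods = list(base) + [(pos, dm, label) for pos, (dm, label) in combo]
            mods.sort(key=lambda m: m[0])
            forms.append(Peptidoform(pep, tuple(mods)))
    return forms


def fragment_ions(form: Peptidoform, charges=(1,)) -> list[FragmentIon]:
    """Theoretical b/y singly-to-multiply charged fragment ions.

    b_i is the N-terminal fragment of i residues (sum of residue masses plus
    mods, protonated); y_i is the C-terminal fragment of i residues (residue
    masses plus water plus mods, protonated), carrying the amide delta when
    the peptide is amidated.  2 (L-1) |charges| ions are produced.
    """
    from ._tables import AMIDE_DELTA_MASS
    seq = form.sequence
    if len(seq) < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")
    mod_at = {}
    for pos, dm, _ in form.mods:
        mod_at[pos] = mod_at.get(pos, 0.0) + dm
    prefix = [0.0]
    for i, aa in enumerate(seq, start=1):
        prefix.append(prefix[-1] + residue_mass(aa) + mod_at.get(i, 0.0))
    total = prefix[-1]
    ions = []
    for i in range(1, len(seq)):
        b_neutral = prefix[i]
        y_neutral = total - prefix[len(seq) - i] + _WATER_MASS
        if form.c_amidated:
            y_neutral += AMIDE_DELTA_MASS
        for z in charges:
            ions.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", i, z, (y_neutral + z * PROTON) / z))
    return ions


def digest_table(parent: Proteoform, enzyme: str, max_missed: int) -> str:
    """Tab-separated digest report (Enzyme, Peptide, AA-from, AA-to,
    Missed Cleavages), amidated peptides marked with an -NH2 suffix."""
    lines = ["Enzyme\tPeptide\tAA-from\tAA-to\tMissed Cleavages"]
    for pep in digest(parent, enzyme, max_missed):
        name = pep.sequence + ("-NH2" if pep.c_amidated else "")
        lines.append(f"{enzyme}\t{name}\t{pep.start}\t{pep.end}\t"
                     f"{pep.missed_cleavages}")
    return "\n".join(lines) + "\n"
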