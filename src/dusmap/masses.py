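"""Monoisotopic and average masses of modified oligonucleotide fragments.

An RNA fragment is priced as the sum of its nucleoside-3'-monophosphate
residue masses (parent nucleotide plus the modification's mass delta) minus
one water per phosphodiester condensation, with terminal adjustments:

    neutral = sum(NMP_i) - (n-1)*H2O  [gives 5'-OH / 3'-phosphate]
    3'-OH               : -HPO3
    2',3'-cyclic        : -H2O
    5'-phosphate        : +HPO3

MALDI spectra in positive ion mode observe the singly protonated species
[M+H]+; nominal (integer) m/z rounds half away from zero, matching the way
peak labels are printed on linear-mode MALDI-TOF spectra of short
oligonucleotides.  Dihydrouridine adds two hydrogens to uridine (+2.016 Da),
so a D-containing fragment sits 2 nominal Da above its unmodified
counterpart — equivalently, loss of D in a knockout shifts the peak -2 Da.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .digestion import Fragment
from .trna import ModificationTable, DEFAULT_MODIFICATIONS, TRNAError

__all__ = ["MassSpec", "fragment_mass", "mass_delta", "collision_check",
           "theoretical_peak_table", "PROTON"]

# Monoisotopic element masses (CODATA/IUPAC, 5 decimals) and standard
# atomic weights for average masses.
MONO = {"H": 1.00783, "C": 12.00000, "N": 14.00307, "O": 15.99491, "P": 30.97376}
AVG = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}

# Nucleoside-3'-monophosphate elemental compositions.
_NMP_FORMULA = {
    "A": {"C": 10, "H": 14, "N": 5, "O": 7, "P": 1},
    "C": {"C": 9, "H": 14, "N": 3, "O": 8, "P": 1},
    "G": {"C": 10, "H": 14, "N": 5, "O": 8, "P": 1},
    "U": {"C": 9, "H": 13, "N": 2, "O": 9, "P": 1},
}


def _formula_mass(formula: dict[str, int], elements: dict[str, float]) -> float:
    return sum(elements[el] * k for el, k in formula.items())


NMP_MONO = {b: _formula_mass(f, MONO) for b, f in _NMP_FORMULA.items()}
NMP_AVG = {b: _formula_mass(f, AVG) for b, f in _NMP_FORMULA.items()}

H2O_MONO = _formula_mass({"H": 2, "O": 1}, MONO)
H2O_AVG = _formula_mass({"H": 2, "O": 1}, AVG)
HPO3_MONO = _formula_mass({"H": 1, "P": 1, "O": 3}, MONO)
HPO3_AVG = _formula_mass({"H": 1, "P": 1, "O": 3}, AVG)
PROTON = 1.00728


@dataclass(frozen=True)
class MassSpec:
    """How to report a fragment mass.

    mode: "monoisotopic" or "average"; adduct: "M+H", "M-H" or "neutral";
    rounding: "exact" (full precision) or "nominal" (nearest integer, half
    away from zero).  The default matches positive-mode MALDI with integer
    peak labels.
    """

    mode: str = "monoisotopic"
    adduct: str = "M+H"
    rounding: str = "exact"

    def __post_init__(self) -> None:
        if self.mode not in ("monoisotopic", "average"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.adduct not in ("M+H", "M-H", "neutral"):
            raise ValueError(f"invalid adduct {self.adduct!r}")
        if self.rounding not in ("exact", "nominal"):
            raise ValueError(f"invalid rounding {self.rounding!r}")


MALDI_POSITIVE = MassSpec("monoisotopic", "M+H", "nominal")


def _round_half_away(x: float) -> float:
    import math
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


def fragment_mass(fragment: Fragment, spec: MassSpec = MassSpec(),
                  table: ModificationTable = DEFAULT_MODIFICATIONS) -> float:
    """Mass of a fragment under the given reporting convention (Da)."""
    if len(fragment) == 0:
        raise TRNAError("empty fragment has no mass")
    mono = spec.mode == "monoisotopic"
    nmp = NMP_MONO if mono else NMP_AVG
    h2o = H2O_MONO if mono else H2O_AVG
    hpo3 = HPO3_MONO if mono else HPO3_AVG

    mass = 0.0
    for r in fragment.residues:
        if r.base not in nmp:
            raise TRNAError(f"invalid base {r.base!r}")
        mass += nmp[r.base]
        if r.modification is not None:
            entry = table[r.modification]
            mass += entry.mono_delta if mono else entry.avg_delta
    mass -= (len(fragment) - 1) * h2o

    if fragment.three_prime == "OH":
        mass -= hpo3
    elif fragment.three_prime == "cyclic_phosphate":
        mass -= h2o
    if fragment.five_prime == "P":
        mass += hpo3

    if spec.adduct == "M+H":
        mass += PROTON
    elif spec.adduct == "M-H":
        mass -= PROTON

    if spec.rounding == "nominal":
        return _round_half_away(mass)
    return mass


def mass_delta(frag_modified: Fragment, frag_unmodified: Fragment,
               spec: MassSpec = MassSpec(),
               table: ModificationTable = DEFAULT_MODIFICATIONS) -> float:
    """Mass difference between two fragments equal up to modification codes."""
    if len(frag_modified) != len(frag_unmodified):
        raise TRNAError("fragments differ in length")
    for a, b in zip(frag_modified.residues, frag_unmodified.residues):
        if a.base != b.base:
            raise TRNAError(
                f"fragments differ in base composition ({a.base} vs {b.base})")
    if (frag_modified.five_prime != frag_unmodified.five_prime
            or frag_modified.three_prime != frag_unmodified.three_prime):
        raise TRNAError("fragments differ in terminal chemistry")
    neutral = MassSpec(spec.mode, "neutral", spec.rounding)
    return fragment_mass(frag_modified, neutral, table) - \
        fragment_mass(frag_unmodified, neutral, table)


def collision_check(fragments, spec: MassSpec = MassSpec(),
                    tolerance_da: float = 0.5,
                    table: ModificationTable = DEFAULT_MODIFICATIONS,
                    ) -> list[tuple[Fragment, Fragment]]:
    """All unordered fragment pairs whose masses differ by <= tolerance."""
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    frags = list(fragments)
    masses = [fragment_mass(f, spec, table) for f in frags]
    out = []
    for (i, fa), (j, fb) in itertools.combinations(enumerate(frags), 2):
        if abs(masses[i] - masses[j]) <= tolerance_da:
            out.append((fa, fb))
    return out


def theoretical_peak_table(fragments, table: ModificationTable = DEFAULT_MODIFICATIONS) -> str:
    """TSV of neutral mass, [M+H]+ and nominal m/z per fragment."""
    lines = ["fragment\tcomposition\tneutral_mass\tmz_MplusH\tnominal_mz"]
    for f in fragments:
        neutral = fragment_mass(f, MassSpec(adduct="neutral"), table)
        mh = fragment_mass(f, MassSpec(adduct="M+H"), table)
        nominal = fragment_mass(f, MALDI_POSITIVE, table)
        comp = "".join(sorted(r.code() for r in f.residues))
        lines.append(f"{f.display()}\t{comp}\t{neutral:.5f}\t{mh:.4f}\t{nominal:.0f}")
    return "\n".join(lines) + "\n"
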