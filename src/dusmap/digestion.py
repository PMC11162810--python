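"""In-silico RNase T1 / RNase A digestion of annotated tRNAs.

Both nucleases cleave the phosphodiester backbone 3' of their recognition
residue through a 2'-OH-mediated transesterification, leaving (after
linearization of the cyclic intermediate) a 3'-phosphate on the upstream
fragment and a 5'-OH on the downstream fragment:

* RNase T1 cuts after guanosine (including base-methylated forms such as
  m7G, whose Watson-Crick face modification does not block the enzyme);
* RNase A cuts after pyrimidines — C, U and, as the observed dihydrouridine-
  terminal fragments show, D as well.

2'-O-methylated residues (Um, Cm, Gm, Am) are resistant to both enzymes
because the transesterification chemistry requires the 2'-OH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

from .trna import AnnotatedTRNA, PositionLabel, Residue

__all__ = [
    "Fragment",
    "CleavageRule",
    "RNASE_T1",
    "RNASE_A",
    "get_rule",
    "digest",
    "fragments_covering",
    "fragment_table",
]

_RIBOSE_METHYL = "2'O-methyl"


@dataclass(frozen=True)
class Fragment:
    """A contiguous digestion product with defined terminal chemistry."""

    residues: tuple[Residue, ...]
    parent_id: str = ""
    five_prime: str = "OH"            # {"OH", "P"}
    three_prime: str = "phosphate"    # {"phosphate", "cyclic_phosphate", "OH"}

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty fragment")
        if self.five_prime not in ("OH", "P"):
            raise ValueError(f"invalid 5' chemistry {self.five_prime!r}")
        if self.three_prime not in ("phosphate", "cyclic_phosphate", "OH"):
            raise ValueError(f"invalid 3' chemistry {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start_label(self) -> PositionLabel:
        return self.residues[0].label

    @property
    def end_label(self) -> PositionLabel:
        return self.residues[-1].label

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def display(self) -> str:
        """Sequence with modification codes, e.g. ``U[D]G``."""
        out = []
        for r in self.residues:
            out.append(f"[{r.modification}]" if r.modification else r.base)
        return "".join(out)

    def covers(self, label: PositionLabel) -> bool:
        return any(r.label == label for r in self.residues)


@dataclass(frozen=True)
class CleavageRule:
    enzyme: str
    cleave_after: Callable[[Residue], bool] = field(compare=False)
    resistant_codes: frozenset[str] = frozenset()

    def cuts_after(self, residue: Residue) -> bool:
        if residue.modification in self.resistant_codes:
            return False
        return self.cleave_after(residue)

    def with_resistant(self, codes: Iterable[str]) -> "CleavageRule":
        return replace(self, resistant_codes=frozenset(codes))


_2OM_CODES = frozenset({"Um", "Cm", "Gm", "Am"})

RNASE_T1 = CleavageRule(
    "RNaseT1", lambda r: r.base == "G", resistant_codes=_2OM_CODES)
RNASE_A = CleavageRule(
    "RNaseA", lambda r: r.base in ("C", "U"), resistant_codes=_2OM_CODES)

_RULES = {"RNaseT1": RNASE_T1, "RNaseA": RNASE_A, "T1": RNASE_T1, "A": RNASE_A}


def get_rule(enzyme) -> CleavageRule:
    if isinstance(enzyme, CleavageRule):
        return enzyme
    try:
        return _RULES[str(enzyme)]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; use RNaseT1 or RNaseA") from None


def digest(trna: AnnotatedTRNA, enzyme, missed_cleavages: int = 0,
           parent_five_prime: str = "P") -> list[Fragment]:
    """Digest a tRNA, returning fragments in 5'->3' order.

    A complete digest partitions the sequence at every qualifying residue;
    with ``missed_cleavages = k`` every union of up to k+1 adjacent complete-
    digest fragments is additionally returned.  Internal fragments carry
    5'-OH / 3'-phosphate; the molecule's first fragment keeps the parent 5'
    chemistry (mature tRNA: 5'-P) and the 3'-terminal fragment ends 3'-OH
    unless its last residue was itself a cut site.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    rule = get_rule(enzyme)
    n = len(trna)
    # cut points: index i means a cut between residue i and i+1
    cuts = [i for i in range(n - 1) if rule.cuts_after(trna.residues[i])]
    terminal_cut = n > 0 and rule.cuts_after(trna.residues[n - 1])
    bounds = [0] + [c + 1 for c in cuts] + [n]
    pieces = list(zip(bounds[:-1], bounds[1:]))

    frags: list[Fragment] = []
    for span in range(1, missed_cleavages + 2):
        for i in range(len(pieces) - span + 1):
            start = pieces[i][0]
            end = pieces[i + span - 1][1]
            five = parent_five_prime if start == 0 else "OH"
            if end == n:
                three = "phosphate" if terminal_cut else "OH"
            else:
                three = "phosphate"
            frags.append(Fragment(tuple(trna.residues[start:end]),
                                  parent_id=trna.id,
                                  five_prime=five, three_prime=three))
    return frags


def fragments_covering(trna: AnnotatedTRNA, enzyme,
                       label: PositionLabel | str | int,
                       missed_cleavages: int = 0) -> list[Fragment]:
    """All digest fragments whose span includes the given position label."""
    if not isinstance(label, PositionLabel):
        label = PositionLabel.parse(label)
    trna.label_to_index(label)  # raises if absent
    return [f for f in digest(trna, enzyme, missed_cleavages) if f.covers(label)]


def fragment_table(fragments: Iterable[Fragment]) -> str:
    """TSV fragment report: parent, span, sequence-with-mods, termini."""
    lines = ["parent_id\tstart_label\tend_label\tsequence_with_mods\t"
             "five_prime\tthree_prime"]
    for f in fragments:
        lines.append(f"{f.parent_id}\t{f.start_label}\t{f.end_label}\t"
                     f"{f.display()}\t{f.five_prime}\t{f.three_prime}")
    return "\n".join(lines) + "\n"
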