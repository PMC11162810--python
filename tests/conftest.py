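import re

import pytest

from dusmap.digestion import Fragment
from dusmap.trna import AnnotatedTRNA, PositionLabel, Residue

_TOKEN = re.compile(r"\[([^\]]+)\]|(.)")


def parse_residues(code: str) -> list[Residue]:
    """'U[D]G' or 'UDG' -> residues; bare 'D' means dihydrouridine on U."""
    residues = []
    for i, m in enumerate(_TOKEN.finditer(code)):
        tok = m.group(1) or m.group(2)
        lab = PositionLabel(i + 1)
        if tok == "D":
            residues.append(Residue("U", lab, "D"))
        elif len(tok) > 1:
            base = {"m7G": "G", "m5U": "U", "Um": "U", "Cm": "C",
                    "Gm": "G", "Am": "A", "m1A": "A", "m3C": "C",
                    "m5C": "C", "ho5C": "C"}[tok]
            residues.append(Residue(base, lab, tok))
        else:
            residues.append(Residue(tok, lab))
    return residues


def make_fragment(code: str, five: str = "OH",
                  three: str = "phosphate") -> Fragment:
    """Build a standalone fragment such as the MALDI diagnostics (UDG etc.)."""
    return Fragment(tuple(parse_residues(code)), parent_id="frag",
                    five_prime=five, three_prime=three)


def make_trna(trna_id: str, code: str, labels=None) -> AnnotatedTRNA:
    residues = parse_residues(code)
    if labels is not None:
        labels = [PositionLabel.parse(x) for x in labels]
        residues = [Residue(r.base, lab, r.modification)
                    for r, lab in zip(residues, labels)]
    return AnnotatedTRNA(trna_id, residues)


@pytest.fixture
def gudga():
    """The diagnostic trinucleotide context: G | U-D-G | A after RNase T1."""
    return make_trna("t-gudga", "GU[D]GA")
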