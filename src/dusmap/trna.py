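"""Data model and I/O for modification-annotated tRNA sequences.

tRNA residues are addressed by canonical (Sprinzl-style) position labels such
as ``17``, ``20``, ``20a``, ``20b`` or ``47``: a positive integer plus an
optional insertion letter.  No automatic canonical alignment is performed —
labels are either supplied explicitly alongside the sequence or default to
``1..n``.  Internally all algorithms work on 0-based indices; labels are a
display/IO concern only.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PositionLabel",
    "Residue",
    "ModificationTable",
    "AnnotatedTRNA",
    "TRNAError",
    "read_trna_set",
    "write_trna_set",
    "DEFAULT_MODIFICATIONS",
]

BASES = frozenset("ACGU")

_LABEL_RE = re.compile(r"^(\d+)([a-z]?)$")


class TRNAError(ValueError):
    """Invalid tRNA annotation, label or modification input."""


@total_ordering
@dataclass(frozen=True)
class PositionLabel:
    """Canonical tRNA position: a number plus optional insertion letter.

    Ordering compares the number first, then the suffix with the bare
    position sorting before any lettered insertion ("20" < "20a" < "20b").
    """

    number: int
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.number <= 0:
            raise TRNAError(f"position number must be positive, got {self.number}")
        if self.suffix and not (len(self.suffix) == 1 and self.suffix.islower()):
            raise TRNAError(f"suffix must be one lowercase letter, got {self.suffix!r}")

    @classmethod
    def parse(cls, text: str | int) -> "PositionLabel":
        if isinstance(text, int):
            return cls(text)
        m = _LABEL_RE.match(str(text).strip())
        if not m:
            raise TRNAError(f"cannot parse position label {text!r}")
        return cls(int(m.group(1)), m.group(2))

    def __str__(self) -> str:
        return f"{self.number}{self.suffix}"

    def __lt__(self, other: "PositionLabel") -> bool:
        if not isinstance(other, PositionLabel):
            return NotImplemented
        return (self.number, self.suffix) < (other.number, other.suffix)


@dataclass(frozen=True)
class ModificationEntry:
    parent_base: str
    mono_delta: float
    avg_delta: float
    flags: frozenset[str] = frozenset()


class ModificationTable:
    """Registry of modification codes -> parent base, mass deltas, flags.

    The flag ``"2'O-methyl"`` marks ribose methylation, which blocks the
    transesterification step of RNase T1 / RNase A cleavage.
    """

    def __init__(self, entries: Mapping[str, ModificationEntry] | None = None):
        self._entries: dict[str, ModificationEntry] = dict(entries or {})

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> ModificationEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise TRNAError(f"unknown modification code {code!r}") from None

    def codes(self) -> list[str]:
        return sorted(self._entries)

    def add(self, code: str, parent_base: str, mono_delta: float,
            avg_delta: float, flags: Iterable[str] = ()) -> None:
        self._entries[code] = ModificationEntry(
            parent_base, mono_delta, avg_delta, frozenset(flags))

    @classmethod
    def from_tsv(cls, source) -> "ModificationTable":
        """Load a user table: columns code, parent_base, mono_delta, avg_delta[, flags]."""
        df = pd.read_csv(source, sep="\t")
        table = cls()
        for row in df.itertuples(index=False):
            flags = ()
            if hasattr(row, "flags") and isinstance(row.flags, str):
                flags = tuple(f for f in row.flags.split(",") if f)
            table.add(row.code, row.parent_base, float(row.mono_delta),
                      float(row.avg_delta), flags)
        return table


_METHYL_MONO, _METHYL_AVG = 14.01565, 14.0266
_2OM = ("2'O-methyl",)

#: Default modification registry (MODOMICS-style short names).  Dihydrouridine
#: ("D") adds two hydrogens to U; the remaining entries are the common tRNA
#: methylations needed to annotate realistic substrates.
DEFAULT_MODIFICATIONS = ModificationTable()
for _code, _base, _dm, _da, _flags in [
    ("D",   "U", 2.01565, 2.0159, ()),
    ("m7G", "G", _METHYL_MONO, _METHYL_AVG, ()),
    ("m5U", "U", _METHYL_MONO, _METHYL_AVG, ()),
    ("m1A", "A", _METHYL_MONO, _METHYL_AVG, ()),
    ("m3C", "C", _METHYL_MONO, _METHYL_AVG, ()),
    ("m5C", "C", _METHYL_MONO, _METHYL_AVG, ()),
    ("ho5C", "C", 15.99491, 15.999, ()),
    ("Um",  "U", _METHYL_MONO, _METHYL_AVG, _2OM),
    ("Cm",  "C", _METHYL_MONO, _METHYL_AVG, _2OM),
    ("Gm",  "G", _METHYL_MONO, _METHYL_AVG, _2OM),
    ("Am",  "A", _METHYL_MONO, _METHYL_AVG, _2OM),
]:
    DEFAULT_MODIFICATIONS.add(_code, _base, _dm, _da, _flags)


@dataclass(frozen=True)
class Residue:
    base: str
    label: PositionLabel
    modification: str | None = None

    def validate(self, table: ModificationTable) -> None:
        if self.base not in BASES:
            raise TRNAError(f"invalid base {self.base!r} at {self.label}")
        if self.modification is not None:
            entry = table[self.modification]
            if entry.parent_base != self.base:
                raise TRNAError(
                    f"modification {self.modification!r} requires base "
                    f"{entry.parent_base}, found {self.base} at position {self.label}")

    def code(self) -> str:
        """Display form: the modification code if modified, else the base."""
        return self.modification if self.modification else self.base


@dataclass
class AnnotatedTRNA:
    """A tRNA sequence whose residues carry position labels and modifications."""

    id: str
    residues: list[Residue]
    isoacceptor: str = ""
    modifications: ModificationTable = field(default=DEFAULT_MODIFICATIONS, repr=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise TRNAError(f"tRNA {self.id}: empty sequence")
        labels = [r.label for r in self.residues]
        for a, b in zip(labels, labels[1:]):
            if not a < b:
                raise TRNAError(
                    f"tRNA {self.id}: labels must be strictly increasing "
                    f"({a} then {b})")
        for r in self.residues:
            r.validate(self.modifications)
        self._label_index = {r.label: i for i, r in enumerate(self.residues)}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)

    def label_to_index(self, label: PositionLabel | str | int) -> int:
        if not isinstance(label, PositionLabel):
            label = PositionLabel.parse(label)
        try:
            return self._label_index[label]
        except KeyError:
            raise TRNAError(f"tRNA {self.id} has no position {label}") from None

    def index_to_label(self, index: int) -> PositionLabel:
        return self.residues[index].label

    def labels(self) -> list[PositionLabel]:
        return [r.label for r in self.residues]

    @classmethod
    def from_sequence(cls, trna_id: str, sequence: str,
                      labels: Iterable[str | int] | None = None,
                      modifications_at: Mapping[str | int, str] | None = None,
                      isoacceptor: str = "",
                      table: ModificationTable = DEFAULT_MODIFICATIONS,
                      ) -> "AnnotatedTRNA":
        """Build a tRNA from a plain sequence (T accepted, normalized to U).

        ``labels`` defaults to 1..n; ``modifications_at`` maps label -> code.
        """
        seq = sequence.strip().upper().replace("T", "U")
        if labels is None:
            labs = [PositionLabel(i + 1) for i in range(len(seq))]
        else:
            labs = [PositionLabel.parse(x) for x in labels]
            if len(labs) != len(seq):
                raise TRNAError(
                    f"tRNA {trna_id}: {len(labs)} labels for {len(seq)} residues")
        mods: dict[PositionLabel, str] = {}
        for key, code in (modifications_at or {}).items():
            lab = PositionLabel.parse(key)
            if lab in mods:
                raise TRNAError(f"tRNA {trna_id}: duplicate annotation at {lab}")
            mods[lab] = code
        unknown = set(mods) - set(labs)
        if unknown:
            raise TRNAError(
                f"tRNA {trna_id}: annotated positions not in sequence: "
                f"{sorted(map(str, unknown))}")
        residues = [Residue(b, lab, mods.get(lab)) for b, lab in zip(seq, labs)]
        return cls(trna_id, residues, isoacceptor=isoacceptor, modifications=table)


def read_trna_set(fasta_source, modification_tsv_source=None,
                  label_tsv_source=None,
                  table: ModificationTable = DEFAULT_MODIFICATIONS,
                  ) -> list[AnnotatedTRNA]:
    """Read a FASTA of tRNA sequences plus a modification sidecar TSV.

    The sidecar has columns ``trna_id, position_label, modification_code``;
    the optional label TSV (``trna_id, position_label`` one row per residue,
    in order) overrides the default 1..n labelling.  FASTA descriptions of
    the form ``>id isoacceptor`` keep the second token as the isoacceptor.
    """
    records = list(SeqIO.parse(_as_text_handle(fasta_source), "fasta"))
    if not records:
        raise TRNAError("FASTA source contains no records")

    labels_by_id: dict[str, list[str]] = {}
    if label_tsv_source is not None:
        ldf = pd.read_csv(_as_text_handle(label_tsv_source), sep="\t",
                          dtype={"trna_id": str, "position_label": str})
        for trna_id, grp in ldf.groupby("trna_id", sort=False):
            labels_by_id[trna_id] = list(grp["position_label"])

    mods_by_id: dict[str, list[tuple[str, str]]] = {}
    if modification_tsv_source is not None:
        mdf = pd.read_csv(_as_text_handle(modification_tsv_source), sep="\t",
                          dtype=str)
        for row in mdf.itertuples(index=False):
            mods_by_id.setdefault(row.trna_id, []).append(
                (row.position_label, row.modification_code))

    known_ids = {rec.id for rec in records}
    for trna_id in set(mods_by_id) | set(labels_by_id):
        if trna_id not in known_ids:
            raise TRNAError(f"sidecar refers to unknown tRNA id {trna_id!r}")

    trnas = []
    for rec in records:
        parts = rec.description.split(None, 1)
        isoacceptor = parts[1].strip() if len(parts) > 1 else ""
        mod_rows = mods_by_id.get(rec.id, [])
        mod_map: dict[str, str] = {}
        for pos, code in mod_rows:
            if pos in mod_map:
                raise TRNAError(f"tRNA {rec.id}: duplicate annotation at {pos}")
            mod_map[pos] = code
        trnas.append(AnnotatedTRNA.from_sequence(
            rec.id, str(rec.seq), labels=labels_by_id.get(rec.id),
            modifications_at=mod_map, isoacceptor=isoacceptor, table=table))
    return trnas


def write_trna_set(trnas: Iterable[AnnotatedTRNA]) -> tuple[str, str, str]:
    """Serialize back to (fasta, modification TSV, label TSV) text blocks."""
    fasta, mods, labs = [], ["trna_id\tposition_label\tmodification_code"], \
        ["trna_id\tposition_label"]
    for t in trnas:
        header = f">{t.id} {t.isoacceptor}".rstrip()
        fasta.append(f"{header}\n{t.sequence}")
        for r in t.residues:
            labs.append(f"{t.id}\t{r.label}")
            if r.modification:
                mods.append(f"{t.id}\t{r.label}\t{r.modification}")
    return "\n".join(fasta) + "\n", "\n".join(mods) + "\n", "\n".join(labs) + "\n"


def _as_text_handle(source):
    if hasattr(source, "read"):
        return source
    if isinstance(source, str) and "\n" in source:
        return io.StringIO(source)
    return open(source)
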