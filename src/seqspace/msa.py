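"""Multiple sequence alignment container, IO, column filtering and residue numbering.

The alignment is the raw material of the whole analysis: a set of protein
sequences aligned to common columns.  Downstream statistics assume columns
are comparable across sequences, so the module also implements the standard
pre-processing step of discarding columns with appreciable gap content, and
the Ballesteros–Weinstein-style relative numbering used for membrane
receptors, where the most conserved residue of transmembrane helix *n* is
labelled ``n.50`` and neighbouring columns are numbered by their offset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

_FORMATS = {"fasta": "fasta", "clustal": "clustal"}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids...)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    ids : list of str
        Unique, non-empty sequence identifiers.
    rows : list of str
        Equal-length residue strings over the 20 amino acids, gap ``-``
        and unknown ``X``.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not self.ids:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if any(not i for i in self.ids):
            raise AlignmentError("empty sequence id")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {length}"
                )

    @classmethod
    def from_mapping(cls, pairs) -> "Alignment":
        ids, rows = zip(*pairs)
        return cls(tuple(ids), tuple(_normalize(r) for r in rows))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        """Residues as an (n_sequences, length) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def select_columns(self, columns) -> "Alignment":
        cols = list(columns)
        arr = self.to_array()[:, cols]
        return Alignment(self.ids, tuple("".join(r) for r in arr))

    def gap_fraction(self) -> np.ndarray:
        """Per-column fraction of gap characters."""
        return (self.to_array() == GAP).mean(axis=0)


def _normalize(row: str) -> str:
    return row.upper().replace(".", GAP)


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read an alignment from a FASTA or Clustal file.

    Residues are upper-cased and ``.`` gap characters normalized to ``-``.
    Ragged rows or duplicate identifiers raise :class:`AlignmentError`.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), _FORMATS[fmt])
    except ValueError as exc:
        # biopython reports ragged FASTA as a generic ValueError; re-raise
        # with the offending file for context
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return Alignment.from_mapping((rec.id, str(rec.seq)) for rec in msa)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown alignment format {fmt!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    )
    AlignIO.write(msa, str(path), _FORMATS[fmt])


def alignment_to_str(aln: Alignment, fmt: str = "fasta") -> str:
    buf = io.StringIO()
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    )
    AlignIO.write(msa, buf, _FORMATS[fmt])
    return buf.getvalue()


@dataclass(frozen=True)
class ColumnMask:
    """Columns retained by a gap filter, in original (0-based) order."""

    kept: tuple[int, ...]
    threshold: float

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValueError("kept columns must be strictly increasing")


def filter_gappy_columns(
    aln: Alignment, threshold: float = 0.02
) -> tuple[Alignment, ColumnMask]:
    """Drop columns whose gap fraction is >= ``threshold``.

    The bound is strict: a column survives only if its gap fraction is
    *less than* the threshold.  ``X`` counts as a residue, not a gap.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    frac = aln.gap_fraction()
    kept = tuple(int(c) for c in np.flatnonzero(frac < threshold))
    if not kept:
        raise AlignmentError("no columns survive filter")
    return aln.select_columns(kept), ColumnMask(kept, threshold)


@dataclass(frozen=True)
class HelixSpan:
    """One helix: anchor column (the ``n.50`` residue) and an inclusive span."""

    helix: int
    anchor_column: int  # 0-based alignment column carrying label n.50
    start: int  # 0-based inclusive
    end: int  # 0-based inclusive

    def __post_init__(self):
        if not (self.start <= self.anchor_column <= self.end):
            raise ValueError(
                f"helix {self.helix}: anchor column {self.anchor_column} "
                f"outside span [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class NumberingMap:
    """Mapping between alignment columns and helix-relative residue labels.

    Column at offset *k* from the helix-*n* anchor is labelled ``n.(50+k)``;
    each column carries at most one label.
    """

    spans: tuple[HelixSpan, ...]
    labels: dict = field(hash=False)  # column -> "n.pp"

    def column_of(self, label: str) -> int:
        for col, lab in self.labels.items():
            if lab == label:
                return col
        raise KeyError(f"position {label!r} is not labeled in the numbering map")

    def label_of(self, column: int) -> str | None:
        return self.labels.get(column)

    @property
    def n_labeled(self) -> int:
        return len(self.labels)


def build_numbering(aln: Alignment, spans) -> NumberingMap:
    """Label alignment columns by helix-relative numbering.

    ``spans`` is an iterable of :class:`HelixSpan` (or ``(helix,
    anchor_column, start, end)`` tuples, 0-based).  Spans must not overlap
    and must fit in the alignment.
    """
    spans = tuple(s if isinstance(s, HelixSpan) else HelixSpan(*s) for s in spans)
    labels: dict[int, str] = {}
    for sp in spans:
        if sp.end >= aln.length or sp.start < 0:
            raise ValueError(
                f"helix {sp.helix}: span [{sp.start}, {sp.end}] outside "
                f"alignment of length {aln.length}"
            )
        for col in range(sp.start, sp.end + 1):
            if col in labels:
                raise ValueError(
                    f"overlapping spans: column {col} already labeled {labels[col]}"
                )
            offset = col - sp.anchor_column
            labels[col] = f"{sp.helix}.{50 + offset}"
    return NumberingMap(spans, labels)


def read_anchor_table(path) -> tuple[HelixSpan, ...]:
    """Read a helix anchor/span table.

    TSV with columns ``helix  anchor_column  span_start  span_end`` using
    1-based alignment columns (converted to 0-based internally).
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    required = {"helix", "anchor_column", "span_start", "span_end"}
    if not required.issubset(tab.columns):
        raise ValueError(f"anchor table must have columns {sorted(required)}")
    return tuple(
        HelixSpan(
            int(r.helix),
            int(r.anchor_column) - 1,
            int(r.span_start) - 1,
            int(r.span_end) - 1,
        )
        for r in tab.itertuples()
    )


def write_anchor_table(spans, path) -> None:
    pd.DataFrame(
        [
            {
                "helix": s.helix,
                "anchor_column": s.anchor_column + 1,
                "span_start": s.start + 1,
                "span_end": s.end + 1,
            }
            for s in spans
        ]
    ).to_csv(path, sep="\t", index=False)
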