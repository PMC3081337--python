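"""Group-contrast statistics on alignment columns.

For a partition of the aligned sequences into a focus group *g* and its
complement, two per-column statistics locate group-specific positions:

* the frequency correlation ``FC(l)`` — a χ²-derived measure in [0, 1],
  equal to φ² = χ²/N of the residue-by-group contingency table at column
  *l*: 0 when the residue distribution is identical in both groups, 1 when
  residue identity perfectly determines group membership;
* the entropy difference ``ΔS(l) = S(l, g) − S(l, g^C)`` (natural log):
  negative values mean the position is specifically conserved in *g*,
  positive values that it is specifically variable there.

Both are standardized to Z-scores across columns; positions with |Z| at or
above 2.58 (the two-sided 99% normal critical value) are flagged.  The
module also provides a residue-pattern census with the conventional
−/+/++/+++ frequency bands and a χ² test of independence between two
binary patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .msa import GAP, Alignment, NumberingMap

#: two-sided standard-normal critical value at the 99% confidence level
Z_SIGNIFICANCE = 2.58


class UndefinedStatError(ValueError):
    """A group is entirely gapped at the requested column."""


@dataclass(frozen=True)
class GroupPartition:
    """Assignment of every aligned sequence to a group, with one focus group."""

    assignment: dict
    focus: str

    def __post_init__(self):
        labels = set(self.assignment.values())
        if self.focus not in labels:
            raise ValueError(f"focus group {self.focus!r} has no members")
        if labels == {self.focus}:
            raise ValueError("focus group must be a proper subset (complement empty)")

    def masks(self, ids) -> tuple[np.ndarray, np.ndarray]:
        missing = [i for i in ids if i not in self.assignment]
        if missing:
            raise ValueError(f"sequences without group assignment: {missing[:5]}")
        in_g = np.array([self.assignment[i] == self.focus for i in ids])
        return in_g, ~in_g


def _column_counts(column: np.ndarray, mask: np.ndarray) -> dict[str, int]:
    vals, counts = np.unique(column[mask], return_counts=True)
    return {v: int(c) for v, c in zip(vals, counts) if v != GAP}


def frequency_correlation(aln: Alignment, partition: GroupPartition, l: int) -> float:
    """χ²-derived frequency correlation FC(l) between column l and the groups.

    Gaps are excluded and frequencies renormalized over the residues
    present.  Equals χ²/N (φ²) of the 2×R contingency table of group vs
    residue, hence lies in [0, 1].
    """
    col = aln.to_array()[:, l]
    in_g, in_c = partition.masks(aln.ids)
    cg = _column_counts(col, in_g)
    cc = _column_counts(col, in_c)
    ng, nc = sum(cg.values()), sum(cc.values())
    if ng == 0 or nc == 0:
        raise UndefinedStatError(
            f"column {l}: group {'g' if ng == 0 else 'g^C'} entirely gapped"
        )
    n = ng + nc
    fg, fc = ng / n, nc / n
    total = 0.0
    for res in set(cg) | set(cc):
        fi = (cg.get(res, 0) + cc.get(res, 0)) / n
        fig = cg.get(res, 0) / ng
        fic = cc.get(res, 0) / nc
        total += (fig - fic) ** 2 / fi
    return fg * fc * total


def _entropy(counts: dict[str, int]) -> float:
    n = sum(counts.values())
    f = np.array(list(counts.values()), dtype=float) / n
    return float(-(f * np.log(f)).sum())


def entropy_difference(aln: Alignment, partition: GroupPartition, l: int) -> float:
    """ΔS(l) = S(l, g) − S(l, g^C), Shannon entropy with natural log.

    Negative when the column is specifically conserved in the focus group.
    """
    col = aln.to_array()[:, l]
    in_g, in_c = partition.masks(aln.ids)
    cg = _column_counts(col, in_g)
    cc = _column_counts(col, in_c)
    if not cg or not cc:
        raise UndefinedStatError(
            f"column {l}: group {'g' if not cg else 'g^C'} entirely gapped"
        )
    return _entropy(cg) - _entropy(cc)


@dataclass(frozen=True)
class PositionStats:
    """Per-column FC, ΔS and Z-scores for one group partition."""

    table: pd.DataFrame  # column, label, FC, dS, Z_FC, Z_dS, significant
    focus: str

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def position_zscores(
    aln: Alignment,
    partition: GroupPartition,
    numbering: NumberingMap | None = None,
    z_threshold: float = Z_SIGNIFICANCE,
) -> PositionStats:
    """FC(l) and ΔS(l) for every column, standardized across columns.

    Columns where either group is entirely gapped get NaN statistics and
    are excluded from the standardization.  Raises if fewer than two
    columns have defined statistics or if a statistic is constant across
    columns (zero variance makes the Z-score undefined).
    """
    records = []
    for l in range(aln.length):
        try:
            fc = frequency_correlation(aln, partition, l)
            ds = entropy_difference(aln, partition, l)
        except UndefinedStatError:
            fc = ds = np.nan
        records.append(
            {
                "column": l,
                "label": numbering.label_of(l) if numbering else None,
                "FC": fc,
                "dS": ds,
            }
        )
    tab = pd.DataFrame(records)
    defined = tab["FC"].notna()
    if defined.sum() < 2:
        raise ValueError("need at least 2 columns with defined statistics")
    for stat, zcol in (("FC", "Z_FC"), ("dS", "Z_dS")):
        x = tab.loc[defined, stat]
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"{stat} is constant across columns; Z-scores undefined")
        tab[zcol] = (tab[stat] - x.mean()) / sd
    tab["significant"] = (
        (tab["Z_FC"].abs() >= z_threshold) | (tab["Z_dS"].abs() >= z_threshold)
    ) & defined
    return PositionStats(tab, partition.focus)


# ---------------------------------------------------------------------------
# Pattern census


@dataclass(frozen=True)
class PatternSpec:
    """A residue pattern over labeled positions.

    ``positions`` maps a residue-numbering label to the set of residues
    accepted there (``None`` = wildcard).  With ``match='any'`` a sequence
    matches if at least one position carries an accepted residue (e.g.
    proline anywhere in 2.58–2.60); with ``match='all'`` every position
    must match (e.g. the W-x-F-G motif at 3.18–3.21).
    """

    name: str
    positions: tuple[tuple[str, frozenset | None], ...]
    match: str = "any"

    @classmethod
    def residue_at_any(cls, name: str, residue: str, labels) -> "PatternSpec":
        return cls(name, tuple((lab, frozenset(residue)) for lab in labels), "any")

    @classmethod
    def motif(cls, name: str, motif: str, labels, wildcard: str = "X") -> "PatternSpec":
        if len(motif) != len(labels):
            raise ValueError("motif length must equal the number of labels")
        return cls(
            name,
            tuple(
                (lab, None if res == wildcard else frozenset(res))
                for lab, res in zip(labels, motif)
            ),
            "all",
        )


def pattern_flags(
    aln: Alignment, numbering: NumberingMap, pattern: PatternSpec
) -> np.ndarray:
    """Boolean per-sequence match vector for a pattern."""
    arr = aln.to_array()
    cols = [numbering.column_of(lab) for lab, _ in pattern.positions]
    hits = []
    for (lab, allowed), col in zip(pattern.positions, cols):
        if allowed is None:
            hits.append(arr[:, col] != GAP)
        else:
            hits.append(np.isin(arr[:, col], list(allowed)))
    hits = np.vstack(hits)
    return hits.any(axis=0) if pattern.match == "any" else hits.all(axis=0)


def frequency_band(fraction: float) -> str:
    """Conventional symbols: − for 0%, + for (0,50]%, ++ for (50,80)%, +++ for ≥80%."""
    if fraction == 0:
        return "-"
    if fraction <= 0.5:
        return "+"
    if fraction < 0.8:
        return "++"
    return "+++"


def pattern_census(
    aln: Alignment,
    numbering: NumberingMap,
    assignment: dict,
    patterns,
    banded: bool = False,
) -> pd.DataFrame:
    """Per-group fraction of sequences matching each pattern.

    Returns a frame indexed by group with one column per pattern; with
    ``banded=True`` the fractions are rendered as −/+/++/+++ symbols.
    """
    groups = sorted(set(assignment.values()))
    out = {}
    for pat in patterns:
        flags = pattern_flags(aln, numbering, pat)
        col = {}
        for grp in groups:
            members = np.array([assignment[i] == grp for i in aln.ids])
            frac = float(flags[members].mean()) if members.any() else np.nan
            col[grp] = frequency_band(frac) if banded else frac
        out[pat.name] = col
    return pd.DataFrame(out).rename_axis("group")


def chi2_independence(
    flags_a: np.ndarray, flags_b: np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """Pearson χ² test of independence between two binary patterns (1 df).

    No continuity correction by default.  Raises on a degenerate margin
    (a pattern constant over the sequences).
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must cover the same sequences")
    if a.all() or (~a).all() or b.all() or (~b).all():
        raise ValueError("degenerate margin: a pattern is constant")
    table = np.array(
        [
            [(a & b).sum(), (a & ~b).sum()],
            [(~a & b).sum(), (~a & ~b).sum()],
        ]
    )
    chi2, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def write_position_stats(stats: PositionStats, path) -> None:
    """TSV report: 1-based column, label, FC, dS, Z_FC, Z_dS, flag."""
    tab = stats.table.copy()
    tab["column"] = tab["column"] + 1
    tab.to_csv(path, sep="\t", index=False)
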