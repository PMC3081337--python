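"""Identity-based distances between aligned sequences.

The distance between two aligned sequences is the p-distance: the
proportion of comparable sites at which they differ.  Gapped columns can be
removed per pair (pairwise deletion) or once for the whole set (complete
deletion).  Matrices are stored *squared*, because the squared-distance
matrix is what the double-centering step of classical scaling consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .msa import GAP, UNKNOWN, Alignment, ColumnMask

DeletionMode = str  # {"pairwise", "complete"}


class DistanceError(ValueError):
    """Raised when a pair of sequences has no comparable sites."""


@dataclass(frozen=True)
class SquaredDistanceMatrix:
    """Squared pairwise dissimilarities between sequence sets.

    ``values[r, c]`` is the squared distance between ``row_ids[r]`` and
    ``col_ids[c]``.  The square (active) case is symmetric with zero
    diagonal; the rectangular case holds supplementary-vs-active distances.
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    deletion_mode: DeletionMode = "pairwise"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("squared p-distances must lie in [0, 1]")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def distances(self) -> np.ndarray:
        """Un-squared distance view."""
        return np.sqrt(self.values)


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a != GAP) & (b != GAP)


def p_distance(
    row_a: str,
    row_b: str,
    deletion_mode: DeletionMode = "pairwise",
    complete_mask: np.ndarray | None = None,
    x_mismatches: bool = True,
) -> float:
    """Proportion of comparable aligned sites at which two sequences differ.

    Pairwise deletion drops, for this pair only, the columns where either
    sequence is gapped.  Complete deletion restricts the comparison to
    ``complete_mask`` (columns gap-free in the whole set) before comparing.
    With ``x_mismatches`` (default) the unknown residue ``X`` counts as a
    mismatch against everything, including another ``X``.
    """
    a = np.array(list(row_a), dtype="<U1")
    b = np.array(list(row_b), dtype="<U1")
    if a.shape != b.shape:
        raise ValueError("rows have different lengths")
    if deletion_mode == "complete":
        if complete_mask is None:
            raise ValueError("complete deletion requires the set-wide gap mask")
        a, b = a[complete_mask], b[complete_mask]
        use = np.ones(a.shape, dtype=bool)
    elif deletion_mode == "pairwise":
        use = _comparable(a, b)
    else:
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    n = int(use.sum())
    if n == 0:
        raise DistanceError("no comparable sites between the two sequences")
    diff = a[use] != b[use]
    if x_mismatches:
        diff |= (a[use] == UNKNOWN) | (b[use] == UNKNOWN)
    return float(diff.sum()) / n


def _pair_counts(arr_a: np.ndarray, arr_b: np.ndarray, x_mismatches: bool):
    """Vectorized comparable/differing site counts for all row pairs."""
    gap_a = arr_a == GAP
    gap_b = arr_b == GAP
    comp = (~gap_a[:, None, :]) & (~gap_b[None, :, :])
    diff = arr_a[:, None, :] != arr_b[None, :, :]
    if x_mismatches:
        diff = diff | (arr_a == UNKNOWN)[:, None, :] | (arr_b == UNKNOWN)[None, :, :]
    n_comp = comp.sum(axis=2)
    n_diff = (comp & diff).sum(axis=2)
    return n_comp, n_diff


def _complete_columns(*alignments: Alignment) -> np.ndarray:
    masks = [(a.to_array() != GAP).all(axis=0) for a in alignments]
    return np.logical_and.reduce(masks)


def active_distance_matrix(
    aln: Alignment,
    deletion_mode: DeletionMode = "pairwise",
    x_mismatches: bool = True,
    pair_distance: Callable[[str, str], float] | None = None,
) -> SquaredDistanceMatrix:
    """All-against-all squared p-distances within the active set.

    ``pair_distance`` replaces the identity distance with a user-supplied
    dissimilarity (still squared on storage) for extensibility.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if pair_distance is not None:
        d = np.zeros((aln.n_sequences,) * 2)
        for i in range(aln.n_sequences):
            for j in range(i + 1, aln.n_sequences):
                d[i, j] = d[j, i] = pair_distance(aln.rows[i], aln.rows[j])
        return SquaredDistanceMatrix(d**2, aln.ids, aln.ids, deletion_mode)
    arr = aln.to_array()
    if deletion_mode == "complete":
        keep = _complete_columns(aln)
        if not keep.any():
            raise DistanceError("complete deletion removes every column")
        arr = arr[:, keep]
    elif deletion_mode != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    n_comp, n_diff = _pair_counts(arr, arr, x_mismatches)
    if (n_comp == 0).any():
        i, j = np.argwhere(n_comp == 0)[0]
        raise DistanceError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    p = n_diff / n_comp
    np.fill_diagonal(p, 0.0)
    return SquaredDistanceMatrix(p**2, aln.ids, aln.ids, deletion_mode)


def supplementary_distance_matrix(
    sup_aln: Alignment,
    active_aln: Alignment,
    mask: ColumnMask | None = None,
    deletion_mode: DeletionMode = "pairwise",
    x_mismatches: bool = True,
) -> SquaredDistanceMatrix:
    """Squared p-distances of every supplementary sequence to every active one.

    Both alignments must share the active coordinate system (same column
    count before masking); ``mask`` restricts the comparison to the columns
    kept by the gap filter of the active set.
    """
    if sup_aln.length != active_aln.length:
        raise ValueError(
            f"column-count mismatch: supplementary alignment has "
            f"{sup_aln.length} columns, active has {active_aln.length}"
        )
    sup = sup_aln.select_columns(mask.kept) if mask is not None else sup_aln
    act = active_aln.select_columns(mask.kept) if mask is not None else active_aln
    sup_arr, act_arr = sup.to_array(), act.to_array()
    if deletion_mode == "complete":
        keep = _complete_columns(sup, act)
        if not keep.any():
            raise DistanceError("complete deletion removes every column")
        sup_arr, act_arr = sup_arr[:, keep], act_arr[:, keep]
    elif deletion_mode != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    n_comp, n_diff = _pair_counts(sup_arr, act_arr, x_mismatches)
    if (n_comp == 0).any():
        i, j = np.argwhere(n_comp == 0)[0]
        raise DistanceError(
            f"no comparable sites between {sup.ids[i]!r} and {act.ids[j]!r}"
        )
    p = n_diff / n_comp
    return SquaredDistanceMatrix(p**2, sup.ids, act.ids, deletion_mode)


def triangle_violations(dmat: SquaredDistanceMatrix, atol: float = 1e-12):
    """Triples (i, j, k) where d(i,k) > d(i,j) + d(j,k) for the un-squared view.

    Violations are reported, never repaired: non-metricity surfaces
    downstream as negative eigenvalue mass.
    """
    if not dmat.is_square:
        raise ValueError("triangle check needs a square matrix")
    d = dmat.distances()
    n = d.shape[0]
    out = []
    for j in range(n):
        bad = d > d[:, [j]] + d[[j], :] + atol
        for i, k in np.argwhere(bad):
            if j not in (i, k):
                out.append((int(i), int(j), int(k)))
    return out


# ---------------------------------------------------------------------------
# IO: square PHYLIP distance matrix and TSV


def write_phylip(dmat: SquaredDistanceMatrix, path) -> None:
    """Write the *un-squared* distances in square PHYLIP format."""
    if not dmat.is_square:
        raise ValueError("PHYLIP format holds square matrices only")
    d = dmat.distances()
    with open(path, "w") as fh:
        fh.write(f"{len(dmat.row_ids)}\n")
        for sid, row in zip(dmat.row_ids, d):
            fh.write(sid + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


def read_phylip(path, deletion_mode: DeletionMode = "pairwise") -> SquaredDistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(ids) != n:
        raise ValueError(f"PHYLIP header promises {n} rows, found {len(ids)}")
    d = np.asarray(rows)
    return SquaredDistanceMatrix(d**2, tuple(ids), tuple(ids), deletion_mode)


def write_tsv(dmat: SquaredDistanceMatrix, path) -> None:
    """Squared distances as TSV with id header row and column."""
    pd.DataFrame(dmat.values, index=list(dmat.row_ids), columns=list(dmat.col_ids)).to_csv(
        path, sep="\t"
    )


def read_tsv(path, deletion_mode: DeletionMode = "pairwise") -> SquaredDistanceMatrix:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return SquaredDistanceMatrix(
        tab.to_numpy(dtype=float),
        tuple(str(i) for i in tab.index),
        tuple(str(c) for c in tab.columns),
        deletion_mode,
    )
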