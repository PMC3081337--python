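"""Projection of supplementary sequence sets onto a fitted active space.

Supplementary elements (e.g. orthologues from another species) are placed
in the reference coordinate system using only their distances to the active
sequences — the active space itself is never refitted.  Sub-family drift
across species is then summarized by per-set barycenters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import SquaredDistanceMatrix
from .mds import ClassicalMDS


@dataclass(frozen=True)
class ProjectionResult:
    """Supplementary factor scores in the active component basis."""

    scores: np.ndarray  # (N_sup, m)
    sup_ids: tuple[str, ...]
    model: ClassicalMDS

    def __post_init__(self):
        if self.scores.shape != (len(self.sup_ids), self.model.embedding_.shape[1]):
            raise ValueError("score matrix shape does not match ids / model components")

    def to_frame(self) -> pd.DataFrame:
        m = self.scores.shape[1]
        return pd.DataFrame(
            self.scores, index=list(self.sup_ids), columns=[f"comp{k+1}" for k in range(m)]
        ).rename_axis("id")

    def variance_captured(self, n_components: int = 3) -> float:
        """Fraction of supplementary squared score mass on the first components.

        Diagnostic for how much of the supplementary variation is shared
        with the low-dimensional active space rather than specific to the
        supplementary set.
        """
        total = float((self.scores**2).sum())
        if total == 0:
            return 1.0
        return float((self.scores[:, :n_components] ** 2).sum() / total)


def project_supplementary(
    D_sup: SquaredDistanceMatrix | np.ndarray, model: ClassicalMDS
) -> ProjectionResult:
    """Project supplementary elements onto the active space.

    ``D_sup`` holds squared distances from each supplementary sequence to
    every active sequence, with columns in the active model's order (checked
    against ids when both carry them).
    """
    if isinstance(D_sup, SquaredDistanceMatrix):
        sup_ids = D_sup.row_ids
        if model.ids_ is not None and D_sup.col_ids != tuple(model.ids_):
            raise ValueError(
                "supplementary matrix columns do not match the active model's ids"
            )
    else:
        sup_ids = tuple(str(i) for i in range(np.atleast_2d(D_sup).shape[0]))
    scores = model.transform(D_sup)
    return ProjectionResult(scores, sup_ids, model)


@dataclass(frozen=True)
class BarycenterTrack:
    """Mean coordinates of one group across an ordered series of sets."""

    group: str
    set_names: tuple[str, ...]
    barycenters: np.ndarray  # (n_sets, n_components)
    components: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.barycenters,
            index=list(self.set_names),
            columns=[f"comp{k+1}" for k in self.components],
        ).rename_axis("set")


def barycenter_track(
    score_sets: dict[str, pd.DataFrame],
    assignments: dict[str, str],
    group: str,
    components: tuple[int, ...] = (0, 1),
) -> BarycenterTrack:
    """Per-set arithmetic mean of a group's member coordinates.

    ``score_sets`` maps set name (e.g. species) to a frame of scores
    indexed by sequence id; ``assignments`` maps id to group label.  Sets
    with no member of ``group`` are skipped with a warning.
    """
    names, rows = [], []
    cols = list(components)
    for name, frame in score_sets.items():
        member_ids = [i for i in frame.index if assignments.get(i) == group]
        if not member_ids:
            warnings.warn(f"group {group!r} absent from set {name!r}; skipped", stacklevel=2)
            continue
        rows.append(frame.loc[member_ids].to_numpy()[:, cols].mean(axis=0))
        names.append(name)
    if not rows:
        raise ValueError(f"group {group!r} absent from every set")
    return BarycenterTrack(group, tuple(names), np.vstack(rows), tuple(components))
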