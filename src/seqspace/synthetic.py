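"""Synthetic alignments with controlled structure.

Two generators cover the analysis' needs: a fully random alignment used as
a null control for the eigenvalue spectrum (a structureless alignment has a
near-flat scree, so any sharp drop seen on real data is interpretable), and
a hierarchical generator producing groups of sub-families of leaf
sequences, emulating a protein family radiating from a common ancestor.
A third generator interpolates between two ancestors to emulate the
cross-species drift of a sub-family through the reference space.

All generators are pure functions of their parameters and seed; mutation
is replacement by a uniformly chosen *different* residue, which is all the
downstream identity-distance machinery can see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, Alignment

_AA = np.array(list(AMINO_ACIDS))


def random_msa(
    n: int = 283,
    L: int = 236,
    seed: int | None = None,
    frequencies: np.ndarray | None = None,
) -> Alignment:
    """Alignment of ``n`` i.i.d. random sequences of length ``L``, no gaps.

    Residues are uniform over the 20 amino acids unless ``frequencies``
    supplies an empirical composition to sample from.
    """
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 sequences and L >= 1 columns")
    rng = np.random.default_rng(seed)
    if frequencies is not None:
        frequencies = np.asarray(frequencies, dtype=float)
        frequencies = frequencies / frequencies.sum()
    arr = rng.choice(_AA, size=(n, L), p=frequencies)
    ids = tuple(f"rnd{i:04d}" for i in range(n))
    return Alignment(ids, tuple("".join(r) for r in arr))


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each residue, with probability p, by a different residue."""
    out = seq.copy()
    hit = rng.random(seq.size) < p
    for i in np.flatnonzero(hit):
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


@dataclass(frozen=True)
class ClusteredSpec:
    """Parameters of the hierarchical alignment generator.

    ``group_sizes[g][s]`` is the number of leaf sequences in sub-family
    ``s`` of group ``g``.  Mutation probabilities apply per column on the
    branch from root to group ancestor (``p_group``), group to sub-family
    ancestor (``p_subfam``) and sub-family ancestor to leaf (``p_leaf``).
    ``marker_columns`` maps a column index to a per-group residue tuple,
    forcing a perfectly group-determining position.  Defaults mirror a
    4-group, 12-sub-family radiation at desk scale.
    """

    n_columns: int = 236
    group_sizes: tuple[tuple[int, ...], ...] = ((6, 6, 6),) * 4
    p_group: float = 0.6
    p_subfam: float = 0.3
    p_leaf: float = 0.1
    marker_columns: dict = field(default_factory=dict, hash=False)
    gap_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_group, self.p_subfam, self.p_leaf, self.gap_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(size < 1 for grp in self.group_sizes for size in grp):
            raise ValueError("sub-family sizes must be positive")
        for col, residues in self.marker_columns.items():
            if not 0 <= col < self.n_columns:
                raise ValueError(f"marker column {col} outside alignment")
            if len(residues) != len(self.group_sizes):
                raise ValueError("marker needs one residue per group")


@dataclass(frozen=True)
class ClusteredMSA:
    """Generated alignment plus the generating truth."""

    alignment: Alignment
    groups: pd.DataFrame  # id, group, subfamily
    root: str
    group_ancestors: tuple[str, ...]


def clustered_msa(spec: ClusteredSpec) -> ClusteredMSA:
    """Hierarchical alignment: root → group → sub-family → leaf.

    Returns the alignment together with the truth table of group and
    sub-family labels and the ancestor sequences.
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.choice(_AA, size=spec.n_columns)
    ids, rows, recs = [], [], []
    group_ancestors = []
    for g, subfams in enumerate(spec.group_sizes):
        anc_g = _mutate(root, spec.p_group, rng)
        for col, residues in spec.marker_columns.items():
            anc_g[col] = residues[g]
        group_ancestors.append("".join(anc_g))
        for s, n_leaves in enumerate(subfams):
            anc_s = _mutate(anc_g, spec.p_subfam, rng)
            for col, residues in spec.marker_columns.items():
                anc_s[col] = residues[g]
            for t in range(n_leaves):
                leaf = _mutate(anc_s, spec.p_leaf, rng)
                for col, residues in spec.marker_columns.items():
                    leaf[col] = residues[g]
                if spec.gap_probability > 0:
                    gaps = rng.random(leaf.size) < spec.gap_probability
                    leaf = leaf.copy()
                    leaf[gaps] = "-"
                sid = f"g{g}s{s}l{t:03d}"
                ids.append(sid)
                rows.append("".join(leaf))
                recs.append({"id": sid, "group": f"G{g}", "subfamily": f"G{g}S{s}"})
    return ClusteredMSA(
        Alignment(tuple(ids), tuple(rows)),
        pd.DataFrame(recs),
        "".join(root),
        tuple(group_ancestors),
    )


def drifting_supplementary(
    central_ancestor: str,
    peripheral_ancestor: str,
    n: int,
    t: float,
    p_leaf: float = 0.1,
    seed: int | None = None,
    prefix: str = "sup",
) -> Alignment:
    """Supplementary set interpolated between two ancestors.

    Each column of the mosaic ancestor is taken from the peripheral
    ancestor with probability ``t`` (else the central one); ``n`` leaves
    are then mutated off the mosaic with per-column probability
    ``p_leaf``.  As ``t`` goes 0 → 1 the projected barycenter of the set
    moves from the central toward the peripheral cluster.
    """
    if not 0 <= t <= 1:
        raise ValueError("t must lie in [0, 1]")
    if len(central_ancestor) != len(peripheral_ancestor):
        raise ValueError("ancestors must have equal length")
    rng = np.random.default_rng(seed)
    central = np.array(list(central_ancestor))
    peripheral = np.array(list(peripheral_ancestor))
    take = rng.random(central.size) < t
    mosaic = np.where(take, peripheral, central)
    ids, rows = [], []
    for i in range(n):
        ids.append(f"{prefix}{i:03d}")
        rows.append("".join(_mutate(mosaic, p_leaf, rng)))
    return Alignment(tuple(ids), tuple(rows))
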