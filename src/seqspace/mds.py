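"""Classical (metric) multidimensional scaling of a squared-distance matrix.

Classical scaling — also called principal coordinates analysis — turns an
N×N matrix of squared dissimilarities **D** into coordinates.  The matrix is
double-centered into a cross-product (Gram) matrix

    S = -1/2 · C D C,      C = I - (1/N)·1,

with **1** the all-ones matrix, and eigendecomposed as S = U Λ Uᵀ.  Factor
scores F = U₊ Λ₊^{1/2} (restricted to positive eigenvalues) give each
element coordinates whose pairwise Euclidean distances best approximate the
input dissimilarities.  Negative eigenvalues measure how far the input is
from being Euclidean and are kept as a diagnostic.

The fitted model also caches the column means and grand mean of D, which
are exactly the statistics needed to project new ("supplementary") elements
into the same space without refitting (see :mod:`seqspace.projection` and
:meth:`ClassicalMDS.transform`).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .distance import SquaredDistanceMatrix

#: eigenvalues with |λ| below this multiple of max|λ| are treated as zero
EIGENVALUE_RTOL = 1e-9


def _as_square_array(D) -> np.ndarray:
    if isinstance(D, SquaredDistanceMatrix):
        if not D.is_square:
            raise ValueError("active MDS needs a square distance matrix")
        D = D.values
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("squared-distance matrix must be symmetric")
    return D


def double_center(D) -> np.ndarray:
    """Cross-product matrix S = -1/2 · C D C of a squared-distance matrix.

    Rows and columns of S sum to zero (centering), and S is symmetric.
    """
    D = _as_square_array(D)
    row_means = D.mean(axis=1, keepdims=True)
    col_means = D.mean(axis=0, keepdims=True)
    grand = D.mean()
    return -0.5 * (D - row_means - col_means + grand)


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Metric MDS estimator with out-of-sample (supplementary) projection.

    ``fit`` eigendecomposes the double-centered squared-distance matrix of
    the active set; ``transform`` places supplementary elements into the
    fitted space using only their squared distances to the active elements
    (Gower's add-a-point formula), never refitting.

    Parameters
    ----------
    eig_rtol : float
        Relative threshold below which eigenvalues count as zero.

    Attributes
    ----------
    eigenvalues_ : (N,) array, sorted descending (negatives possible).
    eigenvectors_ : (N, N) array, columns orthonormal, ordered to match.
    embedding_ : (N, m) factor scores over the m positive-eigenvalue
        components; each column has zero mean and sum of squares equal to
        its eigenvalue.
    ids_ : tuple of str or None, active element identifiers.
    column_means_, grand_mean_ : centering statistics of D, cached for
        projection.
    """

    def __init__(self, eig_rtol: float = EIGENVALUE_RTOL):
        self.eig_rtol = eig_rtol

    def fit(self, D, y=None):
        ids = D.row_ids if isinstance(D, SquaredDistanceMatrix) else None
        D = _as_square_array(D)
        S = double_center(D)
        lam, U = np.linalg.eigh(S)
        order = np.argsort(-lam, kind="stable")
        lam, U = lam[order], U[:, order]
        # zero out numerically negligible eigenvalues
        tiny = np.abs(lam) < self.eig_rtol * max(np.abs(lam).max(), 1e-300)
        lam[tiny] = 0.0
        # sign convention: largest-|loading| entry of each eigenvector positive
        flip = U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])] < 0
        U[:, flip] *= -1
        pos = lam > 0
        self.eigenvalues_ = lam
        self.eigenvectors_ = U
        self.embedding_ = U[:, pos] * np.sqrt(lam[pos])
        self.ids_ = ids
        self.column_means_ = D.mean(axis=0)
        self.grand_mean_ = D.mean()
        self.n_features_in_ = D.shape[0]
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).embedding_

    def transform(self, D_sup) -> np.ndarray:
        """Project supplementary elements into the active space.

        ``D_sup`` is the N_sup×N matrix of squared distances from each
        supplementary element to every active element (columns in active
        order).  The cross-product rows are centered with *active-set*
        statistics only:

            S_sup = -1/2 · (D_sup - (1/N)·1_sup·D) · (I - (1/N)·1)
            F_sup = S_sup · U₊ · Λ₊^{-1/2}

        so an active element re-presented as supplementary lands exactly on
        its fitted coordinates.
        """
        check_is_fitted(self, "eigenvalues_")
        if isinstance(D_sup, SquaredDistanceMatrix):
            D_sup = D_sup.values
        D_sup = np.atleast_2d(np.asarray(D_sup, dtype=float))
        if D_sup.shape[1] != self.n_features_in_:
            raise ValueError(
                f"supplementary matrix has {D_sup.shape[1]} columns, "
                f"active space was fitted on {self.n_features_in_} elements"
            )
        pos = self.eigenvalues_ > 0
        if not pos.any():
            raise ValueError("model has no positive eigenvalues to project onto")
        R = D_sup - self.column_means_  # subtract (1/N)·1_sup·D
        S_sup = -0.5 * (R - R.mean(axis=1, keepdims=True))  # right-multiply by C
        return S_sup @ self.eigenvectors_[:, pos] / np.sqrt(self.eigenvalues_[pos])

    # -- diagnostics -------------------------------------------------------

    @property
    def negative_eigenvalue_fraction_(self) -> float:
        """Σ|λ<0| / Σ|λ|: the non-Euclidean share of the spectrum."""
        check_is_fitted(self, "eigenvalues_")
        lam = self.eigenvalues_
        total = np.abs(lam).sum()
        if total == 0:
            return 0.0
        return float(np.abs(lam[lam < 0]).sum() / total)

    def scree(self, n: int = 20) -> np.ndarray:
        """First ``n`` eigenvalues, descending; truncates with a warning."""
        check_is_fitted(self, "eigenvalues_")
        if n < 1:
            raise ValueError("n must be >= 1")
        if n > self.eigenvalues_.size:
            warnings.warn(
                f"requested {n} eigenvalues but only "
                f"{self.eigenvalues_.size} exist; truncating",
                stacklevel=2,
            )
            n = self.eigenvalues_.size
        return self.eigenvalues_[:n].copy()


# -- functional wrappers ----------------------------------------------------


def fit_mds(D, eig_rtol: float = EIGENVALUE_RTOL) -> ClassicalMDS:
    """Fit classical MDS on a squared-distance matrix."""
    return ClassicalMDS(eig_rtol=eig_rtol).fit(D)


def negative_eigenvalue_fraction(model: ClassicalMDS) -> float:
    return model.negative_eigenvalue_fraction_


def scree(model: ClassicalMDS, n: int = 20) -> np.ndarray:
    return model.scree(n)


def write_scores(model: ClassicalMDS, path) -> None:
    """Factor scores as TSV: id, comp1..compm."""
    import pandas as pd

    m = model.embedding_.shape[1]
    ids = model.ids_ if model.ids_ is not None else [str(i) for i in range(model.embedding_.shape[0])]
    pd.DataFrame(
        model.embedding_, index=list(ids), columns=[f"comp{k+1}" for k in range(m)]
    ).rename_axis("id").to_csv(path, sep="\t")


def write_eigenvalue_report(model: ClassicalMDS, path) -> None:
    """Eigenvalue report as TSV: rank, eigenvalue, pct_of_abs_sum."""
    import pandas as pd

    lam = model.eigenvalues_
    total = np.abs(lam).sum()
    pct = 100 * np.abs(lam) / total if total > 0 else np.zeros_like(lam)
    pd.DataFrame(
        {"rank": np.arange(1, lam.size + 1), "eigenvalue": lam, "pct_of_abs_sum": pct}
    ).to_csv(path, sep="\t", index=False)
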