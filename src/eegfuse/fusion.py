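"""PCA reduction and CCA-based feature fusion.

Two feature views of the same subjects (spectral and complexity) are each
reduced by PCA to the minimal number of leading components explaining at
least 70% of the variance, then fused by canonical correlation analysis.

The CCA uses the compact-SVD construction: with column-centred reduced
views A = U_A S_A V_A^T and B = U_B S_B V_B^T, the SVD of
U_A^T U_B = U Sigma V^T yields projection matrices
W_A = V_A S_A^{-1} U and W_B = V_B S_B^{-1} V. The projected views
X = A W_A and Y = B W_B have orthonormal columns with
corr(X_i, Y_j) = Sigma_ii delta_ij (the canonical correlations), and the
fused feature matrix is the concatenation Z = [X | Y] with 2r columns,
r = min(rank A, rank B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FusedFeatureMatrix",
    "PCAReduction",
    "assemble_feature_sets",
    "cca_fuse",
    "pca_reduce",
]


@dataclass
class PCAReduction:
    """Result of a variance-thresholded PCA on one feature view."""

    n_components: int
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance_ratio: np.ndarray  # all components, descending
    mean: np.ndarray
    scale: np.ndarray  # ones when standardize=False
    variance_threshold: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X, dtype=float) - self.mean) / self.scale) @ self.loadings


@dataclass
class FusedFeatureMatrix:
    """CCA-fused features Z = [A W_A | B W_B] with canonical correlations."""

    Z: np.ndarray  # (n_subjects, 2r)
    W_A: np.ndarray
    W_B: np.ndarray
    correlations: np.ndarray  # rho_1 >= ... >= rho_r
    mean_A: np.ndarray
    mean_B: np.ndarray

    @property
    def rank(self) -> int:
        return self.correlations.size


def _matrix_rank_by_sv(s: np.ndarray, shape: tuple[int, int]) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    tol = max(shape) * np.finfo(float).eps * s[0]
    return int((s > tol).sum())


def pca_reduce(
    X: np.ndarray,
    variance_threshold: float = 0.70,
    standardize: bool = True,
) -> tuple[PCAReduction, np.ndarray]:
    """Project a subjects x features view onto its leading principal components.

    Retains the minimal number of components whose cumulative explained
    variance reaches ``variance_threshold``. Columns are centred, and by
    default scaled to unit variance first (the two views mix unit-free
    power ratios with entropies in nats, so correlation-matrix PCA is the
    default).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"need a 2-D matrix with >= 2 subjects, got shape {X.shape}")
    if np.isnan(X).any():
        raise ValueError("feature view contains missing values")
    if not 0 < variance_threshold <= 1:
        raise ValueError(f"variance threshold must be in (0, 1], got {variance_threshold}")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    Xc = Xc / scale
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = _matrix_rank_by_sv(s, Xc.shape)
    if rank == 0:
        raise ValueError("feature view is constant (rank 0); PCA is undefined")
    var = s**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    n_keep = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_keep = min(n_keep, rank)
    loadings = Vt[:n_keep].T
    red = PCAReduction(
        n_components=n_keep,
        loadings=loadings,
        explained_variance_ratio=ratio,
        mean=mean,
        scale=scale,
        variance_threshold=variance_threshold,
    )
    return red, Xc @ loadings


def _compact_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = _matrix_rank_by_sv(s, M.shape)
    if rank == 0:
        raise ValueError("zero-rank view: CCA is undefined")
    return U[:, :rank], s[:rank], Vt[:rank].T


def cca_fuse(A: np.ndarray, B: np.ndarray) -> FusedFeatureMatrix:
    """Fuse two reduced views by SVD-based canonical correlation analysis.

    Views must share the subject axis; each is column-centred internally.
    Returns the fused matrix Z = [A W_A | B W_B] (exactly 2r columns) and
    the canonical correlations in descending order.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("views must be 2-D (subjects x features)")
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"subject counts differ: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 2:
        raise ValueError("CCA needs at least 2 subjects")
    mean_A, mean_B = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mean_A, B - mean_B
    UA, sA, VA = _compact_svd(Ac)
    UB, sB, VB = _compact_svd(Bc)
    r = min(sA.size, sB.size)
    U, sig, Vt = np.linalg.svd(UA.T @ UB, full_matrices=False)
    U, sig, V = U[:, :r], sig[:r], Vt[:r].T
    W_A = VA @ np.diag(1.0 / sA) @ U
    W_B = VB @ np.diag(1.0 / sB) @ V
    X = Ac @ W_A
    Y = Bc @ W_B
    return FusedFeatureMatrix(
        Z=np.hstack([X, Y]),
        W_A=W_A,
        W_B=W_B,
        correlations=np.clip(sig, 0.0, None),
        mean_A=mean_A,
        mean_B=mean_B,
    )


def assemble_feature_sets(
    rpsd_view: np.ndarray,
    pe_view: np.ndarray,
    variance_threshold: float = 0.70,
    standardize: bool = True,
) -> dict[str, np.ndarray]:
    """Build the four candidate feature sets from the two views.

    set1: PCA-reduced spectral view; set2: PCA-reduced complexity view;
    set3: column concatenation of set1 and set2; set4: CCA-fused features
    (CCDF) of set1 and set2.
    """
    rpsd_view = np.asarray(rpsd_view, dtype=float)
    pe_view = np.asarray(pe_view, dtype=float)
    if rpsd_view.shape[0] != pe_view.shape[0]:
        raise ValueError("views must share subjects")
    _, set1 = pca_reduce(rpsd_view, variance_threshold, standardize)
    _, set2 = pca_reduce(pe_view, variance_threshold, standardize)
    fused = cca_fuse(set1, set2)
    return {
        "set1": set1,
        "set2": set2,
        "set3": np.hstack([set1, set2]),
        "set4": fused.Z,
    }
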