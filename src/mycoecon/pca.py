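"""Trait-space ordination: correlation PCA, permutation significance,
broken-stick retention, varimax rotation and loading clustering.

PCA is computed on the trait correlation matrix (all traits standardized to
mean 0, SD 1 beforehand), so eigenvalues sum to the number of traits and
"loadings" are trait-score correlations, bounded in [-1, 1]. Axis and
loading significance come from a column-permutation null: each permutation
shuffles every trait column independently, destroying inter-trait
correlation while preserving trait marginals. Significant axes are varimax
rotated into interpretable rotated components (RCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

__all__ = [
    "PCAResult",
    "SignificanceResult",
    "RotatedSpace",
    "run_pca",
    "permutation_significance",
    "broken_stick",
    "varimax",
    "cluster_loadings",
    "orient_axes",
    "tucker_congruence",
]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    pct_variance: np.ndarray  # percentages, sum 100
    loadings: pd.DataFrame  # traits x axes, trait-score correlations
    scores: pd.DataFrame  # isolates x axes, Var(axis m) = eigenvalue m
    n_isolates: int
    n_traits: int


@dataclass
class SignificanceResult:
    n_permutations: int
    alpha: float
    observed_pct: np.ndarray  # per axis
    null_quantiles: np.ndarray  # (1 - alpha) null quantile per axis rank
    p_values: np.ndarray  # per axis
    axis_significant: np.ndarray  # bool per axis
    loading_significant: pd.DataFrame  # traits x axes bool
    n_significant: int  # count of significant axes (not assumed prefix)


@dataclass
class RotatedSpace:
    rc_loadings: pd.DataFrame  # traits x k
    rc_scores: pd.DataFrame  # isolates x k, unit variance
    rotation: np.ndarray  # k x k orthogonal
    rc_variance: np.ndarray  # sum of squared loadings per RC
    rc_pct_variance: np.ndarray  # as % of n_traits


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column: correlation PCA undefined")
    return (X - mu) / sd


def run_pca(table: pd.DataFrame) -> PCAResult:
    """PCA of the trait correlation matrix.

    Scores are the standardized data projected on unit eigenvectors, so the
    variance of axis m equals its eigenvalue; loadings are the correlations
    of each trait with each score axis (eigenvector scaled by sqrt of the
    eigenvalue).

    Raises on missing cells (imputation is the preprocessing contract) and
    on constant columns.
    """
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait table has missing cells; impute before PCA")
    n, p = X.shape
    if n <= 2 or p < 2:
        raise ValueError("need > 2 isolates and >= 2 traits")
    Z = _standardize(X)
    C = (Z.T @ Z) / (n - 1)  # correlation matrix
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    scores = Z @ eigvec
    loadings = eigvec * np.sqrt(eigval)
    axes = [f"PC{i + 1}" for i in range(p)]
    return PCAResult(
        eigenvalues=eigval,
        pct_variance=100.0 * eigval / eigval.sum(),
        loadings=pd.DataFrame(loadings, index=table.columns, columns=axes),
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
        n_isolates=n,
        n_traits=p,
    )


def permutation_significance(
    table: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SignificanceResult:
    """Permutation test of PC axes and loadings.

    Each of ``n_perm`` permutations shuffles every trait column
    independently and re-runs the PCA; the observed percent variance of
    axis rank m is compared with its null distribution. An axis is
    significant when its observed share exceeds the (1 - alpha) null
    quantile; p = (1 + #{null >= obs}) / (n_perm + 1). A trait's loading on
    axis m is significant when |observed| exceeds the (1 - alpha) quantile
    of that trait's null |loading| at the same axis rank.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs = run_pca(table)
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    null_pct = np.empty((n_perm, p))
    null_absload = np.empty((n_perm, p, p))  # (perm, trait, axis rank)
    Xp = np.empty_like(X)
    for b in range(n_perm):
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        Z = _standardize(Xp)
        C = (Z.T @ Z) / (n - 1)
        eigval, eigvec = np.linalg.eigh(C)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        null_pct[b] = 100.0 * eigval / eigval.sum()
        null_absload[b] = np.abs(eigvec[:, order] * np.sqrt(eigval))

    qs = np.quantile(null_pct, 1.0 - alpha, axis=0)
    p_values = (1.0 + (null_pct >= obs.pct_variance).sum(axis=0)) / (n_perm + 1.0)
    # axes beyond the data rank carry numerically-zero variance; never flag them
    axis_sig = (obs.pct_variance > qs) & (obs.pct_variance > 1e-9)
    load_q = np.quantile(null_absload, 1.0 - alpha, axis=0)  # traits x axes
    load_sig = np.abs(obs.loadings.to_numpy()) > load_q
    return SignificanceResult(
        n_permutations=n_perm,
        alpha=alpha,
        observed_pct=obs.pct_variance,
        null_quantiles=qs,
        p_values=p_values,
        axis_significant=axis_sig,
        loading_significant=pd.DataFrame(
            load_sig, index=obs.loadings.index, columns=obs.loadings.columns
        ),
        n_significant=int(axis_sig.sum()),
    )


def broken_stick(n: int) -> np.ndarray:
    """Broken-stick expected variance proportions b_i = (1/n) sum_{j>=i} 1/j."""
    if n < 1:
        raise ValueError("n must be >= 1")
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1] / n


def _varimax_rotation(
    L: np.ndarray, kaiser: bool = True, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Orthogonal rotation matrix maximizing the varimax criterion.

    Lawley-Maxwell/SVD iteration; with Kaiser normalization each loading row
    is scaled to unit communality before optimizing, so every trait counts
    equally.
    """
    p, k = L.shape
    A = L.copy()
    if kaiser:
        h = np.sqrt((A**2).sum(axis=1))
        h[h == 0] = 1.0
        A = A / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        B = A @ R
        grad = A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        U, S, Vt = np.linalg.svd(grad)
        R = U @ Vt
        d_new = S.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    return R


def varimax(
    pca: PCAResult, k: int, kaiser: bool = True, orient: dict[str, str] | None = None
) -> RotatedSpace:
    """Varimax-rotate the first ``k`` PC axes into rotated components.

    The rotation is orthogonal, so RC scores stay mutually uncorrelated and
    per-trait communalities (row sums of squared loadings) are preserved.
    RCs are re-ordered by descending rotated variance (sum of squared
    loadings) and, if ``orient`` maps RC names to anchor trait names, signed
    so the anchor's loading is positive.

    With ``k == 1`` rotation is a no-op (identity).
    """
    if k < 1 or k > pca.n_traits:
        raise ValueError(f"k={k} outside 1..{pca.n_traits}")
    L = pca.loadings.to_numpy()[:, :k]
    if k == 1:
        import warnings

        warnings.warn("varimax with k=1 is an identity rotation", stacklevel=2)
        R = np.eye(1)
    else:
        R = _varimax_rotation(L, kaiser=kaiser)
    Lr = L @ R
    # standardized (unit-variance) scores rotated by the same R
    T = pca.scores.to_numpy()[:, :k] / np.sqrt(pca.eigenvalues[:k])
    Tr = T @ R
    # order RCs by rotated variance, descending (stable)
    var = (Lr**2).sum(axis=0)
    order = np.argsort(-var, kind="stable")
    Lr, Tr, var = Lr[:, order], Tr[:, order], var[order]
    R = R[:, order]
    names = [f"RC{i + 1}" for i in range(k)]
    space = RotatedSpace(
        rc_loadings=pd.DataFrame(Lr, index=pca.loadings.index, columns=names),
        rc_scores=pd.DataFrame(Tr, index=pca.scores.index, columns=names),
        rotation=R,
        rc_variance=var,
        rc_pct_variance=100.0 * var / pca.n_traits,
    )
    if orient:
        space = orient_axes(space, orient)
    return space


def orient_axes(space: RotatedSpace, anchor_rules: dict[str, str]) -> RotatedSpace:
    """Fix axis polarity: flip each named axis so its anchor trait loads > 0.

    The sign of any ordination axis is arbitrary; anchoring (e.g. extension
    rate positive on the dense-fast axis) makes outputs comparable across
    runs. Idempotent.
    """
    L = space.rc_loadings.copy()
    S = space.rc_scores.copy()
    R = space.rotation.copy()
    for axis, trait in anchor_rules.items():
        if axis not in L.columns:
            raise KeyError(f"unknown axis {axis!r}")
        if trait not in L.index:
            raise KeyError(f"anchor trait {trait!r} not in loadings")
        if L.loc[trait, axis] < 0:
            j = L.columns.get_loc(axis)
            L[axis] = -L[axis]
            S[axis] = -S[axis]
            R[:, j] = -R[:, j]
    return RotatedSpace(
        rc_loadings=L,
        rc_scores=S,
        rotation=R,
        rc_variance=space.rc_variance,
        rc_pct_variance=space.rc_pct_variance,
    )


def cluster_loadings(
    loadings: pd.DataFrame, k: int | None = None, height: float | None = None
) -> tuple[np.ndarray, pd.Series]:
    """Hierarchically cluster traits by their loading rows.

    Average linkage on Euclidean distances between loading vectors; returns
    the scipy linkage matrix and flat group labels (cut at ``k`` groups or
    at ``height``; default k=3).
    """
    if loadings.shape[0] < 2:
        raise ValueError("need >= 2 traits to cluster")
    Z = sch.average(pdist(loadings.to_numpy()))
    if height is not None:
        labels = sch.fcluster(Z, t=height, criterion="distance")
    else:
        labels = sch.fcluster(Z, t=(k or 3), criterion="maxclust")
    return Z, pd.Series(labels, index=loadings.index, name="cluster")


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def match_axes_congruence(
    estimated: pd.DataFrame, truth: pd.DataFrame
) -> np.ndarray:
    """Best |congruence| of each truth axis to a distinct estimated axis.

    Axes from an ordination come in arbitrary order and sign; match truth
    columns to estimated columns by maximizing total |Tucker congruence|
    (Hungarian assignment) and return the matched |congruence| per truth
    axis.
    """
    from scipy.optimize import linear_sum_assignment

    est = estimated.to_numpy()
    tru = truth.to_numpy()
    k_t, k_e = tru.shape[1], est.shape[1]
    M = np.zeros((k_t, k_e))
    for i in range(k_t):
        for j in range(k_e):
            M[i, j] = abs(tucker_congruence(tru[:, i], est[:, j]))
    rows, cols = linear_sum_assignment(-M)
    return M[rows, cols]
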