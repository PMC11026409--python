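"""Trait-niche association statistics.

* ``correlate``: Pearson by default, Spearman when a variable fails the
  normality gate (the usual fallback for non-normal niche traits such as
  the water-potential optimum).
* ``permanova``: permutational multivariate ANOVA of a multivariate
  response (e.g. the 3-D matrix of niche optima) on a single continuous
  predictor (an RC axis); pseudo-F on the Gower-centered Euclidean
  distance matrix, significance by permuting predictor rows.
* ``rda_forward_selection``: forward model selection for redundancy
  analysis — at each step add the candidate trait that maximizes the
  adjusted R^2 of the multivariate regression, provided its permutation
  p-value clears alpha and no variance inflation factor exceeds the cap.
* ``trait_correlation_matrix``: all pairwise Pearson correlations with raw
  p and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PermanovaResult",
    "RDASelectionResult",
    "correlate",
    "permanova",
    "rda_forward_selection",
    "trait_correlation_matrix",
]

NORMALITY_ALPHA = 0.05


@dataclass
class PermanovaResult:
    predictor: str
    pseudo_F: float
    r_squared: float
    p_value: float
    n_perm: int
    exhaustive: bool = False


@dataclass
class RDASelectionResult:
    selected: list[str]
    path: pd.DataFrame  # per step: predictor, adj_r2, p_value
    final_vifs: pd.Series
    alpha: float
    vif_cap: float


def correlate(
    x, y, method: str = "auto", alpha: float = NORMALITY_ALPHA
) -> tuple[float, float, str]:
    """Correlation between two paired variables.

    ``auto`` uses Spearman's rank correlation when either variable fails a
    Shapiro-Wilk normality test at ``alpha``, Pearson otherwise. Returns
    (r, two-sided p, method used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "auto":
        px = stats.shapiro(x).pvalue
        py = stats.shapiro(y).pvalue
        method = "spearman" if min(px, py) < alpha else "pearson"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(
    response: pd.DataFrame,
    predictor: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    standardize: bool = True,
) -> PermanovaResult:
    """PERMANOVA of a multivariate response on one continuous predictor.

    The response columns are z-scored (unless ``standardize=False``) and
    converted to a Euclidean distance matrix; the pseudo-F statistic uses
    the Gower-centered matrix G and the hat matrix H of the predictor
    (with intercept):

        F = tr(HGH) / (tr[(I-H)G(I-H)] / (n - 2))

    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1) over random row
    permutations of the predictor, or the exact enumeration of all n!
    permutations when ``exhaustive`` (p = #{F_perm >= F_obs} / n!,
    including the identity).
    """
    Y = response.to_numpy(dtype=float)
    x = np.asarray(predictor, dtype=float).ravel()
    n = Y.shape[0]
    if x.size != n:
        raise ValueError("predictor length mismatch")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    if standardize:
        sd = Y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("degenerate response: constant column")
        Y = (Y - Y.mean(axis=0)) / sd
    D = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2))
    if not D.any():
        raise ValueError("degenerate response: total sum of squares is zero")
    G = _gower_center(D)
    total_ss = np.trace(G)

    def pseudo_f(xp: np.ndarray) -> float:
        X = np.column_stack([np.ones(n), xp])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        R = np.eye(n) - H
        ss_model = float(np.trace(H @ G @ H))
        ss_res = float(np.trace(R @ G @ R))
        return ss_model / (ss_res / (n - 2))

    f_obs = pseudo_f(x)
    X0 = np.column_stack([np.ones(n), x])
    H0 = X0 @ np.linalg.solve(X0.T @ X0, X0.T)
    r2 = float(np.trace(H0 @ G @ H0)) / total_ss

    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = sum(pseudo_f(x[list(pm)]) >= f_obs - 1e-12 for pm in perms)
        p = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if pseudo_f(x[rng.permutation(n)]) >= f_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        n_used = n_perm
    name = predictor.name if isinstance(predictor, pd.Series) else "predictor"
    return PermanovaResult(
        predictor=str(name),
        pseudo_F=float(f_obs),
        r_squared=r2,
        p_value=float(p),
        n_perm=n_used,
        exhaustive=exhaustive,
    )


def _multivariate_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of a multivariate OLS fit (constrained / total variance in RDA)."""
    Xc = np.column_stack([np.ones(Y.shape[0]), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fit = Xc @ beta
    Yc = Y - Y.mean(axis=0)
    fitc = fit - fit.mean(axis=0)
    return float((fitc**2).sum() / (Yc**2).sum())


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _vifs(X: np.ndarray, names: list[str]) -> pd.Series:
    out = {}
    for j in range(X.shape[1]):
        if X.shape[1] == 1:
            out[names[j]] = 1.0
            continue
        others = np.delete(X, j, axis=1)
        r2 = _multivariate_r2(X[:, [j]], others)
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def rda_forward_selection(
    response: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    vif_cap: float = 10.0,
    n_perm: int = 999,
    seed: int | None = None,
) -> RDASelectionResult:
    """Forward selection of trait predictors for a multivariate response.

    At each step every remaining candidate is evaluated by the adjusted
    R^2 of the redundancy analysis (multivariate OLS) with the already
    selected predictors plus the candidate. The best candidate is admitted
    when (i) it increases the adjusted R^2, (ii) its marginal pseudo-F has
    permutation p < alpha (candidate rows permuted, selected predictors
    held fixed), and (iii) every VIF in the augmented predictor set stays
    at or below ``vif_cap``. Selection stops at the first failure.
    """
    Y = response.to_numpy(dtype=float)
    n = Y.shape[0]
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    pool = list(candidates.columns)
    selected: list[str] = []
    steps = []
    adj_prev = 0.0
    while pool and n > len(selected) + 3:
        Xsel = candidates[selected].to_numpy(dtype=float) if selected else None
        best = None
        for cand in pool:
            Xc = candidates[[cand]].to_numpy(dtype=float)
            X = Xc if Xsel is None else np.column_stack([Xsel, Xc])
            r2 = _multivariate_r2(Y, X)
            adj = _adjusted_r2(r2, n, X.shape[1])
            if best is None or adj > best[1]:
                best = (cand, adj, r2, X)
        cand, adj, r2, X = best
        if adj <= adj_prev:
            break
        # VIF screen on the augmented predictor set
        vifs = _vifs(X, selected + [cand])
        if (vifs > vif_cap).any():
            break
        # marginal permutation test of the added candidate
        r2_base = _multivariate_r2(Y, Xsel) if Xsel is not None else 0.0
        q = X.shape[1]
        f_obs = ((r2 - r2_base) / 1.0) / ((1.0 - r2) / (n - q - 1))
        xc = candidates[cand].to_numpy(dtype=float)
        count = 0
        for _ in range(n_perm):
            xp = xc[rng.permutation(n)]
            Xp = xp[:, None] if Xsel is None else np.column_stack([Xsel, xp])
            r2p = _multivariate_r2(Y, Xp)
            fp = ((r2p - r2_base) / 1.0) / ((1.0 - r2p) / (n - q - 1))
            if fp >= f_obs - 1e-12:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        if p >= alpha:
            break
        selected.append(cand)
        pool.remove(cand)
        adj_prev = adj
        steps.append({"predictor": cand, "adj_r2": adj, "p_value": p})
    final_X = candidates[selected].to_numpy(dtype=float) if selected else np.empty((n, 0))
    final_vifs = (
        _vifs(final_X, selected) if selected else pd.Series(dtype=float, name="VIF")
    )
    return RDASelectionResult(
        selected=selected,
        path=pd.DataFrame(steps, columns=["predictor", "adj_r2", "p_value"]),
        final_vifs=final_vifs,
        alpha=alpha,
        vif_cap=vif_cap,
    )


def trait_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise Pearson correlations among traits.

    Long output with columns (var_a, var_b, r, p, q, n); q is the
    Benjamini-Hochberg adjusted p over all pairs (reported alongside raw p,
    never used to filter).
    """
    from statsmodels.stats.multitest import multipletests

    if table.isna().any().any():
        raise ValueError("complete table required")
    cols = list(table.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        r, p = stats.pearsonr(table[a], table[b])
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p),
                     "n": len(table)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
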