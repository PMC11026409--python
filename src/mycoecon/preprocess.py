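"""Raw measurements -> the standardized, imputed trait matrix.

Covers the full preprocessing chain for a replicated trait dataset:

* normality check per trait (Shapiro-Wilk) with log-transform fallback,
  then z-scoring to mean 0, SD 1;
* averaging repeated measurements of one trait across assays (each
  contributing variable z-scored first);
* "syndrome" traits: the first or second PC of a small block of related
  variables (e.g. leaf + wood decomposition), sign-oriented;
* derived traits: carbon-use efficiency, stoichiometric flexibility
  (1/H of C:N homeostasis), complexity-weighted carbon use, and stress
  log-response ratios;
* missing-cell imputation by the column mean or by the k nearest
  relatives on a phylogenetic distance matrix;
* UPGMA clustering of a distance matrix into an ultrametric tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

__all__ = [
    "TransformLog",
    "normalize_and_standardize",
    "zscore",
    "aggregate_repeated",
    "syndrome_pc",
    "impute_missing",
    "carbon_use_efficiency",
    "stoichiometric_flexibility",
    "complex_carbon_use",
    "stress_log_response_ratio",
    "upgma",
    "upgma_newick",
]

LOG_SHIFT_EPS = 1e-6
NORMALITY_ALPHA = 0.05

#: substrate -> complexity weight for complexity-weighted carbon use
DEFAULT_COMPLEXITY_WEIGHTS = {
    "glucose": 1.0,
    "cellobiose": 2.0,
    "xylan": 3.0,
    "cellulose": 4.0,
    "litter": 5.0,
}


@dataclass
class TransformLog:
    """Per-trait record of what preprocessing did."""

    normality_p: dict[str, float] = field(default_factory=dict)
    log_transformed: dict[str, bool] = field(default_factory=dict)
    log_shift: dict[str, float] = field(default_factory=dict)
    imputed_cells: list[tuple[str, str, str]] = field(default_factory=list)
    # (isolate, trait, method)

    def to_dict(self) -> dict:
        return {
            "normality_p": self.normality_p,
            "log_transformed": self.log_transformed,
            "log_shift": self.log_shift,
            "imputed_cells": [list(c) for c in self.imputed_cells],
        }


def zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"constant column {col.name!r}: SD = 0")
    return (col - col.mean()) / sd


def normalize_and_standardize(
    table: pd.DataFrame, alpha: float = NORMALITY_ALPHA
) -> tuple[pd.DataFrame, TransformLog]:
    """Shapiro-Wilk gate, conditional log-transform, then z-score.

    Each trait column (missing cells ignored) is tested for normality; if
    p < alpha it is log-transformed as log(x + shift), where shift = 0 for
    strictly positive columns and |min| + 1e-6 otherwise, then z-scored to
    mean 0, SD 1 (ddof = 1). Needs >= 4 observed values per trait.
    """
    log = TransformLog()
    out = {}
    for name, col in table.items():
        vals = col.dropna()
        if vals.size < 4:
            raise ValueError(f"trait {name!r} has < 4 observed values")
        if vals.nunique() == 1:
            raise ValueError(f"constant column {name!r}")
        p = float(stats.shapiro(vals.to_numpy()).pvalue)
        log.normality_p[name] = p
        if p < alpha:
            shift = 0.0 if vals.min() > 0 else float(abs(vals.min()) + LOG_SHIFT_EPS)
            col = np.log(col + shift)
            log.log_transformed[name] = True
            log.log_shift[name] = shift
        else:
            log.log_transformed[name] = False
            log.log_shift[name] = 0.0
        out[name] = zscore(col)
    return pd.DataFrame(out, index=table.index), log


def aggregate_repeated(
    raw: pd.DataFrame, variables: list[str], name: str
) -> pd.Series:
    """Average repeated measurements of one trait.

    ``raw`` is long format with columns (isolate, variable, value); each
    contributing variable is z-scored across isolates, then the per-isolate
    arithmetic mean over the variables is taken. Isolates missing all
    contributing variables get NaN (left for imputation).
    """
    sub = raw[raw["variable"].isin(variables)]
    if sub.empty:
        raise ValueError(f"no rows for variables {variables}")
    wide = sub.pivot_table(index="isolate", columns="variable", values="value")
    z = wide.apply(zscore)
    agg = z.mean(axis=1)  # skips NaN; all-NaN rows -> NaN
    agg.name = name
    return agg


def syndrome_pc(
    sub_table: pd.DataFrame, axis: int = 1, orient_with: str | None = None
) -> tuple[pd.Series, float]:
    """Extract one PC of a small block of related variables.

    PCA on the correlation matrix of the (complete) sub-table; returns the
    requested axis' scores — sign-oriented so their correlation with the
    ``orient_with`` column is positive — and the proportion of variance (%)
    that axis explains.
    """
    from .pca import run_pca

    if sub_table.shape[1] < 2:
        raise ValueError("syndrome needs >= 2 variables")
    if axis < 1 or axis > sub_table.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    res = run_pca(sub_table)
    scores = res.scores.iloc[:, axis - 1].copy()
    if orient_with is not None:
        if orient_with not in sub_table.columns:
            raise KeyError(f"orientation trait {orient_with!r} not in sub-table")
        r = np.corrcoef(scores, sub_table[orient_with])[0, 1]
        if r < 0:
            scores = -scores
    return scores, float(res.pct_variance[axis - 1])


def impute_missing(
    table: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    mode: str = "global_mean",
    k: int = 3,
) -> tuple[pd.DataFrame, TransformLog]:
    """Fill missing trait cells.

    ``global_mean``: column mean of observed values. ``phylo_neighbors``:
    mean over the k nearest isolates (by the supplied distance matrix) that
    have an observed value for that trait — used when a trait shows
    phylogenetic signal, so close relatives are better guesses than the
    grand mean. Observed cells are never modified.
    """
    if mode not in ("global_mean", "phylo_neighbors"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "phylo_neighbors" and distances is None:
        raise ValueError("phylo_neighbors needs a distance matrix")
    out = table.copy()
    log = TransformLog()
    for trait, col in table.items():
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"trait {trait!r} entirely missing")
        for iso in col.index[col.isna()]:
            if mode == "global_mean":
                out.loc[iso, trait] = obs.mean()
            else:
                d = distances.loc[iso, obs.index].sort_values(kind="stable")
                out.loc[iso, trait] = obs[d.index[:k]].mean()
            log.imputed_cells.append((str(iso), str(trait), mode))
    return out, log


def carbon_use_efficiency(biomass_c, respired_c):
    """CUE = biomass C / (biomass C + respired C), elementwise in [0, 1]."""
    cb = np.asarray(biomass_c, dtype=float)
    cr = np.asarray(respired_c, dtype=float)
    if np.any(cb < 0) or np.any(cr < 0):
        raise ValueError("carbon masses must be nonnegative")
    tot = cb + cr
    if np.any(tot == 0):
        raise ValueError("biomass C + respired C = 0: CUE undefined")
    return cb / tot


def stoichiometric_flexibility(resource_cn, tissue_cn) -> float:
    """1/H: OLS slope of log(tissue C:N) on log(resource C:N).

    0 = strict homeostasis (tissue stoichiometry fixed), 1 = tissue fully
    tracking the resource.
    """
    x = np.log(np.asarray(resource_cn, dtype=float))
    y = np.log(np.asarray(tissue_cn, dtype=float))
    if x.size < 3:
        raise ValueError("need >= 3 resource levels")
    return float(np.polyfit(x, y, 1)[0])


def complex_carbon_use(
    biomass: pd.DataFrame, weights: dict[str, float] | None = None
) -> pd.Series:
    """Complexity-weighted average of z-scored biomass on C substrates.

    ``biomass`` columns are substrates (glucose ... litter); each column is
    z-scored across isolates and averaged with weights increasing in
    substrate complexity (default 1..5 in the order glucose, cellobiose,
    xylan, cellulose, litter).
    """
    weights = weights or DEFAULT_COMPLEXITY_WEIGHTS
    missing = set(biomass.columns) - set(weights)
    if missing:
        raise KeyError(f"no complexity weight for substrates {sorted(missing)}")
    z = biomass.apply(zscore)
    w = np.array([weights[c] for c in z.columns], dtype=float)
    out = (z.to_numpy() * w).sum(axis=1) / w.sum()
    return pd.Series(out, index=biomass.index, name="complC_use")


def stress_log_response_ratio(growth_stress, growth_control):
    """LRR = ln(growth under stress / growth under control).

    Negative when the stressor reduces growth. Requires strictly positive
    growth in both conditions.
    """
    s = np.asarray(growth_stress, dtype=float)
    c = np.asarray(growth_control, dtype=float)
    if np.any(s <= 0) or np.any(c <= 0):
        raise ValueError("growth must be positive to form a log-response ratio")
    return np.log(s / c)


def _check_distance_matrix(distances: pd.DataFrame) -> np.ndarray:
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def upgma(distances: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Returns the scipy linkage matrix; merge heights are the average
    pairwise distances between the merged groups, so the implied tree is
    ultrametric with leaf-to-ancestor heights = merge height / 2.
    """
    D = _check_distance_matrix(distances)
    return sch.average(squareform(D, checks=False))


def upgma_newick(distances: pd.DataFrame) -> str:
    """UPGMA tree serialized as Newick with ultrametric branch lengths."""
    Z = upgma(distances)
    labels = list(distances.index)
    n = len(labels)
    # node -> (newick fragment, height of node)
    nodes: dict[int, tuple[str, float]] = {
        i: (str(labels[i]), 0.0) for i in range(n)
    }
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        height = h / 2.0
        fa, ha = nodes.pop(a)
        fb, hb = nodes.pop(b)
        nodes[n + m] = (
            f"({fa}:{height - ha:.10g},{fb}:{height - hb:.10g})",
            height,
        )
    (frag, _), = nodes.values()
    return frag + ";"
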