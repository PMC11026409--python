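"""Randomized-subset PCA trait alignment.

Which traits consistently align with the primary dense-fast continuum?
Instead of trusting one PCA (whose axes shift when traits are added or
removed), the procedure repeats PCA thousands of times on small random
trait subsets and averages each trait's PC1 loading across runs:

* plain variant: random subsets only, keeping runs with a strong PC1
  (eigenvalue above a quantile of the run distribution);
* anchored variant: every run also contains two anchor traits (mycelial
  extension rate and density, the two poles of the continuum), PC1 sign is
  fixed so extension loads positively, and runs where either anchor loads
  weakly on PC1 (axis not capturing the continuum) are excluded.

Per-trait averages of the (signed) PC1 loadings then sort all traits along
the continuum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RandomizedPCAConfig",
    "AlignmentResult",
    "random_subset_pca",
    "anchored_random_pca",
    "alignment_report",
    "calibrate_anchor_threshold",
]


@dataclass(frozen=True)
class RandomizedPCAConfig:
    n_repeats: int = 10_000
    n_random_traits: int = 10
    anchors: tuple[str, str] = ("extension", "density")
    eigen_selection: float = 0.5  # keep runs with PC1 eigenvalue above this quantile
    anchor_min_loading: float = 0.4  # |PC1 loading| both anchors must reach
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.eigen_selection <= 1:
            raise ValueError("eigen_selection must be in (0, 1]")
        if not 0 <= self.anchor_min_loading < 1:
            raise ValueError("anchor_min_loading must be in [0, 1)")


@dataclass
class AlignmentResult:
    table: pd.DataFrame  # per trait: n_inclusions, mean_abs_loading, mean_signed_loading, sd_loading, side
    n_runs_retained: int
    n_runs_excluded: int
    n_repeats: int
    anchored: bool

    @property
    def exclusion_fraction(self) -> float:
        return self.n_runs_excluded / self.n_repeats


def _corr_and_check(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = table.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("trait table has missing cells; impute first")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant trait column")
    n = X.shape[0]
    Z = (X - X.mean(axis=0)) / sd
    return (Z.T @ Z) / (n - 1), list(table.columns)


def _pc1_loadings(C_sub: np.ndarray) -> tuple[float, np.ndarray]:
    """PC1 eigenvalue and trait-score correlations from a correlation submatrix."""
    eigval, eigvec = np.linalg.eigh(C_sub)
    lam1 = eigval[-1]
    return float(lam1), eigvec[:, -1] * np.sqrt(max(lam1, 0.0))


def _summarize(
    traits: list[str],
    signed_sums: np.ndarray,
    abs_sums: np.ndarray,
    sq_sums: np.ndarray,
    counts: np.ndarray,
) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs = np.where(counts > 0, abs_sums / np.maximum(counts, 1), np.nan)
        mean_signed = np.where(counts > 0, signed_sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq_sums - counts * mean_signed**2) / np.maximum(counts - 1, 1),
            np.nan,
        )
    df = pd.DataFrame(
        {
            "n_inclusions": counts.astype(int),
            "mean_abs_loading": mean_abs,
            "mean_signed_loading": mean_signed,
            "sd_loading": np.sqrt(np.clip(var, 0.0, None)),
        },
        index=pd.Index(traits, name="trait"),
    )
    df["side"] = np.where(
        df["n_inclusions"] == 0,
        "never_sampled",
        np.where(df["mean_signed_loading"] >= 0, "extension", "density"),
    )
    return df


def random_subset_pca(
    table: pd.DataFrame,
    config: RandomizedPCAConfig,
    return_run_log: bool = False,
):
    """Average |PC1 loading| of each trait over random-subset PCAs.

    Each repeat runs a correlation PCA on ``n_random_traits`` traits drawn
    uniformly without replacement; runs whose PC1 eigenvalue falls below
    the ``eigen_selection`` quantile of the run distribution are discarded,
    and the remaining runs are averaged per trait. Traits never sampled in
    a retained run are reported with ``n_inclusions = 0`` and NaN means.
    """
    C, traits = _corr_and_check(table)
    p = len(traits)
    if config.n_random_traits > p:
        raise ValueError("n_random_traits exceeds number of traits")
    rng = np.random.default_rng(config.seed)
    subsets = np.empty((config.n_repeats, config.n_random_traits), dtype=int)
    lam1 = np.empty(config.n_repeats)
    absload = np.empty((config.n_repeats, config.n_random_traits))
    for r in range(config.n_repeats):
        idx = rng.choice(p, size=config.n_random_traits, replace=False)
        subsets[r] = idx
        lam, load = _pc1_loadings(C[np.ix_(idx, idx)])
        lam1[r] = lam
        absload[r] = np.abs(load)
    cutoff = np.quantile(lam1, 1.0 - config.eigen_selection)
    keep = lam1 >= cutoff if config.eigen_selection < 1.0 else np.ones_like(lam1, bool)
    abs_sums = np.zeros(p)
    sq_sums = np.zeros(p)
    counts = np.zeros(p)
    for r in np.flatnonzero(keep):
        np.add.at(abs_sums, subsets[r], absload[r])
        np.add.at(sq_sums, subsets[r], absload[r] ** 2)
        np.add.at(counts, subsets[r], 1.0)
    df = _summarize(traits, abs_sums, abs_sums, sq_sums, counts)
    df["side"] = "unsigned"
    result = AlignmentResult(
        table=df,
        n_runs_retained=int(keep.sum()),
        n_runs_excluded=int((~keep).sum()),
        n_repeats=config.n_repeats,
        anchored=False,
    )
    if return_run_log:
        log = pd.DataFrame(
            {
                "run": np.repeat(np.arange(config.n_repeats), config.n_random_traits),
                "trait": np.asarray(traits, dtype=object)[subsets.ravel()],
                "abs_loading": absload.ravel(),
                "pc1_eigenvalue": np.repeat(lam1, config.n_random_traits),
                "retained": np.repeat(keep, config.n_random_traits),
            }
        )
        return result, log
    return result


def anchored_random_pca(
    table: pd.DataFrame, config: RandomizedPCAConfig
) -> AlignmentResult:
    """Sort every trait along the dense-fast continuum via anchored PCAs.

    Every run's subset is the two anchors plus ``n_random_traits`` traits
    drawn from the remaining pool. PC1 sign is fixed so the first anchor
    (extension) loads positively — the second anchor (density) then loads
    negatively whenever the axis captures the continuum. Runs where either
    anchor's |PC1 loading| is below ``anchor_min_loading`` are excluded.
    Per-trait signed and absolute mean loadings are averaged over retained
    runs; the output is sorted density-side to extension-side.
    """
    C, traits = _corr_and_check(table)
    p = len(traits)
    for a in config.anchors:
        if a not in traits:
            raise KeyError(f"anchor trait {a!r} not in table")
    anchor_idx = np.array([traits.index(a) for a in config.anchors])
    pool = np.array([i for i in range(p) if i not in set(anchor_idx)])
    if config.n_random_traits > pool.size:
        raise ValueError("n_random_traits exceeds non-anchor pool")
    rng = np.random.default_rng(config.seed)
    m = anchor_idx.size + config.n_random_traits
    signed_sums = np.zeros(p)
    abs_sums = np.zeros(p)
    sq_sums = np.zeros(p)
    counts = np.zeros(p)
    n_kept = 0
    for _ in range(config.n_repeats):
        idx = np.concatenate(
            [anchor_idx, rng.choice(pool, size=config.n_random_traits, replace=False)]
        )
        _, load = _pc1_loadings(C[np.ix_(idx, idx)])
        if load[0] < 0:  # extension loads positively by convention
            load = -load
        if min(abs(load[0]), abs(load[1])) < config.anchor_min_loading:
            continue
        n_kept += 1
        np.add.at(signed_sums, idx, load)
        np.add.at(abs_sums, idx, np.abs(load))
        np.add.at(sq_sums, idx, load**2)
        np.add.at(counts, idx, 1.0)
    if n_kept == 0:
        raise RuntimeError(
            "all runs excluded: anchor_min_loading="
            f"{config.anchor_min_loading} too strict for these anchors"
        )
    df = _summarize(traits, signed_sums, abs_sums, sq_sums, counts)
    df = df.sort_values("mean_signed_loading")
    return AlignmentResult(
        table=df,
        n_runs_retained=n_kept,
        n_runs_excluded=config.n_repeats - n_kept,
        n_repeats=config.n_repeats,
        anchored=True,
    )


def calibrate_anchor_threshold(
    table: pd.DataFrame, config: RandomizedPCAConfig, target_exclusion: float
) -> float:
    """Threshold on min anchor |PC1 loading| giving a target exclusion fraction.

    Runs the anchored repeats without exclusion, collects each run's
    min(|loading(anchor1)|, |loading(anchor2)|), and returns its
    ``target_exclusion`` quantile — excluding runs below it removes
    approximately that fraction.
    """
    if not 0 <= target_exclusion < 1:
        raise ValueError("target_exclusion must be in [0, 1)")
    C, traits = _corr_and_check(table)
    p = len(traits)
    anchor_idx = np.array([traits.index(a) for a in config.anchors])
    pool = np.array([i for i in range(p) if i not in set(anchor_idx)])
    rng = np.random.default_rng(config.seed)
    mins = np.empty(config.n_repeats)
    for r in range(config.n_repeats):
        idx = np.concatenate(
            [anchor_idx, rng.choice(pool, size=config.n_random_traits, replace=False)]
        )
        _, load = _pc1_loadings(C[np.ix_(idx, idx)])
        mins[r] = min(abs(load[0]), abs(load[1]))
    return float(np.quantile(mins, target_exclusion))


def alignment_report(
    result: AlignmentResult, path=None, plot_path=None
) -> pd.DataFrame:
    """Ordered per-trait alignment table (and optional CSV / bar plot).

    Traits are ordered by mean signed PC1 loading (density side first) for
    the anchored variant, by mean |loading| for the unsigned variant.
    """
    key = "mean_signed_loading" if result.anchored else "mean_abs_loading"
    df = result.table.sort_values(key, na_position="last")
    if path is not None:
        df.to_csv(path)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4))
        ax.bar(df.index, df[key].fillna(0.0))
        ax.set_ylabel(key)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
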