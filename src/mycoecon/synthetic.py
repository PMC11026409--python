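"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design: ~28 soil saprobic fungal isolates
scored on ~35 standardized traits whose correlation structure is driven by
three mutually orthogonal latent factors (dense-fast, mycelial flexibility,
C acquisition), plus per-isolate skew-normal biomass response curves along
three environmental gradients, a random ultrametric phylogeny, and sparse
missingness. Because the latent scores, loadings and niche parameters are
stored, every downstream estimate can be checked against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import GradientDesign, default_gradient_designs

__all__ = [
    "TraitGroup",
    "NicheParamRanges",
    "SyntheticConfig",
    "SyntheticDataset",
    "skewnorm_curve",
    "generate_trait_matrix",
    "generate_niche_curves",
    "generate_phylogeny",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class TraitGroup:
    """A block of traits loading on one latent factor.

    ``loading`` in [-1, 1] is the common loading magnitude of the block;
    individual traits get alternating signs so each factor has both poles
    (as real trait axes do: e.g. density vs extension on the dense-fast
    continuum).
    """

    name: str
    n_traits: int
    factor: int  # 1-based index of the latent factor (1..3)
    loading: float = 0.8
    alternate_signs: bool = True


@dataclass(frozen=True)
class NicheParamRanges:
    """Uniform sampling ranges for skew-normal niche parameters on one gradient.

    location: curve location xi (gradient units); scale: omega > 0; shape:
    alpha (unitless skewness); amplitude: multiplier A of the unit density
    (units of biomass x gradient units).
    """

    location: tuple[float, float]
    scale: tuple[float, float]
    shape: tuple[float, float] = (-4.0, 4.0)
    amplitude: tuple[float, float] = (20.0, 80.0)


def default_trait_groups() -> tuple[TraitGroup, ...]:
    # 35 traits in 3 ecological blocks mirroring the dense-fast /
    # flexibility / C-acquisition structure of the trait space.
    return (
        TraitGroup("dense_fast", 14, factor=1, loading=0.8),
        TraitGroup("flexibility", 11, factor=2, loading=0.75),
        TraitGroup("c_acquisition", 10, factor=3, loading=0.75),
    )


def default_niche_param_ranges() -> dict[str, NicheParamRanges]:
    # Locations span the tested range; scales give breadths that are a
    # substantial fraction of each gradient, as observed growth curves do.
    return {
        "CN": NicheParamRanges(location=(20.0, 160.0), scale=(20.0, 60.0)),
        "temperature": NicheParamRanges(location=(16.0, 30.0), scale=(2.5, 6.0)),
        "water_potential": NicheParamRanges(location=(-1.6, -0.6), scale=(0.2, 0.6)),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    n_isolates: int = 28
    trait_groups: tuple[TraitGroup, ...] = field(default_factory=default_trait_groups)
    noise_sd: float = 0.3
    missing_rate: float = 0.03
    gradient_designs: dict[str, GradientDesign] = field(
        default_factory=default_gradient_designs
    )
    niche_param_ranges: dict[str, NicheParamRanges] = field(
        default_factory=default_niche_param_ranges
    )
    biomass_noise_frac: float = 0.05  # obs noise SD as a fraction of amplitude A
    n_replicates_per_level: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 4:
            raise ValueError("n_isolates must be >= 4")
        if sum(g.n_traits for g in self.trait_groups) < 4:
            raise ValueError("need at least 4 traits in total")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        factors = {g.factor for g in self.trait_groups}
        if not factors <= {1, 2, 3}:
            raise ValueError("trait-group factors must be in 1..3")
        for name, rng in self.niche_param_ranges.items():
            d = self.gradient_designs[name]
            lo, hi = rng.location
            if lo < d.levels[0] - d.span or hi > d.levels[-1] + d.span:
                raise ValueError(
                    f"location range for {name!r} farther than one gradient width "
                    "outside the tested levels"
                )

    @property
    def trait_names(self) -> list[str]:
        return [
            f"{g.name}_{j + 1}" for g in self.trait_groups for j in range(g.n_traits)
        ]

    @property
    def n_factors(self) -> int:
        return max(g.factor for g in self.trait_groups)


@dataclass
class SyntheticDataset:
    """Generated data plus the ground truth used to generate it."""

    config: SyntheticConfig
    trait_table: pd.DataFrame  # isolates x traits, NaN = missing
    true_loadings: pd.DataFrame  # traits x factors
    true_scores: pd.DataFrame  # isolates x factors, exactly orthogonal
    missing_mask: pd.DataFrame
    biomass_obs: pd.DataFrame | None = None  # long format
    niche_truth: pd.DataFrame | None = None  # isolate x gradient parameters
    distance_matrix: pd.DataFrame | None = None
    newick: str | None = None


def skewnorm_curve(
    x: np.ndarray | float, xi: float, omega: float, alpha: float, amplitude: float
) -> np.ndarray:
    """Amplitude-scaled skew-normal performance curve.

    b(x) = A * (2/omega) * phi((x-xi)/omega) * Phi(alpha*(x-xi)/omega),
    i.e. ``amplitude`` times the skew-normal density; nonnegative everywhere.
    """
    from scipy.stats import skewnorm

    return amplitude * skewnorm.pdf(x, alpha, loc=xi, scale=omega)


def _orthogonal_scores(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n x k scores: centered, exactly orthogonal columns, unit SD (ddof=1)."""
    raw = rng.standard_normal((n, k))
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q = q * np.sign(np.diag(r))  # undo QR sign ambiguity -> deterministic
    q -= q.mean(axis=0)  # re-center (QR preserves it up to fp error)
    return q / q.std(axis=0, ddof=1)


def generate_trait_matrix(config: SyntheticConfig) -> SyntheticDataset:
    """Trait matrix X = S L' + E with planted orthogonal factor structure.

    Scores S are orthogonalized standard-normal columns (QR), loadings L are
    block-structured by trait group with alternating signs inside a block,
    noise E is iid N(0, noise_sd). Columns are then affinely shifted and
    scaled so that downstream standardization is actually exercised, and a
    ``missing_rate`` fraction of cells is blanked.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_isolates, config.n_factors
    traits = config.trait_names
    p = len(traits)

    scores = _orthogonal_scores(rng, n, k)
    loadings = np.zeros((p, k))
    row = 0
    for g in config.trait_groups:
        for j in range(g.n_traits):
            sign = -1.0 if (g.alternate_signs and j % 2 == 1) else 1.0
            loadings[row, g.factor - 1] = sign * g.loading
            row += 1

    X = scores @ loadings.T + rng.normal(0.0, config.noise_sd, size=(n, p))
    # de-standardize so preprocessing has work to do
    col_scale = rng.uniform(0.5, 5.0, size=p)
    col_shift = rng.uniform(-10.0, 10.0, size=p)
    X = X * col_scale + col_shift

    mask = rng.random((n, p)) < config.missing_rate
    # never blank out a full column
    full = mask.all(axis=0)
    mask[:, full] = False
    Xm = X.copy()
    Xm[mask] = np.nan

    isolates = [f"iso{i + 1:02d}" for i in range(n)]
    return SyntheticDataset(
        config=config,
        trait_table=pd.DataFrame(Xm, index=isolates, columns=traits),
        true_loadings=pd.DataFrame(
            loadings, index=traits, columns=[f"F{i + 1}" for i in range(k)]
        ),
        true_scores=pd.DataFrame(
            scores, index=isolates, columns=[f"F{i + 1}" for i in range(k)]
        ),
        missing_mask=pd.DataFrame(mask, index=isolates, columns=traits),
    )


def generate_niche_curves(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate biomass observations along each gradient for each isolate.

    For every isolate x gradient a parameter tuple (xi, omega, alpha, A) is
    drawn uniformly from the configured ranges; the curve is evaluated at
    the design levels, iid normal noise with SD = ``biomass_noise_frac``
    times the curve's peak growth added per replicate, and negative values
    truncated at 0 (measurement floor). Scaling noise to each isolate's
    maximum growth keeps the relative measurement error comparable across
    isolates of very different absolute biomass.

    Returns
    -------
    (biomass_obs, niche_truth):
        long observations ``(isolate, gradient, level, replicate, biomass)``
        and the true parameters per isolate x gradient.
    """
    if not config.gradient_designs:
        raise ValueError("at least one gradient design is required")
    rng = np.random.default_rng(config.seed + 1)
    isolates = [f"iso{i + 1:02d}" for i in range(config.n_isolates)]
    obs_rows = []
    truth_rows = []
    for gname, design in config.gradient_designs.items():
        pr = config.niche_param_ranges[gname]
        levels = np.asarray(design.levels)
        for iso in isolates:
            xi = rng.uniform(*pr.location)
            omega = rng.uniform(*pr.scale)
            alpha = rng.uniform(*pr.shape)
            amp = rng.uniform(*pr.amplitude)
            truth_rows.append(
                {"isolate": iso, "gradient": gname, "xi": xi, "omega": omega,
                 "alpha": alpha, "amplitude": amp}
            )
            curve = skewnorm_curve(levels, xi, omega, alpha, amp)
            fine = np.linspace(xi - 6 * omega, xi + 6 * omega, 2001)
            peak = float(skewnorm_curve(fine, xi, omega, alpha, amp).max())
            for rep in range(config.n_replicates_per_level):
                noisy = curve + rng.normal(
                    0.0, config.biomass_noise_frac * peak, size=levels.size
                )
                noisy = np.clip(noisy, 0.0, None)
                for lev, b in zip(levels, noisy):
                    obs_rows.append(
                        {"isolate": iso, "gradient": gname, "level": float(lev),
                         "replicate": rep + 1, "biomass": float(b)}
                    )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def generate_phylogeny(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, str]:
    """Random ultrametric tree by sequential pair merging at increasing heights.

    Lineages are merged two at a time (coalescent-style) at strictly
    increasing heights; patristic distance between two leaves is twice the
    height of their most recent common ancestor, hence the matrix is
    ultrametric by construction.

    Returns the patristic distance matrix and a Newick string.
    """
    n = config.n_isolates
    if n < 2:
        raise ValueError("need >= 2 isolates for a phylogeny")
    rng = np.random.default_rng(config.seed + 2)
    isolates = [f"iso{i + 1:02d}" for i in range(n)]

    # active nodes: (newick fragment, height, set of leaf indices)
    active: list[tuple[str, float, list[int]]] = [
        (name, 0.0, [i]) for i, name in enumerate(isolates)
    ]
    D = np.zeros((n, n))
    height = 0.0
    while len(active) > 1:
        height += rng.exponential(1.0 / len(active))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        nj = active.pop(j)
        ni = active.pop(i)
        for a in ni[2]:
            for b in nj[2]:
                D[a, b] = D[b, a] = 2.0 * height
        nwk = (
            f"({ni[0]}:{height - ni[1]:.6f},{nj[0]}:{height - nj[1]:.6f})"
        )
        active.append((nwk, height, ni[2] + nj[2]))
    newick = active[0][0] + ";"
    return pd.DataFrame(D, index=isolates, columns=isolates), newick


def brownian_trait(
    distance_matrix: pd.DataFrame, seed: int, sigma2: float = 1.0
) -> pd.Series:
    """Simulate a Brownian-motion trait on an ultrametric tree.

    Under Brownian motion on an ultrametric tree of height H, leaf values
    are multivariate normal with Cov(i, j) = sigma2 * (H - d_ij / 2), the
    shared path length from the root.
    """
    D = distance_matrix.to_numpy()
    H = D.max() / 2.0
    cov = sigma2 * (H - D / 2.0)
    rng = np.random.default_rng(seed)
    vals = rng.multivariate_normal(np.zeros(len(D)), cov, method="cholesky")
    return pd.Series(vals, index=distance_matrix.index)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """All three generators combined under one config/seed."""
    ds = generate_trait_matrix(config)
    ds.biomass_obs, ds.niche_truth = generate_niche_curves(config)
    ds.distance_matrix, ds.newick = generate_phylogeny(config)
    return ds


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write trait CSV, long biomass CSV, Newick tree and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["traits"] = outdir / "traits.csv"
    ds.trait_table.to_csv(paths["traits"], index_label="isolate")
    if ds.biomass_obs is not None:
        paths["biomass"] = outdir / "biomass.csv"
        ds.biomass_obs.to_csv(paths["biomass"], index=False)
    if ds.distance_matrix is not None:
        paths["distances"] = outdir / "distances.csv"
        ds.distance_matrix.to_csv(paths["distances"], index_label="isolate")
    if ds.newick is not None:
        paths["tree"] = outdir / "tree.nwk"
        paths["tree"].write_text(ds.newick + "\n")
    truth = {
        "true_loadings": ds.true_loadings.to_dict(orient="index"),
        "true_scores": ds.true_scores.to_dict(orient="index"),
    }
    if ds.niche_truth is not None:
        truth["niche_truth"] = ds.niche_truth.to_dict(orient="records")
    paths["truth"] = outdir / "ground_truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
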