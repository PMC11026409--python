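"""Fundamental-niche models: skew-normal performance curves and summaries.

Each isolate's biomass response along an environmental gradient is modeled
as an amplitude-scaled skew-normal curve

    b(x) = A * (2/omega) * phi((x - xi)/omega) * Phi(alpha * (x - xi)/omega)

with location xi, scale omega > 0, shape alpha (skewness) and amplitude
A > 0. The niche optimum is the argmax of the fitted curve within the
tested range; the niche breadth is the width of the interval where the
curve stays at or above 25% of the isolate's maximum growth; the
three-dimensional niche volume assumes a cuboid shape with side lengths
equal to the max-standardized relative breadths on the three gradients.
Relative abundances of isolates along a gradient (fitted curves normalized
pointwise across isolates) weight the isolates' rotated-component scores
into community-weighted trait profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .designs import GradientDesign, WATER_PROFILE_FLOOR
from .synthetic import skewnorm_curve

__all__ = [
    "SkewNormalFit",
    "NicheSummary",
    "GradientProfile",
    "fit_skew_normal",
    "fit_all",
    "niche_optimum",
    "niche_breadth",
    "summarize_niches",
    "niche_cube",
    "relative_abundance_profile",
    "weighted_rc_profile",
    "smooth_profile",
]

BREADTH_THRESHOLD = 0.25  # growth fraction defining the niche edge


@dataclass
class SkewNormalFit:
    xi: float
    omega: float
    alpha: float
    amplitude: float
    rss: float
    converged: bool
    n_obs: int

    def curve(self, x) -> np.ndarray:
        return skewnorm_curve(x, self.xi, self.omega, self.alpha, self.amplitude)


@dataclass
class GradientProfile:
    gradient: str
    grid: np.ndarray
    fitted: pd.DataFrame  # grid points x isolates, fitted biomass
    relative_abundance: pd.DataFrame  # row-normalized, rows sum to 1
    dropped_points: np.ndarray  # grid values where all curves were ~0


def _moment_start(levels: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    w = np.clip(y, 0.0, None)
    if w.sum() == 0:
        raise ValueError("no growth: all biomass zero")
    xi0 = float(np.average(levels, weights=w))
    var = float(np.average((levels - xi0) ** 2, weights=w))
    omega0 = max(np.sqrt(var), 1e-3 * (levels[-1] - levels[0]))
    amp0 = float(np.trapezoid(np.interp(
        np.linspace(levels[0], levels[-1], 100), levels, y
    ), dx=(levels[-1] - levels[0]) / 99))
    return xi0, omega0, max(amp0, 1e-8)


def fit_skew_normal(
    obs: pd.DataFrame, design: GradientDesign | None = None
) -> SkewNormalFit:
    """Nonlinear least-squares fit of the skew-normal curve to one
    isolate x gradient set of observations.

    ``obs`` needs columns ``level`` and ``biomass`` (replicates as separate
    rows). Initialization uses biomass-weighted moments of the levels;
    seven starts with shape alpha0 in {-4, -2, -1, 0, 1, 2, 4} are run and
    the lowest-RSS solution kept. Requires >= 4 distinct levels.
    """
    levels = obs["level"].to_numpy(dtype=float)
    y = obs["biomass"].to_numpy(dtype=float)
    uniq = np.unique(levels)
    if uniq.size < 4:
        raise ValueError(f"need >= 4 distinct levels, got {uniq.size}")
    span = uniq[-1] - uniq[0]
    means = np.array([y[levels == u].mean() for u in uniq])
    xi0, omega0, amp0 = _moment_start(uniq, means)

    def resid(theta):
        xi, log_omega, alpha, log_amp = theta
        return skewnorm_curve(levels, xi, np.exp(log_omega), alpha, np.exp(log_amp)) - y

    best = None
    lo = [uniq[0] - span, np.log(1e-3 * span), -50.0, np.log(1e-12)]
    hi = [uniq[-1] + span, np.log(10.0 * span), 50.0, np.log(1e12)]
    for a0 in (-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0):
        try:
            sol = optimize.least_squares(
                resid,
                x0=[xi0, np.log(omega0), a0, np.log(amp0)],
                bounds=(lo, hi),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return SkewNormalFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, y.size)
    rss, sol = best
    xi, log_omega, alpha, log_amp = sol.x
    return SkewNormalFit(
        xi=float(xi),
        omega=float(np.exp(log_omega)),
        alpha=float(alpha),
        amplitude=float(np.exp(log_amp)),
        rss=rss,
        converged=bool(sol.success),
        n_obs=int(y.size),
    )


def fit_all(
    biomass_obs: pd.DataFrame, designs: dict[str, GradientDesign]
) -> dict[tuple[str, str], SkewNormalFit]:
    """Fit every (isolate, gradient) group present in long observations."""
    fits: dict[tuple[str, str], SkewNormalFit] = {}
    for (iso, grad), grp in biomass_obs.groupby(["isolate", "gradient"], sort=True):
        if grad not in designs:
            raise KeyError(f"no design for gradient {grad!r}")
        fits[(str(iso), str(grad))] = fit_skew_normal(grp, designs[grad])
    return fits


def niche_optimum(fit: SkewNormalFit, design: GradientDesign) -> float:
    """Gradient value of maximal fitted growth within the modeling range."""
    lo, hi = design.modeling_range
    res = optimize.minimize_scalar(
        lambda x: -fit.curve(x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10 * (hi - lo) + 1e-12},
    )
    x_star = float(res.x)
    # bounded search can stall a hair inside the edge on monotone curves
    for edge in (lo, hi):
        if fit.curve(edge) > fit.curve(x_star):
            x_star = edge
    return x_star


def niche_breadth(
    fit: SkewNormalFit,
    design: GradientDesign,
    threshold: float = BREADTH_THRESHOLD,
) -> tuple[float, float]:
    """Interval of the modeling range where growth >= threshold * maximum.

    The maximum is the isolate's own fitted peak within the range; edges
    are found by root-finding on b(x) - threshold * b_max on each side of
    the optimum and clipped to the modeling range. The skew-normal is
    unimodal, so the super-level set is a single interval.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    lo, hi = design.modeling_range
    opt = niche_optimum(fit, design)
    b_max = float(fit.curve(opt))
    if b_max <= 0:
        raise ValueError("degenerate fit: zero maximum growth")
    target = threshold * b_max

    def g(x):
        return fit.curve(x) - target

    # left edge: curve is increasing toward the optimum, so search only if
    # the range edge itself is below target; likewise on the right.
    if g(lo) >= 0:
        x_lo = lo
    else:
        x_lo = float(optimize.brentq(g, lo, opt, xtol=1e-10, rtol=1e-12))
    if g(hi) >= 0:
        x_hi = hi
    else:
        x_hi = float(optimize.brentq(g, opt, hi, xtol=1e-10, rtol=1e-12))
    return x_lo, x_hi


def summarize_niches(
    fits: dict[tuple[str, str], SkewNormalFit],
    designs: dict[str, GradientDesign],
    threshold: float = BREADTH_THRESHOLD,
) -> pd.DataFrame:
    """Per isolate x gradient: optimum, max growth, breadth interval,
    breadth, relative breadth (breadth / max breadth across isolates on the
    same gradient). Non-converged fits are reported with NaN summaries.
    """
    rows = []
    for (iso, grad), fit in fits.items():
        design = designs[grad]
        if not fit.converged or not np.isfinite(fit.xi):
            rows.append({"isolate": iso, "gradient": grad, "optimum": np.nan,
                         "max_growth": np.nan, "breadth_lo": np.nan,
                         "breadth_hi": np.nan, "breadth": np.nan})
            continue
        opt = niche_optimum(fit, design)
        x_lo, x_hi = niche_breadth(fit, design, threshold)
        rows.append({
            "isolate": iso, "gradient": grad, "optimum": opt,
            "max_growth": float(fit.curve(opt)),
            "breadth_lo": x_lo, "breadth_hi": x_hi, "breadth": x_hi - x_lo,
        })
    df = pd.DataFrame(rows)
    df["relative_breadth"] = df["breadth"] / df.groupby("gradient")["breadth"].transform(
        "max"
    )
    return df


def niche_cube(summary: pd.DataFrame) -> pd.Series:
    """Cuboid niche volume per isolate: product of relative breadths.

    Isolates missing a converged breadth on any gradient get NaN.
    Values lie in (0, 1]; the isolate with maximal breadth on every
    gradient scores exactly 1.
    """
    wide = summary.pivot(index="isolate", columns="gradient", values="relative_breadth")
    vol = wide.prod(axis=1, skipna=False)
    vol.name = "niche_cube"
    return vol


def relative_abundance_profile(
    fits: dict[tuple[str, str], SkewNormalFit],
    gradient: str,
    design: GradientDesign,
    grid_n: int = 201,
    profile_range: tuple[float, float] | None = None,
) -> GradientProfile:
    """Pointwise relative abundance of isolates along one gradient.

    On a uniform grid, rel_i(x) = b_i(x) / sum_j b_j(x) from the fitted
    curves of all converged isolates on this gradient. Grid points where
    every curve is (numerically) zero are dropped and reported.
    """
    sel = {
        iso: fit
        for (iso, grad), fit in fits.items()
        if grad == gradient and fit.converged and np.isfinite(fit.xi)
    }
    if len(sel) < 2:
        raise ValueError("need >= 2 isolates with converged fits")
    lo, hi = profile_range if profile_range is not None else design.modeling_range
    grid = np.linspace(lo, hi, grid_n)
    fitted = pd.DataFrame(
        {iso: fit.curve(grid) for iso, fit in sel.items()}, index=grid
    )
    totals = fitted.sum(axis=1)
    keep = totals > 1e-300
    if not keep.any():
        raise ValueError("all fitted curves are zero over the whole range")
    rel = fitted.loc[keep].div(totals[keep], axis=0)
    return GradientProfile(
        gradient=gradient,
        grid=grid[keep.to_numpy()],
        fitted=fitted.loc[keep],
        relative_abundance=rel,
        dropped_points=grid[~keep.to_numpy()],
    )


def water_profile_range(design: GradientDesign) -> tuple[float, float]:
    """Profile range for the water-potential gradient: community-weighted
    profiles are only evaluated down to the configured floor (more severe
    water stress is reached by too few isolates)."""
    lo, hi = design.modeling_range
    return max(lo, WATER_PROFILE_FLOOR), hi


def weighted_rc_profile(
    profile: GradientProfile, rc_scores: pd.DataFrame
) -> pd.DataFrame:
    """Abundance-weighted mean RC score at each grid point.

    W_m(x) = sum_i rel_i(x) * score_im — the community-weighted mean trait
    value of the modeled assemblage at gradient value x. Every profiled
    isolate must have a score.
    """
    missing = set(profile.relative_abundance.columns) - set(rc_scores.index)
    if missing:
        raise KeyError(f"isolates without RC scores: {sorted(missing)}")
    S = rc_scores.loc[list(profile.relative_abundance.columns)]
    W = profile.relative_abundance.to_numpy() @ S.to_numpy()
    return pd.DataFrame(W, index=profile.relative_abundance.index, columns=S.columns)


def smooth_profile(
    x: np.ndarray, y: np.ndarray, return_edof: bool = False
):
    """GAM-style smoother: penalized cubic smoothing spline, penalty by GCV.

    Duplicate x values are collapsed by averaging y. Returns fitted values
    at the (unique) x, plus the effective degrees of freedom (trace of the
    smoother matrix) when requested.
    """
    from scipy.interpolate import make_smoothing_spline

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < x.size:
        uy = np.zeros(ux.size)
        np.add.at(uy, inv, y)
        uy /= np.bincount(inv)
    else:
        uy = y
    if ux.size < 8:
        raise ValueError("need >= 8 distinct points to smooth")
    if not return_edof:
        return ux, make_smoothing_spline(ux, uy)(ux)

    # explicit GCV over a penalty grid so the smoother matrix (hence the
    # effective degrees of freedom = its trace) is available
    n = ux.size
    span = ux[-1] - ux[0]
    lams = np.geomspace(1e-8, 1e4, 25) * span**3
    best = None
    for lam in lams:
        S = np.column_stack(
            [make_smoothing_spline(ux, np.eye(n)[:, i], lam=lam)(ux) for i in range(n)]
        )
        fitted = S @ uy
        tr = float(np.trace(S))
        gcv = n * float(((uy - fitted) ** 2).sum()) / (n - tr) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, fitted, tr)
    return ux, best[1], best[2]
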