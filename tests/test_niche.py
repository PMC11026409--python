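"""Skew-normal niche curves: fitting, optima, breadths, volumes, profiles."""

import numpy as np
import pandas as pd
import pytest

import mycoecon as m
from mycoecon.designs import GradientDesign, default_gradient_designs
from mycoecon.niche import (
    BREADTH_THRESHOLD,
    SkewNormalFit,
    fit_skew_normal,
    niche_breadth,
    niche_cube,
    niche_optimum,
    relative_abundance_profile,
    smooth_profile,
    summarize_niches,
    weighted_rc_profile,
)
from mycoecon.synthetic import skewnorm_curve

TEMP = default_gradient_designs()["temperature"]
WIDE = GradientDesign("wide", tuple(np.linspace(-100.0, 100.0, 9)), "x")


def obs_from_curve(levels, xi, omega, alpha, amp, reps=3):
    lv = np.tile(np.asarray(levels, float), reps)
    return pd.DataFrame({"level": lv,
                         "biomass": skewnorm_curve(lv, xi, omega, alpha, amp)})


class TestFit:
    def test_noiseless_symmetric_recovery(self):
        f = fit_skew_normal(obs_from_curve(TEMP.levels, 25, 4, 0, 10))
        assert f.converged
        assert f.xi == pytest.approx(25, rel=1e-4)
        assert f.omega == pytest.approx(4, rel=1e-4)
        assert abs(f.alpha) < 1e-3
        assert f.amplitude == pytest.approx(10, rel=1e-4)
        assert f.rss < 1e-12

    @pytest.mark.parametrize("alpha", [-3.0, 2.0, 4.0])
    def test_noiseless_skewed_recovery(self, alpha):
        f = fit_skew_normal(obs_from_curve(TEMP.levels, 22, 4, alpha, 30))
        assert f.xi == pytest.approx(22, rel=1e-3)
        assert f.alpha == pytest.approx(alpha, abs=0.05)

    def test_too_few_levels_rejected(self):
        obs = pd.DataFrame({"level": [1.0, 2, 3, 1, 2, 3],
                            "biomass": [0.1, 1, 0.1, 0.2, 1.1, 0.1]})
        with pytest.raises(ValueError, match="4 distinct"):
            fit_skew_normal(obs)

    def test_all_zero_biomass_rejected(self):
        obs = pd.DataFrame({"level": list(TEMP.levels),
                            "biomass": np.zeros(8)})
        with pytest.raises(ValueError, match="no growth"):
            fit_skew_normal(obs)


class TestOptimum:
    def test_symmetric_mode_is_location(self):
        f = SkewNormalFit(25, 4, 0, 10, 0, True, 8)
        assert niche_optimum(f, TEMP) == pytest.approx(25, abs=1e-6)

    def test_skewed_mode_matches_grid_oracle(self):
        f = SkewNormalFit(20, 5, 3, 10, 0, True, 8)
        grid = np.linspace(12, 33, 1_000_001)
        oracle = grid[skewnorm_curve(grid, 20, 5, 3, 10).argmax()]
        assert niche_optimum(f, TEMP) == pytest.approx(oracle, abs=3e-5)

    def test_monotone_curve_optimum_at_boundary(self):
        f = SkewNormalFit(40, 10, 0, 10, 0, True, 8)  # mode above range
        assert niche_optimum(f, TEMP) == pytest.approx(33.0)


class TestBreadth:
    def test_gaussian_closed_form(self):
        sigma = 2.0
        f = SkewNormalFit(5, sigma, 0, 10, 0, True, 8)
        lo, hi = niche_breadth(f, WIDE)
        assert hi - lo == pytest.approx(2 * sigma * np.sqrt(2 * np.log(4)), abs=1e-4)

    def test_clipped_to_full_range(self):
        f = SkewNormalFit(25, 10, 0, 10, 0, True, 8)
        lo, hi = niche_breadth(f, TEMP)
        assert (lo, hi) == (12.0, 33.0)

    def test_skewed_interval_matches_grid_scan(self):
        f = SkewNormalFit(20, 4, 4, 10, 0, True, 8)
        lo, hi = niche_breadth(f, TEMP)
        grid = TEMP.grid(2_000_001)
        b = f.curve(grid)
        inside = grid[b >= BREADTH_THRESHOLD * b.max()]
        assert lo == pytest.approx(inside[0], abs=1e-3)
        assert hi == pytest.approx(inside[-1], abs=1e-3)

    def test_optimum_inside_interval_and_monotone_in_threshold(self):
        f = SkewNormalFit(22, 3, -2, 10, 0, True, 8)
        opt = niche_optimum(f, TEMP)
        widths = []
        for thr in (0.1, 0.25, 0.5, 0.9):
            lo, hi = niche_breadth(f, TEMP, thr)
            assert lo <= opt <= hi
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestCubeAndProfiles:
    @pytest.fixture(scope="class")
    @staticmethod
    def fits():
        rng = np.random.default_rng(0)
        designs = default_gradient_designs()
        fits = {}
        for i, iso in enumerate([f"iso{k}" for k in range(1, 5)]):
            for gname, d in designs.items():
                lo, hi = d.modeling_range
                span = hi - lo
                fits[(iso, gname)] = SkewNormalFit(
                    xi=lo + (0.3 + 0.1 * i) * span,
                    omega=(0.1 + 0.07 * i) * span,
                    alpha=(-1.0) ** i * rng.uniform(0, 2),
                    amplitude=10 + 5 * i, rss=0.0, converged=True, n_obs=24,
                )
        return fits, designs

    def test_relative_breadths_and_volume_bounds(self, fits):
        fits, designs = fits
        summ = summarize_niches(fits, designs)
        assert ((summ.relative_breadth > 0) & (summ.relative_breadth <= 1)).all()
        vol = niche_cube(summ)
        assert ((vol > 0) & (vol <= 1)).all()
        # brute-force product oracle
        for iso in vol.index:
            sub = summ[summ.isolate == iso]
            assert vol[iso] == pytest.approx(sub.relative_breadth.prod())

    def test_max_breadth_isolate_scores_one(self, fits):
        fits, designs = fits
        summ = summarize_niches(fits, designs)
        # widest isolate on every gradient here is iso4 by construction
        widest = summ.loc[summ.groupby("gradient")["breadth"].idxmax(), "isolate"]
        if widest.nunique() == 1:
            assert niche_cube(summ)[widest.iloc[0]] == pytest.approx(1.0)

    def test_volume_invariant_to_breadth_rescaling(self, fits):
        fits, designs = fits
        summ = summarize_niches(fits, designs)
        vol = niche_cube(summ)
        scaled = summ.copy()
        mask = scaled.gradient == "temperature"
        scaled.loc[mask, "breadth"] *= 7.0
        scaled["relative_breadth"] = scaled["breadth"] / scaled.groupby(
            "gradient"
        )["breadth"].transform("max")
        pd.testing.assert_series_equal(niche_cube(scaled), vol)

    def test_identical_curves_share_abundance(self):
        d = TEMP
        f = SkewNormalFit(24, 4, 1, 10, 0, True, 8)
        prof = relative_abundance_profile({("a", "t"): f, ("b", "t"): f}, "t", d)
        np.testing.assert_allclose(prof.relative_abundance.to_numpy(), 0.5,
                                   atol=1e-12)

    def test_abundances_row_normalized_and_match_recomputation(self, fits):
        fits, designs = fits
        d = designs["CN"]
        prof = relative_abundance_profile(fits, "CN", d, grid_n=101)
        rows = prof.relative_abundance.to_numpy()
        np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-9)
        # hand-rolled recomputation on the same grid
        curves = np.column_stack(
            [fits[(iso, "CN")].curve(prof.grid)
             for iso in prof.relative_abundance.columns]
        )
        np.testing.assert_allclose(
            rows, curves / curves.sum(axis=1, keepdims=True), atol=1e-12
        )

    def test_weighted_profile_conservation_and_bounds(self, fits):
        fits, designs = fits
        prof = relative_abundance_profile(fits, "temperature",
                                          designs["temperature"])
        isolates = list(prof.relative_abundance.columns)
        const = pd.DataFrame({"RC1": np.full(len(isolates), 2.5)}, index=isolates)
        W = weighted_rc_profile(prof, const)
        np.testing.assert_allclose(W["RC1"].to_numpy(), 2.5, atol=1e-9)
        rng = np.random.default_rng(3)
        scores = pd.DataFrame({"RC1": rng.normal(size=len(isolates))},
                              index=isolates)
        W = weighted_rc_profile(prof, scores)
        assert (W["RC1"] >= scores["RC1"].min() - 1e-9).all()
        assert (W["RC1"] <= scores["RC1"].max() + 1e-9).all()

    def test_weighted_profile_two_isolate_arithmetic(self):
        # abundances (0.75, 0.25) with scores (+1, -1) -> weighted mean 0.5
        f_hi = SkewNormalFit(24, 4, 0, 30, 0, True, 8)
        f_lo = SkewNormalFit(24, 4, 0, 10, 0, True, 8)
        prof = relative_abundance_profile({("a", "t"): f_hi, ("b", "t"): f_lo},
                                          "t", TEMP)
        scores = pd.DataFrame({"RC1": [1.0, -1.0]}, index=["a", "b"])
        W = weighted_rc_profile(prof, scores)
        np.testing.assert_allclose(W["RC1"].to_numpy(), 0.5, atol=1e-9)

    def test_zero_abundance_isolate_changes_nothing(self, fits):
        fits, designs = fits
        d = designs["temperature"]
        prof = relative_abundance_profile(fits, "temperature", d)
        scores = pd.DataFrame(
            {"RC1": np.arange(len(prof.relative_abundance.columns), dtype=float)},
            index=prof.relative_abundance.columns,
        )
        W1 = weighted_rc_profile(prof, scores)
        ghost = dict(fits)
        ghost[("ghost", "temperature")] = SkewNormalFit(
            24, 4, 0, 0.0, 0, True, 8
        )  # amplitude 0 -> never grows
        prof2 = relative_abundance_profile(ghost, "temperature", d)
        scores2 = pd.concat(
            [scores, pd.DataFrame({"RC1": [99.0]}, index=["ghost"])]
        )
        W2 = weighted_rc_profile(prof2, scores2)
        np.testing.assert_allclose(W1["RC1"].to_numpy(), W2["RC1"].to_numpy(),
                                   atol=1e-9)

    def test_missing_score_rejected(self, fits):
        fits, designs = fits
        prof = relative_abundance_profile(fits, "CN", designs["CN"])
        with pytest.raises(KeyError):
            weighted_rc_profile(prof, pd.DataFrame({"RC1": [1.0]}, index=["iso1"]))


class TestSmoother:
    def test_reproduces_line(self):
        x = np.linspace(0, 10, 40)
        ux, fit = smooth_profile(x, 2 * x - 3)
        assert np.abs(fit - (2 * ux - 3)).max() < 1e-6

    def test_constant_input(self):
        x = np.linspace(0, 1, 20)
        _, fit = smooth_profile(x, np.full(20, 4.2))
        np.testing.assert_allclose(fit, 4.2, atol=1e-8)

    def test_noisy_sine_beats_noise_floor(self):
        rng = np.random.default_rng(12)
        x = np.linspace(0, 2 * np.pi, 120)
        noise_sd = 0.3
        y = np.sin(x) + rng.normal(0, noise_sd, x.size)
        ux, fit, edof = smooth_profile(x, y, return_edof=True)
        rmse = np.sqrt(np.mean((fit - np.sin(ux)) ** 2))
        assert rmse < noise_sd
        assert 2 < edof < 60

    def test_duplicate_x_collapsed_by_averaging(self):
        x = np.repeat(np.linspace(0, 1, 10), 2)
        y = np.concatenate([[v - 0.1, v + 0.1] for v in np.linspace(0, 1, 10)])
        ux, fit = smooth_profile(x, y)
        assert ux.size == 10
        assert np.abs(fit - ux).max() < 1e-6  # averages lie on the line y=x

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.arange(5.0), np.arange(5.0))
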