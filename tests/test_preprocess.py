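"""Preprocessing: normality gate, aggregation, syndromes, imputation,
derived traits, UPGMA."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

import mycoecon as m
from mycoecon.preprocess import (
    aggregate_repeated,
    carbon_use_efficiency,
    complex_carbon_use,
    impute_missing,
    normalize_and_standardize,
    stoichiometric_flexibility,
    stress_log_response_ratio,
    syndrome_pc,
    upgma,
    upgma_newick,
    zscore,
)
from mycoecon.synthetic import brownian_trait


class TestNormalizeStandardize:
    def test_normal_column_not_logged(self, rng):
        table = pd.DataFrame({"t": rng.normal(10, 2, 28)})
        out, log = normalize_and_standardize(table)
        assert not log.log_transformed["t"]
        assert out["t"].mean() == pytest.approx(0, abs=1e-9)
        assert out["t"].std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_lognormal_column_logged_and_normalized(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            table = pd.DataFrame({"t": np.exp(r.normal(0, 1.5, 28))})
            out, log = normalize_and_standardize(table)
            if not log.log_transformed["t"]:
                continue  # draw happened to pass the normality gate raw
            if stats.shapiro(out["t"]).pvalue >= 0.05:
                hits += 1
        assert hits >= 80

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_and_standardize(pd.DataFrame({"t": np.ones(10)}))

    def test_zscore_idempotent(self, rng):
        col = pd.Series(rng.normal(size=30))
        z1 = zscore(col)
        np.testing.assert_allclose(zscore(z1), z1, atol=1e-12)

    def test_negative_values_get_shifted_log(self, rng):
        vals = np.exp(rng.normal(0, 2, 28)) - 5.0  # heavy-tailed incl. negatives
        out, log = normalize_and_standardize(pd.DataFrame({"t": vals}))
        if log.log_transformed["t"]:
            assert log.log_shift["t"] == pytest.approx(abs(vals.min()) + 1e-6)
        assert np.isfinite(out["t"]).all()


class TestAggregateRepeated:
    def _raw(self, wide):
        return wide.reset_index().melt(
            id_vars="index", var_name="variable", value_name="value"
        ).rename(columns={"index": "isolate"})

    def test_single_variable_equals_zscores(self, rng):
        wide = pd.DataFrame({"v1": rng.normal(5, 3, 12)})
        agg = aggregate_repeated(self._raw(wide), ["v1"], "trait")
        np.testing.assert_allclose(agg.to_numpy(), zscore(wide["v1"]).to_numpy())

    def test_duplicate_variables_equal_either(self, rng):
        v = rng.normal(size=12)
        wide = pd.DataFrame({"v1": v, "v2": 3.0 * v + 1.0})  # same z-scores
        agg = aggregate_repeated(self._raw(wide), ["v1", "v2"], "trait")
        np.testing.assert_allclose(agg.to_numpy(), zscore(pd.Series(v)).to_numpy(),
                                   atol=1e-12)

    def test_three_variables_brute_force(self, rng):
        wide = pd.DataFrame({f"v{i}": rng.normal(i, i + 1, 15) for i in range(3)})
        agg = aggregate_repeated(self._raw(wide), list(wide.columns), "trait")
        brute = np.column_stack([zscore(wide[c]) for c in wide]).mean(axis=1)
        np.testing.assert_allclose(agg.to_numpy(), brute, atol=1e-12)


class TestSyndromePC:
    def test_perfectly_correlated_pair(self, rng):
        v = rng.normal(size=20)
        sub = pd.DataFrame({"a": v, "b": 2 * v + 3})
        scores, pct = syndrome_pc(sub, axis=1, orient_with="a")
        assert pct == pytest.approx(100.0, abs=1e-9)
        assert abs(np.corrcoef(scores, v)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_orientation_invariant_to_global_sign_flip(self, rng):
        sub = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        s1, _ = syndrome_pc(sub, axis=1, orient_with="a")
        s2, _ = syndrome_pc(-sub, axis=1, orient_with="a")
        # oriented scores correlate positively with the orientation trait
        assert np.corrcoef(s1, sub["a"])[0, 1] > 0
        assert np.corrcoef(s2, -sub["a"])[0, 1] > 0

    def test_axis_out_of_range(self, rng):
        sub = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            syndrome_pc(sub, axis=3)


class TestImputation:
    def test_no_missing_unchanged(self, rng):
        t = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        out, log = impute_missing(t)
        pd.testing.assert_frame_equal(out, t)
        assert log.imputed_cells == []

    def test_global_mean_value_and_observed_untouched(self, rng):
        t = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        obs_mean = t["a"].drop(index=0).mean()
        t.loc[0, "a"] = np.nan
        out, log = impute_missing(t)
        assert out.loc[0, "a"] == pytest.approx(obs_mean)
        pd.testing.assert_series_equal(out["b"], t["b"])
        assert ("0", "a", "global_mean") in log.imputed_cells
        # column mean preserved
        assert out["a"].mean() == pytest.approx(obs_mean)

    def test_fully_missing_column_rejected(self):
        t = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            impute_missing(t)

    def test_phylo_neighbors_beat_global_mean_on_brownian_trait(self):
        wins = 0
        for seed in range(50):
            cfg = m.SyntheticConfig(n_isolates=28, seed=seed)
            D, _ = m.generate_phylogeny(cfg)
            trait = brownian_trait(D, seed=seed + 10_000)
            r = np.random.default_rng(seed)
            mask = r.random(28) < 0.2
            if not mask.any():
                continue
            t = pd.DataFrame({"x": trait})
            t.loc[mask, "x"] = np.nan
            gm, _ = impute_missing(t, mode="global_mean")
            ph, _ = impute_missing(t, distances=D, mode="phylo_neighbors", k=3)
            rmse_gm = np.sqrt(((gm.loc[mask, "x"] - trait[mask]) ** 2).mean())
            rmse_ph = np.sqrt(((ph.loc[mask, "x"] - trait[mask]) ** 2).mean())
            wins += rmse_ph < rmse_gm
        assert wins > 35  # phylogeny-aware imputation wins the paired comparison


class TestDerivedTraits:
    def test_cue_half_and_bounds(self, rng):
        assert carbon_use_efficiency(3.0, 3.0) == pytest.approx(0.5)
        cb, cr = rng.uniform(0.01, 10, 100), rng.uniform(0.01, 10, 100)
        cue = carbon_use_efficiency(cb, cr)
        assert ((cue >= 0) & (cue <= 1)).all()
        with pytest.raises(ValueError):
            carbon_use_efficiency(0.0, 0.0)

    def test_stoich_flex_closed_forms(self):
        resource = np.array([5.0, 10, 20, 40, 80, 160])
        assert stoichiometric_flexibility(resource, np.full(6, 8.0)) == pytest.approx(
            0.0, abs=1e-12
        )
        assert stoichiometric_flexibility(resource, 0.3 * resource) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_stoich_flex_recovery_simulation(self):
        resource = np.array([5.0, 10, 20, 40, 80, 160])
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            tissue = np.exp(0.5 * np.log(resource) + r.normal(0, 0.05, 6))
            if abs(stoichiometric_flexibility(resource, tissue) - 0.5) <= 0.1:
                hits += 1
        assert hits >= 190

    def test_complex_carbon_use_weights(self, rng):
        bio = pd.DataFrame(
            rng.normal(size=(10, 5)),
            columns=["glucose", "cellobiose", "xylan", "cellulose", "litter"],
        )
        out = complex_carbon_use(bio)
        z = bio.apply(zscore)
        w = np.array([1, 2, 3, 4, 5.0])
        brute = (z.to_numpy() * w).sum(axis=1) / 15.0
        np.testing.assert_allclose(out.to_numpy(), brute, atol=1e-12)

    def test_lrr_sign_and_validation(self):
        assert stress_log_response_ratio(1.0, 2.0) < 0  # growth reduced
        assert stress_log_response_ratio(4.0, 2.0) == pytest.approx(np.log(2))
        with pytest.raises(ValueError):
            stress_log_response_ratio(0.0, 1.0)


class TestUPGMA:
    def test_two_taxa(self):
        D = pd.DataFrame([[0, 4.0], [4.0, 0]], index=["A", "B"], columns=["A", "B"])
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(4.0)  # merge distance; leaf height 2
        assert upgma_newick(D) == "(A:2,B:2);"

    def test_three_taxa_hand_calculation(self):
        D = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        Z = upgma(D)
        assert Z[0, 2] == pytest.approx(2.0)  # A,B at height 1
        assert Z[1, 2] == pytest.approx(6.0)  # C joins at height 3
        assert upgma_newick(D) == "(C:3,(A:1,B:1):2);"

    def test_cophenetic_roundtrip_on_ultrametric_input(self):
        cfg = m.SyntheticConfig(n_isolates=8, seed=77)
        D, _ = m.generate_phylogeny(cfg)
        Z = upgma(D)
        coph = squareform(sch.cophenet(Z))
        np.testing.assert_allclose(coph, D.to_numpy(), atol=1e-9)

    def test_output_is_ultrametric(self, rng):
        # arbitrary (non-ultrametric) distances still give an ultrametric tree
        X = rng.normal(size=(9, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(9)]
        nwk = upgma_newick(pd.DataFrame(D, index=labels, columns=labels))
        dendropy = pytest.importorskip("dendropy")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_asymmetric_input_rejected(self):
        D = pd.DataFrame([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            upgma(D)
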