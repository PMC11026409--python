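"""End-to-end orchestration: simulate -> preprocess -> trait space ->
randomized alignment -> niche models -> associations, from one config.

A single master seed deterministically derives one sub-seed per stage, so
re-running an identical config reproduces identical numbers. Every output
file is registered in a manifest with a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, niche, pca, randpca, synthetic
from .designs import default_gradient_designs

__all__ = ["ResultsBundle", "stage_seed", "default_config", "run_pipeline"]


@dataclass
class ResultsBundle:
    outdir: Path
    summary: dict
    files: dict[str, Path] = field(default_factory=dict)

    def register(self, key: str, path: Path) -> None:
        self.files[key] = path

    def write_manifest(self) -> Path:
        manifest = {
            key: {
                "path": str(p.relative_to(self.outdir)),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for key, p in self.files.items()
        }
        mp = self.outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return mp


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2^31), collision-safe by hashing."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def default_config(seed: int = 0, outdir: str = "results/pipeline") -> dict:
    return {
        "seed": seed,
        "outdir": outdir,
        "simulate": {"n_isolates": 28, "noise_sd": 0.3, "missing_rate": 0.03},
        "trait_space": {"n_perm": 499, "alpha": 0.05},
        "randpca": {"n_repeats": 2000, "n_random_traits": 10,
                    "anchor_min_loading": 0.4},
        "niche": {"grid_n": 201},
        "associations": {"n_perm": 499, "alpha": 0.05, "vif_cap": 10.0},
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_pipeline(config: dict) -> ResultsBundle:
    """Run all stages of the analysis on synthetic (or supplied) data.

    Config keys: ``seed``, ``outdir``, ``simulate`` (generator parameters)
    or ``inputs`` (paths to traits/biomass CSVs), and per-stage parameter
    blocks. Stages run in dependency order; any stage error propagates with
    the stage name attached.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}
    bundle = ResultsBundle(outdir=outdir, summary=summary)
    designs = default_gradient_designs()

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # annotate which stage failed
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return deco

    # ---- simulate / load ------------------------------------------------
    @_stage("simulate")
    def data():
        if "inputs" in config:
            traits = pd.read_csv(config["inputs"]["traits"], index_col=0)
            biomass = pd.read_csv(config["inputs"]["biomass"])
            return None, traits, biomass
        sim = dict(config.get("simulate", {}))
        cfg = synthetic.SyntheticConfig(seed=stage_seed(seed, "simulate"), **sim)
        ds = synthetic.generate_dataset(cfg)
        paths = synthetic.write_dataset(ds, outdir / "synthetic")
        for key, p in paths.items():
            bundle.register(f"synthetic/{key}", p)
        return ds, ds.trait_table, ds.biomass_obs

    ds, trait_table, biomass_obs = data

    if config.get("simulate_only"):
        summary["stages"] = ["simulate"]
        sp = outdir / "summary.json"
        sp.write_text(json.dumps(summary, indent=1, default=_json_default, sort_keys=True))
        bundle.register("summary", sp)
        bundle.write_manifest()
        return bundle

    # ---- preprocess -----------------------------------------------------
    @_stage("preprocess")
    def prepped():
        from .preprocess import impute_missing, normalize_and_standardize

        table, tlog = normalize_and_standardize(trait_table)
        table, ilog = impute_missing(table, mode="global_mean")
        # re-standardize after imputation so the PCA contract holds exactly
        table = (table - table.mean()) / table.std(ddof=1)
        p = outdir / "traits_preprocessed.csv"
        table.to_csv(p, index_label="isolate")
        bundle.register("traits_preprocessed", p)
        lp = outdir / "transform_log.json"
        lp.write_text(json.dumps(
            {**tlog.to_dict(), "imputed_cells": ilog.to_dict()["imputed_cells"]},
            indent=1,
        ))
        bundle.register("transform_log", lp)
        return table

    # ---- trait space ----------------------------------------------------
    @_stage("trait_space")
    def space():
        ts = config.get("trait_space", {})
        res = pca.run_pca(prepped)
        sig = pca.permutation_significance(
            prepped,
            n_perm=int(ts.get("n_perm", 499)),
            alpha=float(ts.get("alpha", 0.05)),
            seed=stage_seed(seed, "trait_space"),
        )
        k = max(sig.n_significant, 1)
        rot = pca.varimax(res, k=k)
        _, groups = pca.cluster_loadings(rot.rc_loadings, k=k)
        for name, df in [("loadings", res.loadings), ("scores", res.scores),
                         ("rc_loadings", rot.rc_loadings),
                         ("rc_scores", rot.rc_scores)]:
            p = outdir / f"{name}.csv"
            df.to_csv(p)
            bundle.register(name, p)
        summary["trait_space"] = {
            "n_significant_axes": sig.n_significant,
            "pct_variance": res.pct_variance[: max(k, 3)].tolist(),
            "axis_p_values": sig.p_values[: max(k, 3)].tolist(),
            "rc_pct_variance": rot.rc_pct_variance.tolist(),
            "loading_clusters": groups.to_dict(),
        }
        return res, sig, rot

    res, sig, rot = space

    # ---- randomized anchored PCA ---------------------------------------
    @_stage("randpca")
    def alignment():
        rp = dict(config.get("randpca", {}))
        # anchor on the two strongest-|loading| traits of RC1 with opposite
        # signs (synthetic tables have no literal 'extension'/'density')
        if "anchors" not in rp:
            l1 = rot.rc_loadings.iloc[:, 0]
            rp["anchors"] = (l1.idxmax(), l1.idxmin())
        cfg = randpca.RandomizedPCAConfig(
            seed=stage_seed(seed, "randpca"), **rp
        )
        result = randpca.anchored_random_pca(prepped, cfg)
        p = outdir / "alignment.csv"
        randpca.alignment_report(result, path=p)
        bundle.register("alignment", p)
        summary["randpca"] = {
            "anchors": list(cfg.anchors),
            "n_runs_retained": result.n_runs_retained,
            "exclusion_fraction": result.exclusion_fraction,
        }
        return result

    _ = alignment

    # ---- niche models ---------------------------------------------------
    @_stage("niche")
    def niches():
        fits = niche.fit_all(biomass_obs, designs)
        summ = niche.summarize_niches(fits, designs)
        cube = niche.niche_cube(summ)
        p = outdir / "niche_summary.csv"
        summ.to_csv(p, index=False)
        bundle.register("niche_summary", p)
        pc = outdir / "niche_cube.csv"
        cube.to_csv(pc)
        bundle.register("niche_cube", pc)
        grid_n = int(config.get("niche", {}).get("grid_n", 201))
        profiles = {}
        for gname, design in designs.items():
            pr = (niche.water_profile_range(design)
                  if gname == "water_potential" else None)
            prof = niche.relative_abundance_profile(
                fits, gname, design, grid_n=grid_n, profile_range=pr
            )
            W = niche.weighted_rc_profile(prof, rot.rc_scores)
            pw = outdir / f"weighted_rc_{gname}.csv"
            W.to_csv(pw, index_label="level")
            bundle.register(f"weighted_rc_{gname}", pw)
            profiles[gname] = (prof, W)
        n_conv = sum(f.converged for f in fits.values())
        summary["niche"] = {
            "n_fits": len(fits),
            "n_converged": n_conv,
            "mean_niche_cube": float(cube.mean()),
        }
        return fits, summ, cube, profiles

    fits, summ, cube, profiles = niches

    # ---- associations ---------------------------------------------------
    @_stage("associations")
    def assoc():
        ac = config.get("associations", {})
        optima = summ.pivot(index="isolate", columns="gradient", values="optimum")
        optima = optima.dropna()
        scores = rot.rc_scores.loc[optima.index]
        perm_rows = []
        for axis in scores.columns:
            pr = associations.permanova(
                optima, scores[axis],
                n_perm=int(ac.get("n_perm", 499)),
                seed=stage_seed(seed, f"permanova_{axis}"),
            )
            perm_rows.append({
                "axis": axis, "pseudo_F": pr.pseudo_F, "R2": pr.r_squared,
                "p": pr.p_value,
            })
        perm_df = pd.DataFrame(perm_rows)
        p = outdir / "permanova.csv"
        perm_df.to_csv(p, index=False)
        bundle.register("permanova", p)
        sel = associations.rda_forward_selection(
            optima, prepped.loc[optima.index],
            alpha=float(ac.get("alpha", 0.05)),
            vif_cap=float(ac.get("vif_cap", 10.0)),
            n_perm=int(ac.get("n_perm", 499)),
            seed=stage_seed(seed, "rda"),
        )
        ps = outdir / "rda_selection.csv"
        sel.path.to_csv(ps, index=False)
        bundle.register("rda_selection", ps)
        summary["associations"] = {
            "permanova": perm_rows,
            "rda_selected": sel.selected,
        }
        return perm_df, sel

    _ = assoc

    summary["stages"] = ["simulate", "preprocess", "trait_space", "randpca",
                         "niche", "associations"]
    sp = outdir / "summary.json"
    sp.write_text(json.dumps(summary, indent=1, default=_json_default, sort_keys=True))
    bundle.register("summary", sp)
    bundle.write_manifest()
    return bundle
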