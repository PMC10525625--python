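"""End-to-end pipeline: simulate -> fit -> screen -> diagnose -> pta ->
optimize, with config handling and a reproducibility manifest.

All randomness flows from one master seed through ``numpy``
SeedSequence spawning; each stage's derived seed is logged in the manifest.
Stage outputs are written as they complete, so a failure preserves earlier
results. The PTA and dose-optimization stages use the configured
population parameters (the final published model) rather than the fit from
the small simulated cohort; set ``pta.use_fitted`` to override.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as covmod
from . import diagnostics as diag
from . import estimation as est
from . import io as dio
from . import pta as ptamod
from .cohort import CohortSpec, SamplingDesign, generate_covariates, \
    generate_tdm_dataset
from .pk import DosingRegimen
from .population import PopulationParameters

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("posapk")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "cohort": {"n_subjects": 32},
    "design": {},
    "regimen": {"dose": 300.0, "tau": 24.0},
    "population": {},          # overrides on the final-model defaults
    "estimation": {"n_explore": 300, "n_smooth": 150},
    "screening": {"candidates": ["age", "sex", "height", "weight", "bmi",
                                 "bsa", "creatinine", "egfr", "alt", "ast",
                                 "ggt", "cystic_fibrosis", "indication",
                                 "comed_calcineurin", "comed_mmf",
                                 "comed_acid_suppressant"]},
    "diagnostics": {"K": 1000, "n_bins": 6},
    "pta": {"n_replicates": 500, "trough_scale": "observation",
            "use_fitted": False},
    "optimize": {"min_pta": 0.90,
                 "candidate_doses": [100.0, 200.0, 300.0, 400.0],
                 "trough_scale": "observation"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML/JSON file."""
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    return _merge(DEFAULT_CONFIG, user)


def _estimates_table(res: est.EstimationResult) -> pd.DataFrame:
    """Machine-readable estimate report (parameter / estimate / RSE %)."""
    rows = [("ka_pop (1/h)", res.pop.ka_pop, res.rse.get("ka_pop")),
            ("v_pop (L)", res.pop.v_pop, res.rse.get("v_pop")),
            ("cl_pop (L/h)", res.pop.cl_pop, res.rse.get("cl_pop"))]
    for d, cdict in res.coefs.items():
        for nm, val in cdict.items():
            if nm != "intercept":
                rows.append((f"beta_{d}_{nm}", val,
                             res.rse.get(f"beta_{d}_{nm}")))
    for d in ("ka", "v", "cl"):
        rows.append((f"omega_{d}", res.omegas[d], res.rse.get(f"omega_{d}")))
    rows.append(("b_prop", res.b_prop, res.rse.get("b_prop")))
    return pd.DataFrame(rows, columns=["parameter", "estimate", "rse_pct"])


def run_pipeline(config: dict | None = None, outdir="results/pipeline",
                 stages: tuple = ("simulate", "fit", "screen", "diagnose",
                                  "pta", "optimize")) -> dict:
    """Run the pipeline stages and return the manifest dictionary.

    The manifest records the config, each stage's derived seed and output
    files; identical config + seed give identical manifests.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ("simulate", "fit", "screen", "diagnose", "pta",
                        "optimize"), ss.spawn(6))}
    manifest = {"config": cfg, "seeds": stage_seeds, "outputs": {}}
    pop_cfg = PopulationParameters.from_dict(cfg["population"])

    dataset = None
    fit_res = None
    final_res = None
    final_model: dict = {}

    if "simulate" in stages:
        log.info("stage simulate: cohort + TDM dataset")
        rng = np.random.default_rng(stage_seeds["simulate"])
        cohort = generate_covariates(CohortSpec(**cfg["cohort"]), rng)
        design = SamplingDesign(**cfg["design"])
        regimen = DosingRegimen(**cfg["regimen"])
        dataset = generate_tdm_dataset(cohort, design, pop_cfg, regimen, rng)
        path = outdir / "dataset.csv"
        dio.write_dataset(dataset, path)
        manifest["outputs"]["simulate"] = str(path)

    if "fit" in stages:
        log.info("stage fit: base model SAEM")
        if dataset is None:
            dataset = dio.read_dataset(outdir / "dataset.csv")
        settings = est.EstimationSettings(
            **{**cfg["estimation"], "seed": stage_seeds["fit"]})
        fit_res = est.fit(dataset, covariate_model=None, init=pop_cfg,
                          settings=settings)
        tab = _estimates_table(fit_res)
        path = outdir / "estimates_base.csv"
        tab.to_csv(path, index=False)
        manifest["outputs"]["fit"] = str(path)
        manifest["ofv_base"] = fit_res.ofv

    if "screen" in stages:
        log.info("stage screen: covariate screening + stepwise build")
        if fit_res is None:
            raise RuntimeError("screen stage requires the fit stage")
        cand = cfg["screening"]["candidates"]
        high_shrink = any(s > covmod.SHRINKAGE_GUIDELINE
                          for s in fit_res.shrinkage.values()
                          if np.isfinite(s))
        if high_shrink:
            _, cond = est.estimate_ebes(
                dataset, fit_res.pop, coefs=fit_res.coefs,
                n_cond_samples=50, seed=stage_seeds["screen"])
            screen = covmod.screen_covariates_conditional(
                cond, fit_res.ebes.index, dataset.covariates, cand,
                rng=np.random.default_rng(stage_seeds["screen"]))
        else:
            screen = covmod.screen_covariates(fit_res.ebes,
                                              dataset.covariates, cand)
        (outdir / "screening.txt").write_text(screen.to_text() + "\n")
        screen.pvalues.to_csv(outdir / "screening.csv")
        settings = est.EstimationSettings(
            **{**cfg["estimation"], "seed": stage_seeds["screen"]})
        final_res, trace = covmod.stepwise_build(
            dataset, None, pop_cfg, screen, settings=settings)
        final_model = final_res.covariate_model
        trace.steps.to_csv(outdir / "stepwise.csv", index=False)
        _estimates_table(final_res).to_csv(outdir / "estimates_final.csv",
                                           index=False)
        manifest["outputs"]["screen"] = str(outdir / "screening.csv")
        manifest["final_covariate_model"] = {
            k: list(v) for k, v in final_model.items()}

    if "diagnose" in stages:
        log.info("stage diagnose: GOF + NPDE + VPC")
        res = final_res or fit_res
        if res is None or dataset is None:
            raise RuntimeError("diagnose stage requires a fitted model")
        K = cfg["diagnostics"]["K"]
        gof = diag.gof_table(dataset, res.pop, res.ebes,
                             covariate_model=res.covariate_model, K=K,
                             seed=stage_seeds["diagnose"])
        gof.df.to_csv(outdir / "gof.csv", index=False)
        v = diag.vpc(dataset, res.pop, covariate_model=res.covariate_model,
                     K=K, n_bins=cfg["diagnostics"]["n_bins"],
                     seed=stage_seeds["diagnose"])
        v.df.to_csv(outdir / "vpc.csv", index=False)
        npde = gof.df["npde"].to_numpy()
        manifest["outputs"]["diagnose"] = str(outdir / "gof.csv")
        manifest["npde_summary"] = {"mean": float(np.mean(npde)),
                                    "var": float(np.var(npde, ddof=1))}

    if "pta" in stages or "optimize" in stages:
        pop_sim = (final_res or fit_res).pop if cfg["pta"]["use_fitted"] \
            and (final_res or fit_res) else pop_cfg
        rng = np.random.default_rng(stage_seeds["pta"])
        cohort_cov = dataset.covariates if dataset is not None else \
            generate_covariates(CohortSpec(**cfg["cohort"]), rng)

    if "pta" in stages:
        log.info("stage pta: uniform vs proposed regimen")
        nrep = cfg["pta"]["n_replicates"]
        scale = cfg["pta"]["trough_scale"]
        rows = []
        results = {}
        for name, rmap in (("uniform-300", ptamod.RegimenMap.uniform(300.0)),
                           ("proposed", ptamod.RegimenMap())):
            for ind in ptamod.INDICATIONS:
                sim = ptamod.simulate_population(pop_sim, cohort_cov, nrep,
                                                 rmap, ind, rng)
                target = ptamod.TARGET_BY_INDICATION[ind]
                res_t = ptamod.compute_pta(sim, target, trough_scale=scale)
                res_a = ptamod.compute_pta(sim, ptamod.AUC_TARGET)
                results[(name, ind)] = res_t
                for strat in ("under-60", "over-60", "overall"):
                    rows.append({
                        "regimen": name, "indication": ind,
                        "stratum": strat,
                        "pta_trough": res_t.counts.loc[strat, "pta"],
                        "pta_auc": res_a.counts.loc[strat, "pta"],
                        "auc_median": res_a.auc_summary.loc[strat, "median"],
                    })
        pta_df = pd.DataFrame(rows)
        pta_df.to_csv(outdir / "pta.csv", index=False)
        comp = {ind: ptamod.compare_regimens(results[("uniform-300", ind)],
                                             results[("proposed", ind)])
                for ind in ptamod.INDICATIONS}
        manifest["outputs"]["pta"] = str(outdir / "pta.csv")
        manifest["pta_fisher_p"] = comp

    if "optimize" in stages:
        log.info("stage optimize: stratified dose search")
        opt = ptamod.optimize_regimen(
            pop_sim, cohort_cov, np.random.default_rng(stage_seeds["optimize"]),
            candidate_doses=tuple(cfg["optimize"]["candidate_doses"]),
            min_pta=cfg["optimize"]["min_pta"],
            n_replicates=cfg["pta"]["n_replicates"],
            trough_scale=cfg["optimize"]["trough_scale"])
        opt.pta_table.to_csv(outdir / "dose_pta.csv", index=False)
        regimen_json = {f"{ind}/{s}": opt.regimen.doses[(ind, s)]
                        for ind, s in opt.regimen.doses}
        (outdir / "regimen.json").write_text(json.dumps(
            {"regimen": regimen_json,
             "unattainable": {f"{i}/{s}": v for (i, s), v in
                              opt.unattainable.items()}}, indent=2))
        manifest["outputs"]["optimize"] = str(outdir / "regimen.json")
        manifest["regimen"] = regimen_json

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
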