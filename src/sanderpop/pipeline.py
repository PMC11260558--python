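"""End-to-end orchestration: filter -> sex scan -> ancestry -> population
statistics -> demography, driven by a single config mapping, with a run
manifest recording parameters and seeds.

Outputs are pure functions of (inputs, config, seeds): rerunning with the
same config produces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, demography, popstats, sexscan, simdata, vcfio

logger = logging.getLogger(__name__)

STAGES = ("filter", "sexscan", "ancestry", "popstats", "demography")

DEFAULT_CONFIG = dict(
    preset="hybrid",
    seed=1,
    stages=list(STAGES[:4]),
    sex_quantile=0.99,
    randomization_B=50,
    fst_B=200,
    max_indiv_missing=vcfio.DEFAULT_INDIV_MISSING,
    pseudocount=0.5,
    total_sites=None,          # diversity denominator; defaults to n_loci
    demography=dict(
        n_restarts=3, grid_diploids=30, maxiter=80,
        N_ref=300, nu1=0.5, nu2=0.5, T_gens=60, n1=16, n2=16,
        mu=1e-8, sequence_length=5e5,
    ),
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _validate(config: dict) -> None:
    for key in ("vcf", "samples"):
        if key in config and not Path(config[key]).exists():
            raise PipelineError("config", "missing-input", f"{key} file not found: {config[key]}")
    for key in ("vcf", "samples", "outdir"):
        if key not in config:
            raise PipelineError("config", "missing-key", f"config key {key!r} required")
    unknown = set(config.get("stages", [])) - set(STAGES)
    if unknown:
        raise PipelineError("config", "bad-stage", f"unknown stages: {sorted(unknown)}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages; returns the manifest dict.

    Raises :class:`PipelineError` naming the failing stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _validate(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    manifest: dict = dict(
        package="sanderpop",
        version=__version__,
        seed=seed,
        config={k: v for k, v in config.items() if k != "outdir"},
        stages_run=[],
        outputs={},
    )
    stages = config.get("stages", list(STAGES[:4]))

    def _stage(name):
        def deco(fn):
            if name in stages:
                try:
                    fn()
                    manifest["stages_run"].append(name)
                except PipelineError:
                    raise
                except Exception as exc:
                    raise PipelineError(name, "stage-failed", str(exc)) from exc
            return fn
        return deco

    gm = vcfio.read_vcf(config["vcf"])
    meta = vcfio.read_sample_table(config["samples"])
    meta = meta.set_index("sample_id").loc[gm.samples].reset_index()
    state: dict = dict(gm=gm, meta=meta)

    @_stage("filter")
    def _filter():
        preset = config.get("preset", "hybrid")
        g, report = vcfio.filter_loci(
            state["gm"],
            maf_min=vcfio.PRESETS[preset]["maf_min"],
            max_locus_missing=vcfio.PRESETS[preset]["max_locus_missing"],
            return_report=True,
        )
        g = vcfio.filter_individuals(g, config.get("max_indiv_missing", 0.8))
        state["gm"] = g
        state["meta"] = meta.set_index("sample_id").loc[g.samples].reset_index()
        path = outdir / "filter_report.tsv"
        report.to_frame().to_csv(path, sep="\t", index=False)
        manifest["outputs"]["filter_report"] = path.name

    @_stage("sexscan")
    def _sexscan():
        g, m = state["gm"], state["meta"]
        known = m["sex"].isin(["M", "F"]).to_numpy()
        if known.sum() < 4:
            logger.info("sexscan: too few sexed individuals, skipping")
            return
        sub = g.take_samples(known)
        res = sexscan.dapc(sub, m.loc[known, "sex"].to_numpy())
        flagged = sexscan.flag_sex_loci(res, config.get("sex_quantile", 0.99))
        thr = sexscan.randomization_threshold(
            sub, m.loc[known, "sex"].to_numpy(),
            B=max(20, int(config.get("randomization_B", 50))), seed=seed + 11,
        )
        table = sexscan.sex_scan_table(sub, res, flagged)
        path = outdir / "sex_loci.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["sex_loci"] = path.name
        manifest["sexscan_randomization_threshold"] = thr
        keep = np.ones(g.n_loci, dtype=bool)
        keep[flagged] = False
        state["gm"] = g.take_loci(keep)
        state["sex_loci"] = table

    @_stage("ancestry")
    def _ancestry():
        g, m = state["gm"], state["meta"]
        freqs = ancestry.estimate_parental_freqs(
            g, m["panel"].to_numpy(), pseudocount=config.get("pseudocount", 0.5)
        )
        query = (m["panel"] == "query").to_numpy()
        est = ancestry.estimate_qQ(g.take_samples(query), freqs)
        table = ancestry.ancestry_table(est)
        path = outdir / "ancestry_classes.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest["outputs"]["ancestry_classes"] = path.name
        state["ancestry"] = table

    @_stage("popstats")
    def _popstats():
        g, m = state["gm"], state["meta"]
        pops = m["panel"].to_numpy()
        fst = popstats.fst_bootstrap(
            g, pops, "refA", "refB", B=max(100, int(config.get("fst_B", 200))),
            seed=seed + 23,
        )
        total_sites = config.get("total_sites") or g.n_loci
        div = popstats.diversity_metrics(g, total_sites=int(total_sites))
        scores, varfrac = popstats.pca_genotypes(g)
        report = pd.DataFrame(
            [
                dict(
                    fst_refA_refB=fst.estimate,
                    fst_ci_low=fst.ci_low,
                    fst_ci_high=fst.ci_high,
                    fst_significant=fst.significant_nonzero,
                    theta_w=div.theta_w,
                    pi=div.pi,
                    het_obs=div.het_obs,
                    het_exp=div.het_exp,
                    pc1_varfrac=varfrac[0],
                    pc2_varfrac=varfrac[1] if len(varfrac) > 1 else np.nan,
                )
            ]
        )
        path = outdir / "popstats_report.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["popstats_report"] = path.name

    @_stage("demography")
    def _demography():
        d = config.get("demography", {})
        params = simdata.SplitParams(
            N_ref=int(d.get("N_ref", 300)),
            nu1=float(d.get("nu1", 0.5)),
            nu2=float(d.get("nu2", 0.5)),
            T_gens=float(d.get("T_gens", 60)),
            mu=float(d.get("mu", 1e-8)),
            n1=int(d.get("n1", 16)),
            n2=int(d.get("n2", 16)),
            sequence_length=float(d.get("sequence_length", 5e5)),
        )
        _, sfs, truth = simdata.simulate_split(params, seed=seed + 31)
        fit = demography.fit_model(
            sfs,
            "split_nomig",
            n_restarts=int(d.get("n_restarts", 3)),
            seed=seed + 37,
            grid_diploids=int(d.get("grid_diploids", 30)),
            maxiter=int(d.get("maxiter", 80)),
        )
        scaling = demography.scale_to_real(
            fit, mu=params.mu, L=params.sequence_length
        )["mu"]
        path = outdir / "demography_fit.json"
        with open(path, "w") as fh:
            json.dump(
                dict(
                    model=fit.model,
                    params=fit.params,
                    theta=fit.theta,
                    loglik=fit.loglik,
                    truth=truth,
                    T_generations=scaling.T_generations,
                    T_years=scaling.T_years,
                ),
                fh,
                indent=2,
                sort_keys=True,
            )
        manifest["outputs"]["demography_fit"] = path.name

    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def run_demo(outdir: str | Path, seed: int = 1, n_loci: int = 1200) -> dict:
    """One-command synthetic demo: simulate a study, write its files, run
    the full pipeline (including a scaled-down demography fit)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = simdata.SimConfig(n_loci=n_loci, seed=seed)
    study = simdata.simulate_study(cfg)
    vcf_path = outdir / "demo.vcf"
    tsv_path = outdir / "demo_samples.tsv"
    vcfio.write_vcf(study["genotypes"], vcf_path)
    vcfio.write_sample_table(study["metadata"], tsv_path)
    study["truth"].to_csv(outdir / "demo_truth.tsv", sep="\t", index=False)
    config = dict(
        DEFAULT_CONFIG,
        vcf=str(vcf_path),
        samples=str(tsv_path),
        outdir=str(outdir),
        seed=seed,
        stages=list(STAGES),
    )
    return run_pipeline(config)
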