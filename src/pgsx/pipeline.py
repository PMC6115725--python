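"""End-to-end orchestration from a single YAML config.

Stages: (optional) simulate -> GWAS (full + BMI-stratified) -> PGS ladder
(binning, proxy removal, pruning, scoring, residualization cascade) ->
decile-effect profiles (raw and inverse-normal BMI) -> allele expressivity.
Every stochastic stage draws its seed deterministically from the global
seed, so a config reruns to byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, synthetic_data, association, pgs_builder
from . import decile_effects, expressivity

logger = logging.getLogger(__name__)

REQUIRED_TOP_KEYS = ("outdir", "seed")


class ConfigError(ValueError):
    """Raised when the pipeline config fails validation."""


def validate_config(config: dict) -> dict:
    for key in REQUIRED_TOP_KEYS:
        if key not in config:
            raise ConfigError(f"config is missing required key {key!r}")
    if "simulate" not in config and "bed_prefix" not in config:
        raise ConfigError("config needs either a 'simulate' block or 'bed_prefix'")
    return config


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = np.random.SeedSequence(
        [global_seed, sum(ord(c) for c in stage)]
    ).generate_state(1)[0]
    return int(h % (2**31))


@dataclasses.dataclass
class ReportBundle:
    outdir: Path
    gwas: pd.DataFrame
    stratified: dict[str, pd.DataFrame]
    scores: pd.DataFrame
    profiles: dict[str, decile_effects.DecileEffectProfile]
    trends: pd.DataFrame
    expressivity_result: expressivity.ExpressivityResult | None
    replication: pd.DataFrame | None


def run_all(config: dict) -> ReportBundle:
    """Execute the full analysis described by ``config``; see module docs."""
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    # ---- stage: cohort -----------------------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            sim_cfg.setdefault("seed", stage_seed(seed, "simulate"))
            params = synthetic_data.SimulationParams(**sim_cfg)
            G, pheno, truth = synthetic_data.simulate_cohort(params)
            io_formats.write_plink(G, str(outdir / "cohort"))
            io_formats.write_phenotypes(pheno, outdir / "phenotypes.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            logger.info("simulate: n=%d m=%d", G.n_samples, G.n_snps)
        else:
            G = io_formats.read_plink(config["bed_prefix"])
            pheno = io_formats.read_phenotypes(config["pheno"])
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    # ---- stage: gwas -------------------------------------------------------
    try:
        covars = config.get("covars", association.DEFAULT_COVARIATES)
        maf_min = config.get("maf_min", 0.01)
        own_stats = association.run_gwas(G, pheno, covars, maf_min=maf_min)
        io_formats.write_summary_stats(own_stats, outdir / "gwas_full.tsv")
        stratified = association.stratified_gwas(G, pheno, covars, maf_min=maf_min)
        for label, tab in stratified.items():
            io_formats.write_summary_stats(tab, outdir / f"gwas_{label}.tsv")
        logger.info("gwas: %d SNPs, %d strata", len(own_stats), len(stratified))
    except Exception as exc:
        raise RuntimeError(f"stage 'gwas' failed: {exc}") from exc

    # ---- stage: pgs ladder -------------------------------------------------
    try:
        if "sumstats" in config:
            external = io_formats.read_summary_stats(
                config["sumstats"], config.get("sumstats_columns", {})
            )
        else:
            external = own_stats
        anchor_p = config.get("anchor_p", 1e-5)
        proxy_r2 = config.get("proxy_r2", 0.2)
        prune_cfg = config.get("prune", {})
        window = prune_cfg.get("window", 10_000)
        step = prune_cfg.get("step", 5)
        r2_max = prune_cfg.get("r2_max", 0.5)
        weighted = bool(config.get("weighted", False))

        prio = dict(zip(external["id"], -np.log10(external["p"])))
        anchors = external.loc[external["p"] < anchor_p, "id"].tolist()
        anchors = pgs_builder.ld_prune(G, anchors, window, step, r2_max, prio)

        defs = []
        if anchors:
            defs.append(pgs_builder.make_definition(
                "anchor", external, anchors, weighted=weighted))
        bins = pgs_builder.partition_by_pvalue(external)
        candidates_all = [s for ids in bins.values() for s in ids]
        cleaned = set(pgs_builder.remove_proxies(candidates_all, anchors, G, proxy_r2))
        for label, _, _ in pgs_builder.DEFAULT_BINS:
            ids = [s for s in bins[label] if s in cleaned]
            ids = pgs_builder.ld_prune(G, ids, window, step, r2_max, prio)
            if ids:
                defs.append(pgs_builder.make_definition(
                    label, external, ids, weighted=weighted))

        if not defs:
            raise ValueError("no PGS definitions could be built")
        score_cols = {}
        for d in defs:
            io_formats.write_score_file(d, outdir / f"score_{d.name}.tsv")
            score_cols[d.name] = pgs_builder.compute_score(G, d)["score"].to_numpy()
        raw = pd.DataFrame(score_cols, index=G.samples)
        resid = pgs_builder.residualize_cascade(raw)
        scores = pd.concat(
            [raw.add_suffix("_raw"), resid.add_suffix("_resid")], axis=1
        )
        scores.insert(0, "sample_id", G.samples)
        scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        logger.info("pgs: %d levels (%s)", len(defs), ", ".join(score_cols))
    except Exception as exc:
        raise RuntimeError(f"stage 'pgs' failed: {exc}") from exc

    # ---- stage: decile effects --------------------------------------------
    try:
        method = config.get("decile_method", "quantile")
        # asymptotic (sparsity-based) SEs by default; case bootstrap opt-in
        bootstrap = int(config.get("bootstrap", 0))
        profiles: dict[str, decile_effects.DecileEffectProfile] = {}
        trend_rows = []
        for name in resid.columns:
            sv = pd.DataFrame({"sample_id": G.samples, "score": resid[name]})
            for transform in ("raw", "int"):
                key = f"{name}_{transform}"
                if method == "quantile":
                    prof = decile_effects.profile_by_quantile(
                        pheno, sv, covars, transform=transform,
                        bootstrap=bootstrap,
                        seed=stage_seed(seed, "decile" + key), score_name=key)
                else:
                    prof = decile_effects.profile_by_stratified_ols(
                        pheno, sv, covars, transform=transform, score_name=key)
                profiles[key] = prof
                tr = decile_effects.trend_statistics(prof)
                trend_rows.append({
                    "score": name, "transform": transform, "method": prof.method,
                    "slope": tr.slope, "slope_se": tr.slope_se,
                    "slope_p": tr.slope_p, "ratio_top_bottom": tr.ratio_top_bottom,
                })
        trends = pd.DataFrame(trend_rows)
        prof_tab = pd.concat(
            [p.table.assign(score=k) for k, p in profiles.items()]
        )
        prof_tab.to_csv(outdir / "decile_profiles.tsv", sep="\t", index=False)
        trends.to_csv(outdir / "trend_stats.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'decile-effects' failed: {exc}") from exc

    # ---- stage: expressivity ----------------------------------------------
    expr_result = None
    try:
        panel = anchors if len(anchors) >= 5 else external.nsmallest(
            min(50, len(external)), "p")["id"].tolist()
        if len(panel) >= 5:
            expr_result = expressivity.cohort_expressivity(
                G, panel, pheno,
                maf_min=config.get("expressivity_maf", 0.05),
                background=config.get("background", "include"),
            )
            expr_result.per_snp.to_csv(
                outdir / "expressivity_per_snp.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'expressivity' failed: {exc}") from exc

    # ---- stage: replication + report --------------------------------------
    replication = None
    try:
        if "sumstats" in config and anchors:
            replication = association.replication_summary(own_stats, anchors)
            replication.to_csv(outdir / "replication.tsv", sep="\t", index=False)
        report = {
            "n_samples": G.n_samples,
            "n_snps": G.n_snps,
            "n_gwas_snps": int(len(own_stats)),
            "strata_n": {k: int(v["n"].iloc[0]) for k, v in stratified.items()},
            "pgs_levels": {d.name: d.n_snps for d in defs},
            "trends": trend_rows,
        }
        if expr_result is not None:
            report["expressivity"] = {
                "n": expr_result.n, "k": expr_result.k,
                "fraction_positive": expr_result.fraction_positive,
                "p_binomial": expr_result.p_binomial,
            }
        if replication is not None:
            report["replication"] = replication.to_dict(orient="records")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:
        raise RuntimeError(f"stage 'report' failed: {exc}") from exc

    return ReportBundle(outdir, own_stats, stratified, scores, profiles,
                        trends, expr_result, replication)
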