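"""Config-driven orchestration of the full analysis.

A run executes, in order: (optional) simulation -> probe classification ->
twin correlations and sign tests -> genome-wide ACE (plus a residualized
pass when covariates are configured) -> stratum comparisons and profiles ->
enrichment against external scores -> (optional) EWAS and the DMP
heritability report.  Every stage writes deterministic TSV output under a
fixed directory layout (tables/, profiles/, logs/) and echoes the resolved
config, so reruns with one seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ace, ewas, io, probes, similarity, strata
from .io import ValidationError
from .simulate import (ExposureSpec, MqtlSpec, SimulationConfig,
                       simulate_twin_cohort, synthetic_annotation)

__all__ = ["PipelineConfig", "load_config", "run_full_pipeline", "demo_config"]

log = logging.getLogger(__name__)


@dataclass
class Thresholds:
    variable: float = 0.05
    intermediate_low: float = 0.20
    intermediate_high: float = 0.80
    a_high: float = 0.8
    covariation_cutoff: float = 0.5
    dmp: float = 1e-7

    def __post_init__(self) -> None:
        for v in (self.variable, self.intermediate_low, self.intermediate_high,
                  self.a_high, self.covariation_cutoff):
            if not 0.0 < v < 1.0:
                raise ValidationError(f"threshold {v!r} outside (0, 1)")
        if not 0.0 < self.dmp < 1.0:
            raise ValidationError("dmp threshold outside (0, 1)")


@dataclass
class PipelineConfig:
    output_dir: str = "twinmeth_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    ace_method: str = "fiml"
    residualize: list[str] = field(default_factory=list)
    ewas_exposure: str | None = None
    ewas_adjustments: list[str] = field(default_factory=list)
    profile_window_bp: int = 500
    profile_step_bp: int = 100
    profile_min_n: int = 50

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError(
                "config must provide exactly one of 'simulation' or 'inputs'")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    sim = None
    if "simulation" in raw and raw["simulation"] is not None:
        s = dict(raw["simulation"])
        mqtl = MqtlSpec(**s.pop("mqtl")) if s.get("mqtl") else s.pop("mqtl", None)
        expo = ExposureSpec(**s.pop("exposure")) if s.get("exposure") else s.pop("exposure", None)
        seed = int(raw.get("seed", 0))
        n_sites = int(s.get("n_sites", 200))
        # [lo, hi] entries mean a per-site uniform draw on that range
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(71,)))
        for key in ("mu_beta", "total_sd"):
            if isinstance(s.get(key), (list, tuple)):
                lo, hi = s[key]
                s[key] = rng.uniform(float(lo), float(hi), n_sites)
        sim = SimulationConfig(mqtl=mqtl, exposure=expo, seed=seed, **s)
    thr = Thresholds(**raw.get("thresholds", {}))
    ace_cfg = raw.get("ace", {})
    ewas_cfg = raw.get("ewas", {})
    prof = raw.get("profile", {})
    return PipelineConfig(
        output_dir=raw.get("output_dir", "twinmeth_out"),
        seed=int(raw.get("seed", 0)),
        simulation=sim,
        inputs=raw.get("inputs"),
        thresholds=thr,
        ace_method=ace_cfg.get("method", "fiml"),
        residualize=list(ace_cfg.get("residualize", [])),
        ewas_exposure=ewas_cfg.get("exposure"),
        ewas_adjustments=list(ewas_cfg.get("adjustments", [])),
        profile_window_bp=int(prof.get("window_bp", 500)),
        profile_step_bp=int(prof.get("step_bp", 100)),
        profile_min_n=int(prof.get("min_n", 50)),
    )


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    betas = io.read_beta_matrix(paths["betas"])
    manifest = io.read_pair_manifest(paths["manifest"])
    annotation = (io.read_probe_annotation(paths["annotation"])
                  if paths.get("annotation") else None)
    covariates = (io.read_sample_covariates(paths["covariates"])
                  if paths.get("covariates") else None)
    return betas, manifest, annotation, covariates, None


def _echo_config(cfg: PipelineConfig, out: Path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return [float(x) for x in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple, set, frozenset)):
            return [enc(v) for v in obj]
        return obj
    echoed = enc(cfg)
    echoed.pop("output_dir", None)  # keep the echo location-independent
    (out / "config-echo.yaml").write_text(yaml.safe_dump(echoed, sort_keys=True))


def run_full_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every configured stage; returns the output directory."""
    out = Path(cfg.output_dir)
    tables = out / "tables"
    profiles = out / "profiles"
    logs = out / "logs"
    for d in (tables, profiles, logs):
        d.mkdir(parents=True, exist_ok=True)
    _echo_config(cfg, out)
    counts: dict[str, Any] = {}

    # --- stage: data ------------------------------------------------------
    if cfg.simulation is not None:
        sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        betas, manifest, covariates, truth = simulate_twin_cohort(sim_cfg)
        annotation = synthetic_annotation(betas.probe_ids, seed=cfg.seed)
        io.write_beta_matrix(betas, tables / "betas.tsv")
        io.write_pair_manifest(manifest, tables / "manifest.tsv")
        io.write_sample_covariates(covariates, tables / "covariates.tsv")
        truth.sites.to_csv(tables / "simulation_truth.tsv", sep="\t", na_rep="NA")
        counts["simulation_warnings"] = truth.warnings
    else:
        betas, manifest, annotation, covariates, truth = _load_inputs(cfg)
    counts["n_probes"] = betas.n_probes
    counts["n_samples"] = betas.n_samples
    counts["n_mz_pairs"] = manifest.n_mz
    counts["n_dz_pairs"] = manifest.n_dz
    missing = manifest.missing_from(betas)
    counts["manifest_samples_missing_from_betas"] = len(missing)

    thr = probes.ProbeClassThresholds(cfg.thresholds.variable,
                                      cfg.thresholds.intermediate_low,
                                      cfg.thresholds.intermediate_high)

    # --- stage: classification -------------------------------------------
    classes = probes.classify_probes(betas, thr)
    chrom = (annotation.frame["chrom"].astype(str).str.upper()
             .str.removeprefix("CHR") if annotation is not None else None)
    frames = [classes]
    if chrom is not None and (chrom == "X").any() and covariates is not None \
            and "sex" in covariates.frame.columns:
        x_probes = [p for p in betas.probe_ids if chrom.get(p) == "X"]
        sex = covariates.for_samples(betas.sample_ids)["sex"]
        for label, code in (("male", "M"), ("female", "F")):
            ids = [s for s in betas.sample_ids if sex[s] == code]
            frames.append(probes.classify_probes(
                betas.subset_probes(x_probes), thr, ids, stratum=label))
    pd.concat(frames).to_csv(tables / "probe_classes.tsv", sep="\t", na_rep="NA")
    counts["n_variable"] = int(classes["is_variable"].sum())
    counts["n_intermediate"] = int(classes["is_intermediate"].sum())

    # --- stage: twin correlations + sign tests ----------------------------
    corr = similarity.site_twin_correlations(betas, manifest)
    corr.to_csv(tables / "twin_correlations.tsv", sep="\t", na_rep="NA")
    sign_rows = []
    subsets = {
        "all": pd.Series(True, index=classes.index),
        "variable": classes["is_variable"],
        "intermediate": classes["is_intermediate"],
    }
    for label, member in subsets.items():
        sel = corr.loc[member[member].index.intersection(corr.index)].dropna(
            subset=["r_MZ", "r_DZ"])
        if sel.empty:
            continue
        k = int((sel["r_MZ"] > sel["r_DZ"]).sum())
        m = len(sel)
        st = similarity.exact_sign_test(k, m)
        sign_rows.append({"subset": label, "k_mz_greater": k, "m_sites": m,
                          "p": st.p_two_sided, "log10_p": st.log10_p})
    pd.DataFrame(sign_rows).to_csv(tables / "sign_tests.tsv", sep="\t", index=False)

    prof_corr = similarity.pair_profile_correlation(betas, manifest)
    unrel = similarity.unrelated_profile_correlation(betas, manifest, seed=cfg.seed)
    pd.concat([prof_corr, unrel]).to_csv(tables / "pair_profile_correlations.tsv",
                                         sep="\t", index=False, na_rep="NA")
    mz_r = prof_corr.loc[prof_corr["zygosity"] == "MZ", "r"].to_numpy()
    dz_r = prof_corr.loc[prof_corr["zygosity"] == "DZ", "r"].to_numpy()
    if len(mz_r) >= 2 and len(dz_r) >= 2:
        m1, m2, p = similarity.compare_group_similarity(mz_r, dz_r)
        counts["profile_similarity"] = {"mean_r_MZ": m1, "mean_r_DZ": m2, "p": p}

    # --- stage: genome-wide ACE ------------------------------------------
    analysis_betas = betas
    if cfg.residualize:
        if covariates is None:
            raise ValidationError("residualize requested but no covariates given")
        analysis_betas = ace.residualize_covariates(betas, covariates, cfg.residualize)
    decomps = ace.run_ace_genomewide(analysis_betas, manifest, annotation,
                                     method=cfg.ace_method)
    io.write_results_table(decomps, tables / "ace_results.tsv", annotation)
    counts["n_ace_fitted"] = len(decomps)
    ddf = strata.decomp_frame([d for d in decomps if d.stratum == "all"])

    # --- stage: strata comparisons and profiles ---------------------------
    comp_rows = []
    for label, member in (("variable", classes["is_variable"]),
                          ("intermediate", classes["is_intermediate"])):
        try:
            for c in strata.compare_strata(ddf, member, label, f"non-{label}",
                                           method="asymptotic"):
                comp_rows.append(dataclasses.asdict(c))
        except ValidationError as exc:
            log.warning("stratum comparison %s skipped: %s", label, exc)
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(tables / "stratum_comparisons.tsv",
                                       sep="\t", index=False)

    level = strata.level_profile(classes["mean"], ddf["A"],
                                 window_width=0.1, step=0.02,
                                 min_n=min(cfg.profile_min_n, 20))
    level.to_csv(profiles / "level_profile_A.tsv", sep="\t", index=False, na_rep="NA")
    if annotation is not None and "tss_distance" in annotation.frame.columns:
        pos = strata.positional_profile(ddf, annotation,
                                        window_bp=cfg.profile_window_bp,
                                        step_bp=cfg.profile_step_bp,
                                        min_n=cfg.profile_min_n)
        pos.to_csv(profiles / "tss_profile.tsv", sep="\t", index=False, na_rep="NA")

    # --- stage: enrichment ------------------------------------------------
    mqtl_flags = None
    if annotation is not None and "mqtl_flag" in annotation.frame.columns:
        mqtl_flags = annotation.scores("mqtl_flag")
    elif truth is not None and "has_mqtl" in truth.sites.columns:
        mqtl_flags = truth.sites["has_mqtl"]
    if mqtl_flags is not None:
        enr = strata.mqtl_enrichment(ddf, mqtl_flags,
                                     a_threshold=cfg.thresholds.a_high)
        counts["mqtl_enrichment"] = dataclasses.asdict(enr)
    if annotation is not None and "covariation_r" in annotation.frame.columns:
        try:
            counts["covariation"] = strata.covariation_stratified_heritability(
                ddf, annotation.scores("covariation_r"),
                cutoff=cfg.thresholds.covariation_cutoff)
        except ValidationError as exc:
            log.warning("covariation analysis skipped: %s", exc)

    # --- stage: EWAS ------------------------------------------------------
    if cfg.ewas_exposure is not None:
        if covariates is None:
            raise ValidationError("EWAS requested but no covariates given")
        res = ewas.run_ewas(betas, covariates, cfg.ewas_exposure,
                            cfg.ewas_adjustments, dmp_threshold=cfg.thresholds.dmp)
        res.to_csv(tables / "ewas_results.tsv", sep="\t", na_rep="NA")
        dmps = list(res.index[res["is_dmp"]])
        counts["n_dmps"] = len(dmps)
        if dmps:
            cov = covariates.for_samples(betas.sample_ids)
            exposed = (pd.Series(
                (cov[cfg.ewas_exposure].astype(str) == "current").astype(int)
                if cfg.ewas_exposure == "smoking_status"
                else pd.to_numeric(cov[cfg.ewas_exposure]),
                index=cov.index))
            report = ewas.dmp_heritability_report(dmps, ddf, betas, manifest, exposed)
            stv = report.get("sign_test", {})
            if "result" in stv and stv["result"] is not None:
                counts["dmp_sign_test"] = {
                    "k": stv["k_mz_greater"], "m": stv["m_sites"],
                    "p": stv["result"].p_two_sided,
                    "log10_p": stv["result"].log10_p,
                }
            rows = [dataclasses.asdict(c) for c in report["ace_comparison"]]
            pd.DataFrame(rows).to_csv(tables / "dmp_ace_comparison.tsv",
                                      sep="\t", index=False)
            for label, frame in report["falconer_by_class"].items():
                if isinstance(frame, pd.DataFrame):
                    frame.to_csv(tables / f"dmp_falconer_{label}.tsv",
                                 sep="\t", na_rep="NA")
                else:
                    counts[f"falconer_{label}"] = frame

    (logs / "run.json").write_text(json.dumps(counts, indent=2, sort_keys=True,
                                              default=str))
    return out


def demo_config(output_dir: str = "twinmeth_demo", seed: int = 1) -> PipelineConfig:
    """Small fully-simulated configuration (the bundled ``data/demo.yaml``)
    that runs the entire pipeline in seconds."""
    from importlib import resources

    raw = yaml.safe_load(
        resources.files("twinmeth").joinpath("data/demo.yaml").read_text())
    raw["output_dir"] = output_dir
    raw["seed"] = seed
    return config_from_dict(raw)
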