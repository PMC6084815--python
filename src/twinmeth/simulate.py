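"""Synthetic twin cohorts with known per-site A/C/E structure.

The generator draws, for each site and pair, latent values

    l = mu + a * g + c * s + e * u

with g, s, u standard normal, corr(g1, g2) = 1 for MZ pairs and 0.5 for DZ
pairs (g2 = 0.5 g1 + sqrt(0.75) g'), and a^2 = A_true * total_sd^2 etc.
``linear-clip`` mode maps latents to the beta scale by clipping to [0, 1],
keeping the variance components exact on the observed scale when clipping
is negligible; ``logistic`` mode passes scaled deviations through the
inverse logit around logit(mu_beta), emulating realistic beta
distributions near the boundaries (components are distorted there, but the
MZ > DZ ordering is preserved).

All randomness flows from one integer seed through named sub-streams, so
e.g. adding sites does not perturb the genotype draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (BetaMatrix, PairManifest, ProbeAnnotation, SampleCovariates,
                 ValidationError)

__all__ = [
    "MqtlSpec",
    "ExposureSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_twin_cohort",
    "simulate_sibling_genotypes",
    "spike_exposure_effects",
    "synthetic_annotation",
]

_STREAMS = {"latent": 11, "genotypes": 23, "exposure": 37, "manifest": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class MqtlSpec:
    fraction: float = 0.0          # fraction of sites given an mQTL SNP
    maf: float = 0.2
    effect_per_allele: float = 0.05  # beta units per minor allele

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("mQTL fraction outside [0, 1]")
        if not 0.0 < self.maf <= 0.5:
            raise ValidationError("MAF outside (0, 0.5]")


@dataclass(frozen=True)
class ExposureSpec:
    p_exposed: float = 0.3          # per-family exposure probability
    concordance: float = 1.0        # probability the pair shares one draw
    effect: float = -0.1            # additive beta shift at affected sites
    n_affected_sites: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_exposed <= 1.0:
            raise ValidationError("p_exposed outside [0, 1]")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValidationError("concordance outside [0, 1]")


@dataclass
class SimulationConfig:
    n_mz: int = 426
    n_dz: int = 306
    n_sites: int = 200
    a_true: np.ndarray | float = 0.25
    c_true: np.ndarray | float = 0.15
    e_true: np.ndarray | float = 0.60
    mu_beta: np.ndarray | float = 0.5
    total_sd: np.ndarray | float = 0.05
    scale_mode: str = "linear-clip"
    mqtl: MqtlSpec | None = None
    exposure: ExposureSpec | None = None
    female_fraction: float = 0.49
    seed: int = 0

    def per_site(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        n = self.n_sites
        a = np.broadcast_to(np.asarray(self.a_true, dtype=float), (n,)).copy()
        c = np.broadcast_to(np.asarray(self.c_true, dtype=float), (n,)).copy()
        e = np.broadcast_to(np.asarray(self.e_true, dtype=float), (n,)).copy()
        mu = np.broadcast_to(np.asarray(self.mu_beta, dtype=float), (n,)).copy()
        sd = np.broadcast_to(np.asarray(self.total_sd, dtype=float), (n,)).copy()
        tot = a + c + e
        if not np.allclose(tot, 1.0, atol=1e-12):
            raise ValidationError("A_true + C_true + E_true must equal 1 per site")
        for arr, label in ((a, "A"), (c, "C"), (e, "E")):
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{label}_true outside [0, 1]")
        if ((mu <= 0) | (mu >= 1)).any():
            raise ValidationError("mu_beta outside (0, 1)")
        if (sd <= 0).any():
            raise ValidationError("total_sd must be > 0")
        if self.scale_mode not in ("linear-clip", "logistic"):
            raise ValidationError(f"unknown scale_mode {self.scale_mode!r}")
        return a, c, e, mu, sd


@dataclass
class SimulationTruth:
    """Per-site generating parameters actually used, plus per-sample
    genotypes at mQTL sites and exposure labels."""

    sites: pd.DataFrame                      # probe_id-indexed truth table
    genotypes: pd.DataFrame | None = None    # sites x samples, 0/1/2
    exposure: pd.Series | None = None        # sample_id -> 0/1
    warnings: list = field(default_factory=list)


def simulate_sibling_genotypes(n_pairs: int, zygosity: str, maf: float,
                               seed: int | np.random.Generator) -> np.ndarray:
    """(n_pairs, 2) genotype pairs (minor-allele counts 0/1/2).

    Parental haplotypes are Bernoulli(maf); MZ co-twins share both
    transmitted alleles, DZ co-twins get independent transmissions from the
    same two parents, so marginals are Hardy-Weinberg and the DZ sib
    genotype correlation is 0.5.
    """
    if not 0.0 < maf <= 0.5:
        raise ValidationError("MAF outside (0, 0.5]")
    if zygosity not in ("MZ", "DZ"):
        raise ValidationError(f"unknown zygosity {zygosity!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # two haplotypes per parent
    mother = rng.random((n_pairs, 2)) < maf
    father = rng.random((n_pairs, 2)) < maf
    pick_m1 = rng.integers(0, 2, n_pairs)
    pick_f1 = rng.integers(0, 2, n_pairs)
    twin1 = (mother[np.arange(n_pairs), pick_m1].astype(int)
             + father[np.arange(n_pairs), pick_f1].astype(int))
    if zygosity == "MZ":
        twin2 = twin1.copy()
    else:
        pick_m2 = rng.integers(0, 2, n_pairs)
        pick_f2 = rng.integers(0, 2, n_pairs)
        twin2 = (mother[np.arange(n_pairs), pick_m2].astype(int)
                 + father[np.arange(n_pairs), pick_f2].astype(int))
    return np.column_stack([twin1, twin2])


def _sample_ids(config: SimulationConfig) -> tuple[pd.DataFrame, list[str]]:
    """Build the pair manifest frame (deterministic under the seed)."""
    rng = _rng(config.seed, "manifest")
    rows = []
    idx = 0
    for zyg, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        sexes = np.where(rng.random(n) < config.female_fraction, "F", "M")
        for j in range(n):
            pid = f"{zyg}{j:05d}"
            rows.append((pid, f"{pid}_1", f"{pid}_2", zyg, sexes[j], f"fam_{idx:05d}"))
            idx += 1
    frame = pd.DataFrame(rows, columns=["pair_id", "sample_id_a", "sample_id_b",
                                        "zygosity", "sex", "family_id"])
    samples = list(frame["sample_id_a"]) + list(frame["sample_id_b"])
    return frame, samples


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_twin_cohort(config: SimulationConfig
                         ) -> tuple[BetaMatrix, PairManifest, SampleCovariates,
                                    SimulationTruth]:
    """Draw a full synthetic cohort; reproducible under ``config.seed``."""
    a_p, c_p, e_p, mu, sd = config.per_site()
    n_sites = config.n_sites
    manifest_frame, samples = _sample_ids(config)
    manifest = PairManifest(manifest_frame)

    a = np.sqrt(a_p) * sd
    c = np.sqrt(c_p) * sd
    e = np.sqrt(e_p) * sd

    rng = _rng(config.seed, "latent")
    blocks = []
    for zyg, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        g1 = rng.standard_normal((n_sites, n))
        if zyg == "MZ":
            g2 = g1
        else:
            g2 = 0.5 * g1 + np.sqrt(0.75) * rng.standard_normal((n_sites, n))
        s = rng.standard_normal((n_sites, n))
        u1 = rng.standard_normal((n_sites, n))
        u2 = rng.standard_normal((n_sites, n))
        d1 = a[:, None] * g1 + c[:, None] * s + e[:, None] * u1
        d2 = a[:, None] * g2 + c[:, None] * s + e[:, None] * u2
        blocks.append((d1, d2))
    # column order matches samples: all twin-1 columns then all twin-2
    dev1 = np.concatenate([blocks[0][0], blocks[1][0]], axis=1)
    dev2 = np.concatenate([blocks[0][1], blocks[1][1]], axis=1)
    latent = np.concatenate([dev1, dev2], axis=1) + 0.0

    warnings: list[str] = []
    truth_cols = {
        "A_true": a_p, "C_true": c_p, "E_true": e_p,
        "mu_beta": mu, "total_sd": sd,
        "has_mqtl": np.zeros(n_sites, dtype=bool),
        "mqtl_effect": np.zeros(n_sites),
        "mqtl_maf": np.full(n_sites, np.nan),
        "exposure_effect": np.zeros(n_sites),
    }
    probe_ids = [f"site{j:06d}" for j in range(n_sites)]

    # mQTL sites: genotype effect added on the latent (pre-link) scale
    genotypes = None
    if config.mqtl is not None and config.mqtl.fraction > 0:
        grng = _rng(config.seed, "genotypes")
        n_mqtl = int(round(config.mqtl.fraction * n_sites))
        mqtl_sites = np.arange(n_mqtl)  # leading block, deterministic
        geno = np.zeros((n_mqtl, len(samples)), dtype=int)
        gmz = np.empty((n_mqtl, config.n_mz, 2), dtype=int)
        gdz = np.empty((n_mqtl, config.n_dz, 2), dtype=int)
        for k in range(n_mqtl):
            gmz[k] = simulate_sibling_genotypes(config.n_mz, "MZ", config.mqtl.maf, grng)
            gdz[k] = simulate_sibling_genotypes(config.n_dz, "DZ", config.mqtl.maf, grng)
        geno1 = np.concatenate([gmz[:, :, 0], gdz[:, :, 0]], axis=1)
        geno2 = np.concatenate([gmz[:, :, 1], gdz[:, :, 1]], axis=1)
        geno = np.concatenate([geno1, geno2], axis=1)
        eff = config.mqtl.effect_per_allele
        centred = geno - 2.0 * config.mqtl.maf
        latent[mqtl_sites] += eff * centred
        truth_cols["has_mqtl"][mqtl_sites] = True
        truth_cols["mqtl_effect"][mqtl_sites] = eff
        truth_cols["mqtl_maf"][mqtl_sites] = config.mqtl.maf
        genotypes = pd.DataFrame(geno, index=[probe_ids[i] for i in mqtl_sites],
                                 columns=samples)

    if config.scale_mode == "linear-clip":
        values = np.clip(mu[:, None] + latent, 0.0, 1.0)
        frac_clipped = np.mean((mu[:, None] + latent < 0) | (mu[:, None] + latent > 1))
        if frac_clipped > 0.01:
            warnings.append(
                f"{frac_clipped:.1%} of values clipped to [0, 1]; variance "
                "components on the observed scale are attenuated")
    else:
        base = _logit(mu)
        # scale deviations so the slope at mu matches the beta-scale sd
        slope = mu * (1.0 - mu)
        values = _inv_logit(base[:, None] + latent / slope[:, None])

    betas = BetaMatrix(probe_ids, samples, values)
    truth = SimulationTruth(
        sites=pd.DataFrame(truth_cols, index=pd.Index(probe_ids, name="probe_id")),
        genotypes=genotypes,
        warnings=warnings,
    )

    cov = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    sex_of = {}
    fam_of = {}
    for _, rec in manifest_frame.iterrows():
        for sid in (rec["sample_id_a"], rec["sample_id_b"]):
            sex_of[sid] = rec["sex"]
            fam_of[sid] = rec["family_id"]
    cov["sex"] = [sex_of[s] for s in samples]
    cov["family_id"] = [fam_of[s] for s in samples]
    covariates = SampleCovariates(cov)

    if config.exposure is not None and config.exposure.n_affected_sites > 0:
        betas, covariates, truth = _apply_exposure(betas, manifest, covariates,
                                                  truth, config)
    return betas, manifest, covariates, truth


def _apply_exposure(betas, manifest, covariates, truth, config):
    spec = config.exposure
    affected = betas.probe_ids[-spec.n_affected_sites:]
    betas2, cov2 = spike_exposure_effects(
        betas, manifest, affected, spec, _rng(config.seed, "exposure"))
    frame = covariates.frame.join(cov2.frame[["exposed", "smoking_status"]])
    truth.exposure = cov2.frame["exposed"]
    truth.sites.loc[affected, "exposure_effect"] = spec.effect
    n_aff = len(affected)
    shifted = betas.values[-n_aff:] + spec.effect  # what was added pre-clip
    at_bound = np.mean((shifted <= 0) | (shifted >= 1))
    if at_bound > 0.05:
        truth.warnings.append(
            f"{at_bound:.1%} of exposed affected-site values hit a clip boundary")
    return betas2, SampleCovariates(frame), truth


def spike_exposure_effects(betas: BetaMatrix, manifest: PairManifest,
                           affected_sites: Sequence[str],
                           spec: ExposureSpec,
                           seed: int | np.random.Generator
                           ) -> tuple[BetaMatrix, SampleCovariates]:
    """Assign a family-concordant binary exposure and shift the affected
    sites additively for exposed individuals (re-clipped to [0, 1])."""
    missing = [p for p in affected_sites if p not in set(betas.probe_ids)]
    if missing:
        raise ValidationError(f"affected sites absent from matrix: {missing[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    exposed: dict[str, int] = {}
    for _, rec in manifest.frame.iterrows():
        shared = rng.random() < spec.concordance
        if shared:
            e = int(rng.random() < spec.p_exposed)
            exposed[rec["sample_id_a"]] = e
            exposed[rec["sample_id_b"]] = e
        else:
            exposed[rec["sample_id_a"]] = int(rng.random() < spec.p_exposed)
            exposed[rec["sample_id_b"]] = int(rng.random() < spec.p_exposed)
    flags = np.array([exposed.get(s, 0) for s in betas.sample_ids], dtype=float)

    values = betas.values.copy()
    idx = [betas.probe_ids.index(p) for p in affected_sites]
    values[np.ix_(idx, np.arange(betas.n_samples))] += spec.effect * flags[None, :]
    values = np.clip(values, 0.0, 1.0)

    cov = pd.DataFrame(index=pd.Index(betas.sample_ids, name="sample_id"))
    cov["exposed"] = flags.astype(int)
    cov["smoking_status"] = np.where(flags > 0, "current", "never")
    return (BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), values),
            SampleCovariates(cov))


def synthetic_annotation(probe_ids: Sequence[str],
                         chroms: Sequence[str] | None = None,
                         tss_distances: Sequence[float] | None = None,
                         seed: int = 0) -> ProbeAnnotation:
    """Minimal annotation for simulated cohorts: round-robin autosomes by
    default, evenly spaced positions, optional chrom/tss overrides."""
    n = len(probe_ids)
    rng = np.random.default_rng(seed)
    if chroms is None:
        chroms = [str(1 + (i % 22)) for i in range(n)]
    positions = []
    counters: dict[str, int] = {}
    for ch in chroms:
        counters[ch] = counters.get(ch, 0) + 1
        positions.append(1000 * counters[ch])
    frame = pd.DataFrame({
        "chrom": list(chroms),
        "position": positions,
        "strand": ["+" if i % 2 == 0 else "-" for i in range(n)],
        "gene_features": ["Body"] * n,
        "island_relation": ["OpenSea"] * n,
        "tss_distance": (list(tss_distances) if tss_distances is not None
                         else rng.integers(-5000, 5000, n).astype(float)),
    }, index=pd.Index([str(p) for p in probe_ids], name="probe_id"))
    return ProbeAnnotation(frame)
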