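"""ACE variance decomposition for twin pairs.

Decomposes the variance of a trait measured on MZ and DZ twin pairs into
additive genetic (A), shared environment (C) and unique environment (E)
proportions.  Three routes are provided:

* :func:`fit_ace_fiml` — full-information maximum likelihood on the raw
  pair values (bivariate normal, common mean, exchangeable ACE covariance),
  parameterized by path coefficients so the variance components are
  nonnegative by construction.
* :func:`fit_ace_summary` — maximum likelihood on the two observed twin
  correlations with unit-variance correlation matrices; the interior
  solution coincides with the Falconer closed form.
* :func:`falconer_estimates` — the closed form itself.

Model covariance: off-diagonal a^2 + c^2 for MZ pairs, a^2/2 + c^2 for DZ
pairs, common diagonal a^2 + c^2 + e^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .io import BetaMatrix, PairManifest, ProbeAnnotation, SampleCovariates, ValidationError

__all__ = [
    "VarianceDecomposition",
    "falconer_estimates",
    "fit_ace_summary",
    "fit_ace_fiml",
    "residualize_covariates",
    "run_ace_genomewide",
    "extract_pairs",
]

log = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class VarianceDecomposition:
    """Per-site (or per-phenotype) A/C/E estimates and fit diagnostics."""

    name: str
    A: float
    C: float
    E: float
    a2: float
    c2: float
    e2: float
    sigma2: float
    mu: float
    loglik: float
    converged: bool
    boundary: frozenset = frozenset()
    method: str = "fiml"
    stratum: str = "all"
    n_mz: int | None = None
    n_dz: int | None = None
    r_mz: float | None = None
    r_dz: float | None = None

    def __post_init__(self) -> None:
        total = self.A + self.C + self.E
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValidationError(f"A+C+E = {total!r} != 1 for {self.name!r}")
        for label, v in (("A", self.A), ("C", self.C), ("E", self.E)):
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{label} = {v!r} outside [0, 1] for {self.name!r}")


def falconer_estimates(r_mz: float, r_dz: float) -> dict:
    """Closed-form twin estimates from the two correlations.

    Returns both the raw values ``h2 = 2(rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``,
    ``e2 = 1 - rMZ`` and their truncations to [0, 1].
    """
    if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
        raise ValidationError("correlations must be finite")
    h2_raw = 2.0 * (r_mz - r_dz)
    c2_raw = 2.0 * r_dz - r_mz
    e2_raw = 1.0 - r_mz
    clip = lambda x: float(min(1.0, max(0.0, x)))
    return {
        "h2": clip(h2_raw), "c2": clip(c2_raw), "e2": clip(e2_raw),
        "h2_raw": h2_raw, "c2_raw": c2_raw, "e2_raw": e2_raw,
    }


def _corr_nll(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Per-group negative log-likelihood term for a unit-variance
    exchangeable bivariate normal with model correlation rho and observed
    correlation r over n pairs (constants dropped)."""
    d = 1.0 - rho * rho
    return 0.5 * n * (np.log(d) + (2.0 - 2.0 * rho * r) / d)


def _summary_loglik(A: float, C: float, r_mz: float, r_dz: float,
                    n_mz: int, n_dz: int) -> float:
    rho_mz = A + C
    rho_dz = 0.5 * A + C
    nll = (_corr_nll(np.asarray(rho_mz), r_mz, n_mz)
           + _corr_nll(np.asarray(rho_dz), r_dz, n_dz))
    const = (n_mz + n_dz) * LOG2PI
    return float(-nll - const)


def fit_ace_summary(r_mz: float, r_dz: float, n_mz: int, n_dz: int,
                    name: str = "summary") -> VarianceDecomposition:
    """ACE fit from the two twin correlations alone.

    Maximizes the two-group likelihood of unit-variance correlation
    matrices weighted by pair counts, constraining a^2, c^2 >= 0.  When the
    unconstrained solution is interior it equals the closed form
    A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ (the model is
    saturated); a negative closed-form component is pinned to zero and the
    remainder re-maximized numerically.
    """
    if not (abs(r_mz) < 1 and abs(r_dz) < 1):
        raise ValidationError("|r| must be < 1 for the summary fit")
    if n_mz < 3 or n_dz < 3:
        raise ValidationError("need at least 3 pairs per zygosity group")

    fal = falconer_estimates(r_mz, r_dz)
    A0, C0, E0 = fal["h2_raw"], fal["c2_raw"], fal["e2_raw"]
    boundary: set[str] = set()
    eps = 1e-12

    if A0 >= 0 and C0 >= 0 and E0 > 0:
        A, C = A0, C0
    else:
        def nll(x: np.ndarray) -> float:
            return -_summary_loglik(x[0], x[1], r_mz, r_dz, n_mz, n_dz)

        start = np.clip([A0, C0], 0.0, 1.0)
        if start.sum() > 1 - 1e-9:
            start = start / (start.sum() + 1e-6)
        res = optimize.minimize(
            nll, start, method="SLSQP",
            bounds=[(0.0, 1.0 - 1e-9), (0.0, 1.0 - 1e-9)],
            constraints=[{"type": "ineq",
                          "fun": lambda x: 1.0 - 1e-9 - x[0] - x[1]}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        A, C = float(res.x[0]), float(res.x[1])
        if A < 1e-8:
            A = 0.0
            boundary.add("A")
        if C < 1e-8:
            C = 0.0
            boundary.add("C")
    E = 1.0 - A - C
    ll = _summary_loglik(A, C, r_mz, r_dz, n_mz, n_dz)
    return VarianceDecomposition(
        name=name, A=A, C=C, E=E, a2=A, c2=C, e2=E, sigma2=1.0, mu=0.0,
        loglik=ll, converged=True, boundary=frozenset(boundary),
        method="summary", n_mz=n_mz, n_dz=n_dz, r_mz=r_mz, r_dz=r_dz,
    )


# ---------------------------------------------------------------------------
# FIML on raw pairs


def _suffstats(pairs: np.ndarray) -> tuple[int, float, float, float]:
    y1 = pairs[:, 0]
    y2 = pairs[:, 1]
    return (pairs.shape[0], float(np.sum(y1 + y2)),
            float(np.sum(y1 * y1 + y2 * y2)), float(np.sum(y1 * y2)))


def _group_nll(mu: float, v: float, cv: float,
               stats: tuple[int, float, float, float]) -> float:
    """Negative log-likelihood of n exchangeable bivariate-normal pairs
    given sufficient statistics (n, sum y1+y2, sum y1^2+y2^2, sum y1*y2)."""
    n, s1, s2, s12 = stats
    d = v * v - cv * cv
    if d <= 0 or v <= 0:
        return float("inf")
    q_diag = s2 - 2.0 * mu * s1 + 2.0 * n * mu * mu
    q_cross = s12 - mu * s1 + n * mu * mu
    return n * LOG2PI + 0.5 * n * math.log(d) + (v * q_diag - 2.0 * cv * q_cross) / (2.0 * d)


def _fiml_nll(x: np.ndarray, stats_mz, stats_dz) -> float:
    mu, a, c, e = x
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    return (_group_nll(mu, v, a2 + c2, stats_mz)
            + _group_nll(mu, v, 0.5 * a2 + c2, stats_dz))


def _double_entry_r(pairs: np.ndarray) -> float:
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    sx = x.std()
    if sx == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def fit_ace_fiml(pairs_mz: np.ndarray, pairs_dz: np.ndarray,
                 name: str = "site", e_floor_scale: float = 1e-6,
                 boundary_scale: float = 1e-5) -> VarianceDecomposition:
    """Full-information ML ACE fit on raw MZ/DZ pair values.

    Maximizes the bivariate-normal likelihood with a common mean and the
    exchangeable ACE covariance, over path coefficients (a, c, e) so the
    variance components are nonnegative automatically.  ``e`` is bounded
    below at ``e_floor_scale`` times the pooled SD.  Deterministic
    multi-start: Falconer-informed and equal-thirds starts, best kept.
    """
    pairs_mz = np.asarray(pairs_mz, dtype=float).reshape(-1, 2)
    pairs_dz = np.asarray(pairs_dz, dtype=float).reshape(-1, 2)
    pairs_mz = pairs_mz[~np.isnan(pairs_mz).any(axis=1)]
    pairs_dz = pairs_dz[~np.isnan(pairs_dz).any(axis=1)]
    n_mz, n_dz = pairs_mz.shape[0], pairs_dz.shape[0]
    if n_mz < 3 or n_dz < 3:
        raise ValidationError(
            f"need >= 3 complete pairs per zygosity (got {n_mz} MZ, {n_dz} DZ)")

    allv = np.concatenate([pairs_mz.ravel(), pairs_dz.ravel()])
    sd_tot = float(allv.std(ddof=0))
    if sd_tot == 0.0:
        raise ValidationError(f"zero total variance for {name!r}")
    mu0 = float(allv.mean())
    e_floor = e_floor_scale * sd_tot

    stats_mz = _suffstats(pairs_mz)
    stats_dz = _suffstats(pairs_dz)

    r_mz = _double_entry_r(pairs_mz)
    r_dz = _double_entry_r(pairs_dz)

    # deterministic starts: Falconer solution and equal thirds
    starts = []
    if np.isfinite(r_mz) and np.isfinite(r_dz):
        fal = falconer_estimates(r_mz, r_dz)
        A0 = min(max(fal["h2"], 1e-4), 0.98)
        C0 = min(max(fal["c2"], 1e-4), 0.98)
        E0 = max(1.0 - A0 - C0, 0.02)
        s = A0 + C0 + E0
        starts.append([mu0, math.sqrt(A0 / s) * sd_tot,
                       math.sqrt(C0 / s) * sd_tot, math.sqrt(E0 / s) * sd_tot])
    t = sd_tot / math.sqrt(3.0)
    starts.append([mu0, t, t, t])

    lo, hi = allv.min(), allv.max()
    span = max(hi - lo, sd_tot)
    bounds = [(lo - span, hi + span), (0.0, 10.0 * sd_tot),
              (0.0, 10.0 * sd_tot), (e_floor, 10.0 * sd_tot)]

    opts = {"ftol": 1e-14, "gtol": 1e-9, "maxiter": 2000}

    def _minimize(x0: np.ndarray, fix_a: bool = False, fix_c: bool = False):
        free = [0] + [j for j, fixed in ((1, fix_a), (2, fix_c)) if not fixed] + [3]

        def obj(xf: np.ndarray) -> float:
            x = np.zeros(4)
            x[free] = xf
            return _fiml_nll(x, stats_mz, stats_dz)

        res = optimize.minimize(obj, np.asarray(x0)[free], method="L-BFGS-B",
                                bounds=[bounds[j] for j in free], options=opts)
        full = np.zeros(4)
        full[free] = res.x
        return res, full

    best = None
    best_x = None
    any_success = False
    for x0 in starts:
        res, full = _minimize(np.asarray(x0))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_x = res, full

    # the likelihood is flat in a path coefficient near zero; snap candidate
    # components to the boundary when that costs no likelihood
    boundary = set()
    for label, j in (("A", 1), ("C", 2)):
        if abs(best_x[j]) < 1e-2 * sd_tot:
            res_p, full_p = _minimize(
                np.where(np.arange(4) == j, 0.0, best_x),
                fix_a=(j == 1), fix_c=(j == 2))
            if res_p.fun <= best.fun + 1e-6 * (1.0 + abs(best.fun)):
                best, best_x = res_p, full_p
                boundary.add(label)
                any_success = any_success or bool(res_p.success)

    mu, a, c, e = (float(z) for z in best_x)
    a2, c2, e2 = a * a, c * c, max(e * e, e_floor * e_floor)
    sigma2 = a2 + c2 + e2
    A, C, E = a2 / sigma2, c2 / sigma2, e2 / sigma2
    if abs(a) < boundary_scale * sd_tot:
        boundary.add("A")
    if abs(c) < boundary_scale * sd_tot:
        boundary.add("C")

    grad = np.asarray(best.jac, dtype=float)
    nll = float(best.fun)
    grad_ok = bool(np.linalg.norm(grad) <= 1e-3 * (1.0 + abs(nll)))
    converged = any_success and grad_ok and np.isfinite(nll)

    return VarianceDecomposition(
        name=name, A=A, C=C, E=E, a2=a2, c2=c2, e2=e2, sigma2=sigma2, mu=mu,
        loglik=-nll, converged=converged, boundary=frozenset(boundary),
        method="fiml", n_mz=n_mz, n_dz=n_dz,
        r_mz=None if not np.isfinite(r_mz) else r_mz,
        r_dz=None if not np.isfinite(r_dz) else r_dz,
    )


def fiml_loglik_grid(decomp: VarianceDecomposition, pairs_mz: np.ndarray,
                     pairs_dz: np.ndarray, step: float = 0.002) -> float:
    """Best log-likelihood over a dense (A, C) simplex grid with mu and
    sigma^2 fixed at the fitted values.  Used as an optimizer oracle."""
    pairs_mz = np.asarray(pairs_mz, dtype=float).reshape(-1, 2)
    pairs_dz = np.asarray(pairs_dz, dtype=float).reshape(-1, 2)
    stats_mz = _suffstats(pairs_mz[~np.isnan(pairs_mz).any(axis=1)])
    stats_dz = _suffstats(pairs_dz[~np.isnan(pairs_dz).any(axis=1)])
    grid = np.arange(0.0, 1.0 + step / 2, step)
    Ag, Cg = np.meshgrid(grid, grid)
    keep = Ag + Cg <= 1.0 - 1e-9
    Af, Cf = Ag[keep], Cg[keep]
    v = decomp.sigma2
    mu = decomp.mu

    def vec_nll(cv: np.ndarray, stats) -> np.ndarray:
        n, s1, s2, s12 = stats
        d = v * v - cv * cv
        q_diag = s2 - 2.0 * mu * s1 + 2.0 * n * mu * mu
        q_cross = s12 - mu * s1 + n * mu * mu
        return n * LOG2PI + 0.5 * n * np.log(d) + (v * q_diag - 2.0 * cv * q_cross) / (2.0 * d)

    nll = (vec_nll((Af + Cf) * v, stats_mz) + vec_nll((0.5 * Af + Cf) * v, stats_dz))
    return float(-np.min(nll))


# ---------------------------------------------------------------------------
# covariate residualization and the genome-wide driver


def residualize_covariates(betas: BetaMatrix, covariates: SampleCovariates,
                           covariate_names: Sequence[str]) -> BetaMatrix:
    """Per site, subtract the fitted OLS contribution of the named
    covariates (the intercept is kept, so a site built as a + b*x comes
    back as the constant a and values stay on the original scale)."""
    cov = covariates.for_samples(betas.sample_ids)
    cols = []
    for name in covariate_names:
        if name not in cov.columns:
            raise ValidationError(f"covariate {name!r} not available")
        col = cov[name]
        if col.dtype == object:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(pd.to_numeric(col).rename(name).to_frame())
    X = pd.concat(cols, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValidationError(f"missing covariate values in columns: {bad}")
    design = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, R = np.linalg.qr(design)
        dep = [str(col) for col, d in zip(["(intercept)"] + list(X.columns),
                                          np.abs(np.diag(R)))
               if d < 1e-10]
        raise ValidationError(f"rank-deficient covariate matrix; collinear: {dep}")

    V = betas.values
    out = np.array(V, dtype=float)
    mask = ~np.isnan(V)
    # remove only the covariate contribution, keeping the fitted intercept,
    # so a site y = a + b*x residualizes to the constant a
    pinv = np.linalg.pinv(design)
    full = mask.all(axis=1)
    if full.any():
        Y = V[full]
        coef = Y @ pinv.T
        out[full] = Y - coef[:, 1:] @ design[:, 1:].T
    for i in np.where(~full)[0]:
        m = mask[i]
        if m.sum() <= design.shape[1]:
            continue
        Xi = design[m]
        yi = V[i, m]
        coef, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        out[i, m] = yi - Xi[:, 1:] @ coef[1:]
    # residualized values may stray outside [0,1]; keep raw for modelling
    bm = BetaMatrix.__new__(BetaMatrix)
    bm.probe_ids = list(betas.probe_ids)
    bm.sample_ids = list(betas.sample_ids)
    bm.values = out
    return bm


def extract_pairs(values: np.ndarray, betas_samples: Sequence[str],
                  manifest: PairManifest, zygosity: str,
                  sex: str | None = None) -> np.ndarray:
    """(n_pairs, 2) array of one site's values for pairs of a zygosity
    (optionally one sex), complete pairs only."""
    pos = {s: i for i, s in enumerate(betas_samples)}
    rows = []
    for _, rec in manifest.pairs(zygosity, sex).iterrows():
        ia = pos.get(rec["sample_id_a"])
        ib = pos.get(rec["sample_id_b"])
        if ia is None or ib is None:
            continue
        rows.append((values[ia], values[ib]))
    arr = np.asarray(rows, dtype=float).reshape(-1, 2)
    return arr[~np.isnan(arr).any(axis=1)]


_CHRY = {"Y", "CHRY"}
_CHRX = {"X", "CHRX"}


def run_ace_genomewide(betas: BetaMatrix, manifest: PairManifest,
                       annotation: ProbeAnnotation | None = None,
                       method: str = "fiml",
                       logit_transform: bool = False) -> list[VarianceDecomposition]:
    """Fit the ACE model at every site.

    Autosomal sites use all pairs (stratum ``all``); X-linked sites are
    fitted twice, once per sex; Y-linked sites are skipped with a logged
    count.  Per-site failures are recorded as non-converged placeholders,
    never fatal.
    """
    missing = manifest.missing_from(betas)
    if missing:
        log.warning("%d manifest samples absent from beta matrix", len(missing))
    usable = set(betas.sample_ids)
    keep = manifest.frame[
        manifest.frame["sample_id_a"].isin(usable)
        & manifest.frame["sample_id_b"].isin(usable)
    ]
    if keep.empty:
        raise ValidationError("no usable twin pairs overlap the beta matrix")
    man = PairManifest(keep)

    chrom_of: dict[str, str] = {}
    if annotation is not None:
        chrom_of = annotation.frame["chrom"].astype(str).str.upper().to_dict()

    values = betas.values
    if logit_transform:
        clipped = np.clip(values, 1e-4, 1 - 1e-4)
        values = np.log(clipped / (1 - clipped))

    # pair index arrays computed once per (zygosity, sex) combination
    pos = {s: i for i, s in enumerate(betas.sample_ids)}

    def _pair_idx(zyg: str, sex: str | None) -> tuple[np.ndarray, np.ndarray]:
        f = man.pairs(zyg, sex)
        ia = np.array([pos[s] for s in f["sample_id_a"]], dtype=int)
        ib = np.array([pos[s] for s in f["sample_id_b"]], dtype=int)
        return ia, ib

    idx = {(z, s): _pair_idx(z, s)
           for z in ("MZ", "DZ") for s in (None, "M", "F")}

    results: list[VarianceDecomposition] = []
    n_y_skipped = 0
    for i, probe in enumerate(betas.probe_ids):
        chrom = chrom_of.get(probe, "").removeprefix("CHR")
        site = values[i]
        if chrom in {"Y"}:
            n_y_skipped += 1
            continue
        strata = [("all", None)] if chrom not in {"X"} else [("male", "M"), ("female", "F")]
        for stratum, sex in strata:
            try:
                ia, ib = idx[("MZ", sex)]
                pmz = np.column_stack([site[ia], site[ib]])
                ia, ib = idx[("DZ", sex)]
                pdz = np.column_stack([site[ia], site[ib]])
                dec = _fit_one(pmz, pdz, probe, method)
                results.append(replace(dec, stratum=stratum))
            except ValidationError as exc:
                log.info("site %s (%s) not fitted: %s", probe, stratum, exc)
    if n_y_skipped:
        log.info("skipped %d Y-linked sites", n_y_skipped)
    return results


def _fit_one(pmz: np.ndarray, pdz: np.ndarray, name: str,
             method: str) -> VarianceDecomposition:
    if method == "fiml":
        return fit_ace_fiml(pmz, pdz, name=name)
    if method == "summary":
        r_mz = _double_entry_r(pmz)
        r_dz = _double_entry_r(pdz)
        if not (np.isfinite(r_mz) and np.isfinite(r_dz)):
            raise ValidationError(f"undefined twin correlation for {name!r}")
        return fit_ace_summary(r_mz, r_dz, pmz.shape[0], pdz.shape[0], name=name)
    raise ValidationError(f"unknown ACE method {method!r}")


def fit_ace_phenotype(values: pd.Series, manifest: PairManifest,
                      name: str | None = None) -> VarianceDecomposition:
    """ACE fit for an arbitrary per-sample phenotype (e.g. DNAmAge
    acceleration or an estimated cell proportion), indexed by sample id."""
    values = values.astype(float)
    ids = list(values.index.astype(str))
    arr = values.to_numpy()
    pmz = extract_pairs(arr, ids, manifest, "MZ")
    pdz = extract_pairs(arr, ids, manifest, "DZ")
    return fit_ace_fiml(pmz, pdz, name=name or str(values.name or "phenotype"))
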