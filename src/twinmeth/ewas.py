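"""Site-wise exposure association with cluster-robust standard errors.

Families (twin pairs plus singletons) are the clusters.  The sandwich is
the CR1-corrected cluster estimator

    (X'X)^-1 [ sum_g X_g' u_g u_g' X_g ] (X'X)^-1 * G/(G-1) * (n-1)/(n-k)

with Wald t statistics referred to a t distribution on G - 1 degrees of
freedom.  With every cluster a singleton this reduces to the HC1
heteroskedasticity-robust covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ace import VarianceDecomposition, falconer_estimates
from .io import BetaMatrix, PairManifest, SampleCovariates, ValidationError
from .similarity import SignTestResult, exact_sign_test, site_twin_correlations
from .strata import StratumComparison, compare_strata

__all__ = [
    "EwasResult",
    "fit_clustered_ols",
    "run_ewas",
    "dmp_heritability_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EwasResult:
    probe_id: str
    effect: float
    robust_se: float
    t: float
    p: float
    n_samples: int
    n_clusters: int
    is_dmp: bool


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        dep = [j for j, d in enumerate(np.abs(np.diag(R))) if d < 1e-10]
        raise ValidationError(f"singular design matrix; collinear column indices: {dep}")


def fit_clustered_ols(y: np.ndarray, X: np.ndarray, cluster_ids: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coefficients, cluster-robust covariance, two-sided p-values).

    Coefficients are plain OLS; only the covariance is clustered.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"n = {n} must exceed rank of X = {k}")
    _check_design(X)
    clusters, inv = np.unique(cluster_ids, return_inverse=True)
    G = len(clusters)
    if G < 2:
        raise ValidationError("need >= 2 clusters (one cluster holds all samples)")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    u = y - X @ beta
    # meat: sum over clusters of (X_g' u_g)(X_g' u_g)'
    Xu = X * u[:, None]
    sums = np.zeros((G, k))
    np.add.at(sums, inv, Xu)
    meat = sums.T @ sums
    correction = G / (G - 1) * (n - 1) / (n - k)
    cov = correction * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=G - 1)
    return beta, cov, p


def _exposure_vector(cov: pd.DataFrame, exposure: str) -> np.ndarray:
    col = cov[exposure]
    if exposure == "smoking_status" or col.dtype == object:
        if exposure == "smoking_status":
            # current = 1 vs {former, never} = 0
            return (col.astype(str) == "current").to_numpy(dtype=float)
        levels = sorted(col.dropna().unique())
        if len(levels) != 2:
            raise ValidationError(
                f"categorical exposure {exposure!r} must have 2 levels, got {levels}")
        return (col == levels[1]).to_numpy(dtype=float)
    return pd.to_numeric(col).to_numpy(dtype=float)


def run_ewas(betas: BetaMatrix, covariates: SampleCovariates, exposure: str,
             adjustments: list[str] | None = None,
             cluster: str = "family_id",
             dmp_threshold: float = 1e-7) -> pd.DataFrame:
    """Per-site model ``beta ~ exposure + adjustments`` with cluster-robust
    SEs; returns a frame sorted by p with an ``is_dmp`` flag.

    Singletons (samples without a co-twin) are ordinary one-member
    clusters.  Deterministic: no randomness anywhere.
    """
    cov = covariates.for_samples(betas.sample_ids)
    expo = _exposure_vector(cov, exposure)
    if np.nanstd(expo) == 0:
        raise ValidationError(f"exposure {exposure!r} is constant")
    if cluster not in cov.columns:
        raise ValidationError(f"cluster column {cluster!r} missing from covariates")
    cluster_ids = cov[cluster].astype(str).to_numpy()

    cols = [np.ones(len(expo)), expo]
    names = ["(intercept)", exposure]
    for adj in adjustments or []:
        c = cov[adj]
        if c.dtype == object:
            dummies = pd.get_dummies(c, prefix=adj, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy())
                names.append(name)
        else:
            cols.append(pd.to_numeric(c).to_numpy(dtype=float))
            names.append(adj)
    X = np.column_stack(cols)
    _check_design(X)
    n, k = X.shape
    clusters, inv = np.unique(cluster_ids, return_inverse=True)
    G = len(clusters)
    if G < 2:
        raise ValidationError("need >= 2 clusters")
    correction = G / (G - 1) * (n - 1) / (n - k)

    XtX_inv = np.linalg.inv(X.T @ X)
    proj = XtX_inv @ X.T                      # k x n
    z = proj[1]                               # row giving the exposure coefficient
    Y = betas.values                          # sites x n

    full = ~np.isnan(Y).any(axis=1)
    effects = np.full(betas.n_probes, np.nan)
    ses = np.full(betas.n_probes, np.nan)
    ns = np.full(betas.n_probes, n, dtype=int)
    gs = np.full(betas.n_probes, G, dtype=int)
    if full.any():
        Yf = Y[full]
        coefs = Yf @ proj.T                   # sites x k
        resid = Yf - coefs @ X.T
        zu = resid * z[None, :]               # sites x n
        gsum = np.zeros((full.sum(), G))
        np.add.at(gsum.T, inv, zu.T)
        var = correction * (gsum ** 2).sum(axis=1)
        effects[full] = coefs[:, 1]
        ses[full] = np.sqrt(var)
    for i in np.where(~full)[0]:
        m = ~np.isnan(Y[i])
        try:
            beta_i, cov_i, _ = fit_clustered_ols(Y[i, m], X[m], cluster_ids[m])
        except ValidationError:
            continue
        effects[i] = beta_i[1]
        ses[i] = math.sqrt(cov_i[1, 1])
        ns[i] = int(m.sum())
        gs[i] = len(np.unique(cluster_ids[m]))

    t = effects / ses
    p = 2.0 * stats.t.sf(np.abs(t), df=gs - 1)
    out = pd.DataFrame({
        "probe_id": betas.probe_ids,
        "effect": effects,
        "robust_se": ses,
        "t": t,
        "p": p,
        "n_samples": ns,
        "n_clusters": gs,
        "is_dmp": p < dmp_threshold,
    }).set_index("probe_id")
    return out.sort_values("p", kind="mergesort")


def _concordance_classes(manifest: PairManifest,
                         exposed: pd.Series) -> dict[str, PairManifest]:
    """Split pairs into concordant-unexposed / discordant /
    concordant-exposed manifests by the binary exposure labels."""
    e = exposed.astype(int)
    classes = {"concordant_unexposed": [], "discordant": [], "concordant_exposed": []}
    for _, rec in manifest.frame.iterrows():
        a, b = rec["sample_id_a"], rec["sample_id_b"]
        if a not in e.index or b not in e.index:
            continue
        s = int(e[a]) + int(e[b])
        key = ("concordant_unexposed", "discordant", "concordant_exposed")[s]
        classes[key].append(rec)
    return {k: PairManifest(pd.DataFrame(v)) if v else None
            for k, v in classes.items()}


def dmp_heritability_report(dmp_ids: list[str],
                            decomps: list[VarianceDecomposition] | pd.DataFrame,
                            betas: BetaMatrix, manifest: PairManifest,
                            exposed: pd.Series,
                            background_ids: list[str] | None = None) -> dict:
    """Heritability profile of an exposure's DMP set.

    Returns a dict with (i) A/C/E comparisons of DMPs vs background probes,
    (ii) among concordant-unexposed pairs the per-site rMZ vs rDZ counts
    and the exact sign test, and (iii) Falconer h2 per DMP within each
    exposure-concordance class.  Sections that lack enough pairs are
    replaced by a skip reason.
    """
    if not dmp_ids:
        raise ValidationError("empty DMP set")
    from .strata import decomp_frame  # local import to avoid cycle at module load
    df = decomps if isinstance(decomps, pd.DataFrame) else decomp_frame(decomps)

    background = (pd.Index(background_ids) if background_ids is not None
                  else df.index.difference(dmp_ids))
    membership = pd.Series(False, index=df.index)
    membership.loc[[p for p in dmp_ids if p in membership.index]] = True
    keep = membership.index.isin(dmp_ids) | membership.index.isin(background)
    comparisons = compare_strata(df.loc[keep], membership.loc[keep],
                                 label_in="DMP", label_out="background",
                                 method="asymptotic")

    report: dict = {"ace_comparison": comparisons}

    classes = _concordance_classes(manifest, exposed)
    dmp_in_matrix = [p for p in dmp_ids if p in set(betas.probe_ids)]
    sub = betas.subset_probes(dmp_in_matrix)

    cu = classes["concordant_unexposed"]
    if cu is None or cu.n_mz < 3 or cu.n_dz < 3:
        report["sign_test"] = {"skipped": "fewer than 3 concordant-unexposed "
                                          "pairs in a zygosity group"}
    else:
        corr = site_twin_correlations(sub, cu)
        ok = corr.dropna(subset=["r_MZ", "r_DZ"])
        k = int((ok["r_MZ"] > ok["r_DZ"]).sum())
        m = len(ok)
        report["sign_test"] = {
            "k_mz_greater": k, "m_sites": m,
            "result": exact_sign_test(k, m) if m >= 1 else None,
            "n_mz_pairs": cu.n_mz, "n_dz_pairs": cu.n_dz,
        }

    falconer: dict[str, pd.DataFrame | str] = {}
    for label, man in classes.items():
        if man is None or man.n_mz < 3 or man.n_dz < 3:
            falconer[label] = "skipped: fewer than 3 pairs per zygosity"
            continue
        corr = site_twin_correlations(sub, man)
        h2 = []
        for pid, row in corr.iterrows():
            if np.isnan(row["r_MZ"]) or np.isnan(row["r_DZ"]):
                h2.append(np.nan)
            else:
                h2.append(falconer_estimates(row["r_MZ"], row["r_DZ"])["h2"])
        falconer[label] = corr.assign(h2=h2)
    report["falconer_by_class"] = falconer
    return report
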