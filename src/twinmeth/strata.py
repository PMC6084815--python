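"""Comparisons of A/C/E distributions across probe strata, positional and
level profiles, and enrichment against external per-probe scores."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .ace import VarianceDecomposition
from .io import ProbeAnnotation, ValidationError

__all__ = [
    "StratumComparison",
    "EnrichmentResult",
    "compare_strata",
    "compare_strata_one",
    "mann_whitney",
    "positional_profile",
    "level_profile",
    "mqtl_enrichment",
    "covariation_stratified_heritability",
    "decomp_frame",
]


@dataclass(frozen=True)
class StratumComparison:
    component: str
    label1: str
    label2: str
    n1: int
    n2: int
    mean1: float   # percent scale
    sd1: float
    mean2: float
    sd2: float
    U: float
    p: float


@dataclass(frozen=True)
class EnrichmentResult:
    counts: tuple    # ((in_flagged, in_unflagged), (out_flagged, out_unflagged))
    prop_in: float
    prop_out: float
    odds_ratio: float
    p: float
    log10_p: float
    infinite_or: bool


def decomp_frame(decomps: list[VarianceDecomposition]) -> pd.DataFrame:
    """Tidy frame of decomposition records indexed by name (probe id)."""
    return pd.DataFrame(
        {
            "A": [d.A for d in decomps],
            "C": [d.C for d in decomps],
            "E": [d.E for d in decomps],
            "stratum": [d.stratum for d in decomps],
            "converged": [d.converged for d in decomps],
        },
        index=pd.Index([d.name for d in decomps], name="probe_id"),
    )


def _mwu_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating which pooled positions
    belong to the first sample.  Feasible for n1 + n2 <= ~16."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    total = 0
    extreme = 0
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    d_obs = abs(u_obs - mean_u)
    for combo in itertools.combinations(range(n), n1):
        u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mean_u) >= d_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def mann_whitney(x: np.ndarray, y: np.ndarray,
                 method: str = "auto") -> tuple[float, float]:
    """(U, two-sided p).  ``asymptotic`` uses the normal approximation with
    tie correction; ``exact`` enumerates rank assignments (small samples);
    ``auto`` picks exact when n1 + n2 <= 16."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both strata must be non-empty")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= 16 else "asymptotic"
    if method == "exact":
        return _mwu_exact_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_strata_one(values1: np.ndarray, values2: np.ndarray,
                       component: str, label1: str, label2: str,
                       method: str = "auto") -> StratumComparison:
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1 = v1[~np.isnan(v1)]
    v2 = v2[~np.isnan(v2)]
    if len(v1) == 0 or len(v2) == 0:
        raise ValidationError("a stratum has size 0")
    U, p = mann_whitney(v1, v2, method=method)
    return StratumComparison(
        component=component, label1=label1, label2=label2,
        n1=len(v1), n2=len(v2),
        mean1=float(v1.mean() * 100), sd1=float(v1.std(ddof=1) * 100) if len(v1) > 1 else 0.0,
        mean2=float(v2.mean() * 100), sd2=float(v2.std(ddof=1) * 100) if len(v2) > 1 else 0.0,
        U=U, p=max(p, np.nextafter(0, 1)),
    )


def compare_strata(decomps: list[VarianceDecomposition] | pd.DataFrame,
                   membership: pd.Series,
                   label_in: str = "in", label_out: str = "out",
                   method: str = "auto") -> list[StratumComparison]:
    """Mann-Whitney comparison of each of A, C, E between probes inside and
    outside a stratum.  ``membership`` is a boolean probe_id-indexed
    series; probes absent from it are excluded."""
    df = decomps if isinstance(decomps, pd.DataFrame) else decomp_frame(decomps)
    common = df.index.intersection(membership.index)
    if len(common) == 0:
        raise ValidationError("membership covers no decomposed probes")
    df = df.loc[common]
    flag = membership.loc[common].astype(bool)
    out = []
    for comp in ("A", "C", "E"):
        out.append(compare_strata_one(
            df.loc[flag, comp].to_numpy(), df.loc[~flag, comp].to_numpy(),
            comp, label_in, label_out, method=method))
    return out


def _windows(centers: np.ndarray, xs: np.ndarray, width: float,
             ys: pd.DataFrame, min_n: int) -> pd.DataFrame:
    rows = []
    half = width / 2.0
    for c in centers:
        inside = (xs >= c - half) & (xs < c + half)
        n = int(inside.sum())
        rec = {"center": float(c), "n": n}
        for col in ys.columns:
            if n >= min_n:
                w = ys.loc[inside, col]
                rec[f"mean_{col}"] = float(w.mean())
                rec[f"q025_{col}"] = float(w.quantile(0.025))
                rec[f"q975_{col}"] = float(w.quantile(0.975))
            else:
                rec[f"mean_{col}"] = np.nan
                rec[f"q025_{col}"] = np.nan
                rec[f"q975_{col}"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def positional_profile(decomps: list[VarianceDecomposition] | pd.DataFrame,
                       annotation: ProbeAnnotation,
                       window_bp: int = 500, step_bp: int = 100,
                       anchor: str = "TSS", min_n: int = 50,
                       max_distance: int = 100_000) -> pd.DataFrame:
    """Sliding-window mean A/C/E against signed distance from the anchor.

    Windows advance by ``step_bp``; a probe contributes to a window when
    its anchored distance lies in [center - window/2, center + window/2).
    Windows with fewer than ``min_n`` probes report NaN means.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValidationError("window and step must be positive")
    df = decomps if isinstance(decomps, pd.DataFrame) else decomp_frame(decomps)
    col = {"TSS": "tss_distance", "TES": "tes_distance"}.get(anchor)
    if col is None:
        raise ValidationError(f"unknown anchor {anchor!r}")
    if col not in annotation.frame.columns:
        raise ValidationError(f"annotation lacks {col!r}")
    dist = pd.to_numeric(annotation.frame[col], errors="coerce")
    common = df.index.intersection(dist.index)
    dist = dist.loc[common]
    keep = dist.abs() <= max_distance
    dist = dist[keep].dropna()
    df = df.loc[dist.index, ["A", "C", "E"]]
    xs = dist.to_numpy(dtype=float)
    if xs.size == 0:
        raise ValidationError("no probes with anchored distances")
    lo = step_bp * math.floor(xs.min() / step_bp)
    hi = step_bp * math.ceil(xs.max() / step_bp)
    centers = np.arange(lo, hi + step_bp / 2, step_bp)
    frame = df.set_axis(pd.RangeIndex(len(df)))
    return _windows(centers, xs, float(window_bp), frame, min_n)


def level_profile(x: pd.Series, y: pd.Series, window_width: float = 0.05,
                  step: float = 0.01, min_n: int = 50) -> pd.DataFrame:
    """Moving mean of y over windows of x with a 95% interquantile band."""
    if window_width <= 0 or step <= 0:
        raise ValidationError("window and step must be positive")
    common = x.index.intersection(y.index)
    xs = pd.to_numeric(x.loc[common], errors="coerce")
    ys = pd.to_numeric(y.loc[common], errors="coerce")
    ok = ~(xs.isna() | ys.isna())
    xs, ys = xs[ok].to_numpy(), ys[ok]
    if xs.size == 0:
        raise ValidationError("no probes with both x and y values")
    lo = step * math.floor(xs.min() / step)
    hi = step * math.ceil(xs.max() / step)
    centers = np.arange(lo, hi + step / 2, step)
    frame = ys.to_frame("y").set_axis(pd.RangeIndex(len(ys)))
    return _windows(centers, xs, window_width, frame, min_n)


def _fisher_exact_log(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p for a 2x2 table, summed in log space.

    Conditional on the margins, sums hypergeometric probabilities of all
    tables no more probable than the observed one.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (n - row1))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    logpmf = stats.hypergeom.logpmf(support, n, row1, col1)
    obs = float(stats.hypergeom.logpmf(a, n, row1, col1))
    keep = logpmf <= obs + 1e-7
    logp = float(min(logsumexp(logpmf[keep]), 0.0))
    return math.exp(logp), logp / math.log(10.0)


def mqtl_enrichment(decomps: list[VarianceDecomposition] | pd.DataFrame,
                    mqtl_flags: pd.Series, a_threshold: float = 0.8
                    ) -> EnrichmentResult:
    """2x2 enrichment of (A > threshold) x (has mQTL), Fisher exact.

    Probes without a flag entry are excluded (their count is implicit in
    the table margins vs the decomposition size).
    """
    df = decomps if isinstance(decomps, pd.DataFrame) else decomp_frame(decomps)
    common = df.index.intersection(mqtl_flags.index)
    if len(common) == 0:
        raise ValidationError("mQTL flags cover no decomposed probes")
    A = df.loc[common, "A"]
    flag = mqtl_flags.loc[common].astype(bool)
    high = A > a_threshold
    a_ = int((high & flag).sum())
    b_ = int((high & ~flag).sum())
    c_ = int((~high & flag).sum())
    d_ = int((~high & ~flag).sum())
    table = np.array([[a_, b_], [c_, d_]])
    infinite = (b_ == 0 and c_ > 0) or (c_ == 0 and b_ > 0) \
        or (a_ == 0 and d_ == 0) or (b_ == 0 and c_ == 0)
    if b_ * c_ == 0:
        orat = math.inf if a_ * d_ > 0 or (b_ == 0 and c_ == 0) else 0.0
        infinite = True
    else:
        orat = (a_ * d_) / (b_ * c_)
        infinite = False
    p, log10p = _fisher_exact_log(table)
    return EnrichmentResult(
        counts=((a_, b_), (c_, d_)),
        prop_in=a_ / (a_ + b_) if a_ + b_ else float("nan"),
        prop_out=c_ / (c_ + d_) if c_ + d_ else float("nan"),
        odds_ratio=orat, p=p, log10_p=log10p, infinite_or=infinite,
    )


def covariation_stratified_heritability(decomps: list[VarianceDecomposition] | pd.DataFrame,
                                        covariation_r: pd.Series,
                                        cutoff: float = 0.5,
                                        min_each: int = 10) -> dict:
    """Median A above/below a cross-tissue covariation cutoff, the
    Mann-Whitney comparison and the overall Pearson r(A, covariation)."""
    df = decomps if isinstance(decomps, pd.DataFrame) else decomp_frame(decomps)
    common = df.index.intersection(covariation_r.index)
    A = df.loc[common, "A"].astype(float)
    cv = pd.to_numeric(covariation_r.loc[common], errors="coerce")
    ok = ~(A.isna() | cv.isna())
    A, cv = A[ok], cv[ok]
    above = cv > cutoff
    if above.sum() < min_each or (~above).sum() < min_each:
        raise ValidationError(
            f"need >= {min_each} probes on each side of cutoff {cutoff}")
    _, p = mann_whitney(A[above].to_numpy(), A[~above].to_numpy(), method="asymptotic")
    r = float(np.corrcoef(A.to_numpy(), cv.to_numpy())[0, 1])
    return {
        "median_A_above": float(A[above].median()),
        "median_A_below": float(A[~above].median()),
        "n_above": int(above.sum()),
        "n_below": int((~above).sum()),
        "p": p,
        "pearson_r": r,
    }
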