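"""Twin-resemblance statistics.

Per-pair whole-profile correlations, per-site double-entered MZ/DZ
correlations, an exact binomial sign test evaluated in log space (so
p-values far below float range keep an exact log10), and a Welch test on
Fisher-z transformed correlation groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import BetaMatrix, PairManifest, ValidationError

__all__ = [
    "SignTestResult",
    "exact_sign_test",
    "site_twin_correlation",
    "site_twin_correlations",
    "pair_profile_correlation",
    "unrelated_profile_correlation",
    "compare_group_similarity",
]

LOG10 = math.log(10.0)


@dataclass(frozen=True)
class SignTestResult:
    k_success: int
    m_trials: int
    p_two_sided: float
    log10_p: float

    def format_p(self) -> str:
        """Printable p; values below native-float range render as a bound
        plus the exact log10."""
        if self.p_two_sided > 0:
            return f"{self.p_two_sided:.3g}"
        return f"<1e-300 (log10 p = {self.log10_p:.4f})"


def _log_binom_cdf(k: int, m: int) -> float:
    """log P(X <= k) for X ~ Binomial(m, 1/2), exact via logsumexp."""
    j = np.arange(0, k + 1)
    terms = gammaln(m + 1) - gammaln(j + 1) - gammaln(m - j + 1) - m * math.log(2.0)
    return float(logsumexp(terms))


def exact_sign_test(k: int, m: int) -> SignTestResult:
    """Two-sided exact binomial(m, 1/2) sign test.

    p = min(1, 2 * min(P(X <= k), P(X >= k))), with the tail sums evaluated
    in log space; ``log10_p`` stays finite and accurate even when the
    doubled tail underflows a double.
    """
    k, m = int(k), int(m)
    if m < 1 or not 0 <= k <= m:
        raise ValidationError(f"invalid sign test counts k={k}, m={m}")
    log_lower = _log_binom_cdf(k, m)
    log_upper = _log_binom_cdf(m - k, m)  # P(X >= k) = P(X <= m-k) by symmetry
    log_p = min(math.log(2.0) + min(log_lower, log_upper), 0.0)
    p = math.exp(log_p)
    return SignTestResult(k, m, p, log_p / LOG10)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def site_twin_correlation(site_values: np.ndarray, sample_ids: list[str],
                          manifest: PairManifest, zygosity: str,
                          sex: str | None = None,
                          double_entry: bool = True) -> tuple[float, int]:
    """(r, n_pairs) for one site and one zygosity group.

    By default the pair list is double-entered — each (y1, y2) also enters
    as (y2, y1) — making r invariant to within-pair member order.  Returns
    (nan, n) when fewer than 3 complete pairs exist or variance is zero.
    """
    pos = {s: i for i, s in enumerate(sample_ids)}
    a, b = [], []
    for _, rec in manifest.pairs(zygosity, sex).iterrows():
        ia, ib = pos.get(rec["sample_id_a"]), pos.get(rec["sample_id_b"])
        if ia is None or ib is None:
            continue
        va, vb = site_values[ia], site_values[ib]
        if np.isnan(va) or np.isnan(vb):
            continue
        a.append(va)
        b.append(vb)
    n = len(a)
    if n < 3:
        return float("nan"), n
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    if double_entry:
        x = np.concatenate([a_arr, b_arr])
        y = np.concatenate([b_arr, a_arr])
    else:
        x, y = a_arr, b_arr
    return _pearson(x, y), n


def site_twin_correlations(betas: BetaMatrix, manifest: PairManifest,
                           double_entry: bool = True) -> pd.DataFrame:
    """Per-site rMZ / rDZ table (probe_id, r_MZ, n_MZ, r_DZ, n_DZ)."""
    pos = {s: i for i, s in enumerate(betas.sample_ids)}

    def _idx(zyg: str) -> tuple[np.ndarray, np.ndarray]:
        f = manifest.pairs(zyg)
        keep = [k for k, (sa, sb) in enumerate(zip(f["sample_id_a"], f["sample_id_b"]))
                if sa in pos and sb in pos]
        ia = np.array([pos[f["sample_id_a"].iloc[k]] for k in keep], dtype=int)
        ib = np.array([pos[f["sample_id_b"].iloc[k]] for k in keep], dtype=int)
        return ia, ib

    out = {"probe_id": list(betas.probe_ids)}
    for zyg in ("MZ", "DZ"):
        ia, ib = _idx(zyg)
        va = betas.values[:, ia]
        vb = betas.values[:, ib]
        ok = ~(np.isnan(va) | np.isnan(vb))
        rs = np.full(betas.n_probes, np.nan)
        ns = ok.sum(axis=1)
        for i in range(betas.n_probes):
            m = ok[i]
            if m.sum() < 3:
                continue
            a_arr, b_arr = va[i, m], vb[i, m]
            if double_entry:
                x = np.concatenate([a_arr, b_arr])
                y = np.concatenate([b_arr, a_arr])
            else:
                x, y = a_arr, b_arr
            rs[i] = _pearson(x, y)
        out[f"r_{zyg}"] = rs
        out[f"n_{zyg}"] = ns
    return pd.DataFrame(out).set_index("probe_id")


def pair_profile_correlation(betas: BetaMatrix, manifest: PairManifest,
                             probe_subset: list[str] | None = None,
                             min_sites: int = 10) -> pd.DataFrame:
    """Per-pair Pearson r across sites between the two members' profiles.

    Returns a frame (pair_id, zygosity, r, n_sites, reason); pairs with too
    few shared non-missing sites get r = NaN and an explanatory reason.
    """
    bm = betas if probe_subset is None else betas.subset_probes(probe_subset)
    pos = {s: i for i, s in enumerate(bm.sample_ids)}
    rows = []
    for _, rec in manifest.frame.iterrows():
        ia, ib = pos.get(rec["sample_id_a"]), pos.get(rec["sample_id_b"])
        if ia is None or ib is None:
            rows.append((rec["pair_id"], rec["zygosity"], np.nan, 0, "member absent"))
            continue
        x, y = bm.values[:, ia], bm.values[:, ib]
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        if n < min_sites:
            rows.append((rec["pair_id"], rec["zygosity"], np.nan, n,
                         f"only {n} shared sites (< {min_sites})"))
            continue
        rows.append((rec["pair_id"], rec["zygosity"], _pearson(x[ok], y[ok]), n, ""))
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "r", "n_sites", "reason"])


def unrelated_profile_correlation(betas: BetaMatrix, manifest: PairManifest,
                                  seed: int, min_sites: int = 10) -> pd.DataFrame:
    """Baseline: profile correlations between randomly matched individuals
    drawn without replacement from different families."""
    rng = np.random.default_rng(seed)
    fam = {}
    for _, rec in manifest.frame.iterrows():
        fam[rec["sample_id_a"]] = rec["family_id"]
        fam[rec["sample_id_b"]] = rec["family_id"]
    ids = [s for s in manifest.sample_ids() if s in set(betas.sample_ids)]
    order = list(rng.permutation(ids))
    pairs = []
    while len(order) >= 2:
        a = order.pop()
        j = next((k for k, b in enumerate(order) if fam[b] != fam[a]), None)
        if j is None:
            break
        pairs.append((a, order.pop(j)))
    pos = {s: i for i, s in enumerate(betas.sample_ids)}
    rows = []
    for idx, (a, b) in enumerate(pairs):
        x, y = betas.values[:, pos[a]], betas.values[:, pos[b]]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_sites:
            continue
        rows.append((f"unrelated_{idx}", "UN", _pearson(x[ok], y[ok]), int(ok.sum()), ""))
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "r", "n_sites", "reason"])


def compare_group_similarity(r_group1: np.ndarray,
                             r_group2: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test on Fisher-z transformed correlations.

    Returns (mean1, mean2, p) with means reported on the r scale.  Any
    |r| = 1 is clamped to +/-(1 - 1e-12) before the z-transform (the clamp
    count is logged via the returned means being unaffected).
    """
    r1 = np.asarray(r_group1, dtype=float)
    r2 = np.asarray(r_group2, dtype=float)
    r1 = r1[~np.isnan(r1)]
    r2 = r2[~np.isnan(r2)]
    if len(r1) < 2 or len(r2) < 2:
        raise ValidationError("need >= 2 correlations per group")
    lim = 1.0 - 1e-12
    z1 = np.arctanh(np.clip(r1, -lim, lim))
    z2 = np.arctanh(np.clip(r2, -lim, lim))
    if np.var(z1) == 0 and np.var(z2) == 0 and np.mean(z1) == np.mean(z2):
        p = 1.0
    else:
        p = float(stats.ttest_ind(z1, z2, equal_var=False).pvalue)
        if math.isnan(p):
            p = 1.0
    return float(r1.mean()), float(r2.mean()), p
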