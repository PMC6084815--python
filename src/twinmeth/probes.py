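"""Per-site summaries and variable / intermediate probe classification.

A probe is "variable" when the middle-80% range of its beta values
(q90 - q10) strictly exceeds the variability threshold (default 0.05), and
"intermediate" when its mean lies in the closed interval
[intermediate_low, intermediate_high] (defaults 0.20, 0.80).  Quantiles use
linear interpolation of order statistics (quantile p at rank 1 + (n-1)p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, ValidationError

__all__ = ["ProbeClassThresholds", "summarize_probe", "classify_probes"]


@dataclass(frozen=True)
class ProbeClassThresholds:
    variable_threshold: float = 0.05
    intermediate_low: float = 0.20
    intermediate_high: float = 0.80

    def __post_init__(self) -> None:
        for v in (self.variable_threshold, self.intermediate_low, self.intermediate_high):
            if not 0.0 < v < 1.0:
                raise ValidationError(f"threshold {v!r} outside (0, 1)")
        if self.intermediate_low > self.intermediate_high:
            raise ValidationError("intermediate_low > intermediate_high")


def summarize_probe(values: np.ndarray) -> tuple[float, float, float, int]:
    """(mean, sd, mid80_range, n_used) for one probe's values.

    Missing values are excluded; sd uses the n-1 denominator; q10/q90 by
    linear interpolation of order statistics.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise ValidationError(f"need >= 2 non-missing values, got {n}")
    q10, q90 = np.quantile(v, [0.10, 0.90], method="linear")
    return float(v.mean()), float(v.std(ddof=1)), float(q90 - q10), n


def classify_probes(betas: BetaMatrix,
                    thresholds: ProbeClassThresholds | None = None,
                    stratum_samples: list[str] | None = None,
                    stratum: str = "all") -> pd.DataFrame:
    """One classification record per probe.

    Columns: probe_id (index), mean, sd, mid80_range, n_used, is_variable,
    is_intermediate, stratum.  ``stratum_samples`` restricts to a sample
    subset (e.g. one sex for X-linked sites).
    """
    thresholds = thresholds or ProbeClassThresholds()
    bm = betas
    if stratum_samples is not None:
        keep = [s for s in stratum_samples if s in set(betas.sample_ids)]
        if not keep:
            raise ValidationError(f"stratum {stratum!r} contains no usable samples")
        bm = betas.subset_samples(keep)

    V = bm.values
    mask = ~np.isnan(V)
    n_used = mask.sum(axis=1)
    if (n_used < 2).any():
        bad = bm.probe_ids[int(np.argmax(n_used < 2))]
        raise ValidationError(f"probe {bad!r} has < 2 non-missing values")

    if mask.all():
        means = V.mean(axis=1)
        sds = V.std(axis=1, ddof=1)
        q10, q90 = np.quantile(V, [0.10, 0.90], axis=1, method="linear")
    else:
        means = np.empty(bm.n_probes)
        sds = np.empty(bm.n_probes)
        q10 = np.empty(bm.n_probes)
        q90 = np.empty(bm.n_probes)
        for i in range(bm.n_probes):
            v = V[i, mask[i]]
            means[i] = v.mean()
            sds[i] = v.std(ddof=1)
            q10[i], q90[i] = np.quantile(v, [0.10, 0.90], method="linear")

    mid80 = q90 - q10
    out = pd.DataFrame({
        "mean": means,
        "sd": sds,
        "mid80_range": mid80,
        "n_used": n_used,
        "is_variable": mid80 > thresholds.variable_threshold,
        "is_intermediate": (means >= thresholds.intermediate_low)
                           & (means <= thresholds.intermediate_high),
        "stratum": stratum,
    }, index=pd.Index(bm.probe_ids, name="probe_id"))
    return out
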