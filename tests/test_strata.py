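import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from twinmeth.io import ValidationError
from twinmeth.simulate import synthetic_annotation
from twinmeth.strata import (compare_strata, compare_strata_one,
                             covariation_stratified_heritability,
                             level_profile, mann_whitney, mqtl_enrichment,
                             positional_profile)


def _decomp_df(A, index=None):
    A = np.asarray(A, dtype=float)
    idx = index if index is not None else [f"cg{i}" for i in range(len(A))]
    rest = (1 - A) / 2
    return pd.DataFrame({"A": A, "C": rest, "E": rest, "stratum": "all",
                         "converged": True},
                        index=pd.Index(idx, name="probe_id"))


def enumeration_mwu_p(x, y):
    """Independent oracle: distribution of U over all group assignments."""
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        x = np.full(6, 0.1)
        y = np.full(6, 0.9)
        U, p = mann_whitney(x, y)
        assert U in (0.0, 36.0)
        assert p == pytest.approx(enumeration_mwu_p(x, y))
        # closed form: 2 / C(12, 6)
        assert p == pytest.approx(2 / math.comb(12, 6))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_small(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(rng.integers(3, 8))
        y = rng.random(rng.integers(3, 8))
        _, p = mann_whitney(x, y, method="exact")
        assert p == pytest.approx(enumeration_mwu_p(x, y), rel=1e-12)

    def test_identical_strata_p_near_one(self):
        rng = np.random.default_rng(1)
        v = rng.random(100)
        c = compare_strata_one(v, v.copy(), "A", "s1", "s2", method="asymptotic")
        assert c.p > 0.9

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(40), rng.random(55) * 0.8
        c1 = compare_strata_one(x, y, "A", "x", "y", method="asymptotic")
        c2 = compare_strata_one(y, x, "A", "y", "x", method="asymptotic")
        assert c1.p == pytest.approx(c2.p, rel=1e-9)
        assert c1.mean1 == c2.mean2 and c1.mean2 == c2.mean1


class TestCompareStrata:
    def test_constructed_difference(self):
        rng = np.random.default_rng(3)
        A = np.concatenate([np.clip(rng.normal(0.4, 0.1, 200), 0, 1),
                            np.clip(rng.normal(0.1, 0.05, 200), 0, 1)])
        df = _decomp_df(A)
        member = pd.Series([True] * 200 + [False] * 200, index=df.index)
        comps = {c.component: c for c in compare_strata(df, member)}
        assert comps["A"].mean1 > comps["A"].mean2
        assert comps["A"].p < 0.01

    def test_means_on_percent_scale(self):
        df = _decomp_df([0.5] * 10 + [0.1] * 10)
        member = pd.Series([True] * 10 + [False] * 10, index=df.index)
        comps = {c.component: c for c in compare_strata(df, member,
                                                        method="asymptotic")}
        assert comps["A"].mean1 == pytest.approx(50.0)
        assert comps["A"].mean2 == pytest.approx(10.0)

    def test_empty_stratum_errors(self):
        df = _decomp_df([0.5, 0.2])
        member = pd.Series([True, True], index=df.index)
        with pytest.raises(ValidationError):
            compare_strata(df, member)


class TestPositionalProfile:
    def test_constant_component(self):
        df = _decomp_df(np.full(200, 0.3))
        ann = synthetic_annotation(df.index,
                                   tss_distances=np.linspace(-1000, 1000, 200))
        prof = positional_profile(df, ann, window_bp=200, step_bp=100, min_n=5)
        got = prof["mean_A"].dropna()
        assert len(got) > 5
        np.testing.assert_allclose(got, 0.3, atol=1e-12)

    def test_step_function_transition(self):
        dist = np.concatenate([np.linspace(-2000, -1, 300),
                               np.linspace(1, 2000, 300)])
        A = np.where(dist < 0, 0.1, 0.5)
        df = _decomp_df(A)
        ann = synthetic_annotation(df.index, tss_distances=dist)
        prof = positional_profile(df, ann, window_bp=200, step_bp=100, min_n=5)
        far_up = prof[prof["center"] <= -400]["mean_A"].dropna()
        far_down = prof[prof["center"] >= 400]["mean_A"].dropna()
        np.testing.assert_allclose(far_up, 0.1, atol=1e-12)
        np.testing.assert_allclose(far_down, 0.5, atol=1e-12)

    def test_sparse_window_is_missing_not_zero(self):
        dist = np.concatenate([np.full(60, -5000.0), np.full(60, 5000.0)])
        df = _decomp_df(np.full(120, 0.3))
        ann = synthetic_annotation(df.index, tss_distances=dist)
        prof = positional_profile(df, ann, window_bp=200, step_bp=1000, min_n=5)
        mid = prof[(prof["center"] > -4000) & (prof["center"] < 4000)]
        assert mid["mean_A"].isna().all()
        assert (mid["n"] == 0).all()

    def test_bad_window_rejected(self):
        df = _decomp_df([0.3, 0.4, 0.5])
        ann = synthetic_annotation(df.index, tss_distances=[0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            positional_profile(df, ann, window_bp=0, step_bp=100)

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(4)
        dist = rng.uniform(-3000, 3000, 150)
        A = rng.uniform(0, 1, 150)
        df = _decomp_df(A)
        ann = synthetic_annotation(df.index, tss_distances=dist)
        p1 = positional_profile(df, ann, window_bp=500, step_bp=250, min_n=3)
        perm = rng.permutation(len(df))
        p2 = positional_profile(df.iloc[perm], ann, window_bp=500, step_bp=250,
                                min_n=3)
        pd.testing.assert_frame_equal(p1, p2)


class TestLevelProfile:
    def test_constant_y(self):
        idx = pd.Index([f"cg{i}" for i in range(100)], name="probe_id")
        x = pd.Series(np.linspace(0, 1, 100), index=idx)
        y = pd.Series(np.full(100, 0.42), index=idx)
        prof = level_profile(x, y, window_width=0.2, step=0.1, min_n=5)
        got = prof.dropna(subset=["mean_y"])
        np.testing.assert_allclose(got["mean_y"], 0.42)
        np.testing.assert_allclose(got["q975_y"] - got["q025_y"], 0.0)

    def test_identity_curve(self):
        idx = pd.Index([f"cg{i}" for i in range(201)], name="probe_id")
        x = pd.Series(np.linspace(0, 1, 201), index=idx)
        prof = level_profile(x, x.copy(), window_width=0.1, step=0.05, min_n=5)
        inner = prof[(prof["center"] > 0.1) & (prof["center"] < 0.9)].dropna(
            subset=["mean_y"])
        np.testing.assert_allclose(inner["mean_y"], inner["center"], atol=0.01)

    def test_inverted_u_peak_central(self):
        idx = pd.Index([f"cg{i}" for i in range(400)], name="probe_id")
        x = pd.Series(np.linspace(0, 1, 400), index=idx)
        y = pd.Series(1 - (x - 0.5) ** 2 * 4, index=idx)
        prof = level_profile(x, y, window_width=0.1, step=0.05, min_n=5)
        best = prof.loc[prof["mean_y"].idxmax(), "center"]
        assert abs(best - 0.5) <= 0.1


def fisher_enumeration_p(a, b, c, d):
    """Exact rational hypergeometric oracle."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return (Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k),
                         math.comb(n, col1)))

    obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        q = pmf(k)
        if q <= obs:
            total += q
    return float(min(total, Fraction(1)))


class TestMqtlEnrichment:
    def test_toy_table_matches_enumeration(self):
        # 8 of 10 high-A flagged, 10 of 100 low-A flagged
        A = np.array([0.9] * 10 + [0.1] * 100)
        flags = pd.Series([True] * 8 + [False] * 2 + [True] * 10 + [False] * 90,
                          index=[f"cg{i}" for i in range(110)])
        df = _decomp_df(A)
        res = mqtl_enrichment(df, flags, a_threshold=0.8)
        assert res.counts == ((8, 2), (10, 90))
        assert res.p == pytest.approx(fisher_enumeration_p(8, 2, 10, 90), rel=1e-9)
        assert res.prop_in == pytest.approx(0.8)
        assert res.prop_out == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            a, b, c, d = rng.integers(0, 16, 4)
            if (a + b) > 0 and (c + d) > 0 and a + b + c + d <= 60:
                break
        A = np.array([0.9] * (a + b) + [0.1] * (c + d))
        flags = pd.Series([True] * a + [False] * b + [True] * c + [False] * d,
                          index=[f"cg{i}" for i in range(a + b + c + d)])
        res = mqtl_enrichment(_decomp_df(A), flags)
        assert res.p == pytest.approx(fisher_enumeration_p(a, b, c, d), rel=1e-9)

    def test_all_flagged(self):
        A = np.array([0.9] * 5 + [0.1] * 5)
        flags = pd.Series(True, index=[f"cg{i}" for i in range(10)])
        res = mqtl_enrichment(_decomp_df(A), flags)
        assert res.prop_in == 1.0 and res.prop_out == 1.0
        assert res.p == pytest.approx(1.0)

    def test_null_odds_ratio_near_one(self):
        rng = np.random.default_rng(5)
        ors = []
        for rep in range(10):
            A = rng.uniform(0, 1, 400)
            flags = pd.Series(rng.random(400) < 0.5,
                              index=[f"cg{i}" for i in range(400)])
            res = mqtl_enrichment(_decomp_df(A), flags)
            if np.isfinite(res.odds_ratio):
                ors.append(res.odds_ratio)
        assert np.median(ors) == pytest.approx(1.0, abs=0.5)

    def test_log10_p_finite_for_extreme_tables(self):
        A = np.array([0.9] * 500 + [0.1] * 500)
        flags = pd.Series([True] * 500 + [False] * 500,
                          index=[f"cg{i}" for i in range(1000)])
        res = mqtl_enrichment(_decomp_df(A), flags)
        assert res.p == 0.0 or res.p < 1e-200
        assert math.isfinite(res.log10_p) and res.log10_p < -200


class TestCovariationStratification:
    def _df(self, A):
        return _decomp_df(A)

    def test_score_equal_to_a_gives_r_one(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0, 1, 100)
        df = self._df(A)
        score = pd.Series(A, index=df.index)
        out = covariation_stratified_heritability(df, score, cutoff=0.5)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constructed_difference(self):
        rng = np.random.default_rng(7)
        A = np.concatenate([np.clip(rng.normal(0.6, 0.1, 300), 0, 1),
                            np.clip(rng.normal(0.1, 0.05, 300), 0, 1)])
        df = self._df(A)
        score = pd.Series([0.8] * 300 + [0.2] * 300, index=df.index)
        out = covariation_stratified_heritability(df, score)
        assert out["median_A_above"] - out["median_A_below"] > 0.3
        assert out["p"] < 1e-4

    def test_independent_score_small_difference(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, 600)
        df = self._df(A)
        score = pd.Series(rng.uniform(0, 1, 600), index=df.index)
        out = covariation_stratified_heritability(df, score)
        assert abs(out["median_A_above"] - out["median_A_below"]) < 0.15

    def test_one_sided_emptiness(self):
        df = self._df(np.linspace(0.1, 0.9, 30))
        score = pd.Series(0.9, index=df.index)
        with pytest.raises(ValidationError):
            covariation_stratified_heritability(df, score)
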