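"""Exact contingency tests, correlations, t-tests and the Table-1-style
cross-tabulations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tetrameth import cohort as coh
from tetrameth import synthetic as syn
from tetrameth.errors import DataError, ParameterError


def brute_force_fisher(a, b, c, d):
    """Exact two-sided p by enumeration of all tables with fixed margins,
    in exact rational arithmetic (minimum-likelihood rule)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(a_):
        return (
            math.comb(r1, a_) * math.comb(r2, c1 - a_),
            1,
        )

    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, a_) * math.comb(r2, c1 - a_)
        if w <= p_obs:
            total += w
    return total / denom


class TestFisherExact:
    def test_tp53_moderate_or_strong_vs_rest(self):
        assert coh.fisher_exact([[44, 32], [5, 18]]) == pytest.approx(0.0037, abs=5e-5)

    def test_kras_strong_vs_rest(self):
        assert coh.fisher_exact([[7, 0], [87, 54]]) == pytest.approx(0.048, abs=5e-4)

    def test_symmetric_table_p_one(self):
        assert coh.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DataError):
            coh.fisher_exact([[0, 0], [0, 0]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            coh.fisher_exact([[1, -1], [2, 3]])

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_equals_exhaustive_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert coh.fisher_exact([[a, b], [c, d]]) == pytest.approx(
            brute_force_fisher(a, b, c, d), rel=1e-9, abs=1e-12
        )

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_invariant_to_transposition_and_double_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = coh.fisher_exact([[a, b], [c, d]])
        assert coh.fisher_exact([[a, c], [b, d]]) == pytest.approx(p)
        assert coh.fisher_exact([[d, c], [b, a]]) == pytest.approx(p)


def table1_like_cohort():
    """A cohort whose class/TP53 cross-tabulation reproduces the printed
    counts: not-demethylated 44 WT / 32 MUT, moderate 5 WT / 11 MUT,
    strong 0 WT / 7 MUT."""
    rows = []
    spec = [("none", 44, 32), ("moderate", 5, 11), ("strong", 0, 7)]
    delta = {"none": 0.0, "moderate": 2.0, "strong": 4.0}
    for klass, n_wt, n_mut in spec:
        for i in range(n_wt):
            rows.append((klass, "WT"))
        for i in range(n_mut):
            rows.append((klass, "MUT"))
    df = pd.DataFrame(rows, columns=["class_sst1", "tp53"])
    df["patient_id"] = [f"P{i}" for i in range(len(df))]
    df["delta_rdl_sst1"] = df["class_sst1"].map(delta)
    df["delta_rdl_line1"] = 0.0
    return coh.CohortTable(df)


class TestCrosstab:
    def test_tp53_moderate_or_strong_contrast_reproduces_p(self):
        r = coh.crosstab(table1_like_cohort(), "tp53", "none_vs_rest")
        assert r.p_value == pytest.approx(0.0037, abs=5e-5)
        assert r.n_used == 99 and not r.degenerate

    def test_tp53_strong_vs_rest_table_and_p(self):
        r = coh.crosstab(table1_like_cohort(), "tp53", "strong_vs_rest")
        arr = r.table.as_array()
        # strong row: 0 WT, 7 MUT; rest row: 49 WT, 43 MUT
        assert sorted(arr[0].tolist()) == [0, 7]
        assert sorted(arr[1].tolist()) == [43, 49]
        assert r.p_value == pytest.approx(0.012, abs=5e-4)

    def test_none_vs_strong_contrast_excludes_moderate(self):
        r = coh.crosstab(table1_like_cohort(), "tp53", "none_vs_strong")
        assert r.n_used == 83
        assert r.p_value == pytest.approx(0.0037, abs=5e-4)

    def test_fully_missing_factor_degenerate(self):
        t = table1_like_cohort()
        t.data["kras"] = np.nan
        r = coh.crosstab(t, "kras", "none_vs_rest")
        assert r.degenerate and math.isnan(r.p_value)

    def test_counts_plus_missing_equal_cohort_size(self):
        t = table1_like_cohort()
        t.data.loc[t.data.index[:10], "tp53"] = np.nan
        r = coh.crosstab(t, "tp53", "none_vs_rest")
        assert r.n_used + r.n_missing == t.n
        assert int(r.table.as_array().sum()) == r.n_used

    def test_null_association_rejection_rate_is_nominal(self):
        """Fisher p is discrete and conservative, so exact uniformity fails;
        the operative calibration is the rejection rate at alpha."""
        ps = []
        for s in range(400):
            t, _ = syn.gen_cohort(
                syn.CohortSimSpec(n_patients=300, tp53_odds=1.0, seed=s)
            )
            ps.append(coh.crosstab(t, "gender", "none_vs_rest").p_value)
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.08
        assert 0.40 <= ps.mean() <= 0.65


class TestPearsonCi:
    def test_perfect_correlations(self):
        r, _, _ = coh.pearson_ci([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)
        r, _, _ = coh.pearson_ci([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_fisher_z_interval_matches_printed_span_scale(self):
        # construct a sample with empirical r exactly 0.51 at n=107
        rng = np.random.default_rng(0)
        x = rng.normal(size=107)
        e = rng.normal(size=107)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)  # orthogonalize
        e /= e.std()
        y = 0.51 * x + math.sqrt(1 - 0.51**2) * e
        r, (lo, hi), p = coh.pearson_ci(x, y)
        assert r == pytest.approx(0.51, abs=1e-9)
        assert lo == pytest.approx(0.355, abs=0.01)
        assert hi == pytest.approx(0.638, abs=0.01)
        assert p < 1e-7

    def test_coverage_of_true_correlation(self):
        rng = np.random.default_rng(1)
        rho, n, n_rep = 0.4, 80, 400
        hits = 0
        for _ in range(n_rep):
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
            _, (lo, hi), _ = coh.pearson_ci(x, y)
            hits += lo <= rho <= hi
        assert 0.92 <= hits / n_rep <= 0.98

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            coh.pearson_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestPairedT:
    def test_identical_vectors_p_one(self):
        assert coh.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_unit_shift_at_cohort_size_overwhelming(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=107)
        assert coh.paired_t(x + 1.0 + rng.normal(0, 1, 107) * 0, x) < 1e-15

    def test_noisy_unit_shift_significant(self):
        rng = np.random.default_rng(3)
        normal = rng.normal(size=107)
        tumor = normal + 1.0 + rng.normal(0, 1, 107)
        assert coh.paired_t(tumor, normal) < 1e-5

    def test_constant_nonzero_shift_error(self):
        with pytest.raises(DataError):
            coh.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestSummaryT:
    def test_clone_methylation_contrast(self):
        t, df, p = coh.summary_t(30.1, 2.8, 4, 43.6, 4.0, 8)
        assert df == 10
        assert 1.0e-4 / 1.5 <= p <= 1.0e-4 * 1.5

    def test_equal_means_p_one(self):
        t, _, p = coh.summary_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_ten_sd_separation(self):
        _, _, p = coh.summary_t(0.0, 1.0, 10, 10.0, 1.0, 10)
        assert p < 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            coh.summary_t(1.0, 1.0, 1, 2.0, 1.0, 5)
        with pytest.raises(ParameterError):
            coh.summary_t(1.0, 0.0, 5, 2.0, 1.0, 5)


class TestContinuousAssociation:
    def test_tp53_effect_detected_with_calibrated_nulls(self):
        """Cohorts where only TP53 carries signal: TP53 reaches alpha=0.05 in
        at least 90% of seeds while null factors reject near nominal rate."""
        tp53_hits = 0
        null_rej = []
        n_seeds = 30
        for s in range(n_seeds):
            t, _ = syn.gen_cohort(
                syn.CohortSimSpec(n_patients=2000, frac_strong=0.05, tp53_odds=10, seed=s)
            )
            res = coh.continuous_association(t)
            pf = res.per_factor.set_index("factor")["p"]
            tp53_hits += pf["tp53"] < 0.05
            null_rej.extend((pf.drop("tp53") < 0.05).tolist())
        assert tp53_hits / n_seeds >= 0.9
        assert np.mean(null_rej) < 0.12

    def test_constant_response_degenerate(self):
        t, _ = syn.gen_cohort(syn.CohortSimSpec(n_patients=50, seed=1))
        t.data["delta_rdl_sst1"] = 0.0
        res = coh.continuous_association(t)
        assert res.degenerate
        assert (res.per_factor["p"].dropna() == 1.0).all()

    def test_single_binary_factor_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(60)],
                "delta_rdl_sst1": rng.normal(size=60),
                "delta_rdl_line1": 0.0,
                "class_sst1": "none",
                "tp53": rng.choice(["WT", "MUT"], 60),
            }
        )
        df.loc[df.tp53 == "MUT", "delta_rdl_sst1"] += 0.8
        t = coh.CohortTable(df)
        res = coh.continuous_association(t, factors=["tp53"])
        g1 = df.loc[df.tp53 == "MUT", "delta_rdl_sst1"]
        g2 = df.loc[df.tp53 == "WT", "delta_rdl_sst1"]
        _, _, p_expected = coh.summary_t(
            g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
        )
        p_factor = res.per_factor.set_index("factor").loc["tp53", "p"]
        assert p_factor == pytest.approx(p_expected)
        # the joint OLS with the single factor carries the same t-test
        ols_p = res.ols_results.pvalues.iloc[1]
        assert ols_p == pytest.approx(p_expected, rel=1e-6)
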