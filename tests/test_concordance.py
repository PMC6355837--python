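import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methconcord import concordance as cc

from conftest import make_sheet


def spearman_enum_oracle(x, y):
    """Exhaustive permutation Spearman p, one permutation at a time."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(obs) - 1e-12
        total += 1
    return obs, count / total


class TestMeanProfile:
    def test_single_sample(self):
        b = pd.DataFrame({"s1": [0.1, 0.9]}, index=["a", "b"])
        pd.testing.assert_series_equal(cc.mean_profile(b), b["s1"], check_names=False)

    def test_mean_and_missing(self):
        b = pd.DataFrame([[0.2, 0.4, 0.6], [0.2, np.nan, 0.6]], index=["a", "b"])
        prof = cc.mean_profile(b)
        assert prof["a"] == pytest.approx(0.4)
        assert prof["b"] == pytest.approx(0.4)


class TestAcrossSubject:
    def test_identical_profiles(self):
        p = pd.Series([0.1, 0.5, 0.9])
        assert cc.across_subject_correlation(p, p)[0] == pytest.approx(1.0)

    def test_reversed(self):
        a = pd.Series([0.1, 0.2, 0.3])
        b = pd.Series([0.3, 0.2, 0.1])
        assert cc.across_subject_correlation(a, b)[0] == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self):
        a = pd.Series([0.1, 0.4, 0.5, 0.9])
        b = pd.Series([0.2, 0.3, 0.7, 0.8])
        n = 4
        sx, sy = a.sum(), b.sum()
        sxy = (a * b).sum()
        sxx, syy = (a**2).sum(), (b**2).sum()
        expected = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        got, n_used = cc.across_subject_correlation(a, b)
        assert n_used == 4
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_names_profile(self):
        a = pd.Series([0.5, 0.5, 0.5])
        b = pd.Series([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="profile_a"):
            cc.across_subject_correlation(a, b)

    def test_subset_reproduces_stratum(self):
        rng = np.random.default_rng(1)
        a = pd.Series(rng.random(20), index=[f"p{i}" for i in range(20)])
        b = pd.Series(rng.random(20), index=a.index)
        subset = [f"p{i}" for i in range(0, 20, 2)]
        r_sub, _ = cc.across_subject_correlation(a, b, subset)
        expected = np.corrcoef(a[subset], b[subset])[0, 1]
        assert r_sub == pytest.approx(expected, abs=1e-12)


class TestWithinSubject:
    def make_pair(self, a_vals, b_vals):
        subjects = [f"S{i}" for i in range(len(a_vals[0]))]
        sheet = make_sheet(subjects, ["x", "y"])
        ba = pd.DataFrame(a_vals, columns=[f"{s}_x" for s in subjects])
        bb = pd.DataFrame(b_vals, columns=[f"{s}_y" for s in subjects])
        return ba, bb, sheet

    def test_monotone_pair_exact_p(self):
        x = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
        y = x**2
        ba, bb, sheet = self.make_pair(x, y)
        (rec,) = cc.within_subject_correlations(ba, bb, sheet)
        assert rec.rho == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(2 / 720, abs=1e-15)

    def test_constant_vector_null_record(self):
        x = np.full((1, 6), 0.5)
        y = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
        ba, bb, sheet = self.make_pair(x, y)
        (rec,) = cc.within_subject_correlations(ba, bb, sheet)
        assert not rec.evaluable
        assert rec.n_pairs == 6

    def test_exact_matches_enumeration_oracle_n7(self, rng):
        x = rng.random((1, 7))
        y = rng.random((1, 7))
        ba, bb, sheet = self.make_pair(x, y)
        (rec,) = cc.within_subject_correlations(ba, bb, sheet)
        rho_o, p_o = spearman_enum_oracle(x[0], y[0])
        assert rec.rho == pytest.approx(rho_o, abs=1e-12)
        assert rec.p_value == pytest.approx(p_o, abs=1e-12)

    def test_too_few_pairs_is_null(self):
        x = np.random.default_rng(0).random((1, 6))
        y = np.random.default_rng(1).random((1, 6))
        x[0, :2] = np.nan
        ba, bb, sheet = self.make_pair(x, y)
        (rec,) = cc.within_subject_correlations(ba, bb, sheet)
        assert not rec.evaluable
        assert rec.n_pairs == 4

    def test_fast_path_matches_per_probe_path(self, rng):
        """The vectorized complete-case path must agree with scipy per probe."""
        n = 12
        x = rng.random((30, n))
        y = rng.random((30, n))
        ba, bb, sheet = self.make_pair(x, y)
        recs = cc.within_subject_correlations(ba, bb, sheet)
        for i, rec in enumerate(recs):
            rho, p = stats.spearmanr(x[i], y[i])
            assert rec.rho == pytest.approx(rho, abs=1e-12)
            assert rec.p_value == pytest.approx(p, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((5, 10))
        y = rng.random((5, 10))
        ba, bb, sheet = self.make_pair(x, y)
        r1 = cc.within_subject_correlations(ba, bb, sheet)
        # strictly monotone transform of tissue-a values preserves ranks
        ba2 = np.exp(3 * ba) / (1 + np.exp(3 * ba))
        r2 = cc.within_subject_correlations(ba2, bb, sheet)
        np.testing.assert_allclose([r.rho for r in r1], [r.rho for r in r2], atol=1e-12)


def variable_oracle(values, trim=0.10, min_range=0.05):
    """Brute-force sort-trim-range classifier."""
    vals = np.sort(np.asarray(values, dtype=float))
    lo = np.quantile(vals, trim)
    hi = np.quantile(vals, 1 - trim)
    kept = [v for v in vals if lo <= v <= hi]
    return (max(kept) - min(kept)) >= min_range


class TestClassifyVariable:
    def test_constant_not_variable(self):
        b = pd.DataFrame(np.full((1, 21), 0.3))
        assert not cc.classify_variable(b).iloc[0]

    def test_even_spread_variable(self):
        b = pd.DataFrame(np.linspace(0, 1, 21)[None, :])
        assert cc.classify_variable(b).iloc[0]

    def test_boundary_inclusive(self):
        """A post-trim range of exactly min_range counts as variable.

        With 21 values the 10th/90th percentiles land exactly on the 3rd and
        19th order statistics, so the post-trim range is exactly their
        difference."""
        vals = np.concatenate(
            [[0.0, 0.29, 0.30], np.linspace(0.305, 0.345, 15), [0.35, 0.40, 1.0]]
        )
        edge = float(0.35 - 0.30)  # the exact float the trimmed range equals
        b = pd.DataFrame(vals[None, :])
        flag = cc.classify_variable(b, trim=0.10, min_range=edge)
        assert bool(flag.iloc[0]) == variable_oracle(vals, min_range=edge)
        assert flag.iloc[0]
        # one ulp above the boundary flips the flag off
        assert not cc.classify_variable(b, trim=0.10, min_range=np.nextafter(edge, 1)).iloc[0]

    def test_matches_oracle_random(self, rng):
        vals = rng.random((200, 21)) * rng.uniform(0.02, 0.3, (200, 1))
        flags = cc.classify_variable(pd.DataFrame(vals))
        expected = [variable_oracle(row) for row in vals]
        assert flags.tolist() == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lowering_min_range_monotone(self, seed):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.random((20, 21)) * 0.2)
        strict = cc.classify_variable(vals, min_range=0.08)
        loose = cc.classify_variable(vals, min_range=0.03)
        assert (loose | ~strict).all()  # strict implies loose

    def test_bad_trim(self):
        with pytest.raises(ValueError):
            cc.classify_variable(pd.DataFrame([[0.1] * 5]), trim=0.6)


class TestBonferroni:
    def test_study_family_size(self):
        t = cc.bonferroni_threshold(0.05, 822_996)
        assert f"{t:.1e}" == "6.1e-08"

    def test_single_test(self):
        assert cc.bonferroni_threshold(0.05, 1) == 0.05

    def test_arithmetic(self):
        assert f"{cc.bonferroni_threshold(0.05, 450_000):.1e}" == "1.1e-07"


def make_records(rhos, ps, var_a=None, var_b=None):
    var_a = var_a or [False] * len(rhos)
    var_b = var_b or [False] * len(rhos)
    return [
        cc.CorrelationRecord(f"p{i}", r, p, 10, a, b)
        for i, (r, p, a, b) in enumerate(zip(rhos, ps, var_a, var_b))
    ]


class TestSummarize:
    def test_all_null_effects(self):
        recs = make_records([0.0] * 5, [1.0] * 5)
        s = cc.summarize(recs)
        assert s.prop_nominal == 0.0 and s.prop_moderate == 0.0 and s.mean_rho == 0.0

    def test_nominal_fraction(self):
        recs = make_records([0.1] * 10, [0.01] * 3 + [0.5] * 7)
        assert cc.summarize(recs).prop_nominal == pytest.approx(0.3)

    def test_null_records_excluded_from_denominator(self):
        recs = make_records([0.6, np.nan, 0.1], [0.01, np.nan, 0.9])
        s = cc.summarize(recs)
        assert s.n_cpgs == 2 and s.n_total == 3
        assert s.prop_nominal == pytest.approx(0.5)

    def test_restrict_variable_recount(self, rng):
        rhos = rng.uniform(-1, 1, 50)
        ps = rng.random(50)
        vb = list(rng.random(50) < 0.5)
        recs = make_records(list(rhos), list(ps), var_b=vb)
        s = cc.summarize(recs, restrict_variable="b")
        expected = np.mean([p < 0.05 for p, v in zip(ps, vb) if v])
        assert s.prop_nominal == pytest.approx(expected)
        assert s.n_total == sum(vb)

    def test_order_invariance(self, rng):
        recs = make_records(list(rng.uniform(-1, 1, 30)), list(rng.random(30)))
        s1 = cc.summarize(recs)
        s2 = cc.summarize(list(reversed(recs)))
        assert s1.prop_nominal == s2.prop_nominal and s1.mean_rho == s2.mean_rho

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cc.summarize([])


class TestDependentCorrelations:
    def test_equal_correlations_null(self):
        z, p = cc.compare_dependent_correlations(0.6, 0.6, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_study_scale_comparison_underflows(self):
        _, p = cc.compare_dependent_correlations(0.90, 0.86, 0.97, 822_996)
        assert p < 2.2e-16

    def test_sign_follows_difference(self):
        z_pos, _ = cc.compare_dependent_correlations(0.8, 0.6, 0.5, 100)
        z_neg, _ = cc.compare_dependent_correlations(0.6, 0.8, 0.5, 100)
        assert z_pos > 0 > z_neg
        assert z_pos == pytest.approx(-z_neg)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="r_common_a"):
            cc.compare_dependent_correlations(1.0, 0.5, 0.5, 50)
        with pytest.raises(ValueError, match="n"):
            cc.compare_dependent_correlations(0.5, 0.4, 0.3, 3)
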