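"""Eligibility rules and the statistical primitives against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppct import (
    SubjectRecord,
    apply_eligibility,
    bonferroni_alpha,
    chi_square_counts,
    ks_normality,
    pearson_r,
    percent_difference,
    two_sample_t,
)


def record(**overrides):
    base = dict(
        id="s1", group="control", cohort_role="teaching", age=68.0, sex="M",
        spherical_equivalent=0.5, astigmatism=0.5, bcva=0.05, iop=16.0,
        disc_area=1.9,
    )
    base.update(overrides)
    return SubjectRecord(**base)


class TestEligibility:
    def test_high_iop_excluded(self):
        res = apply_eligibility(record(iop=21.0))
        assert not res.eligible and res.reasons == ["IOP"]

    def test_all_boundaries_eligible(self):
        # IOP 20, SE 5.0 D, astigmatism 3.0 D, Snellen VA exactly 0.1
        res = apply_eligibility(
            record(iop=20.0, spherical_equivalent=5.0, astigmatism=3.0, bcva=1.0)
        )
        assert res.eligible

    def test_high_myopia_excluded(self):
        res = apply_eligibility(record(spherical_equivalent=-5.5))
        assert res.reasons == ["refraction"]

    def test_poor_acuity_excluded(self):
        # logMAR 1.3 is Snellen 0.05 < 0.1
        res = apply_eligibility(record(bcva=1.3))
        assert res.reasons == ["visual acuity"]

    def test_reasons_accumulate(self):
        res = apply_eligibility(record(iop=25.0, astigmatism=4.0))
        assert set(res.reasons) == {"IOP", "astigmatism"}

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="iop"):
            apply_eligibility(record(iop=None))

    def test_control_cannot_carry_severity(self):
        with pytest.raises(ValueError, match="severity"):
            record(updrs=20.0)


class TestStudentT:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # means 12 vs 22, each s^2 = 4, pooled s^2 = 4:
        # t = -10 / (2 sqrt(2/3)) = -6.1237, df = 4
        t, df, p = two_sample_t([10.0, 12.0, 14.0], [20.0, 22.0, 24.0])
        assert t == pytest.approx(-10 / (2 * np.sqrt(2 / 3)))
        assert df == 4

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_textbook_formula(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        if sp2 <= 0:
            return  # degenerate: both samples constant
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        t, df, _ = two_sample_t(x, y)
        assert t == pytest.approx(expected, rel=1e-9)
        assert df == len(x) + len(y) - 2

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_identical_sex_margins(self):
        chi2, df, p = chi_square_counts([[26, 14], [26, 14]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association(self):
        chi2, df, p = chi_square_counts([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    @given(st.lists(st.integers(1, 40), min_size=4, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_matches_definition_sum(self, cells):
        table = np.array(cells, dtype=float).reshape(2, 2)
        expected_cells = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected_cells) ** 2 / expected_cells).sum()
        chi2, _, _ = chi_square_counts(table)
        assert chi2 == pytest.approx(oracle, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_counts([[0, 0], [5, 5]])


class TestKSNormality:
    def test_normal_sample_passes(self, rng):
        x = rng.normal(100, 10, size=800)
        _, p = ks_normality(x)
        assert p > 0.05

    def test_normal_quantiles_near_zero_statistic(self):
        from scipy.stats import norm
        q = norm.ppf(np.linspace(0.005, 0.995, 200))
        d, _ = ks_normality(q)
        assert d < 0.05

    def test_uniform_sample_fails(self, rng):
        x = rng.uniform(0, 1, size=800)
        _, p = ks_normality(x)
        assert p < 0.05

    def test_degenerate_sample(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality([5.0] * 10)


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        oracle = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(oracle, rel=1e-9)

    def test_independent_samples_small_r(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        r, _ = pearson_r(x, y)
        assert abs(r) < 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSmallHelpers:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_bonferroni_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    @pytest.mark.parametrize(
        "case,control,expected",
        [(126.89, 96.53, 31.5), (100.0, 100.0, 0.0), (163.01, 131.51, 24.0)],
    )
    def test_percent_difference(self, case, control, expected):
        assert round(percent_difference(case, control), 1) == expected

    def test_percent_difference_invalid_control(self):
        with pytest.raises(ValueError):
            percent_difference(100.0, 0.0)
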