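import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from prevest import frequentist as fq
from prevest.datasim import CountData, MLEstimates


class TestRoganGladen:
    def test_worked_example_row(self):
        raw = fq.rogan_gladen(0.3993808, 0.74, 0.965)
        assert raw == pytest.approx(0.5168522, abs=1e-6)

    @pytest.mark.parametrize(
        "ap,se,sp,expected",
        [
            (0.035, 0.74, 0.965, 0.0),   # ap_hat = 1 - sp_hat
            (0.74, 0.74, 0.965, 1.0),    # ap_hat = se_hat
            (0.37, 1.0, 1.0, 0.37),      # perfect test: estimate is ap_hat
        ],
    )
    def test_endpoints(self, ap, se, sp, expected):
        assert fq.rogan_gladen(ap, se, sp) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            fq.rogan_gladen(0.4, 0.5, 0.5)


class TestTruncate:
    @pytest.mark.parametrize("v,expected", [(-0.1, 0.0), (1.2, 1.0), (0.517, 0.517)])
    def test_examples(self, v, expected):
        assert fq.truncate_unit(v) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fq.truncate_unit(float("nan"))

    @given(st.floats(-5, 5))
    @settings(derandomize=True, max_examples=100)
    def test_idempotent_and_bounded(self, v):
        t = fq.truncate_unit(v)
        assert 0.0 <= t <= 1.0
        assert fq.truncate_unit(t) == t


class TestExactBinomialIntervals:
    def test_clopper_pearson_closed_form_at_zero(self):
        lo, hi = fq.exact_binomial_ci(0, 20, 0.95, "clopper_pearson")
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-10)

    @pytest.mark.parametrize("ordering", ["clopper_pearson", "sterne", "blaker"])
    def test_upper_is_one_at_full_count(self, ordering):
        lo, hi = fq.exact_binomial_ci(20, 20, 0.95, ordering)
        assert hi == 1.0
        assert 0.0 < lo < 1.0

    def test_clopper_pearson_matches_independent_oracle(self):
        res = stats.binomtest(129, 323).proportion_ci(confidence_level=0.95, method="exact")
        lo, hi = fq.exact_binomial_ci(129, 323, 0.95, "clopper_pearson")
        assert lo == pytest.approx(res.low, abs=1e-6)
        assert hi == pytest.approx(res.high, abs=1e-6)

    def test_clopper_pearson_is_conservative_everywhere(self):
        # exact coverage by binomial sums over a fine grid, all n <= 25
        grid = np.linspace(0.0005, 0.9995, 999)
        for n in range(1, 26):
            lo, hi = fq.clopper_pearson_interval(np.arange(n + 1), np.full(n + 1, n), 0.95)
            pmf = stats.binom.pmf(np.arange(n + 1)[:, None], n, grid[None, :])
            covered = (lo[:, None] <= grid[None, :]) & (grid[None, :] <= hi[:, None])
            coverage = np.sum(pmf * covered, axis=0)
            assert np.all(coverage >= 0.95 - 1e-12)

    @pytest.mark.parametrize("n", [5, 17, 40, 73, 100])
    def test_blaker_nested_within_clopper_pearson(self, n):
        for x in range(n + 1):
            cp = fq.clopper_pearson_interval(x, n, 0.95)
            bl = fq.blaker_interval(x, n, 0.95)
            assert bl[0] >= cp[0] - 1e-7
            assert bl[1] <= cp[1] + 1e-7

    @pytest.mark.parametrize("ordering", ["sterne", "blaker"])
    @pytest.mark.parametrize("x,n", [(3, 20), (0, 20), (17, 60), (129, 323)])
    def test_inversion_consistent_with_its_test(self, ordering, x, n):
        lo, hi = fq.exact_binomial_ci(x, n, 0.95, ordering)
        assert 0 <= lo <= x / n <= hi <= 1
        # p-values just inside the interval exceed alpha; just outside fall below
        eps = 1e-4
        if lo > 0:
            assert fq.exact_test_pvalue(x, n, lo + eps, ordering) > 0.05
            assert fq.exact_test_pvalue(x, n, max(lo - eps, 1e-9), ordering) <= 0.05 + 1e-6
        if hi < 1:
            assert fq.exact_test_pvalue(x, n, hi - eps, ordering) > 0.05
            assert fq.exact_test_pvalue(x, n, min(hi + eps, 1 - 1e-9), ordering) <= 0.05 + 1e-6

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            fq.exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            fq.exact_binomial_ci(1, 4, ordering="wilson")


class TestTransform:
    def test_endpoint_map_gives_unit_interval(self):
        est = fq.transform_ap_interval((0.035, 0.74), 0.74, 0.965, point_raw=0.5)
        assert (est.lower, est.upper) == (0.0, 1.0)

    def test_identity_under_perfect_test(self):
        est = fq.transform_ap_interval((0.2, 0.4), 1.0, 1.0, point_raw=0.3)
        assert est.lower == pytest.approx(0.2) and est.upper == pytest.approx(0.4)

    def test_linear_map_arithmetic(self):
        est = fq.transform_ap_interval((0.35, 0.45), 0.74, 0.965, point_raw=0.5)
        assert est.lower == pytest.approx(0.44681, abs=1e-5)
        assert est.upper == pytest.approx(0.58865, abs=1e-5)

    def test_truncation_order_invariance(self):
        # truncating endpoints then reporting equals reporting then truncating
        se, sp = 0.74, 0.965
        for lo, hi in [(0.0, 0.9), (0.02, 0.5), (0.5, 0.99)]:
            est = fq.transform_ap_interval((lo, hi), se, sp, point_raw=0.5)
            denom = se - (1 - sp)
            raw_lo = (lo - (1 - sp)) / denom
            raw_hi = (hi - (1 - sp)) / denom
            assert est.lower == fq.truncate_unit(raw_lo)
            assert est.upper == fq.truncate_unit(raw_hi)
            assert est.lower <= est.upper

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            fq.transform_ap_interval((0.2, 0.4), 0.5, 0.5, point_raw=0.1)


class TestWaldRoganGladen:
    def test_full_variance_half_width_matches_independent_recomputation(self):
        m = MLEstimates(0.74, 0.965, 129 / 323)
        est = fq.wald_rogan_gladen_ci(m, (323, 100, 200), 0.95,
                                      include_validation_uncertainty=True)
        pi_hat = min(max((m.ap_hat - 0.035) / 0.705, 0.0), 1.0)
        var = (
            m.ap_hat * (1 - m.ap_hat) / 323
            + pi_hat**2 * 0.74 * 0.26 / 100
            + (1 - pi_hat) ** 2 * 0.965 * 0.035 / 200
        ) / 0.705**2
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        assert est.upper - est.point == pytest.approx(half, abs=1e-8)
        assert est.point - est.lower == pytest.approx(half, abs=1e-8)

    def test_reduces_to_plain_wald_with_perfect_known_test(self):
        m = MLEstimates(1.0 - 1e-12, 1.0 - 1e-12, 0.4)
        est = fq.wald_rogan_gladen_ci(m, (100, 10**12, 10**12), 0.95)
        half = stats.norm.ppf(0.975) * np.sqrt(0.4 * 0.6 / 100)
        assert est.upper - est.lower == pytest.approx(2 * half, rel=1e-5)

    def test_containment_after_truncation(self):
        m = MLEstimates(0.62, 0.61, 0.9)  # case3: raw estimate > 1
        for full in (False, True):
            est = fq.wald_rogan_gladen_ci(m, (50, 50, 50), 0.95,
                                          include_validation_uncertainty=full)
            assert 0 <= est.lower <= est.point <= est.upper <= 1

    def test_default_interval_nested_in_full_variance_interval(self):
        m = MLEstimates(0.74, 0.965, 129 / 323)
        known = fq.wald_rogan_gladen_ci(m, (323, 100, 200))
        full = fq.wald_rogan_gladen_ci(m, (323, 100, 200),
                                       include_validation_uncertainty=True)
        assert full.lower <= known.lower <= known.upper <= full.upper
        assert full.length > known.length


class TestLangReiczigel:
    def test_converges_to_wald_rg_for_huge_samples(self):
        big = 10**7
        x, x_se, x_sp = int(0.4 * big), int(0.9 * big), int(0.95 * big)
        c = CountData(1, 1, x_se=x_se, x_sp=x_sp, x=x)
        lr = fq.lang_reiczigel_ci(c, (big, big, big), 0.95)
        m = MLEstimates(0.9, 0.95, 0.4)
        w = fq.wald_rogan_gladen_ci(m, (big, big, big), 0.95,
                                    include_validation_uncertainty=True)
        assert lr.lower == pytest.approx(w.lower, abs=1e-5)
        assert lr.upper == pytest.approx(w.upper, abs=1e-5)

    def test_zero_count_truncates_lower_endpoint_to_zero(self):
        c = CountData(1, 1, x_se=90, x_sp=98, x=0)
        est = fq.lang_reiczigel_ci(c, (50, 100, 100), 0.95)
        assert est.lower == 0.0

    def test_degenerate_adjusted_test_rejected(self):
        # raw MLEs barely above chance collapse below it after adjustment:
        # the small sensitivity study shrinks hard, the big specificity one barely
        c = CountData(1, 1, x_se=26, x_sp=2403, x=10)
        with pytest.raises(ValueError):
            fq.lang_reiczigel_ci(c, (50, 50, 5000), 0.95)

    def test_adjustment_constants_are_configurable(self):
        c = CountData(1, 1, x_se=74, x_sp=193, x=129)
        default = fq.lang_reiczigel_ci(c, (323, 100, 200))
        alt = fq.lang_reiczigel_ci(c, (323, 100, 200),
                                   adjustment=fq.LangReiczigelAdjustment(se_add=2.0, sp_add=2.0))
        assert default.lower != alt.lower
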