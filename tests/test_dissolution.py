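import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from formsim.dissolution import (
    DissolutionProfile,
    DoubleWeibull,
    eval_double_weibull,
    f2,
    f2_bootstrap,
    fit_double_weibull,
)
from formsim.errors import InsufficientDataError, InvalidParameterError


def single_weibull(fmax, scale, shape, lag=0.0):
    return DoubleWeibull(fmax=fmax, w1=1.0, scale1=scale, shape1=shape, lag=lag)


class TestEvalDoubleWeibull:
    def test_zero_at_time_zero_without_lag(self):
        p = single_weibull(100, 1, 1)
        assert eval_double_weibull(p, 0.0) == 0.0

    def test_asymptote_reaches_fmax(self):
        p = single_weibull(100, 1, 1)
        assert eval_double_weibull(p, 1e6) == pytest.approx(100.0)

    def test_closed_form_exponential_point(self):
        # fmax=100, scale=2, shape=1 at t=2 -> 100*(1 - e^-1)
        p = single_weibull(100, 2, 1)
        assert eval_double_weibull(p, 2.0) == pytest.approx(100 * (1 - math.exp(-1)),
                                                            abs=1e-10)

    def test_zero_before_lag(self):
        p = single_weibull(100, 1, 1, lag=2.0)
        assert eval_double_weibull(p, 1.5) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            DoubleWeibull(fmax=float("nan"), w1=1, scale1=1, shape1=1)
        with pytest.raises(InvalidParameterError):
            DoubleWeibull(fmax=100, w1=1.5, scale1=1, shape1=1)
        with pytest.raises(InvalidParameterError):
            DoubleWeibull(fmax=100, w1=1, scale1=-1, shape1=1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(fmax=st.floats(10, 110), w1=st.floats(0, 1),
           s1=st.floats(0.1, 50), sh1=st.floats(0.25, 4),
           s2=st.floats(0.1, 50), sh2=st.floats(0.25, 4),
           lag=st.floats(0, 2))
    def test_release_monotone_and_bounded(self, fmax, w1, s1, sh1, s2, sh2, lag):
        """Cumulative release never decreases and never exceeds fmax."""
        p = DoubleWeibull(fmax=fmax, w1=w1, scale1=s1, shape1=sh1,
                          scale2=s2, shape2=sh2, lag=lag)
        t = np.linspace(0, 100, 400)
        y = p.release(t)
        assert np.all(np.diff(y) >= -1e-9)
        assert np.all(y <= fmax + 1e-9)
        assert np.all(y >= 0)


class TestProfileValidation:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(InvalidParameterError):
            DissolutionProfile(times=[1, 1, 2], released=[1, 2, 3])

    def test_rejects_out_of_range_release(self):
        with pytest.raises(InvalidParameterError):
            DissolutionProfile(times=[1, 2], released=[0, 120])

    def test_monotone_cleanup(self):
        p = DissolutionProfile(times=[1, 2, 3], released=[10, 9, 30],
                               monotone_cleanup=True)
        assert list(p.released) == [10, 10, 30]


class TestFitDoubleWeibull:
    def test_recovers_single_weibull_parameters(self):
        truth = single_weibull(80, 3, 1.2)
        t = np.array([0.5, 1, 2, 4, 8, 13])  # 6 points -> reduced model
        prof = DissolutionProfile(times=t, released=truth.release(t))
        fit = fit_double_weibull(prof)
        assert fit.single_phase
        assert fit.params.fmax == pytest.approx(80, rel=0.01)
        assert fit.params.scale1 == pytest.approx(3, rel=0.01)
        assert fit.params.shape1 == pytest.approx(1.2, rel=0.01)

    def test_noise_free_curve_recovered_pointwise(self):
        truth = single_weibull(77, 2, 1.5)
        t = np.array([0.25, 0.5, 1, 2, 4, 8, 13])
        prof = DissolutionProfile(times=t, released=truth.release(t))
        fit = fit_double_weibull(prof)
        grid = np.linspace(0, 24, 200)
        assert np.max(np.abs(fit.params.release(grid) - truth.release(grid))) < 0.1

    def test_all_zero_profile_flagged_degenerate(self):
        prof = DissolutionProfile(times=[1, 2, 3], released=[0, 0, 0])
        fit = fit_double_weibull(prof)
        assert fit.degenerate
        assert fit.params.fmax == pytest.approx(0, abs=1e-9)

    def test_biphasic_fit_quality_with_noise(self, rng):
        truth = DoubleWeibull(fmax=90, w1=0.45, scale1=0.5, shape1=1.2,
                              scale2=6.0, shape2=1.8)
        t = np.array([0.25, 0.5, 1, 2, 4, 8, 12, 16])
        y = np.clip(truth.release(t) + rng.normal(0, 1.0, size=t.size), 0, 110)
        prof = DissolutionProfile(times=t, released=y, monotone_cleanup=True)
        fit = fit_double_weibull(prof)
        assert not fit.single_phase
        assert fit.r2 > 0.97

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_double_weibull(DissolutionProfile(times=[1, 2], released=[10, 20]))


class TestF2:
    def test_identical_profiles_give_100(self):
        p = DissolutionProfile(times=[1, 2, 3], released=[20, 40, 60])
        res = f2(p, p)
        assert res.f2 == pytest.approx(100.0)
        assert res.similar

    def test_reference_vs_optimized_worked_example(self):
        ref = DissolutionProfile(times=[1, 2.5, 13], released=[23, 58, 77])
        tst = DissolutionProfile(times=[1, 2.5, 13], released=[22, 55, 76])
        res = f2(ref, tst)
        assert res.f2 > 50
        # direct evaluation: msd = (1+9+1)/3
        expected = 50 * math.log10(100 / math.sqrt(1 + 11 / 3))
        assert res.f2 == pytest.approx(expected, abs=1e-12)

    def test_uniform_ten_point_difference_rounds_to_50(self):
        t = [1, 2, 4, 6]
        ref = DissolutionProfile(times=t, released=[20, 40, 60, 80])
        tst = DissolutionProfile(times=t, released=[10, 30, 50, 70])
        res = f2(ref, tst)
        assert round(res.f2) == 50

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=3, max_size=8))
    def test_matches_direct_formula(self, pairs):
        """Module f2 equals a one-line evaluation of the defining formula."""
        r = np.array([p[0] for p in pairs])
        t = np.array([p[1] for p in pairs])
        times = np.arange(1, len(pairs) + 1, dtype=float)
        # keep clear of the >85% truncation so all points enter the formula
        r, t = r * 0.8, t * 0.8
        res = f2(DissolutionProfile(times=times, released=r),
                 DissolutionProfile(times=times, released=t))
        direct = 50 * math.log10(100 * (1 + np.mean((r - t) ** 2)) ** -0.5)
        assert res.f2 == pytest.approx(direct, abs=1e-12)

    def test_f2_decreases_as_differences_grow(self):
        t = [1, 2, 3]
        base = np.array([30.0, 50.0, 70.0])
        diffs = np.array([2.0, 3.0, 4.0])
        prev = math.inf
        for k in (0.5, 1.0, 2.0, 3.0):
            res = f2(DissolutionProfile(times=t, released=base),
                     DissolutionProfile(times=t, released=base + k * diffs))
            assert res.f2 < prev
            prev = res.f2

    def test_at_most_one_point_kept_above_85(self):
        t = [1, 2, 3, 4, 5]
        ref = DissolutionProfile(times=t, released=[40, 60, 88, 92, 95])
        tst = DissolutionProfile(times=t, released=[42, 63, 89, 93, 96])
        res = f2(ref, tst)
        assert res.n_points == 3  # 40/60 points plus the first both->85 point

    def test_insufficient_common_timepoints(self):
        a = DissolutionProfile(times=[1, 2, 3], released=[10, 20, 30])
        b = DissolutionProfile(times=[1.5, 2.5, 3.5], released=[10, 20, 30])
        with pytest.raises(InsufficientDataError):
            f2(a, b)


class TestF2Bootstrap:
    def test_identical_vessels_collapse_ci(self):
        t = [1, 2, 3]
        vessels = [DissolutionProfile(times=t, released=[20, 40, 60],
                                      vessel_id=f"v{i}") for i in range(12)]
        res = f2_bootstrap(vessels, vessels, n_boot=50, seed=0)
        assert res.bootstrap_ci == (pytest.approx(100.0), pytest.approx(100.0))

    def test_null_difference_lower_bound_above_50(self, ref_weibull, rng):
        t = np.array([0.5, 1, 2.5, 5, 13])
        clean = ref_weibull.release(t)

        def vessels(n):
            return [DissolutionProfile(
                times=t,
                released=np.maximum.accumulate(
                    np.clip(clean + rng.normal(0, 1.0, t.size), 0, 100)))
                for _ in range(n)]

        res = f2_bootstrap(vessels(12), vessels(12), n_boot=2000, seed=3)
        assert res.bootstrap_ci[0] > 50
        assert res.similar

    def test_seed_reproducibility(self):
        t = [1, 2, 3]
        arm = [DissolutionProfile(times=t, released=[20 + i, 40 + i, 60 + i])
               for i in range(4)]
        r1 = f2_bootstrap(arm, arm, n_boot=200, seed=11)
        r2 = f2_bootstrap(arm, arm, n_boot=200, seed=11)
        assert r1.bootstrap_ci == r2.bootstrap_ci

    def test_single_vessel_rejected(self):
        t = [1, 2, 3]
        one = [DissolutionProfile(times=t, released=[20, 40, 60])]
        with pytest.raises(InsufficientDataError):
            f2_bootstrap(one, one, n_boot=10, seed=0)
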