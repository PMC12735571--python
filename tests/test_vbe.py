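import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from formsim.absorption_pbpk import ReleaseInput, default_config
from formsim.dissolution import DoubleWeibull
from formsim.errors import InvalidParameterError
from formsim.vbe import (
    VBE_PARAMETERS,
    VariabilitySpec,
    build_population,
    crossover_be,
    risk_tier,
    run_trial,
    run_vbe_study,
    sample_size_step,
)


@pytest.fixture()
def fast_base():
    cfg = default_config()
    cfg.duration, cfg.grid = 48.0, 0.1
    return cfg


@pytest.fixture()
def releases(ref_weibull, opt_weibull):
    return (ReleaseInput(mode="xr_weibull", weibull=opt_weibull),
            ReleaseInput(mode="xr_weibull", weibull=ref_weibull))


class TestBuildPopulation:
    def test_zero_cv_gives_unit_multipliers(self):
        pop = build_population(VariabilitySpec.zero(), 5, seed=0)
        for s in pop:
            assert all(v == 1.0 for v in s.bsv.values())
            for period in s.wsv:
                assert all(v == 1.0 for v in period.values())

    def test_empirical_cv_matches_target(self):
        spec = VariabilitySpec(cvs={"peff": (30.0, 30.0)})
        pop = build_population(spec, 10000, seed=1)
        mults = np.array([s.bsv["peff"] for s in pop])
        cv = mults.std(ddof=1) / mults.mean()
        assert abs(cv * 100 - 30.0) < 1.0
        # median-1 log-normal: mean of logs ~ 0
        assert abs(np.mean(np.log(mults))) < 0.01

    def test_seed_reproducibility(self):
        a = build_population(VariabilitySpec(), 6, seed=9)
        b = build_population(VariabilitySpec(), 6, seed=9)
        for s1, s2 in zip(a, b):
            assert s1.bsv == s2.bsv and s1.wsv == s2.wsv

    def test_default_cvs_are_the_tuned_donepezil_set(self):
        spec = VariabilitySpec()
        assert spec.cvs["cyp3a4_vmax"] == (15.0, 15.0)
        assert spec.cvs["stomach_transit_time"] == (35.0, 35.0)
        assert spec.cvs["peff"] == (30.0, 30.0)
        assert spec.cvs["weibscale1"] == (5.0, 5.0)
        assert spec.cvs["fmax"] == (3.2, 3.2)
        assert set(spec.cvs) == set(VBE_PARAMETERS)


class TestCrossoverStatistics:
    def test_matches_ols_crossover_oracle(self):
        """GMR and CI equal the fixed-effects sequence+period+subject OLS fit."""
        rng = np.random.default_rng(7)
        n = 12
        seqs = np.array(["TR"] * (n // 2) + ["RT"] * (n // 2))
        subj_eff = rng.normal(0, 0.3, n)
        true_diff = math.log(0.95)
        period_eff = 0.05
        log_r = 3.0 + subj_eff + rng.normal(0, 0.1, n)
        log_t = 3.0 + true_diff + subj_eff + rng.normal(0, 0.1, n)
        # apply the period effect to whichever value sits in period 2
        log_t_adj = log_t + np.where(seqs == "TR", 0.0, period_eff)
        log_r_adj = log_r + np.where(seqs == "TR", period_eff, 0.0)

        res = crossover_be(log_t_adj, log_r_adj, seqs)

        # independent oracle: OLS with sequence, period and subject dummies
        import statsmodels.formula.api as smf
        rows = []
        for i in range(n):
            t_period = 1 if seqs[i] == "TR" else 2
            rows.append({"y": log_t_adj[i], "subj": i, "seq": seqs[i],
                         "period": t_period, "trt": "T"})
            rows.append({"y": log_r_adj[i], "subj": i, "seq": seqs[i],
                         "period": 3 - t_period, "trt": "R"})
        df = pd.DataFrame(rows)
        fit = smf.ols("y ~ C(trt, Treatment('R')) + C(period) + C(subj)",
                      data=df).fit()
        est = fit.params["C(trt, Treatment('R'))[T.T]"]
        ci = fit.conf_int(alpha=0.10).loc["C(trt, Treatment('R'))[T.T]"]
        assert res.gmr == pytest.approx(math.exp(est), abs=1e-9)
        assert res.ci90[0] == pytest.approx(math.exp(ci[0]), abs=1e-9)
        assert res.ci90[1] == pytest.approx(math.exp(ci[1]), abs=1e-9)

    def test_degenerate_interval_when_no_residual_variance(self):
        log_r = np.array([1.0, 1.2, 0.9, 1.1])
        log_t = log_r + 0.1
        res = crossover_be(log_t, log_r, np.array(["TR", "TR", "RT", "RT"]))
        assert res.ci90 == (pytest.approx(math.exp(0.1)), pytest.approx(math.exp(0.1)))
        assert res.passed

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        d_pool = rng.normal(0.0, 0.2, 64)

        def width(n):
            log_r = np.zeros(n)
            log_t = d_pool[:n]
            seqs = np.array(["TR"] * (n // 2) + ["RT"] * (n // 2))
            res = crossover_be(log_t, log_r, seqs)
            return math.log(res.ci90[1]) - math.log(res.ci90[0])

        assert width(64) < width(32) < width(16)

    def test_needs_two_subjects_per_sequence(self):
        with pytest.raises(InvalidParameterError):
            crossover_be(np.zeros(3), np.zeros(3), np.array(["TR", "TR", "TR"]))


class TestRunTrial:
    def test_identity_formulations_without_variability(self, fast_base, releases):
        test, _ = releases
        pop = build_population(VariabilitySpec.zero(), 4, seed=0)
        trial = run_trial(test, test, pop, fast_base)
        for be in trial.be.metrics.values():
            assert be.gmr == pytest.approx(1.0, abs=1e-9)
            assert be.ci90 == (pytest.approx(1.0), pytest.approx(1.0))
            assert be.passed

    def test_half_fmax_fails_with_auc_ratio_near_half(self, fast_base, releases):
        test, ref = releases
        halved = ReleaseInput(
            mode="xr_weibull",
            weibull=dataclasses.replace(ref.weibull, fmax=ref.weibull.fmax / 2))
        pop = build_population(VariabilitySpec.zero(), 4, seed=0)
        trial = run_trial(halved, ref, pop, fast_base)
        auc = trial.be.metrics["auc_0_t"]
        assert auc.gmr == pytest.approx(0.5, abs=0.05)
        assert not trial.be.passed

    def test_balanced_sequences_required(self, fast_base, releases):
        test, ref = releases
        pop = build_population(VariabilitySpec.zero(), 5, seed=0)
        with pytest.raises(InvalidParameterError):
            run_trial(test, ref, pop, fast_base)

    def test_crossover_bookkeeping(self, fast_base, releases):
        test, ref = releases
        pop = build_population(VariabilitySpec.zero(), 4, seed=0)
        trial = run_trial(test, ref, pop, fast_base)
        rec = trial.records
        for _, g in rec.groupby("subject"):
            assert sorted(g.formulation) == ["R", "T"]
            assert sorted(g.period) == [1, 2]


class TestRiskTier:
    @pytest.mark.parametrize("n_pass,tier", [
        (15, "low"), (13, "low"), (12, "moderate"), (10, "moderate"),
        (9, "moderate"), (8, "high"), (0, "high"),
    ])
    def test_boundaries_for_fifteen_trials(self, n_pass, tier):
        assert risk_tier(n_pass, 15) == tier

    def test_proportional_generalization(self):
        assert risk_tier(5, 5) == "low"
        assert risk_tier(3, 5) == "moderate"
        assert risk_tier(2, 5) == "high"


class TestStudy:
    def test_seed_reproducibility(self, fast_base, releases):
        test, ref = releases
        spec = VariabilitySpec().scaled(0.5)
        r1, t1 = run_vbe_study(test, ref, spec, fast_base,
                               n_subjects=4, n_trials=2, seed=5)
        r2, t2 = run_vbe_study(test, ref, spec, fast_base,
                               n_subjects=4, n_trials=2, seed=5)
        assert r1.n_pass == r2.n_pass
        for a, b in zip(t1, t2):
            for m in a.metrics:
                assert a.metrics[m].gmr == b.metrics[m].gmr
                assert a.metrics[m].ci90 == b.metrics[m].ci90

    def test_identical_formulations_tiny_wsv_pass_at_start_n(self, fast_base,
                                                             releases):
        test, _ = releases
        spec = VariabilitySpec().scaled(0.05)
        n_found, curve = sample_size_step(test, test, spec, fast_base,
                                          start_n=6, step=2, max_n=8,
                                          n_trials=2, seed=2)
        assert n_found == 6
        assert curve.iloc[0].power == 1.0
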