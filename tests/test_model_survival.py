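"""Survival model, Kaplan-Meier, exponential fits and the global fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from curtainkit.model_survival import (
    FrameSchedule,
    GlobalFitSpec,
    KineticParams,
    SpotDataset,
    UnderIdentifiedWarning,
    binomial_weight,
    compare_lifetimes_ztest,
    effective_lambda,
    fit_exponential_curve,
    fit_global,
    fit_single_exponential,
    kaplan_meier,
    survival_model,
)
from curtainkit.synthetic import five_delay_design


def _dataset(times, censored=None, delay=10.0, **kw):
    times = np.asarray(times, dtype=float)
    if censored is None:
        censored = np.zeros(times.size, dtype=bool)
    return SpotDataset(times, np.asarray(censored, bool), FrameSchedule(0.1, delay), **kw)


class TestEffectiveLambda:
    @pytest.mark.parametrize(
        "tau, tau_nu, r, expected",
        [
            (math.inf, 200.0, 4.0, 800.0),        # bleaching only: lambda = r*tau_nu
            (600.0, math.inf, 4.0, 600.0),        # no bleaching: lambda = tau
            (600.0, 200.0, 4.0, 1.0 / (1 / 600 + 1 / 800)),
        ],
    )
    def test_values(self, tau, tau_nu, r, expected):
        assert effective_lambda(tau, tau_nu, r) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 200, 4), (600, 0, 4), (600, 200, 0),
                                     (math.inf, math.inf, 4)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            effective_lambda(*bad)

    def test_monotone_in_each_argument(self):
        base = effective_lambda(600, 200, 4)
        assert effective_lambda(700, 200, 4) > base
        assert effective_lambda(600, 250, 4) > base
        assert effective_lambda(600, 200, 5) > base


class TestBinomialWeight:
    def test_hand_values(self):
        assert binomial_weight(2, 0.5, 4) == pytest.approx(0.375)
        assert binomial_weight(0, 0.52, 4) == pytest.approx(0.48**4)

    @given(l=st.floats(0, 1), N=st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_normalization(self, l, N):
        assert sum(binomial_weight(i, l, N) for i in range(N + 1)) == pytest.approx(1.0)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            binomial_weight(5, 0.5, 4)


class TestSurvivalModel:
    def test_at_cutoff_is_one(self):
        p = KineticParams(tau=600, tau_nu=200, r=4, N=4, l=0.52, c=30)
        assert survival_model(30.0, p) == pytest.approx(1.0)

    def test_single_site_reduces_to_exponential(self):
        # N = 1, c = 0: the mixture collapses to exp(-t/lambda) for every l
        t = np.linspace(0, 5000, 64)
        for l in (0.1, 0.52, 1.0):
            p = KineticParams(tau=600, tau_nu=200, r=4, N=1, l=l)
            np.testing.assert_allclose(
                survival_model(t, p), np.exp(-t / p.lam), rtol=0, atol=1e-15
            )

    def test_max_of_four_exponentials(self):
        p = KineticParams(tau=math.inf, tau_nu=200, r=4, N=4, l=1.0)
        assert survival_model(p.lam * math.log(2), p) == pytest.approx(1 - 0.5**4)

    def test_monotone_nonincreasing_and_limits(self):
        p = KineticParams(tau=900, tau_nu=100, r=10, N=4, l=0.52, c=12.0)
        t = np.linspace(12.0, 1e5, 2000)
        s = survival_model(t, p)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] == pytest.approx(1.0)
        assert s[-1] < 1e-6

    def test_domain_errors(self):
        p = KineticParams(tau=600, tau_nu=200, r=4, N=4, l=0.52, c=10)
        with pytest.raises(ValueError):
            survival_model(5.0, p)
        with pytest.raises(ValueError):
            survival_model(20.0, KineticParams(tau=600, tau_nu=200, r=4, N=4, l=0.0))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        cv = kaplan_meier(_dataset([2, 4, 6]))
        np.testing.assert_allclose(cv.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(cv.at_risk, [3, 2, 1])

    def test_censored_spot_leaves_risk_set(self):
        cv = kaplan_meier(_dataset([2, 4, 6], [False, True, False]))
        np.testing.assert_allclose(cv.times, [2, 6])
        np.testing.assert_allclose(cv.survival, [2 / 3, 0.0])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no uncensored"):
            kaplan_meier(_dataset([2, 4, 6], [True, True, True]))

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(50.0, 200)
        censored = times > 80.0
        times = np.minimum(times, 80.0)
        cv = kaplan_meier(_dataset(times, censored))
        kmf = lifelines.KaplanMeierFitter().fit(times, ~censored)
        ours = cv.survival
        theirs = kmf.survival_function_at_times(cv.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestSingleExponentialFit:
    def test_recovers_simulated_lifetime(self, rng):
        times = rng.exponential(30.0, 1000)
        tau, se = fit_single_exponential(_dataset(times))
        assert tau == pytest.approx(30.0, rel=0.10)
        assert se > 0

    def test_noiseless_curve_inversion(self):
        t = np.linspace(1, 200, 20)
        tau, _ = fit_exponential_curve(t, np.exp(-t / 50.0))
        assert tau == pytest.approx(50.0, rel=1e-6)

    def test_too_few_events(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_single_exponential(_dataset([3.0, 7.0]))

    def test_degenerate_times_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_single_exponential(_dataset([5.0] * 8))


class TestLifetimeZTest:
    def test_identity(self):
        z, p = compare_lifetimes_ztest(100, 10, 100, 10)
        assert z == 0 and p == pytest.approx(1.0)

    def test_hand_value(self):
        z, p = compare_lifetimes_ztest(100, 10, 60, 10)
        assert z == pytest.approx(2.828, abs=1e-3)
        assert p == pytest.approx(0.00468, rel=1e-2)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            compare_lifetimes_ztest(100, 0, 60, 10)


class TestGlobalFit:
    SPEC = dict(dna_params={"4x": (4, 0.52)}, tau_nu_init=100.0)

    def test_noiseless_self_consistency(self):
        # survival points evaluated exactly from the model are returned
        # with (near) zero objective and the exact parameters
        from curtainkit.model_survival import SurvivalCurve

        truth = dict(tau=3000.0, tau_nu=30.0)
        datasets, curves = [], []
        for delay in (1.0, 4.0, 10.0, 40.0, 60.0):
            sched = FrameSchedule(0.1, delay)
            p = KineticParams(tau=truth["tau"], tau_nu=truth["tau_nu"],
                              r=sched.r_init, N=4, l=0.52)
            t = np.linspace(5, 3600, 60)
            s = survival_model(t, p)
            datasets.append(_dataset(t, delay=delay, dna_id="4x", construct_id="wt"))
            curves.append(SurvivalCurve(t, np.asarray(s), np.arange(60, 0, -1),
                                        np.full(60, 1e-4)))
        spec = GlobalFitSpec(**self.SPEC, n_starts=2)
        res = fit_global(datasets, spec, curves=curves)
        assert res.objective_value < 1e-8
        assert res.tau("wt") == pytest.approx(3000.0, rel=1e-3)
        assert res.estimates["tau_nu"] == pytest.approx(30.0, rel=1e-3)

    def test_recovery_from_simulated_design(self):
        datasets, truth = five_delay_design(seed=11)
        res = fit_global(datasets, GlobalFitSpec(**self.SPEC))
        assert res.converged
        assert res.tau("wt") == pytest.approx(truth["tau"], rel=0.15)
        assert res.estimates["tau_nu"] == pytest.approx(truth["tau_nu"], rel=0.20)
        assert res.tau_se("wt") > 0

    def test_exponential_limit_matches_sample_mean(self, rng):
        # N=1, l=1, tau_nu fixed at infinity: the fit degenerates to a
        # one-parameter exponential fit of the KM curve
        times = rng.exponential(120.0, 800)
        ds = _dataset(times, dna_id="1x", construct_id="c")
        spec = GlobalFitSpec(
            dna_params={"1x": (1, 1.0)}, fixed={"tau_nu": math.inf}, n_starts=2
        )
        res = fit_global([ds], spec)
        assert res.tau("c") == pytest.approx(times.mean(), rel=0.05)

    def test_single_delay_flagged_under_identified(self, rng):
        ds = _dataset(rng.exponential(100.0, 100), dna_id="4x")
        with pytest.warns(UnderIdentifiedWarning):
            res = fit_global([ds], GlobalFitSpec(**self.SPEC, n_starts=1))
        assert res.warnings
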