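"""CRP transit-compartment dynamics and treatment-duration utilities."""

import numpy as np
import pytest

from vancomipd import (
    DoseRegimen,
    PatientCovariates,
    PDParameters,
    drug_effect,
    initial_state,
    mean_transit_time,
    simulate_crp,
    time_to_normalization,
    transit_rate,
    typical_parameters,
)
from vancomipd.crp import (
    NOT_REACHED,
    cumulative_auc_interpolant,
    linear_auc_approximation,
)


def reference_exposure(daily_dose_g=2.0, horizon=1800.0):
    """Cumulative AUC for the label-dose reference adult (500 mg q6h)."""
    cov = PatientCovariates(age=40, weight=70, creatinine=1.0, bun=15)
    pk = typical_parameters(cov)
    regimen = DoseRegimen(
        dose_amount=daily_dose_g * 250.0, infusion_duration=1, interval=6,
        n_doses=int(np.ceil(horizon / 6)),
    )
    return cumulative_auc_interpolant(regimen, pk, horizon), pk


class TestTransitChain:
    @pytest.mark.parametrize("pne, expected", [(0, 0.0129), (1, 0.0187)])
    def test_transit_rate(self, pne, expected):
        assert transit_rate(pne) == pytest.approx(expected)

    def test_no_pneumonia_effect_when_theta_zero(self):
        p = PDParameters(theta_pne=0.0)
        assert transit_rate(0, p) == transit_rate(1, p)

    @pytest.mark.parametrize(
        "ktr, expected_days",
        [(0.0129, 9.69), (0.0187, 6.68), (0.125, 1.0)],
    )
    def test_mean_transit_time(self, ktr, expected_days):
        assert mean_transit_time(ktr) == pytest.approx(expected_days, abs=0.01)

    def test_mtt_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mean_transit_time(0.0)


class TestDrugEffect:
    def test_linear_in_exposure(self, pd_params):
        assert drug_effect(0.0) == 0.0
        assert drug_effect(1000.0) == pytest.approx(0.239, abs=1e-4)
        assert drug_effect(1.0 / pd_params.alpha) == pytest.approx(1.0)


class TestInitialState:
    def test_severity_from_baseline_crp(self):
        state = initial_state(PDParameters(), ktr=0.0129)
        assert state.d == pytest.approx(3.042, abs=1e-3)
        assert state.crp == 110.0
        assert state.prol == state.tran1 == state.tran2

    def test_healthy_baseline_gives_zero_severity(self, pd_params):
        healthy = pd_params.model_copy(update={"crp0": 0.0129 / 0.0365})
        state = initial_state(healthy, ktr=0.0129)
        assert state.d == pytest.approx(0.0, abs=1e-12)

    def test_pneumonia_lowers_inferred_severity(self):
        state = initial_state(PDParameters(), ktr=0.0187)
        assert state.d == pytest.approx(2.095, abs=1e-3)

    def test_invalid_crp0(self):
        with pytest.raises(Exception):
            initial_state(PDParameters(crp0=-1.0))


class TestSimulation:
    def test_untreated_severity_grows_exponentially(self, pd_params):
        no_drug = pd_params.model_copy(update={"alpha": 0.0})
        sim = simulate_crp(no_drug, 0, lambda t: np.zeros_like(np.asarray(t, float)), 361.0)
        d0 = initial_state(no_drug, 0.0129).d
        expected = d0 * np.exp(no_drug.k_d * sim.times)
        np.testing.assert_allclose(sim.severity, expected, rtol=1e-6)
        assert sim.severity[-1] == pytest.approx(6.08, abs=0.01)

    def test_healthy_steady_state_preserved(self, pd_params):
        healthy = pd_params.model_copy(update={"crp0": 0.0129 / 0.0365})
        sim = simulate_crp(healthy, 0, lambda t: np.zeros_like(np.asarray(t, float)), 500.0)
        np.testing.assert_allclose(sim.crp, healthy.crp0, rtol=1e-5)

    def test_frozen_severity_converges_to_analytic_level(self, pd_params):
        # kD -> 0 freezes D at its initial value; CRP must converge to
        # ktr * (1 + S_CRP * D) / k_CRP
        frozen = pd_params.model_copy(update={"k_d": 1e-12, "crp0": 50.0})
        ktr = 0.0129
        sim = simulate_crp(frozen, 0, lambda t: np.zeros_like(np.asarray(t, float)), 4000.0, step=4.0)
        d_star = initial_state(frozen, ktr).d
        level = ktr * (1 + frozen.s_crp * d_star) / frozen.k_crp
        assert sim.crp[-1] == pytest.approx(level, rel=5e-3)

    def test_higher_exposure_lowers_late_crp(self, pd_params):
        exp2, _ = reference_exposure(2.0, horizon=1400.0)
        exp3, _ = reference_exposure(3.0, horizon=1400.0)
        sim2 = simulate_crp(pd_params, 0, exp2, 1400.0, step=2.0)
        sim3 = simulate_crp(pd_params, 0, exp3, 1400.0, step=2.0)
        late = sim2.times > 400
        assert np.all(sim3.crp[late] <= sim2.crp[late] + 1e-9)

    def test_linear_exposure_rate_matches_steady_state(self):
        # daily increments of the true exposure approach daily dose / CL
        exposure, pk = reference_exposure(2.0, horizon=600.0)
        daily = 2000.0 / pk.cl
        for day in (10, 15, 20):
            inc = exposure(24.0 * (day + 1)) - exposure(24.0 * day)
            assert inc == pytest.approx(daily, rel=0.02)

    def test_deficit_corrected_linear_exposure(self):
        # with the accumulation-deficit term, cumulative agreement reaches
        # 2% once treatment has run for several terminal half-lives
        exposure, pk = reference_exposure(2.0, horizon=900.0)
        approx = linear_auc_approximation(2000.0, pk.cl, v_ss=pk.v + pk.v2)
        t = np.linspace(240.0, 900.0, 30)
        np.testing.assert_allclose(approx(t), exposure(t), rtol=0.02)

    def test_step_halving_stable_normalization_time(self, pd_params):
        exposure, _ = reference_exposure(2.0)
        t_coarse = simulate_crp(pd_params, 0, exposure, 1500.0, step=2.0)
        t_fine = simulate_crp(pd_params, 0, exposure, 1500.0, step=1.0)
        n1 = time_to_normalization(t_coarse.times, t_coarse.crp)
        n2 = time_to_normalization(t_fine.times, t_fine.crp)
        assert abs(n1 - n2) / n2 < 0.01


class TestNormalizationTime:
    def test_constant_series_inside_range(self):
        t = np.arange(0.0, 10.0)
        assert time_to_normalization(t, np.full(10, 5.0)) == 0.0

    def test_monotone_decay_crossing(self):
        t = np.arange(0.0, 1001.0)
        crp = 100.0 * np.exp(-np.log(10) * t / 500.0)  # hits 10 at t=500
        assert time_to_normalization(t, crp) == pytest.approx(500.0, abs=1.0)

    def test_rebound_disqualifies_first_entry(self):
        t = np.arange(0.0, 6.0)
        crp = np.array([50.0, 8.0, 20.0, 9.0, 5.0, 3.0])
        assert time_to_normalization(t, crp) == 3.0

    def test_never_normalizing_series(self):
        t = np.arange(0.0, 5.0)
        assert time_to_normalization(t, np.full(5, 50.0)) == NOT_REACHED

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            time_to_normalization(np.array([]), np.array([]))
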