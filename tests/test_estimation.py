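"""Approximate marginal likelihood, fixed-effect recovery, stepwise
covariate selection and VPC diagnostics."""

import numpy as np
import pytest

from vancomipd import (
    DoseRegimen,
    PKParameters,
    PopulationSpec,
    fit_fixed_effects,
    objective,
    sample_covariates,
    simulate_pk_dataset,
    stepwise_covariates,
    typical_parameters,
    vpc,
)
from vancomipd.estimation import PKDesign
from vancomipd.pk import concentration_at


def make_dataset(n, seed, params=None, zero_variance=False):
    spec = PopulationSpec(n_subjects=n, seed=seed, zero_variance=zero_variance)
    covs = sample_covariates(PopulationSpec(n_subjects=n, seed=seed))
    return simulate_pk_dataset(spec, pk_params=params, covariates=covs), covs


def exact_wls_m2ll(design, params):
    """Independent oracle: fixed-effect -2 log-likelihood with no BSV."""
    total = 0.0
    for sub in design.subjects:
        pk = typical_parameters(sub.cov, 0.0, params)
        regimen = DoseRegimen(
            dose_amount=float(sub.dose_rates[0] * sub.dose_durations[0]),
            infusion_duration=float(sub.dose_durations[0]),
            interval=float(np.diff(sub.dose_times)[0]),
            n_doses=len(sub.dose_times),
        )
        pred = concentration_at(sub.obs_times, regimen, pk)
        sd_prop = np.where(sub.obs_is_peak, params.sigma_prop_peak, params.sigma_prop_trough)
        sd_add = np.where(sub.obs_is_peak, params.sigma_add_peak, params.sigma_add_trough)
        var = (sd_prop * pred) ** 2 + sd_add**2
        total += np.sum(np.log(2 * np.pi * var) + (sub.obs_dv - pred) ** 2 / var)
    return total


class TestObjective:
    def test_zero_variance_collapses_to_exact_wls(self, pk_params):
        data, _ = make_dataset(20, seed=3)
        design = PKDesign(data)
        no_bsv = pk_params.model_copy(update={"omega_cl": 0.0, "omega_v2": 0.0})
        ofv = objective({}, design, no_bsv, n_draws=50)
        assert ofv == pytest.approx(exact_wls_m2ll(design, no_bsv), rel=1e-12)

    def test_truth_beats_inflated_parameters(self, pk_params):
        hits = 0
        for seed in (1, 2, 3):
            data, _ = make_dataset(80, seed=seed)
            design = PKDesign(data)
            at_truth = objective({}, design, pk_params, n_draws=40)
            inflated = objective(
                {"theta_cl": 1.5 * pk_params.theta_cl, "theta_v": 1.5 * pk_params.theta_v},
                design, pk_params, n_draws=40,
            )
            hits += at_truth < inflated
        assert hits == 3

    def test_nested_model_ofv_not_worse(self, pk_params):
        data, _ = make_dataset(40, seed=8)
        design = PKDesign(data)
        reduced = fit_fixed_effects(design, pk_params, free=("theta_cl",), n_draws=40)
        full = fit_fixed_effects(design, pk_params, free=("theta_cl", "theta_v"), n_draws=40)
        assert full.ofv <= reduced.ofv + 1e-6


class TestRecovery:
    def test_noise_free_data_identify_thetas_exactly(self, pk_params):
        # constant (additive-only) error makes the objective a pure sum of
        # squares, whose minimum sits exactly at the generating values;
        # with prediction-proportional variance the log-variance term
        # shifts the optimum slightly even on noise-free data
        data, _ = make_dataset(25, seed=5, zero_variance=True)
        no_bsv = pk_params.model_copy(update={
            "omega_cl": 0.0, "omega_v2": 0.0,
            "sigma_prop_trough": 0.0, "sigma_prop_peak": 0.0,
            "sigma_add_trough": 1.0, "sigma_add_peak": 1.0,
        })
        fit = fit_fixed_effects(
            data, no_bsv, init={"theta_cl": 3.0, "theta_v": 50.0}, n_draws=1,
        )
        assert fit.converged
        assert fit.estimates["theta_cl"] == pytest.approx(pk_params.theta_cl, rel=1e-4)
        assert fit.estimates["theta_v"] == pytest.approx(pk_params.theta_v, rel=1e-4)

    def test_sparse_data_recovery_within_15_percent(self):
        data, _ = make_dataset(150, seed=1)
        fit = fit_fixed_effects(data, init={"theta_cl": 3.0, "theta_v": 30.0}, n_draws=60)
        assert fit.converged
        assert fit.estimates["theta_cl"] == pytest.approx(4.31, rel=0.15)
        assert fit.estimates["theta_v"] == pytest.approx(38.6, rel=0.15)

    def test_fit_is_deterministic(self):
        data, _ = make_dataset(30, seed=12)
        f1 = fit_fixed_effects(data, n_draws=30)
        f2 = fit_fixed_effects(data, n_draws=30)
        assert f1.estimates == f2.estimates and f1.ofv == f2.ofv


class TestStepwise:
    def test_true_sex_effect_detected(self, pk_params):
        found = 0
        for seed in (1, 2, 3):
            data, _ = make_dataset(100, seed=seed)  # generated with theta_fem = -0.199
            selected = stepwise_covariates(
                data, candidates=("theta_fem", "theta_dm"), params=pk_params, n_draws=24,
            )
            found += "theta_fem" in selected
        assert found >= 2

    def test_null_effects_rarely_selected(self, pk_params):
        null_params = pk_params.model_copy(
            update={"theta_fem": 0.0, "theta_dm": 0.0, "theta_ren": 0.0}
        )
        false_hits = 0
        for seed in (4, 5, 6):
            spec = PopulationSpec(n_subjects=100, seed=seed)
            covs = sample_covariates(spec)
            data = simulate_pk_dataset(spec, pk_params=null_params, covariates=covs)
            selected = stepwise_covariates(
                data, candidates=("theta_fem", "theta_dm"), params=pk_params, n_draws=24,
            )
            false_hits += len(selected)
        assert false_hits <= 1

    def test_empty_candidate_list(self, pk_params):
        data, _ = make_dataset(20, seed=2)
        assert stepwise_covariates(data, candidates=(), params=pk_params, n_draws=20) == []


class TestVPC:
    def test_self_consistency(self, pk_params):
        data, _ = make_dataset(80, seed=21)
        bands = vpc(data, pk_params, n_sim=150, seed=0)
        inside = (bands["observed"] >= bands["ci_lo"]) & (bands["observed"] <= bands["ci_hi"])
        assert inside.mean() >= 0.9

    def test_zero_variance_bands_collapse(self, pk_params):
        data, _ = make_dataset(20, seed=22, zero_variance=True)
        frozen = pk_params.model_copy(update={
            "omega_cl": 0.0, "omega_v2": 0.0,
            "sigma_prop_trough": 0.0, "sigma_add_trough": 0.0,
            "sigma_prop_peak": 0.0, "sigma_add_peak": 0.0,
        })
        bands = vpc(data, frozen, n_sim=100, seed=0)
        np.testing.assert_allclose(bands["ci_lo"], bands["observed"], rtol=1e-9)
        np.testing.assert_allclose(bands["ci_hi"], bands["observed"], rtol=1e-9)

    def test_requires_minimum_simulations(self, pk_params):
        data, _ = make_dataset(10, seed=23)
        with pytest.raises(ValueError):
            vpc(data, pk_params, n_sim=10)
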