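"""Covariate submodels and two-compartment IV-infusion kinetics.

The typical-value model is

    CL = theta_cl * (WT/70)^0.75 * Fren * Fmat * COVCL
    V  = theta_v  * (WT/70)      * COVV
    Q  = theta_q  * (WT/70)^0.75
    V2 = theta_v2 * (WT/70)

with a renal-function factor Fren built from an age-dependent creatinine
production rate, a sigmoid maturation factor Fmat active under 4 years of
age, and log-linear / proportional covariate multipliers COVCL (BUN, sex,
diabetes, renal disease) and COVV (age).  Between-subject variability is
log-normal on CL and V2.  Concentrations follow the linear two-compartment
disposition model under superposed zero-order infusions and are available
both in closed form (bi-exponential) and by numerical ODE integration.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .types import (
    ALLOMETRIC_WEIGHT_REF,
    DoseRegimen,
    ExposureMetrics,
    IndividualPK,
    PatientCovariates,
    PKParameters,
)

__all__ = [
    "renal_production_rate",
    "creatinine_clearance",
    "renal_factor",
    "maturation_factor",
    "clearance_covariate_multiplier",
    "volume_covariate_multiplier",
    "typical_parameters",
    "individual_parameters",
    "simulate_concentrations",
    "ode_concentrations",
    "concentration_at",
    "steady_state_metrics",
    "apply_residual_error",
]


# ---------------------------------------------------------------------------
# covariate submodels

def renal_production_rate(age: float, params: Optional[PKParameters] = None) -> float:
    """Creatinine production rate RCr(age) in mg/h.

    RCr = rcr_ref * exp(k_cr * (age - 30)) with the slope switching sign at
    age 30 (positive below, non-positive above), so production is maximal
    at age 30.
    """
    params = params or PKParameters()
    if age < 0:
        raise ValueError("age must be non-negative")
    k_cr = params.k_cr_younger if age < 30 else params.k_cr_older
    return params.rcr_ref * np.exp(k_cr * (age - 30.0))


def creatinine_clearance(
    age: float, cr: float, t_treat: float = 0.0, params: Optional[PKParameters] = None
) -> float:
    """Model creatinine clearance: RCr(age)/Cr * exp(-k_tox * t_treat).

    ``t_treat`` is days since the first vancomycin dose; the exponential
    term captures the gradual CLCr decline attributed to vancomycin
    nephrotoxicity.
    """
    params = params or PKParameters()
    if cr <= 0:
        raise ValueError("creatinine must be positive")
    if t_treat < 0:
        raise ValueError("treatment time must be non-negative")
    return renal_production_rate(age, params) / cr * np.exp(-params.k_tox * t_treat)


def renal_factor(clcr: float, params: Optional[PKParameters] = None) -> float:
    """Renal-function factor Fren = (CLCr / CLCr_TV)^lambda.

    CLCr_TV is the typical clearance of a 30-year-old with creatinine
    ``cr_ref`` (default 1.0 mg/dL), i.e. rcr_ref / cr_ref.
    """
    params = params or PKParameters()
    if clcr <= 0:
        raise ValueError("creatinine clearance must be positive")
    clcr_tv = params.rcr_ref / params.cr_ref
    return (clcr / clcr_tv) ** params.lambda_exp


def maturation_factor(
    pma: Optional[float], age: float, params: Optional[PKParameters] = None
) -> float:
    """Sigmoid organ-maturation factor, active only under 4 years of age.

    Fmat = PMA^gamma / (PMA50^gamma + PMA^gamma) for age < 4, else exactly 1.
    """
    params = params or PKParameters()
    if age >= 4:
        return 1.0
    if pma is None or pma <= 0:
        raise ValueError("pma (weeks) is required and must be positive for age < 4")
    pg = pma**params.gamma
    return pg / (params.pma50**params.gamma + pg)


def clearance_covariate_multiplier(
    cov: PatientCovariates, params: Optional[PKParameters] = None
) -> float:
    """COVCL = exp(k_bun*(BUN-15)) * (1+theta_fem*FEM) * (1+theta_dm*DM) * (1+theta_ren*REN)."""
    params = params or PKParameters()
    return (
        np.exp(params.k_bun * (cov.bun - 15.0))
        * (1.0 + params.theta_fem * cov.sex_female)
        * (1.0 + params.theta_dm * cov.diabetes)
        * (1.0 + params.theta_ren * cov.renal_disease)
    )


def volume_covariate_multiplier(age: float, params: Optional[PKParameters] = None) -> float:
    """COVV = exp(k_v * (age - 40)); unity at age 40."""
    params = params or PKParameters()
    if age < 0:
        raise ValueError("age must be non-negative")
    return np.exp(params.k_v * (age - 40.0))


def typical_parameters(
    cov: PatientCovariates, t_treat: float = 0.0, params: Optional[PKParameters] = None
) -> IndividualPK:
    """Population typical disposition parameters for one subject."""
    params = params or PKParameters()
    wt_cl = (cov.weight / ALLOMETRIC_WEIGHT_REF) ** 0.75
    wt_v = cov.weight / ALLOMETRIC_WEIGHT_REF
    clcr = creatinine_clearance(cov.age, cov.creatinine, t_treat, params)
    cl = (
        params.theta_cl
        * wt_cl
        * renal_factor(clcr, params)
        * maturation_factor(cov.pma, cov.age, params)
        * clearance_covariate_multiplier(cov, params)
    )
    v = params.theta_v * wt_v * volume_covariate_multiplier(cov.age, params)
    return IndividualPK(cl=cl, v=v, q=params.theta_q * wt_cl, v2=params.theta_v2 * wt_v)


def individual_parameters(
    typical: IndividualPK, eta_cl: float = 0.0, eta_v2: float = 0.0
) -> IndividualPK:
    """Apply log-normal random effects; BSV is estimated on CL and V2 only."""
    if not (np.isfinite(eta_cl) and np.isfinite(eta_v2)):
        raise ValueError("random-effect deviates must be finite")
    return IndividualPK(
        cl=typical.cl * float(np.exp(eta_cl)),
        v=typical.v,
        q=typical.q,
        v2=typical.v2 * float(np.exp(eta_v2)),
    )


# ---------------------------------------------------------------------------
# disposition

def _disposition_exponentials(pk: IndividualPK) -> Tuple[np.ndarray, np.ndarray]:
    """Macro rates and coefficients of the unit-bolus response.

    Returns (lam, coef) such that C_bolus(t) = (D/V) * sum_i coef_i * exp(-lam_i t),
    with sum(coef) = 1.  Degenerates to mono-exponential when Q = 0.
    """
    if pk.q == 0.0:
        return np.array([pk.cl / pk.v]), np.array([1.0])
    k10 = pk.cl / pk.v
    k12 = pk.q / pk.v
    k21 = pk.q / pk.v2
    a = k10 + k12 + k21
    disc = np.sqrt(a * a - 4.0 * k10 * k21)
    lam1 = (a + disc) / 2.0
    lam2 = (a - disc) / 2.0
    c1 = (lam1 - k21) / (lam1 - lam2)
    return np.array([lam1, lam2]), np.array([c1, 1.0 - c1])


def concentration_at(
    times: np.ndarray, regimen: DoseRegimen, pk: IndividualPK
) -> np.ndarray:
    """Closed-form central concentration (mg/L) at arbitrary times.

    Superposes the bi-exponential zero-order-infusion response of every
    dose in the regimen; exact for the linear model.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if regimen.dose_amount == 0.0:
        return np.zeros_like(t)
    lam, coef = _disposition_exponentials(pk)
    rate_v = regimen.rate / pk.v
    out = np.zeros_like(t)
    for n in range(regimen.n_doses):
        ts = t - n * regimen.interval
        m = ts > 0
        if not m.any():
            break
        dur = np.minimum(ts[m], regimen.infusion_duration)
        tail = np.maximum(ts[m] - regimen.infusion_duration, 0.0)
        for l, c in zip(lam, coef):
            out[m] += rate_v * c / l * (1.0 - np.exp(-l * dur)) * np.exp(-l * tail)
    return out


def simulate_concentrations(
    regimen: DoseRegimen, pk: IndividualPK, times: Sequence[float]
) -> np.ndarray:
    """Concentration series for a sorted, non-negative time grid (h)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be a 1-D sorted array")
    return concentration_at(t, regimen, pk)


def ode_concentrations(
    regimen: DoseRegimen,
    pk: IndividualPK,
    times: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerical ODE solution of the same model (cross-check of the closed form).

    Integrates the two-compartment amounts piecewise between infusion on/off
    switch points so the piecewise-constant input is represented exactly.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    k10 = pk.cl / pk.v
    k12 = pk.q / pk.v
    k21 = pk.q / pk.v2 if pk.v2 > 0 else 0.0

    switch = []
    for n in range(regimen.n_doses):
        switch.append(n * regimen.interval)
        switch.append(n * regimen.interval + regimen.infusion_duration)
    edges = np.unique(np.concatenate([switch, t, [0.0]]))
    edges = edges[edges <= max(t.max(), edges.max())]

    def infusing(tm: float) -> float:
        for n in range(regimen.n_doses):
            start = n * regimen.interval
            if start <= tm < start + regimen.infusion_duration:
                return regimen.rate
        return 0.0

    def rhs(tm, y, rate):
        a1, a2 = y
        return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    y = np.array([0.0, 0.0])
    out = np.zeros_like(t)
    done = t == 0.0
    out[done] = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        rate = infusing((lo + hi) / 2.0)
        sel = (t > lo) & (t <= hi)
        eval_t = np.concatenate([t[sel], [hi]])
        eval_t = np.unique(eval_t)
        sol = solve_ivp(
            rhs, (lo, hi), y, t_eval=eval_t, args=(rate,), rtol=rtol, atol=atol, method="LSODA"
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        for tm, col in zip(sol.t, sol.y.T):
            hits = np.isclose(t, tm) & sel
            out[hits] = col[0] / pk.v
        y = sol.y[:, -1]
    return out


# ---------------------------------------------------------------------------
# steady state

def steady_state_trough_peak(
    regimen: DoseRegimen, pk: IndividualPK
) -> Tuple[float, float]:
    """Analytic steady-state trough (start of infusion) and peak (end)."""
    lam, coef = _disposition_exponentials(pk)
    rate_v = regimen.rate / pk.v
    tau = regimen.interval
    tinf = regimen.infusion_duration
    acc = 1.0 - np.exp(-lam * tau)
    if tinf >= tau:
        # continuous infusion: flat steady state at rate / CL
        css = regimen.rate / pk.cl
        return css, css
    trough = float(
        np.sum(rate_v * coef / lam * (np.exp(lam * tinf) - 1.0) * np.exp(-lam * tau) / acc)
    )
    peak = float(np.sum(rate_v * coef / lam * (1.0 - np.exp(-lam * tinf)) / acc))
    return trough, peak


def steady_state_metrics(regimen: DoseRegimen, pk: IndividualPK) -> ExposureMetrics:
    """Steady-state trough, peak and AUC over 24 h.

    AUC24 uses the linear-kinetics identity daily dose / CL, which equals
    the integral of the periodic steady-state profile over 24 h.
    """
    trough, peak = steady_state_trough_peak(regimen, pk)
    auc24 = regimen.daily_dose / pk.cl
    return ExposureMetrics(trough_ss=trough, peak_ss=peak, auc24_ss=auc24)


# ---------------------------------------------------------------------------
# residual error

def apply_residual_error(
    conc: np.ndarray,
    sample_type: str,
    rng: np.random.Generator,
    params: Optional[PKParameters] = None,
) -> np.ndarray:
    """Combined proportional + additive observation noise, by sample type.

    DV = conc * (1 + eps_prop) + eps_add, with SDs specific to trough or
    peak samples; negative draws are truncated at zero.
    """
    params = params or PKParameters()
    if sample_type == "trough":
        sd_prop, sd_add = params.sigma_prop_trough, params.sigma_add_trough
    elif sample_type == "peak":
        sd_prop, sd_add = params.sigma_prop_peak, params.sigma_add_peak
    else:
        raise ValueError(f"unknown sample type: {sample_type!r}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    dv = c * (1.0 + sd_prop * rng.standard_normal(c.shape)) + sd_add * rng.standard_normal(c.shape)
    return np.maximum(dv, 0.0)
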