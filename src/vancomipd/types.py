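"""Domain types shared across the package.

All models are pydantic so that parameter files and covariate scenarios
validate on construction.  Units follow the conventions used throughout
vancomycin population PK work: hours for time inside the models, years for
age, weeks for postmenstrual age (PMA), days for the nephrotoxicity clock,
mg/L for concentrations and mg.h/L for exposure.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

HOURS_PER_DAY = 24.0
WEEKS_PER_YEAR = 52.1775  # 365.25 / 7; converts age in years to PMA weeks
ALLOMETRIC_WEIGHT_REF = 70.0  # kg


class PatientCovariates(BaseModel):
    """One subject's demographic / laboratory / comorbidity state.

    ``pma`` (postmenstrual age, weeks) is only consulted for subjects under
    4 years, where the clearance maturation factor is active; it is
    mandatory there and ignored elsewhere.
    """

    model_config = ConfigDict(validate_assignment=True)

    age: float = Field(ge=0, le=120, description="age in years")
    weight: float = Field(gt=0, description="body weight, kg")
    creatinine: float = Field(gt=0, description="plasma creatinine, mg/dL")
    bun: float = Field(gt=0, description="blood urea nitrogen, mg/dL")
    pma: Optional[float] = Field(default=None, gt=0, description="postmenstrual age, weeks")
    sex_female: int = Field(default=0, ge=0, le=1)
    diabetes: int = Field(default=0, ge=0, le=1)
    renal_disease: int = Field(default=0, ge=0, le=1)
    pneumonia: int = Field(default=0, ge=0, le=1)

    @model_validator(mode="after")
    def _pma_required_for_infants(self) -> "PatientCovariates":
        if self.age < 4 and self.pma is None:
            raise ValueError("pma (weeks) is required for subjects under 4 years")
        return self


class PKParameters(BaseModel):
    """Fixed effects, between-subject variability and residual error of the
    final population PK model.

    Defaults are the published estimates for the two-compartment vancomycin
    model with allometric scaling, renal-function factor, maturation factor
    and covariate effects on clearance (BUN, sex, diabetes, renal disease)
    and central volume (age).

    ``omega_*`` are SDs of log-scale random effects; printed CV% values are
    read as 100*SD.  ``sigma_prop_*`` are proportional-error SDs (fractions)
    and ``sigma_add_*`` additive SDs (mg/L), stratified by sample type.
    ``rcr_ref``/``cr_ref`` define the reference creatinine clearance of a
    30-year-old (the renal factor equals 1 there).
    """

    model_config = ConfigDict(populate_by_name=True)

    theta_cl: float = Field(default=4.32, gt=0, description="typical clearance, L/h (70 kg)")
    theta_v: float = Field(default=38.6, gt=0, description="typical central volume, L (70 kg)")
    theta_q: float = Field(default=3.93, ge=0, description="inter-compartmental clearance, L/h")
    theta_v2: float = Field(default=66.8, gt=0, description="peripheral volume, L (70 kg)")
    k_cr_older: float = Field(default=-0.0127, description="creatinine production age slope, 1/yr, age >= 30")
    k_cr_younger: float = Field(default=0.0193, description="creatinine production age slope, 1/yr, age < 30")
    lambda_exp: float = Field(default=0.655, gt=0, alias="lambda", description="renal factor exponent")
    pma50: float = Field(default=43.9, gt=0, description="PMA at half-maximal maturation, weeks")
    gamma: float = Field(default=2.08, gt=0, description="maturation sigmoid steepness")
    k_tox: float = Field(default=0.00598, ge=0, description="nephrotoxic CLCr decline, 1/day")
    k_v: float = Field(default=0.00957, description="volume age slope, 1/yr")
    k_bun: float = Field(default=-0.00874, description="BUN slope on clearance, dL/mg")
    theta_ren: float = Field(default=-0.237, gt=-1, description="renal-disease fraction on CL")
    theta_fem: float = Field(default=-0.199, gt=-1, description="female fraction on CL")
    theta_dm: float = Field(default=-0.151, gt=-1, description="diabetes fraction on CL")
    omega_cl: float = Field(default=0.291, ge=0, description="BSV SD on CL (log scale)")
    omega_v2: float = Field(default=1.01, ge=0, description="BSV SD on V2 (log scale)")
    sigma_prop_trough: float = Field(default=0.178, ge=0)
    sigma_add_trough: float = Field(default=0.956, ge=0, description="mg/L")
    sigma_prop_peak: float = Field(default=0.110, ge=0)
    sigma_add_peak: float = Field(default=4.47, ge=0, description="mg/L")
    rcr_ref: float = Field(default=64.2, gt=0, description="creatinine production at age 30, mg/h")
    cr_ref: float = Field(default=1.0, gt=0, description="reference creatinine defining CLCr_TV, mg/dL")


class PDParameters(BaseModel):
    """Fixed effects and variability of the CRP transit-compartment model.

    The CRP elimination rate ``k_crp`` defaults to ln(2)/19 h = 0.0365 1/h
    (19-h CRP half-life), held fixed rather than estimated.
    """

    theta_ktr: float = Field(default=0.0129, gt=0, description="base transit rate, 1/h")
    theta_pne: float = Field(default=0.0058, ge=0, description="pneumonia shift on ktr, 1/h")
    k_crp: float = Field(default=0.0365, gt=0, description="CRP elimination rate, 1/h")
    crp0: float = Field(default=110.0, gt=0, description="initial CRP, mg/L")
    k_d: float = Field(default=0.00192, gt=0, description="disease progression rate, 1/h")
    alpha: float = Field(default=0.000239, ge=0, description="drug-effect scale, per mg.h/L")
    s_crp: float = Field(default=102.0, gt=0, description="severity scaling on CRP production")
    omega_kd: float = Field(default=1.476, ge=0, description="BSV SD on kD (log scale)")
    omega_crp0: float = Field(default=1.072, ge=0, description="BSV SD on CRP0 (log scale)")
    sigma_prop: float = Field(default=0.549, ge=0, description="proportional residual SD")


class DoseRegimen(BaseModel):
    """Repeated zero-order IV infusion schedule starting at t = 0."""

    dose_amount: float = Field(ge=0, description="mg per administration")
    infusion_duration: float = Field(gt=0, description="h")
    interval: float = Field(gt=0, description="h between infusion starts")
    n_doses: int = Field(ge=1)

    @model_validator(mode="after")
    def _duration_fits_interval(self) -> "DoseRegimen":
        if self.infusion_duration > self.interval:
            raise ValueError("infusion_duration must not exceed the dosing interval")
        return self

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.dose_amount / self.infusion_duration

    @property
    def daily_dose(self) -> float:
        """Nominal daily dose, mg/day, assuming the interval divides 24 h."""
        return self.dose_amount * HOURS_PER_DAY / self.interval


class IndividualPK(BaseModel):
    """Disposition parameters of one subject (two-compartment model)."""

    cl: float = Field(gt=0, description="L/h")
    v: float = Field(gt=0, description="L")
    q: float = Field(ge=0, description="L/h")
    v2: float = Field(gt=0, description="L")


class ExposureMetrics(BaseModel):
    """Steady-state exposure summary for one regimen x subject pair.

    Trough is the concentration at the start of an infusion, peak at the
    end of that infusion (the sampling definition used in routine TDM).
    """

    trough_ss: float = Field(ge=0, description="mg/L")
    peak_ss: float = Field(ge=0, description="mg/L")
    auc24_ss: float = Field(ge=0, description="mg.h/L over 24 h")

    @model_validator(mode="after")
    def _ordered(self) -> "ExposureMetrics":
        if self.trough_ss > self.peak_ss + 1e-9:
            raise ValueError("steady-state trough cannot exceed the peak")
        return self


class PDState(BaseModel):
    """Five-state CRP/disease system plus cumulative drug exposure."""

    prol: float = Field(ge=0)
    tran1: float = Field(ge=0)
    tran2: float = Field(ge=0)
    crp: float = Field(ge=0, description="mg/L")
    d: float = Field(ge=0, description="disease severity, dimensionless")
    cum_auc: float = Field(ge=0, description="cumulative vancomycin AUC, mg.h/L")
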