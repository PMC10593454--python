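"""Virtual-patient and study-dataset generation.

Emulates the source study's population: 542 hospitalized patients (40 of
them pediatric) with sparse TDM sampling — peak and trough vancomycin
samples on one or two occasions (about three samples per subject) — and a
128-patient subset with serial CRP measurements.  Covariates are drawn to
match the published medians and ranges (age 60 y, weight 59 kg, creatinine
0.7 mg/dL, BUN 15.25 mg/dL); creatinine and BUN share a rank correlation
of 0.5 through a Gaussian copula, and weight follows a growth-curve-like
median for subjects under 20 years.

Datasets are emitted as NONMEM-style event tables (ID, TIME, AMT, RATE,
EVID, MDV, DV, CMT, STYPE plus covariate columns).  Each subject draws
from a deterministic substream of the global seed, so subject i is
invariant to the total number of subjects generated.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .types import DoseRegimen, PatientCovariates, PDParameters, PKParameters
from .pk import apply_residual_error, concentration_at, individual_parameters, typical_parameters
from .crp import linear_auc_approximation, simulate_crp

__all__ = [
    "PopulationSpec",
    "sample_covariates",
    "simulate_pk_dataset",
    "simulate_crp_dataset",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "CMT", "STYPE",
    "AGE", "PMA", "WT", "SEX", "CR", "BUN", "DM", "REN", "PNE",
]


class PopulationSpec(BaseModel):
    """Covariate distribution and sampling-design settings.

    Medians/ranges default to the published demographics; comorbidity
    prevalences are not published and default to plausible hospital-cohort
    values (diabetes 20%, renal disease 15%, pneumonia 30%).
    """

    n_subjects: int = Field(default=542, ge=1)
    pediatric_fraction: float = Field(default=40.0 / 542.0, ge=0, le=1)
    under4_fraction: float = Field(default=22.0 / 40.0, ge=0, le=1, description="of pediatric subjects")
    age_adult_median: float = 61.0
    age_adult_sd: float = 15.0
    age_range: tuple[float, float] = (0.0, 93.0)
    weight_adult_median: float = 61.0
    weight_sigma: float = 0.16
    weight_range: tuple[float, float] = (2.6, 106.0)
    cr_median: float = 0.7
    cr_sigma: float = 0.55
    cr_range: tuple[float, float] = (0.2, 12.9)
    bun_median: float = 15.25
    bun_sigma: float = 0.60
    bun_range: tuple[float, float] = (1.5, 141.5)
    cr_bun_corr: float = Field(default=0.5, ge=-1, le=1)
    prev_diabetes: float = Field(default=0.20, ge=0, le=1)
    prev_renal: float = Field(default=0.15, ge=0, le=1)
    prev_pneumonia: float = Field(default=0.30, ge=0, le=1)
    mean_occasions: float = 1.5  # trough+peak pairs per subject -> ~3 samples
    crp_subset: int = Field(default=128, ge=1)
    crp_sampling_days: tuple[float, float] = (2.5, 3.5)
    crp_stay_days: tuple[float, float] = (12.0, 21.0)
    zero_variance: bool = Field(default=False, description="suppress all BSV and residual noise")
    seed: int = 0


# piecewise growth-curve median weight (kg) by age (years) for subjects <20 y
_GROWTH_AGE = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0])
_GROWTH_WT = np.array([3.3, 7.5, 10.0, 12.5, 18.0, 32.0, 52.0, 60.0])


def _median_weight(age: float, spec: PopulationSpec) -> float:
    if age >= 20.0:
        return spec.weight_adult_median
    return float(np.interp(age, _GROWTH_AGE, _GROWTH_WT))


def _median_cr(age: float, spec: PopulationSpec) -> float:
    # children run lower creatinine; scale the adult median down
    if age < 4.0:
        return spec.cr_median * 0.45
    if age < 13.0:
        return spec.cr_median * 0.7
    return spec.cr_median


def _subject_rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_covariates(spec: PopulationSpec, seed: Optional[int] = None) -> List[PatientCovariates]:
    """Draw ``n_subjects`` virtual patients from the population spec."""
    seed = spec.seed if seed is None else seed
    out: List[PatientCovariates] = []
    for rng in _subject_rngs(seed, spec.n_subjects):
        if spec.zero_variance:
            out.append(
                PatientCovariates(
                    age=spec.age_adult_median, weight=spec.weight_adult_median,
                    creatinine=spec.cr_median, bun=spec.bun_median,
                )
            )
            continue
        pediatric = rng.random() < spec.pediatric_fraction
        pma = None
        if pediatric:
            if rng.random() < spec.under4_fraction:
                age = float(rng.uniform(0.0, 4.0))
                pma = float(rng.uniform(30.0, 42.0) + age * 52.1775)
            else:
                age = float(rng.uniform(4.0, 20.0))
        else:
            age = float(np.clip(rng.normal(spec.age_adult_median, spec.age_adult_sd), 20.0, spec.age_range[1]))
        wt = float(np.clip(
            _median_weight(age, spec) * np.exp(rng.normal(0.0, spec.weight_sigma)),
            spec.weight_range[0], spec.weight_range[1],
        ))
        # Gaussian copula for the renal pair (Cr, BUN)
        z1, z2 = rng.standard_normal(2)
        z2 = spec.cr_bun_corr * z1 + np.sqrt(1.0 - spec.cr_bun_corr**2) * z2
        cr = float(np.clip(_median_cr(age, spec) * np.exp(spec.cr_sigma * z1), *spec.cr_range))
        bun = float(np.clip(spec.bun_median * np.exp(spec.bun_sigma * z2), *spec.bun_range))
        out.append(
            PatientCovariates(
                age=age, pma=pma, weight=wt, creatinine=cr, bun=bun,
                sex_female=int(rng.random() < 0.5),
                diabetes=int(rng.random() < spec.prev_diabetes),
                renal_disease=int(rng.random() < spec.prev_renal),
                pneumonia=int(rng.random() < spec.prev_pneumonia),
            )
        )
    return out


def _dose_policy(cov: PatientCovariates, rng: np.random.Generator, zero_variance: bool) -> DoseRegimen:
    """Label-style dosing: 500-1500 mg per administration, q6-24h, 3-5 days."""
    if cov.age < 20.0:
        per_admin = float(np.clip(round(12.5 * cov.weight / 25.0) * 25.0, 25.0, 1500.0))
        interval = 6.0
    else:
        per_admin = float(np.clip(round(15.0 * cov.weight / 250.0) * 250.0, 500.0, 1500.0))
        interval = 12.0 if zero_variance else float(rng.choice([6.0, 8.0, 12.0, 24.0], p=[0.15, 0.2, 0.45, 0.2]))
    days = 4.0 if zero_variance else float(rng.uniform(3.0, 5.0))
    n_doses = max(int(np.ceil(days * 24.0 / interval)), 2)
    return DoseRegimen(dose_amount=per_admin, infusion_duration=1.0, interval=interval, n_doses=n_doses)


def _covariate_fields(cov: PatientCovariates) -> dict:
    return {
        "AGE": cov.age, "PMA": cov.pma if cov.pma is not None else 0.0, "WT": cov.weight,
        "SEX": cov.sex_female, "CR": cov.creatinine, "BUN": cov.bun,
        "DM": cov.diabetes, "REN": cov.renal_disease, "PNE": cov.pneumonia,
    }


def simulate_pk_dataset(
    spec: PopulationSpec,
    pk_params: Optional[PKParameters] = None,
    seed: Optional[int] = None,
    covariates: Optional[List[PatientCovariates]] = None,
) -> pd.DataFrame:
    """Sparse peak/trough TDM dataset in NONMEM event format.

    Per subject: log-normal random effects on CL and V2, a label-style
    dosing course, trough samples at infusion starts and peak samples at
    infusion ends on one or two late occasions, and sample-type-specific
    combined residual error.  With ``spec.zero_variance`` the observations
    equal the typical-model predictions exactly.
    """
    pk_params = pk_params or PKParameters()
    seed = spec.seed if seed is None else seed
    covs = covariates if covariates is not None else sample_covariates(spec, seed)
    rows = []
    for sid, (cov, rng) in enumerate(zip(covs, _subject_rngs(seed + 1, len(covs))), start=1):
        regimen = _dose_policy(cov, rng, spec.zero_variance)
        if spec.zero_variance:
            eta_cl = eta_v2 = 0.0
            n_occ = 2
        else:
            eta_cl = rng.normal(0.0, pk_params.omega_cl)
            eta_v2 = rng.normal(0.0, pk_params.omega_v2)
            n_occ = 1 + int(rng.random() < (spec.mean_occasions - 1.0))
        pk = individual_parameters(typical_parameters(cov, 0.0, pk_params), eta_cl, eta_v2)
        base = _covariate_fields(cov)
        for n in range(regimen.n_doses):
            rows.append({
                "ID": sid, "TIME": n * regimen.interval, "AMT": regimen.dose_amount,
                "RATE": regimen.rate, "EVID": 1, "MDV": 1, "DV": np.nan,
                "CMT": "vanco", "STYPE": "dose", **base,
            })
        # occasions anchored to the last doses of the course
        occ_doses = sorted(set(
            regimen.n_doses - 1 - k for k in range(n_occ) if regimen.n_doses - 1 - k >= 1
        ))
        for dn in occ_doses:
            t_trough = dn * regimen.interval
            t_peak = dn * regimen.interval + regimen.infusion_duration
            for t, stype in ((t_trough, "trough"), (t_peak, "peak")):
                pred = float(concentration_at(np.array([t]), regimen, pk)[0])
                if spec.zero_variance:
                    dv = pred
                else:
                    dv = float(apply_residual_error(np.array([pred]), stype, rng, pk_params)[0])
                rows.append({
                    "ID": sid, "TIME": t, "AMT": 0.0, "RATE": 0.0, "EVID": 0, "MDV": 0,
                    "DV": dv, "CMT": "vanco", "STYPE": stype, **base,
                })
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def simulate_crp_dataset(
    spec: PopulationSpec,
    pd_params: Optional[PDParameters] = None,
    pk_params: Optional[PKParameters] = None,
    seed: Optional[int] = None,
    covariates: Optional[List[PatientCovariates]] = None,
) -> pd.DataFrame:
    """Serial CRP dataset for a subject subset (default 128 of 542).

    Random effects apply to kD and CRP0; exposure uses the subject's
    individual clearance and dosing policy through the linear cumulative-
    AUC approximation; observations carry proportional residual error.
    """
    pd_params = pd_params or PDParameters()
    pk_params = pk_params or PKParameters()
    seed = spec.seed if seed is None else seed
    covs = covariates if covariates is not None else sample_covariates(spec, seed)
    covs = covs[: spec.crp_subset]
    rows = []
    for sid, (cov, rng) in enumerate(zip(covs, _subject_rngs(seed + 2, len(covs))), start=1):
        regimen = _dose_policy(cov, rng, spec.zero_variance)
        pk = typical_parameters(cov, 0.0, pk_params)
        exposure = linear_auc_approximation(regimen.daily_dose, pk.cl, v_ss=pk.v + pk.v2)
        if spec.zero_variance:
            eta_kd = eta_crp0 = 0.0
            stay_h = spec.crp_stay_days[1] * 24.0
            sample_times = np.arange(0.0, stay_h + 1e-9, spec.crp_sampling_days[1] * 24.0)
        else:
            eta_kd = rng.normal(0.0, pd_params.omega_kd)
            eta_crp0 = rng.normal(0.0, pd_params.omega_crp0)
            stay_h = rng.uniform(*spec.crp_stay_days) * 24.0
            gaps = rng.uniform(spec.crp_sampling_days[0], spec.crp_sampling_days[1], size=32) * 24.0
            sample_times = np.concatenate([[0.0], np.cumsum(gaps)])
            sample_times = sample_times[sample_times <= stay_h]
        sim = simulate_crp(
            pd_params, cov.pneumonia, exposure, horizon=float(sample_times[-1]) + 1.0,
            step=1.0, eta_kd=eta_kd, eta_crp0=eta_crp0,
        )
        crp_pred = np.interp(sample_times, sim.times, sim.crp)
        base = _covariate_fields(cov)
        for t, pred in zip(sample_times, crp_pred):
            if spec.zero_variance:
                dv = float(pred)
            else:
                dv = max(float(pred) * (1.0 + pd_params.sigma_prop * rng.standard_normal()), 0.0)
            rows.append({
                "ID": sid, "TIME": float(t), "AMT": 0.0, "RATE": 0.0, "EVID": 0, "MDV": 0,
                "DV": dv, "CMT": "crp", "STYPE": "crp", **base,
            })
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
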