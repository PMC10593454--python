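"""Approximate maximum-likelihood estimation on sparse TDM datasets.

The marginal likelihood over the log-normal random effects on CL and V2 is
approximated by Monte-Carlo integration with common random draws: a fixed
panel of standard-normal deviates per subject is scaled by the omegas, so
the objective is a smooth deterministic function of the fixed effects and
collapses exactly to the weighted least-squares -2LL when the omegas are
zero.  The objective is reported on the -2 log-likelihood (OFV) scale used
for likelihood-ratio covariate tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .types import PatientCovariates, PKParameters
from .pk import typical_parameters

__all__ = [
    "PKDesign",
    "FitResult",
    "objective",
    "fit_fixed_effects",
    "stepwise_covariates",
    "vpc",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# parameters that may be freed in a fit; values must stay positive unless
# listed as unconstrained coefficients
_POSITIVE = {"theta_cl", "theta_v", "theta_q", "theta_v2"}
_COEFFICIENTS = {"theta_fem", "theta_dm", "theta_ren", "k_bun", "k_v"}


@dataclass
class _Subject:
    cov: PatientCovariates
    dose_times: np.ndarray
    dose_rates: np.ndarray
    dose_durations: np.ndarray
    obs_times: np.ndarray
    obs_dv: np.ndarray
    obs_is_peak: np.ndarray  # bool; False -> trough


class PKDesign:
    """Parsed event dataset: per-subject dosing schedule and observations."""

    def __init__(self, data: pd.DataFrame):
        self.subjects: List[_Subject] = []
        for _, g in data[data["CMT"] == "vanco"].groupby("ID", sort=True):
            doses = g[g["EVID"] == 1]
            obs = g[g["EVID"] == 0]
            if len(obs) == 0:
                continue
            first = g.iloc[0]
            cov = PatientCovariates(
                age=first["AGE"], pma=first["PMA"] if first["PMA"] > 0 else None,
                weight=first["WT"], creatinine=first["CR"], bun=first["BUN"],
                sex_female=int(first["SEX"]), diabetes=int(first["DM"]),
                renal_disease=int(first["REN"]), pneumonia=int(first["PNE"]),
            )
            self.subjects.append(
                _Subject(
                    cov=cov,
                    dose_times=doses["TIME"].to_numpy(float),
                    dose_rates=doses["RATE"].to_numpy(float),
                    dose_durations=(doses["AMT"] / doses["RATE"]).to_numpy(float),
                    obs_times=obs["TIME"].to_numpy(float),
                    obs_dv=obs["DV"].to_numpy(float),
                    obs_is_peak=(obs["STYPE"] == "peak").to_numpy(),
                )
            )
        self.n_obs = int(sum(len(s.obs_times) for s in self.subjects))

    def draws(self, n_draws: int, seed: int) -> np.ndarray:
        """Fixed standard-normal panel, shape (n_subjects, n_draws, 2)."""
        rng = np.random.Generator(np.random.PCG64(seed))
        z = rng.standard_normal((len(self.subjects), max(n_draws, 1), 2))
        z[:, 0, :] = 0.0  # first draw at the mode so omega=0 collapses exactly
        return z


def _conc_panel(sub: _Subject, cl: np.ndarray, v: float, q: float, v2: np.ndarray) -> np.ndarray:
    """Central concentration for one subject across parameter draws.

    ``cl`` and ``v2`` are arrays over draws (K,); returns (n_obs, K).
    """
    k10 = cl / v
    k12 = q / v
    k21 = q / v2
    a = k10 + k12 + k21
    disc = np.sqrt(a * a - 4.0 * k10 * k21)
    lam = np.stack([(a + disc) / 2.0, (a - disc) / 2.0], axis=-1)  # (K, 2)
    c1 = (lam[:, 0] - k21) / (lam[:, 0] - lam[:, 1])
    coef = np.stack([c1, 1.0 - c1], axis=-1)  # (K, 2)

    ts = sub.obs_times[:, None] - sub.dose_times[None, :]  # (n, m)
    dur = np.minimum(ts, sub.dose_durations[None, :])
    tail = np.maximum(ts - sub.dose_durations[None, :], 0.0)
    active = ts > 0
    lam_e = lam[None, None, :, :]  # (1, 1, K, 2)
    dur_e = np.where(active, dur, 0.0)[:, :, None, None]
    tail_e = tail[:, :, None, None]
    rate_v = (sub.dose_rates[None, :, None, None] / v)
    contrib = rate_v * coef[None, None] / lam_e * (1.0 - np.exp(-lam_e * dur_e)) * np.exp(-lam_e * tail_e)
    contrib = np.where(active[:, :, None, None], contrib, 0.0)
    return contrib.sum(axis=(1, 3))  # (n, K)


def _subject_loglik(
    sub: _Subject, params: PKParameters, z: np.ndarray
) -> float:
    """Monte-Carlo marginal log-likelihood of one subject's observations."""
    typ = typical_parameters(sub.cov, 0.0, params)
    eta = z * np.array([params.omega_cl, params.omega_v2])  # (K, 2)
    cl = typ.cl * np.exp(eta[:, 0])
    v2 = typ.v2 * np.exp(eta[:, 1])
    pred = _conc_panel(sub, cl, typ.v, typ.q, v2)  # (n, K)
    sd_prop = np.where(sub.obs_is_peak, params.sigma_prop_peak, params.sigma_prop_trough)
    sd_add = np.where(sub.obs_is_peak, params.sigma_add_peak, params.sigma_add_trough)
    var = (sd_prop[:, None] * pred) ** 2 + sd_add[:, None] ** 2
    resid = sub.obs_dv[:, None] - pred
    ll = -0.5 * (_LOG_2PI + np.log(var) + resid**2 / var)  # (n, K)
    per_draw = ll.sum(axis=0)
    if not np.all(np.isfinite(per_draw)):
        return -1e10
    if params.omega_cl == 0.0 and params.omega_v2 == 0.0:
        return float(per_draw[0])
    return float(logsumexp(per_draw) - np.log(per_draw.size))


def objective(
    theta: Dict[str, float],
    design: PKDesign,
    params: Optional[PKParameters] = None,
    n_draws: int = 100,
    draw_seed: int = 20230 ,
    draws: Optional[np.ndarray] = None,
) -> float:
    """Approximate marginal -2 log-likelihood (OFV scale).

    ``theta`` overrides fields of ``params``; variance components come from
    ``params`` unchanged.  Non-finite model predictions return a large
    penalty instead of raising.
    """
    params = (params or PKParameters()).model_copy(update=theta)
    if draws is None:
        draws = design.draws(n_draws, draw_seed)
    total = 0.0
    for sub, z in zip(design.subjects, draws):
        total += _subject_loglik(sub, params, z)
    return -2.0 * total


@dataclass
class FitResult:
    """Outcome of a fixed-effect fit."""

    estimates: Dict[str, float]
    ofv: float
    converged: bool
    free: Tuple[str, ...]
    n_obs: int
    n_evaluations: int = 0


def _to_unconstrained(name: str, value: float) -> float:
    return np.log(value) if name in _POSITIVE else value


def _from_unconstrained(name: str, x: float) -> float:
    return float(np.exp(x)) if name in _POSITIVE else float(x)


def fit_fixed_effects(
    data,
    params: Optional[PKParameters] = None,
    free: Sequence[str] = ("theta_cl", "theta_v"),
    init: Optional[Dict[str, float]] = None,
    n_draws: int = 100,
    draw_seed: int = 20230,
    xtol: float = 1e-6,
) -> FitResult:
    """Minimize the approximate OFV over the free fixed effects.

    Structural parameters are log-transformed so positivity is maintained;
    covariate coefficients are unconstrained.  Deterministic given the data,
    initial values and draw seed.
    """
    params = params or PKParameters()
    design = data if isinstance(data, PKDesign) else PKDesign(data)
    if design.n_obs < 2 * len(free):
        raise ValueError("need at least two observations per free parameter")
    init = init or {}
    x0 = np.array([
        _to_unconstrained(name, init.get(name, getattr(params, name)))
        for name in free
    ])
    draws = design.draws(n_draws, draw_seed)

    def fun(x):
        theta = {n: _from_unconstrained(n, xi) for n, xi in zip(free, x)}
        return objective(theta, design, params, draws=draws)

    res = minimize(fun, x0, method="Nelder-Mead", options={"xatol": xtol, "fatol": 1e-8, "maxiter": 2000})
    est = {n: _from_unconstrained(n, xi) for n, xi in zip(free, res.x)}
    return FitResult(
        estimates=est, ofv=float(res.fun), converged=bool(res.success),
        free=tuple(free), n_obs=design.n_obs, n_evaluations=int(res.nfev),
    )


def stepwise_covariates(
    data,
    candidates: Sequence[str] = ("theta_fem", "theta_dm", "theta_ren", "k_bun"),
    params: Optional[PKParameters] = None,
    base_free: Sequence[str] = ("theta_cl", "theta_v"),
    forward_dofv: float = 6.63,
    backward_dofv: float = 10.82,
    n_draws: int = 100,
    draw_seed: int = 20230,
) -> List[str]:
    """Stepwise covariate selection by likelihood-ratio OFV drops.

    Forward inclusion requires an OFV drop of at least ``forward_dofv``
    (p < 0.01, 1 df on the chi-square scale); backward deletion retains an
    effect only if removing it raises the OFV by at least
    ``backward_dofv``.  At each forward step the candidate with the
    largest drop enters first, making the procedure order-invariant.
    """
    params = params or PKParameters()
    design = data if isinstance(data, PKDesign) else PKDesign(data)
    null = params.model_copy(update={c: 0.0 for c in candidates})

    selected: List[str] = []
    remaining = list(candidates)

    def fit_with(effects: Sequence[str]) -> FitResult:
        return fit_fixed_effects(
            design, null, free=tuple(base_free) + tuple(effects),
            init={e: 0.0 for e in effects},
            n_draws=n_draws, draw_seed=draw_seed,
        )

    current = fit_with(selected)
    while remaining:
        trials = [(cand, fit_with(selected + [cand])) for cand in remaining]
        drops = [(current.ofv - fit.ofv, cand, fit) for cand, fit in trials]
        drops.sort(key=lambda x: (-x[0], x[1]))
        best_drop, best_cand, best_fit = drops[0]
        if best_drop < forward_dofv:
            break
        selected.append(best_cand)
        remaining.remove(best_cand)
        current = best_fit
    # backward deletion
    pruned = True
    while pruned and selected:
        pruned = False
        for cand in sorted(selected):
            reduced = fit_with([c for c in selected if c != cand])
            if reduced.ofv - current.ofv < backward_dofv:
                selected.remove(cand)
                current = reduced
                pruned = True
                break
    return selected


def vpc(
    data: pd.DataFrame,
    params: Optional[PKParameters] = None,
    n_sim: int = 200,
    percentiles: Sequence[float] = (2.5, 50.0, 97.5),
    n_time_bins: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Visual-predictive-check summary table.

    Simulates ``n_sim`` replicates of the dataset at its own design points
    (same subjects, doses and sampling times; fresh random effects and
    residual errors) and returns, per sample-type x time bin and requested
    percentile: the observed percentile and the 95% confidence band of
    that percentile across replicates.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    params = params or PKParameters()
    design = PKDesign(data)
    rng = np.random.Generator(np.random.PCG64(seed))

    obs_dv, obs_time, obs_peak, subj_idx = [], [], [], []
    for i, sub in enumerate(design.subjects):
        obs_dv.append(sub.obs_dv)
        obs_time.append(sub.obs_times)
        obs_peak.append(sub.obs_is_peak)
        subj_idx.append(np.full(len(sub.obs_times), i))
    obs_dv = np.concatenate(obs_dv)
    obs_time = np.concatenate(obs_time)
    obs_peak = np.concatenate(obs_peak)

    sims = np.empty((n_sim, obs_dv.size))
    for r in range(n_sim):
        vals = []
        for sub in design.subjects:
            typ = typical_parameters(sub.cov, 0.0, params)
            eta = rng.standard_normal(2) * np.array([params.omega_cl, params.omega_v2])
            pred = _conc_panel(
                sub, np.array([typ.cl * np.exp(eta[0])]), typ.v, typ.q,
                np.array([typ.v2 * np.exp(eta[1])]),
            )[:, 0]
            sd_prop = np.where(sub.obs_is_peak, params.sigma_prop_peak, params.sigma_prop_trough)
            sd_add = np.where(sub.obs_is_peak, params.sigma_add_peak, params.sigma_add_trough)
            dv = pred * (1.0 + sd_prop * rng.standard_normal(pred.shape))
            dv = np.maximum(dv + sd_add * rng.standard_normal(pred.shape), 0.0)
            vals.append(dv)
        sims[r] = np.concatenate(vals)

    edges = np.quantile(obs_time, np.linspace(0, 1, n_time_bins + 1))
    edges[-1] += 1e-9
    rows = []
    for is_peak in (False, True):
        for b in range(n_time_bins):
            m = (obs_peak == is_peak) & (obs_time >= edges[b]) & (obs_time < edges[b + 1])
            if m.sum() < 3:
                continue
            for p in percentiles:
                obs_p = float(np.percentile(obs_dv[m], p))
                sim_p = np.percentile(sims[:, m], p, axis=1)
                rows.append({
                    "sample_type": "peak" if is_peak else "trough",
                    "time_bin": b,
                    "percentile": p,
                    "observed": obs_p,
                    "ci_lo": float(np.percentile(sim_p, 2.5)),
                    "ci_hi": float(np.percentile(sim_p, 97.5)),
                    "n": int(m.sum()),
                })
    return pd.DataFrame(rows)
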