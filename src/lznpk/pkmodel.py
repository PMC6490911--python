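"""One-compartment oral-absorption PK model with allometric weight scaling.

The disposition model is the classic first-order absorption / first-order
elimination one-compartment model, parameterized by apparent clearance CL/F
and apparent central volume V/F (oral dosing only, F fixed at 1).  Typical
values scale allometrically with body weight relative to a 70 kg reference
(exponent 0.75 on CL, 1.0 on V), and the absorption rate constant is
parameterized as an additive offset above the elimination rate constant,

    Ka = theta_ka + CL/V,

which enforces Ka > CL/V by construction and thereby rules out flip-flop
kinetics, where absorption is rate limiting and the roles of the absorption
and elimination parameters become ambiguous.

Everything here is deterministic and closed form; the estimation, simulation
and dose-optimization modules all call into these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationModel",
    "IndividualParameters",
    "Regimen",
    "CovariateEffect",
    "individual_parameters",
    "concentration",
    "exposure_metrics",
]

REFERENCE_WEIGHT = 70.0  # kg

# relative tolerance below which ka - k is treated as zero and the
# analytic ka -> k limit of the concentration curve is used instead
_KA_K_RTOL = 1e-8


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate-parameter relationship.

    ``factor`` multiplies the typical value of the target parameter
    (``cl``, ``v`` or ``ka``, the latter acting on the absorption offset).

    Forms
    -----
    linear       : 1 + beta * (x - center)
    power        : (x / center) ** beta
    exponential  : exp(beta * (x - center))
    categorical  : 1 + beta * x          (x an indicator, center unused)
    """

    parameter: str  # "cl" | "v" | "ka"
    covariate: str
    form: str  # "linear" | "power" | "exponential" | "categorical"
    beta: float = 0.0
    center: float = 1.0

    def __post_init__(self):
        if self.parameter not in ("cl", "v", "ka"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("linear", "power", "exponential", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    def factor(self, x, beta=None):
        """Multiplicative factor for covariate value(s) ``x``."""
        b = self.beta if beta is None else beta
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            f = 1.0 + b * (x - self.center)
            # keep the typical value positive for extreme candidate betas
            return np.maximum(f, 1e-6)
        if self.form == "power":
            return (x / self.center) ** b
        if self.form == "exponential":
            return np.exp(b * (x - self.center))
        return np.maximum(1.0 + b * x, 1e-6)  # categorical shift


@dataclass(frozen=True)
class PopulationModel:
    """Population PK parameters.

    Defaults are the final-model estimates for linezolid in children with
    MDR-TB: typical CL/F 4.73 L/h and V/F 54.8 L at 70 kg, absorption offset
    0.77 1/h, between-subject variability 37% (CL) and 32% (V) expressed as
    variances of log-scale subject effects, and a combined residual error
    (additive SD 0.78 mg/L, proportional SD 25%).
    """

    theta_ka: float = 0.77        # 1/h, absorption offset above CL/V
    theta_cl: float = 4.73        # L/h at reference weight
    theta_v: float = 54.8         # L at reference weight
    omega2_cl: float = 0.37 ** 2  # var of log-scale BSV on CL
    omega2_v: float = 0.32 ** 2   # var of log-scale BSV on V
    sigma2_prop: float = 0.25 ** 2  # proportional residual variance
    sigma2_add: float = 0.78 ** 2   # additive residual variance, (mg/L)^2
    reference_weight: float = REFERENCE_WEIGHT
    allometric_cl: float = 0.75
    allometric_v: float = 1.0
    # optional extra variance components (excluded from the final model)
    omega2_iov_cl: float = 0.0      # inter-occasion variability on CL
    omega2_cohort_cl: float = 0.0   # CL-variance inflation for the flagged cohort
    covariate_effects: tuple[CovariateEffect, ...] = field(default_factory=tuple)

    def __post_init__(self):
        for name in ("theta_ka", "theta_cl", "theta_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("omega2_cl", "omega2_v", "sigma2_prop", "sigma2_add",
                     "omega2_iov_cl", "omega2_cohort_cl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def bsv_cl_pct(self) -> float:
        """Between-subject variability on CL as an approximate CV%."""
        return 100.0 * math.sqrt(self.omega2_cl)

    @property
    def bsv_v_pct(self) -> float:
        return 100.0 * math.sqrt(self.omega2_v)

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)

    def typical_values(self, weight, covariates=None):
        """Typical (eta = 0) CL, V and Ka offset at the given weight(s).

        ``covariates`` maps covariate name -> value(s) for any configured
        covariate effects; effects whose covariate is missing raise KeyError.
        """
        weight = np.asarray(weight, dtype=float)
        if np.any(weight <= 0):
            raise ValueError("weight must be positive")
        fw = weight / self.reference_weight
        cl = self.theta_cl * fw ** self.allometric_cl
        v = self.theta_v * fw ** self.allometric_v
        ka_off = self.theta_ka * np.ones_like(fw)
        for eff in self.covariate_effects:
            x = (covariates or {})[eff.covariate]
            f = eff.factor(x)
            if eff.parameter == "cl":
                cl = cl * f
            elif eff.parameter == "v":
                v = v * f
            else:
                ka_off = ka_off * f
        return cl, v, ka_off


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-level PK parameters (apparent, F = 1)."""

    cl: float  # L/h
    v: float   # L
    ka: float  # 1/h

    def __post_init__(self):
        if self.cl <= 0 or self.v <= 0 or self.ka <= 0:
            raise ValueError("cl, v and ka must all be positive")
        if self.ka <= self.k:
            raise ValueError("ka must exceed the elimination rate cl/v "
                             "(flip-flop kinetics is excluded)")

    @property
    def k(self) -> float:
        """Elimination rate constant CL/V, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class Regimen:
    """An oral dosing regimen for the closed-form profiles."""

    dose: float            # mg per administration
    interval: float = 24.0  # h (24 once daily, 48 alternate-day)
    mode: str = "single_dose"  # "single_dose" | "steady_state"

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.mode not in ("single_dose", "steady_state"):
            raise ValueError(f"unknown regimen mode {self.mode!r}")


def individual_parameters(model: PopulationModel, eta_cl: float, eta_v: float,
                          weight: float, covariates=None) -> IndividualParameters:
    """Subject parameters from population model, random effects and weight.

    CL = theta_cl * (WT/70)^0.75 * exp(eta_cl),
    V  = theta_v  * (WT/70)      * exp(eta_v),
    Ka = ka_offset + CL/V  (strictly above the elimination rate).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    tcl, tv, toff = model.typical_values(weight, covariates)
    cl = float(tcl * math.exp(eta_cl))
    v = float(tv * math.exp(eta_v))
    ka = float(toff) + cl / v
    return IndividualParameters(cl=cl, v=v, ka=ka)


def _conc_arrays(t, dose, tau, steady_state, cl, v, ka):
    """Vectorized closed-form concentration; complex-step safe.

    All array arguments broadcast; ``cl``/``v``/``ka`` may be complex (for
    complex-step differentiation in the estimator).  ``t`` is time since the
    (first) dose; at steady state the profile is periodic so t is wrapped
    into [0, tau).
    """
    t = np.asarray(t, dtype=float)
    dose = np.asarray(dose, dtype=float)
    tau = np.asarray(tau, dtype=float)
    ss = np.asarray(steady_state, dtype=bool)
    k = cl / v
    diff = ka - k
    small = np.abs(np.real(np.asarray(diff))) <= _KA_K_RTOL * np.abs(np.real(np.asarray(k)))

    t_eff = np.where(ss & (tau > 0), np.mod(t, np.where(tau > 0, tau, 1.0)), t)
    e_k = np.exp(-k * t_eff)
    e_ka = np.exp(-ka * t_eff)
    safe_diff = np.where(small, 1.0, diff)
    coef = dose * ka / (v * safe_diff)

    single = coef * (e_k - e_ka)
    with np.errstate(over="ignore", invalid="ignore"):
        ektau = np.exp(-k * tau)
        ekatau = np.exp(-ka * tau)
        accum = coef * (e_k / (1.0 - ektau) - e_ka / (1.0 - ekatau))
    regular = np.where(ss, accum, single)

    # ka -> k limit: C = D k t e^{-kt}/V (single dose); the steady-state limit
    # follows from differentiating e^{-xt}/(1 - e^{-x tau}) at x = k.
    lim_single = dose * k * t_eff * e_k / v
    with np.errstate(invalid="ignore", divide="ignore"):
        lim_ss = (dose * k / v) * e_k * (t_eff * (1.0 - ektau) + tau * ektau) / (1.0 - ektau) ** 2
    limit = np.where(ss, lim_ss, lim_single)

    return np.where(small, limit, regular)


def concentration(ind: IndividualParameters, regimen: Regimen, t):
    """Plasma concentration (mg/L) at time(s) ``t`` hours after dosing.

    Single dose:  C(t) = D ka / (V (ka-k)) (e^{-k t} - e^{-ka t}).
    Steady state: the superposition-summed profile over one interval,
    C(t) = D ka / (V (ka-k)) (e^{-k t}/(1-e^{-k tau}) - e^{-ka t}/(1-e^{-ka tau})).

    When |ka - k| underflows the ka->k limiting form is used; the curve is
    never evaluated as 0/0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = _conc_arrays(t, regimen.dose, regimen.interval,
                       regimen.mode == "steady_state", ind.cl, ind.v, ind.ka)
    out = np.real(out)
    return float(out) if out.ndim == 0 else out


def exposure_metrics(ind: IndividualParameters, daily_dose: float,
                     interval: float = 24.0) -> dict:
    """Steady-state exposure metrics at a given total daily dose.

    AUC over 24 h at steady state follows the linear-PK identity
    AUC_0-24ss = F * daily dose / CL (F = 1).  Cmax, Tmax and the pre-dose
    trough Cmin come from the steady-state closed form over one dosing
    interval (``interval`` hours, dose per administration =
    daily_dose * interval / 24).
    """
    if daily_dose <= 0:
        raise ValueError("daily_dose must be positive")
    dose = daily_dose * interval / 24.0
    reg = Regimen(dose=dose, interval=interval, mode="steady_state")
    auc = daily_dose / ind.cl

    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda x: -concentration(ind, reg, x),
                          bounds=(0.0, interval), method="bounded",
                          options={"xatol": 1e-8})
    tmax = float(res.x)
    cmax = float(-res.fun)
    cmin = float(concentration(ind, reg, 0.0))  # pre-dose trough
    return {"auc24ss": auc, "cmax": cmax, "tmax": tmax, "cmin": cmin}
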