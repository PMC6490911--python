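"""Synthetic paediatric cohorts with the statistical structure of the study.

The generator emulates two observational cohorts of children treated for
MDR-TB: ages 0.6-15.3 years, weights roughly 5-56 kg, intensive sampling
after either a single ~10 mg/kg linezolid dose or at steady state
(twice daily under 10 years of age, once daily from 10 years, capped at
600 mg/day), two sampling designs (pre-dose + 1, 2, 4, 8 and 6-or-11 h;
pre-dose + 1, 4, 10 h), concentrations from the one-compartment allometric
model with lognormal between-subject variability and combined
additive + proportional residual error, and adverse events whose hazard
rises exponentially with steady-state exposure.

Weight is generated from age through a smooth monotone growth
approximation with lognormal noise; the joint covariate distribution of the
real cohorts is emulated only at the level of ranges and frequencies.
Cohort, concentration and safety generation use independent sub-streams of
the seed so changing one leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PKDataset, make_pk_dataset
from .pkmodel import PopulationModel, _conc_arrays

__all__ = [
    "CohortDesign",
    "ToxicityModel",
    "generate_cohort",
    "generate_concentrations",
    "generate_safety",
    "generate_pk_dataset",
]

MDRPK1_TIMES = (0.0, 1.0, 2.0, 4.0, 8.0)  # plus 6 or 11 h, split 50/50
MDRPK2_TIMES = (0.0, 1.0, 4.0, 10.0)

DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class CohortDesign:
    """Study-design knobs for the synthetic cohort generator.

    Defaults reproduce the combined cohorts: 48 children, 31 of them
    sampled after a single dose (all from the second study), 9 multiple-dose
    children from the first study, routine dosing 10 mg/kg/dose twice daily
    below 10 years and once daily from 10 years, at most 600 mg/day.
    """

    n_subjects: int = 48
    age_range: tuple = (0.6, 15.3)
    single_dose_fraction: float = 31 / 48
    mdrpk1_fraction: float = 9 / 48       # multiple-dose, first cohort
    dosing_rule: str = "exact"            # "exact" 10 mg/kg or "banded"
    mg_per_kg: float = 10.0
    max_daily_dose: float = 600.0
    sex_male_fraction: float = 0.5
    hiv_fraction: float = 3 / 48
    ngt_fraction: float = 0.25
    ethnicity_black_fraction: float = 25 / 48
    fixed_weight_sampler: object = None   # callable(rng, n) -> weights; overrides growth model
    steady_state_interval_lt10: float = 12.0
    steady_state_interval_ge10: float = 24.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for f in (self.single_dose_fraction, self.mdrpk1_fraction,
                  self.sex_male_fraction, self.hiv_fraction, self.ngt_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dosing_rule not in ("exact", "banded"):
            raise ValueError("dosing_rule must be 'exact' or 'banded'")


@dataclass(frozen=True)
class ToxicityModel:
    """Exposure-dependent adverse-event process for the safety generator.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hazard_slope * (auc - auc_center))`` per
    day; grade 3/4 odds also rise with exposure.  Follow-up is lognormal in
    months.  Calibrated loosely so that at the adult-target exposure about
    60% of subjects have an event within a typical 17.7-month follow-up.
    """

    baseline_hazard: float = 0.0018      # events/day at auc_center
    log_hazard_slope: float = 0.01       # per mg.h/L of AUC0-24ss
    auc_center: float = 110.0            # mg.h/L
    grade34_intercept: float = -1.4      # logit of grade-3/4 given an event
    grade34_slope: float = 0.02          # per mg.h/L
    followup_median_months: float = 17.7
    followup_log_sd: float = 0.7
    event_type_probs: tuple = (
        ("low haemoglobin", 0.75), ("low platelets", 0.125),
        ("peripheral neuropathy", 0.0625), ("low white blood cell count", 0.0625))

    def __post_init__(self):
        if self.baseline_hazard < 0:
            raise ValueError("baseline hazard must be >= 0")


def _weight_from_age(age, rng):
    """Smooth monotone growth approximation with lognormal noise.

    Median weight 4 + 2.2*age + 0.07*age^2 kg spans roughly 5-56 kg over
    ages 0.6-15.3 y; 15% CV lognormal noise, clipped to [4.5, 60] kg.
    """
    med = 4.0 + 2.2 * age + 0.07 * age ** 2
    w = med * np.exp(rng.normal(0.0, 0.15, size=np.shape(age)))
    return np.clip(w, 4.5, 60.0)


def _banded_dose(weight):
    """Routine-care weight-banded ~10 mg/kg dose in 10 mg steps."""
    return np.maximum(np.round(weight * 10.0 / 10.0) * 10.0, 10.0)


def generate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Subject-level covariates and the dosing/sampling skeleton.

    Returns an event-level DataFrame in the canonical NONMEM-style layout
    with dose rows filled in and observation rows carrying ``DV`` = NaN,
    ready for :func:`generate_concentrations`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    n = design.n_subjects
    age = rng.uniform(*design.age_range, size=n)
    if design.fixed_weight_sampler is not None:
        weight = np.asarray(design.fixed_weight_sampler(rng, n), dtype=float)
    else:
        weight = _weight_from_age(age, rng)

    n_single = int(round(design.single_dose_fraction * n))
    n_mdrpk1 = int(round(design.mdrpk1_fraction * n))
    single = np.zeros(n, dtype=bool)
    single[rng.choice(n, size=n_single, replace=False)] = True
    multi_idx = np.flatnonzero(~single)
    cohort = np.array(["MDRPK2"] * n, dtype=object)
    if len(multi_idx):
        take = rng.choice(multi_idx, size=min(n_mdrpk1, len(multi_idx)),
                          replace=False)
        cohort[take] = "MDRPK1"

    sex = np.where(rng.random(n) < design.sex_male_fraction, "M", "F")
    hiv = (rng.random(n) < design.hiv_fraction).astype(int)
    route = np.where(rng.random(n) < design.ngt_fraction, "NGT", "oral")
    ethn = np.where(rng.random(n) < design.ethnicity_black_fraction,
                    "black", "mixed")
    # formulation tracks age: suspension for young children, tablets older
    form = np.where(age < 7.0, "suspension",
                    np.where(rng.random(n) < 0.5, "crushed", "whole"))

    rows = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        w = float(weight[i])
        per_dose = (design.mg_per_kg * w if design.dosing_rule == "exact"
                    else _banded_dose(w))
        bid = age[i] < 10.0
        ii = (design.steady_state_interval_lt10 if bid
              else design.steady_state_interval_ge10)
        daily = per_dose * 24.0 / ii
        if daily > design.max_daily_dose:
            per_dose = design.max_daily_dose * ii / 24.0
        if cohort[i] == "MDRPK1":
            extra = 6.0 if rng.random() < 0.5 else 11.0
            times = sorted(MDRPK1_TIMES + (extra,))
        else:
            times = list(MDRPK2_TIMES)
        is_ss = not single[i]
        base = dict(ID=sid, OCC=1, WT=round(w, 2), AGE=round(float(age[i]), 2),
                    SEX=sex[i], ETHN=ethn[i], HIV=int(hiv[i]), FORM=form[i],
                    ROUTE=route[i], COHORT=cohort[i])
        rows.append(dict(base, TIME=0.0, EVID=1, AMT=round(float(per_dose), 1),
                         DV=np.nan, SS=int(is_ss), II=ii if is_ss else 0.0))
        for t in times:
            rows.append(dict(base, TIME=float(t), EVID=0, AMT=0.0, DV=np.nan,
                             SS=0, II=0.0))
    df = pd.DataFrame(rows)
    cols = ["ID", "OCC", "TIME", "EVID", "AMT", "DV", "SS", "II", "WT", "AGE",
            "SEX", "ETHN", "HIV", "FORM", "ROUTE", "COHORT"]
    # dose row first, then observations in time order within each subject
    df = df[cols]
    return df


def generate_concentrations(skeleton: pd.DataFrame, model: PopulationModel,
                            seed: int, truncate_negative: bool = False):
    """Fill a skeleton's observation rows with simulated concentrations.

    Draws (eta_cl, eta_v) per subject from the between-subject distribution,
    evaluates the closed-form profile and applies combined residual error
    y = f (1 + eps_prop) + eps_add.  Negative draws are resampled by default
    (``truncate_negative`` clips to 0 instead).  Returns
    ``(PKDataset, truth)`` where ``truth`` holds the per-subject etas and
    individual parameters used.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    df = skeleton.copy().reset_index(drop=True)
    sub = df.groupby("ID", sort=False).first()
    sids = list(sub.index)
    n = len(sids)
    eta_cl = rng.normal(0.0, np.sqrt(model.omega2_cl), n)
    eta_v = rng.normal(0.0, np.sqrt(model.omega2_v), n)
    wt = sub["WT"].to_numpy(dtype=float)
    covariates = None
    if model.covariate_effects:
        from .estimate import _numeric_covariate
        covariates = {c: _numeric_covariate(sub[c])
                      for c in sub.columns if c != "WT"}
        covariates["WT"] = wt
    tcl, tv, toff = model.typical_values(wt, covariates)
    cl = tcl * np.exp(eta_cl)
    v = tv * np.exp(eta_v)
    ka = toff + cl / v
    index = {s: i for i, s in enumerate(sids)}

    dv = df["DV"].to_numpy(dtype=float)
    for (sid, occ), g in df.groupby(["ID", "OCC"], sort=False):
        i = index[sid]
        dose_rows = g[g["EVID"] == 1]
        obs_rows = g[g["EVID"] == 0]
        if not len(obs_rows):
            continue
        amt = float(dose_rows["AMT"].iloc[0])
        is_ss = bool(int(dose_rows["SS"].iloc[0]))
        ii = float(dose_rows["II"].iloc[0]) if is_ss else 24.0
        t = obs_rows["TIME"].to_numpy(dtype=float)
        f = np.real(_conc_arrays(t, amt, ii, is_ss, cl[i], v[i], ka[i]))
        y = np.empty_like(f)
        for j, fj in enumerate(f):
            for _ in range(100):
                cand = fj * (1.0 + rng.normal(0.0, np.sqrt(model.sigma2_prop))) \
                    + rng.normal(0.0, np.sqrt(model.sigma2_add))
                if cand >= 0.0:
                    break
            else:
                cand = 0.0
            y[j] = max(cand, 0.0) if truncate_negative else cand
        dv[obs_rows.index] = np.round(y, 6)
    df["DV"] = dv

    truth = pd.DataFrame({"ID": sids, "WT": wt, "eta_cl": eta_cl,
                          "eta_v": eta_v, "cl": cl, "v": v, "ka": ka})
    dataset = make_pk_dataset(df, provenance=f"synthetic seed={seed}")
    return dataset, truth


def generate_pk_dataset(design: CohortDesign, model: PopulationModel,
                        seed: int):
    """Convenience wrapper: cohort skeleton + simulated concentrations."""
    skeleton = generate_cohort(design, seed)
    return generate_concentrations(skeleton, model, seed)


def generate_safety(subjects: pd.DataFrame, tox: ToxicityModel,
                    seed: int) -> pd.DataFrame:
    """Simulated time-to-event safety records for subjects with exposures.

    ``subjects`` needs columns ``ID`` (or ``subject_id``) and ``auc24ss``;
    an optional ``cmin`` column is carried through.  Returns one row per
    subject in the safety-CSV layout (subjects without an event have an
    empty event_type); onset never exceeds follow-up.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
    df = subjects.rename(columns={"ID": "subject_id"}).copy()
    if "auc24ss" not in df.columns:
        raise ValueError("subjects must carry an 'auc24ss' column")
    n = len(df)
    auc = df["auc24ss"].to_numpy(dtype=float)
    followup = (tox.followup_median_months
                * np.exp(rng.normal(0.0, tox.followup_log_sd, n))
                * DAYS_PER_MONTH)
    followup = np.round(np.clip(followup, 30.0, 720.0))
    hazard = tox.baseline_hazard * np.exp(
        tox.log_hazard_slope * (auc - tox.auc_center))
    with np.errstate(divide="ignore"):
        t_event = np.where(hazard > 0,
                           rng.exponential(1.0, n) / np.where(hazard > 0, hazard, 1.0),
                           np.inf)
    has_event = t_event <= followup
    onset = np.where(has_event, np.ceil(np.maximum(t_event, 1.0)), np.nan)

    types, probs = zip(*tox.event_type_probs)
    probs = np.asarray(probs) / np.sum(probs)
    etype = rng.choice(types, size=n, p=probs)
    p34 = 1.0 / (1.0 + np.exp(-(tox.grade34_intercept
                                + tox.grade34_slope * (auc - tox.auc_center))))
    is34 = rng.random(n) < p34
    grade = np.where(is34, rng.integers(3, 5, n), rng.integers(1, 3, n))

    out = pd.DataFrame({
        "subject_id": df["subject_id"],
        "event_type": np.where(has_event, etype, ""),
        "grade": np.where(has_event, grade, 0),
        "onset_day": onset,
        "related": np.where(has_event, 1, 0),
        "followup_days": followup,
        "discontinuation_day": followup,
        "auc24ss": auc,
    })
    if "cmin" in df.columns:
        out["cmin"] = df["cmin"].to_numpy(dtype=float)
    return out
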