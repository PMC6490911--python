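"""Reading, validation and writing of the pipeline's file formats.

The longitudinal PK dataset follows the NONMEM convention: one row per
event, ``EVID`` 1 for doses (with ``AMT`` in mg) and 0 for observations
(with ``DV`` in mg/L), ``SS``/``II`` marking steady-state dosing with its
interdose interval in hours.  Arbitrary source column names are absorbed by
a dialect map.  Units are fixed internally: hours, mg, mg/L, kg, years.

Validation is total: a file either yields a dataset satisfying every record
invariant or a diagnostic naming the first offending row.  Concentrations
outside the assay calibration range (0.1-30 mg/L) are flagged as warnings,
never errors.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PKDataset",
    "ConfigurationError",
    "DatasetParseError",
    "DatasetValidationError",
    "CalibrationWarning",
    "read_pk_dataset",
    "write_pk_dataset",
    "read_safety_dataset",
    "write_result",
    "read_fit_result",
    "read_dose_table",
    "LLOQ",
    "ULOQ",
]

LLOQ = 0.1   # mg/L, lower limit of quantitation of the assay
ULOQ = 30.0  # mg/L, upper limit

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "DV", "WT")
OPTIONAL_DEFAULTS = {
    "OCC": 1, "SS": 0, "II": 0.0, "AGE": np.nan,
    "SEX": "", "ETHN": "", "HIV": 0, "FORM": "", "ROUTE": "", "COHORT": "",
}
ALL_COLUMNS = REQUIRED_COLUMNS + tuple(OPTIONAL_DEFAULTS)


class ConfigurationError(Exception):
    """Missing or inconsistent configuration (e.g. absent required column)."""


class DatasetParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


class DatasetValidationError(ValueError):
    """A record invariant is violated; the message names the first bad row."""


class CalibrationWarning(UserWarning):
    """Observed concentration outside the assay calibration range."""


@dataclass
class PKDataset:
    """A validated longitudinal PK dataset (one row per dose/observation)."""

    df: pd.DataFrame
    provenance: str = ""
    warnings: list = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def subject_ids(self):
        return list(dict.fromkeys(self.df["ID"]))

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def subject_table(self) -> pd.DataFrame:
        """First-row covariates per subject (weight, age, categoricals)."""
        cols = [c for c in ("WT", "AGE", "SEX", "ETHN", "HIV", "FORM",
                            "ROUTE", "COHORT") if c in self.df.columns]
        return self.df.groupby("ID", sort=False)[cols].first().reset_index()


def _validate(df: pd.DataFrame) -> list:
    """Check every record invariant; raise on the first offending row."""
    warns = []
    ids = df["ID"].to_numpy()
    # subjects must form contiguous blocks
    first_seen, last_seen = {}, {}
    for i, s in enumerate(ids):
        if s in last_seen and last_seen[s] != i - 1 and s != ids[i - 1]:
            raise DatasetValidationError(
                f"row {i}: subject {s!r} is not a contiguous block")
        first_seen.setdefault(s, i)
        last_seen[s] = i

    time = df["TIME"].to_numpy(dtype=float)
    evid = df["EVID"].to_numpy(dtype=int)
    amt = df["AMT"].to_numpy(dtype=float)
    dv = df["DV"].to_numpy(dtype=float)
    wt = df["WT"].to_numpy(dtype=float)
    ss = df["SS"].to_numpy(dtype=int)
    ii = df["II"].to_numpy(dtype=float)

    if np.any(time < 0):
        i = int(np.argmax(time < 0))
        raise DatasetValidationError(f"row {i}: negative time {time[i]}")
    bad = (evid == 1) & ~(amt > 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DatasetValidationError(f"row {i}: dose row with amount {amt[i]}")
    bad = (evid == 0) & ~(dv >= 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DatasetValidationError(
            f"row {i}: observation with concentration {dv[i]}")
    if np.any(~(wt > 0)):
        i = int(np.argmax(~(wt > 0)))
        raise DatasetValidationError(f"row {i}: non-positive weight {wt[i]}")
    bad = (evid == 1) & (ss == 1) & ~(ii > 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DatasetValidationError(
            f"row {i}: steady-state dose without interdose interval")

    # per subject/occasion: times non-decreasing, observations covered by a
    # preceding dose (or a steady-state dose at any time on the occasion)
    for (sid, occ), g in df.groupby(["ID", "OCC"], sort=False):
        tg = g["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(tg) < 0):
            i = g.index[int(np.argmax(np.diff(tg) < 0)) + 1]
            raise DatasetValidationError(
                f"row {i}: time decreases within subject {sid!r} occasion {occ}")
        eg = g["EVID"].to_numpy(dtype=int)
        obs_idx = np.flatnonzero(eg == 0)
        if obs_idx.size:
            has_ss_dose = bool(np.any((eg == 1) & (g["SS"].to_numpy(dtype=int) == 1)))
            dose_pos = np.flatnonzero(eg == 1)
            if dose_pos.size == 0:
                i = g.index[obs_idx[0]]
                raise DatasetValidationError(
                    f"row {i}: subject {sid!r} occasion {occ} has observations "
                    "but no dose information")
            if not has_ss_dose and obs_idx[0] < dose_pos[0]:
                # pre-dose sample at time 0 on a single-dose occasion is fine
                t_first = tg[obs_idx[0]]
                if t_first > 0:
                    i = g.index[obs_idx[0]]
                    raise DatasetValidationError(
                        f"row {i}: observation precedes any dose on subject "
                        f"{sid!r} occasion {occ}")

    obs = df[df["EVID"] == 0]
    out = obs[(obs["DV"] < LLOQ) | (obs["DV"] > ULOQ)]
    for i, row in out.iterrows():
        msg = (f"row {i}: concentration {row['DV']} mg/L outside the assay "
               f"calibration range [{LLOQ}, {ULOQ}] mg/L")
        warns.append(msg)
        _warnings.warn(msg, CalibrationWarning, stacklevel=3)
    return warns


def make_pk_dataset(df: pd.DataFrame, provenance: str = "") -> PKDataset:
    """Validate a canonical-column DataFrame and wrap it as a PKDataset."""
    df = df.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} is missing")
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    for col in ("TIME", "AMT", "DV", "WT", "II", "AGE"):
        try:
            df[col] = pd.to_numeric(df[col].replace({"": np.nan, ".": np.nan}))
        except (ValueError, TypeError):
            cleaned = df[col].replace({"": np.nan, ".": np.nan})
            coerced = pd.to_numeric(cleaned, errors="coerce")
            bad = coerced.isna() & cleaned.notna()
            i = int(np.argmax(bad.to_numpy()))
            raise DatasetParseError(
                f"row {i}: non-numeric value {df[col].iloc[i]!r} in column {col}")
    df["AMT"] = df["AMT"].fillna(0.0)
    df["DV"] = df["DV"].fillna(0.0)
    for col in ("EVID", "SS", "OCC", "HIV"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    for col in ("SEX", "ETHN", "FORM", "ROUTE", "COHORT"):
        df[col] = df[col].fillna("").astype(str)
    df = df[list(ALL_COLUMNS)].reset_index(drop=True)
    warns = _validate(df)
    return PKDataset(df=df, provenance=provenance, warnings=warns)


def read_pk_dataset(path, dialect: dict | None = None,
                    drop_blq: bool = False) -> PKDataset:
    """Read and validate a PK dataset from CSV.

    ``dialect`` maps source column names to the canonical NONMEM-style names
    (e.g. ``{"subject": "ID", "conc": "DV"}``).  ``drop_blq`` removes
    observations below the 0.1 mg/L quantitation limit; by default they are
    retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    df.columns = [c.upper() for c in df.columns]
    if drop_blq and "DV" in df.columns and "EVID" in df.columns:
        dv = pd.to_numeric(df["DV"], errors="coerce")
        df = df[~((df["EVID"].astype(int) == 0) & (dv < LLOQ))]
    return make_pk_dataset(df, provenance=str(path))


def _check_overwrite(path, force):
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(
            f"{path} exists; pass force=True to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def write_pk_dataset(dataset: PKDataset, path, force: bool = False) -> None:
    path = _check_overwrite(path, force)
    dataset.df.to_csv(path, index=False)


def write_result(result, path, force: bool = False) -> None:
    """Serialize a finalized result object.

    Fit results (anything exposing ``to_dict``) are written as JSON with
    full float precision; dose tables and plain DataFrames as CSV.
    Re-reading reproduces integers bit-identically and reals to at least
    12 significant digits.  Refuses to overwrite unless ``force``.
    """
    path = _check_overwrite(path, force)
    if hasattr(result, "to_dict") and not isinstance(result, pd.DataFrame):
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=1)
    elif hasattr(result, "to_frame"):
        result.to_frame().to_csv(path, index=False)
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
    else:
        raise TypeError(f"do not know how to serialize {type(result).__name__}")


def read_fit_result(path):
    from .estimate import FitResult
    with open(path) as fh:
        return FitResult.from_dict(json.load(fh))


def read_dose_table(path):
    from .doseopt import DoseTable, WeightBand
    df = pd.read_csv(path)
    bands = [WeightBand(lower=r.band_lo_kg, upper=r.band_hi_kg, dose=r.dose_mg,
                        interval=r.interval_h,
                        note="" if pd.isna(r.formulation_note) else str(r.formulation_note))
             for r in df.itertuples()]
    regime = str(df["regime"].iloc[0]) if "regime" in df.columns and len(df) else "exact"
    return DoseTable(bands=tuple(bands), regime=regime)


def read_safety_dataset(path):
    """Read a safety CSV into (subjects, events) frames.

    Expected columns: subject_id, event_type, grade, onset_day, related,
    followup_days, discontinuation_day, and optionally auc24ss / cmin.
    Rows with an empty event_type carry subject-level follow-up only.
    """
    from .safety import SafetyDataset
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    need = {"subject_id", "followup_days"}
    missing = need - set(df.columns)
    if missing:
        raise ConfigurationError(f"safety file missing columns {sorted(missing)}")
    sub_cols = ["subject_id", "followup_days"]
    for c in ("discontinuation_day", "auc24ss", "cmin"):
        if c in df.columns:
            sub_cols.append(c)
    subjects = df.groupby("subject_id", sort=False)[sub_cols[1:]].first().reset_index()
    has_event = df.get("event_type", pd.Series("", index=df.index)).fillna("") != ""
    events = df[has_event][[c for c in ("subject_id", "event_type", "grade",
                                        "onset_day", "related") if c in df.columns]]
    return SafetyDataset(subjects=subjects.reset_index(drop=True),
                         events=events.reset_index(drop=True))
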