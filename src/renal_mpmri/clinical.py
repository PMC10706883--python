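"""Clinical derivations: eGFR, eGFR slope, proteinuria transform, progression label.

eGFR is computed with the 2009 CKD-EPI creatinine equation.  Disease
trajectory is summarised per subject by the ordinary-least-squares slope of
eGFR on time (in years, using all available eGFR values); a decline of at
least 5 mL/min/1.73 m²/year classifies the subject as a CKD progressor,
otherwise stable.  The urine protein-to-creatinine ratio (PCR) is analysed
as log10(PCR) because of its skewed distribution (the base only rescales;
rank-based statistics are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PROGRESSION_THRESHOLD",
    "SubjectRecord",
    "egfr_ckdepi2009",
    "creatinine_for_egfr",
    "egfr_slope",
    "classify_progression",
    "log_pcr",
    "derive_subject",
]

#: eGFR slope (mL/min/1.73 m²/yr) at or below which a subject is a progressor.
PROGRESSION_THRESHOLD = -5.0

UMOL_PER_MGDL = 88.4  # creatinine: 1 mg/dL = 88.4 µmol/L


def egfr_ckdepi2009(
    creatinine,
    age,
    sex,
    black=False,
    unit: str = "umol/L",
):
    """2009 CKD-EPI creatinine eGFR (mL/min/1.73 m²), vectorised.

    eGFR = 141 * min(Scr/κ, 1)^a * max(Scr/κ, 1)^-1.209 * 0.993^Age
           * 1.018 [female] * 1.159 [black]

    with κ = 0.7 (F) / 0.9 (M) and a = -0.329 (F) / -0.411 (M); Scr in
    mg/dL.  ``sex`` is "F"/"M"; ``unit`` selects µmol/L (divided by 88.4)
    or mg/dL input.
    """
    scr = np.asarray(creatinine, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    age = np.asarray(age, dtype=float)
    if np.any(age < 18):
        raise ValueError("equation applies to adults (age >= 18)")
    if unit == "umol/L":
        scr = scr / UMOL_PER_MGDL
    elif unit != "mg/dL":
        raise ValueError(f"unknown creatinine unit {unit!r}")

    female = np.asarray(sex) == "F"
    kappa = np.where(female, 0.7, 0.9)
    a = np.where(female, -0.329, -0.411)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** a
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993**age
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(black, dtype=bool), 1.159, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def creatinine_for_egfr(egfr, age, sex, black=False, unit: str = "umol/L"):
    """Invert the 2009 CKD-EPI equation: creatinine giving a target eGFR.

    Closed-form piecewise inverse (the equation is strictly decreasing in
    creatinine).  Used by the cohort simulator to back-compute creatinine
    series from prescribed eGFR trajectories.
    """
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr <= 0):
        raise ValueError("eGFR must be positive")
    female = np.asarray(sex) == "F"
    kappa = np.where(female, 0.7, 0.9)
    a = np.where(female, -0.329, -0.411)
    c = (
        141.0
        * 0.993 ** np.asarray(age, dtype=float)
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(black, dtype=bool), 1.159, 1.0)
    )
    # ratio <= 1 branch: egfr = c * ratio^a (a < 0); valid when egfr >= c.
    with np.errstate(invalid="ignore"):
        r_low = (egfr / c) ** (1.0 / a)
        r_high = (egfr / c) ** (-1.0 / 1.209)
    ratio = np.where(egfr >= c, r_low, r_high)
    scr = ratio * kappa  # mg/dL
    if unit == "umol/L":
        scr = scr * UMOL_PER_MGDL
    elif unit != "mg/dL":
        raise ValueError(f"unknown creatinine unit {unit!r}")
    return scr if scr.ndim else float(scr)


def egfr_slope(dates, egfr_values) -> tuple[float, bool]:
    """OLS slope of eGFR on time in years; returns (slope, low_confidence).

    ``dates`` may be datetimes (parsed ISO-8601) or numeric days.  Time is
    measured in years from the first measurement (365.25 days/year); the
    slope is translation invariant.  Fewer than 2 points is an error;
    exactly 2 points yields a slope flagged low-confidence.
    """
    egfr_values = np.asarray(egfr_values, dtype=float)
    if len(egfr_values) < 2:
        raise ValueError("at least 2 eGFR values are required for a slope")
    arr = np.asarray(dates)
    if np.issubdtype(arr.dtype, np.number):
        t_days = arr.astype(float)
    else:
        dt = pd.to_datetime(arr)
        t_days = np.asarray((dt - dt[0]) / pd.Timedelta(days=1), dtype=float)
    if np.any(np.diff(t_days) <= 0):
        raise ValueError("dates must be strictly increasing")
    t = (t_days - t_days[0]) / 365.25
    slope = float(np.polyfit(t, egfr_values, 1)[0])
    return slope, len(egfr_values) < 3


def classify_progression(slope: float) -> str:
    """Label a subject from their eGFR slope: decline ≥ 5/yr -> progressor."""
    return "progressor" if slope <= PROGRESSION_THRESHOLD else "stable"


def log_pcr(pcr):
    """log10 of the urine protein-to-creatinine ratio; PCR must be positive."""
    pcr = np.asarray(pcr, dtype=float)
    if np.any(pcr <= 0):
        raise ValueError("PCR must be positive to take its logarithm")
    out = np.log10(pcr)
    return out if out.ndim else float(out)


@dataclass
class SubjectRecord:
    """Longitudinal clinical record with derived eGFR series, slope and label."""

    subject_id: str
    sex: str
    ethnicity_black: bool
    visits: pd.DataFrame  # columns: visit_date, age, creatinine_umol_L, pcr_mg_mmol
    egfr: np.ndarray = field(default=None)
    slope: float = float("nan")
    slope_low_confidence: bool = False
    label: str = ""


def derive_subject(
    subject_id: str,
    sex: str,
    ethnicity_black: bool,
    visits: pd.DataFrame,
) -> SubjectRecord:
    """Compute the eGFR series, slope and progression label for one subject."""
    visits = visits.sort_values("visit_date").reset_index(drop=True)
    egfr = egfr_ckdepi2009(
        visits["creatinine_umol_L"].to_numpy(),
        visits["age"].to_numpy(),
        np.full(len(visits), sex),
        black=np.full(len(visits), ethnicity_black),
        unit="umol/L",
    )
    slope, lowconf = egfr_slope(visits["visit_date"].to_numpy(), egfr)
    return SubjectRecord(
        subject_id=subject_id,
        sex=sex,
        ethnicity_black=ethnicity_black,
        visits=visits,
        egfr=np.asarray(egfr, dtype=float),
        slope=slope,
        slope_low_confidence=lowconf,
        label=classify_progression(slope),
    )
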