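"""Digital kidney phantom and synthetic CKD cohort with known ground truth.

The imaging phantom places two axis-aligned ellipsoidal "kidneys" in a 3D
grid at the acquisition resolution (3 × 3 mm in-plane, 5 mm slices).  Each
kidney has an inner medullary ellipsoid (a concentric, scaled copy) and an
outer cortical shell.  Every in-kidney voxel is assigned ground-truth
tissue parameters (T1, M0, ADC, T2*, perfusion, arterial transit time,
bolus duration) drawn from a per-tissue table plus an intra-tissue
standard deviation, so every downstream fitting, segmentation and
statistics stage can be validated against a known answer.  Anatomic
realism is deliberately out of scope: what matters is that cortex and
medulla are histogram-separable, as they are in vivo at 3 T.

Signal simulators produce the four acquisition series of the protocol:

* inversion recovery, 13 TIs from 200 to 1500 ms;
* diffusion weighting, 11 b-values 0–500 s/mm² in three orthogonal
  directions;
* multi-echo gradient echo, 12 echoes from TE 5 ms in 3 ms steps;
* FAIR ASL selective/non-selective pairs at PLDs of 300/500/700/900 ms
  (4 pairs each) and 1800 ms (25 pairs), plus a base M0 volume.

Noise is Gaussian on the magnitude signal by default (adequate at the
simulated SNRs and keeps analytic oracles simple); Rician noise is
available by flag.

The cohort simulator emulates a two-group CKD study: per subject an eGFR
trajectory (intercept + slope·t) is prescribed, creatinine is
back-computed through the inverse CKD-EPI equation with multiplicative
measurement noise, and both the *intended* group and the *realized* label
(re-derived from the noisy creatinine series by the classification rule)
are recorded; analyses always use realized labels.  Per-visit tissue
summaries follow group-specific baseline distributions and per-year
drifts with a between-session measurement CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import clinical
from .asl import ASLConstants, forward_kinetic
from .core import AcquisitionSeries, ParameterMap, TissueMasks

__all__ = [
    "PAPER_TI_MS",
    "PAPER_TE_MS",
    "PAPER_B_VALUES",
    "PAPER_PLD_SCHEME",
    "MEASURES",
    "MEASURE_UNITS",
    "PhantomSpec",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "make_phantom",
    "simulate_ir_series",
    "simulate_dwi_series",
    "simulate_mfe_series",
    "simulate_asl_pairs",
    "simulate_cohort",
]

# Acquisition protocol defaults.
PAPER_TI_MS = (200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0,
               1000.0, 1100.0, 1200.0, 1300.0, 1500.0)
PAPER_TE_MS = tuple(5.0 + 3.0 * i for i in range(12))  # 5, 8, ..., 38 ms
PAPER_B_VALUES = (0.0, 5.0, 10.0, 20.0, 30.0, 50.0, 100.0, 200.0, 300.0,
                  400.0, 500.0)
PAPER_PLD_SCHEME = {300: 4, 500: 4, 700: 4, 900: 4, 1800: 25}

#: Cohort-level tissue measures and their units.
MEASURES = (
    "tkv", "t1_cortex", "t1_medulla", "adc_cortex", "adc_medulla",
    "t2star_cortex", "t2star_medulla", "perfusion_cortex", "perfusion_medulla",
)
MEASURE_UNITS = {
    "tkv": "mL",
    "t1_cortex": "ms", "t1_medulla": "ms",
    "adc_cortex": "mm^2/s", "adc_medulla": "mm^2/s",
    "t2star_cortex": "ms", "t2star_medulla": "ms",
    "perfusion_cortex": "mL/100g/min", "perfusion_medulla": "mL/100g/min",
}

_PARAM_NAMES = ("t1", "m0", "adc", "t2star", "perfusion", "att", "tau")
_PARAM_UNITS = {
    "t1": "ms", "m0": "a.u.", "adc": "mm^2/s", "t2star": "ms",
    "perfusion": "mL/100g/min", "att": "ms", "tau": "ms",
}


def _default_tissue_params() -> dict[str, dict[str, float]]:
    return {
        "background": {p: 0.0 for p in _PARAM_NAMES},
        "cortex": {"t1": 1500.0, "m0": 100.0, "adc": 2.2e-3, "t2star": 55.0,
                   "perfusion": 250.0, "att": 400.0, "tau": 800.0},
        "medulla": {"t1": 1900.0, "m0": 100.0, "adc": 1.9e-3, "t2star": 40.0,
                    "perfusion": 80.0, "att": 600.0, "tau": 800.0},
    }


def _default_intra_sd() -> dict[str, float]:
    return {"t1": 50.0, "m0": 2.0, "adc": 0.08e-3, "t2star": 2.5,
            "perfusion": 12.0, "att": 20.0, "tau": 0.0}


@dataclass
class PhantomSpec:
    """Specification of the digital kidney phantom.

    ``tissue_params`` maps tissue -> parameter -> ground-truth mean;
    ``intra_tissue_sd`` gives the voxel-to-voxel SD per parameter (applied
    within cortex and medulla only).  ``noise_sd_frac`` is the acquisition
    noise SD as a fraction of the cortex M0.  ``size_scale`` scales the
    kidney semi-axes isotropically (used to prescribe per-subject TKV).
    The seed fixes all randomness.
    """

    shape: tuple[int, int, int] = (48, 48, 16)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 5.0)
    tissue_params: dict[str, dict[str, float]] = field(
        default_factory=_default_tissue_params)
    intra_tissue_sd: dict[str, float] = field(default_factory=_default_intra_sd)
    noise_sd_frac: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0
    kidney_semiaxes_mm: tuple[float, float, float] = (20.0, 38.0, 20.0)
    medulla_scale: float = 0.55
    size_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValueError("phantom grid must be at least 8 voxels per dimension")
        if self.noise_sd_frac < 0:
            raise ValueError("noise SD must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for tissue, params in self.tissue_params.items():
            for name, value in params.items():
                if tissue != "background" and value <= 0:
                    raise ValueError(f"{tissue} {name} must be positive")
                if tissue == "background" and value < 0:
                    raise ValueError("background parameters must be >= 0")

    @property
    def noise_sd(self) -> float:
        return self.noise_sd_frac * self.tissue_params["cortex"]["m0"]

    def analytic_kidney_volume_ml(self) -> float:
        """Exact ellipsoid-pair volume implied by the spec, in mL."""
        a, b, c = (s * self.size_scale for s in self.kidney_semiaxes_mm)
        return 2.0 * (4.0 / 3.0) * np.pi * a * b * c / 1000.0


def make_phantom(
    spec: PhantomSpec,
) -> tuple[TissueMasks, dict[str, ParameterMap]]:
    """Build masks and ground-truth parameter maps for the phantom."""
    nx, ny, nz = spec.shape
    vx, vy, vz = spec.voxel_size_mm
    x = (np.arange(nx) + 0.5) * vx
    y = (np.arange(ny) + 0.5) * vy
    z = (np.arange(nz) + 0.5) * vz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    cx = nx * vx / 2.0
    cy = ny * vy / 2.0
    cz = nz * vz / 2.0
    a, b, c = (s * spec.size_scale for s in spec.kidney_semiaxes_mm)
    offset = nx * vx / 4.0  # kidney centres at 1/4 and 3/4 of the x extent
    if a > offset or b > ny * vy / 2.0 or c > nz * vz / 2.0:
        raise ValueError(
            f"kidney semi-axes ({a:.0f}, {b:.0f}, {c:.0f}) mm do not fit the "
            f"{nx * vx:.0f} x {ny * vy:.0f} x {nz * vz:.0f} mm grid")

    kidney = np.zeros(spec.shape, dtype=bool)
    medulla = np.zeros(spec.shape, dtype=bool)
    for sign in (-1.0, 1.0):
        dx = (X - (cx + sign * offset)) / a
        dy = (Y - cy) / b
        dz = (Z - cz) / c
        r2 = dx**2 + dy**2 + dz**2
        kidney |= r2 <= 1.0
        medulla |= r2 <= spec.medulla_scale**2
    cortex = kidney & ~medulla

    masks = TissueMasks(kidney=kidney, cortex=cortex, medulla=medulla,
                        voxel_volume_mm3=float(vx * vy * vz))

    rng = np.random.default_rng(spec.seed)
    maps: dict[str, ParameterMap] = {}
    for name in _PARAM_NAMES:
        vol = np.full(spec.shape, spec.tissue_params["background"][name])
        sd = spec.intra_tissue_sd.get(name, 0.0)
        for tissue, mask in (("cortex", cortex), ("medulla", medulla)):
            mean = spec.tissue_params[tissue][name]
            draws = mean + sd * rng.standard_normal(int(mask.sum()))
            # keep parameters physical: truncate far-tail draws
            draws = np.maximum(draws, 0.05 * mean)
            vol[mask] = draws
        maps[name] = ParameterMap(vol, _PARAM_UNITS[name], name,
                                  voxel_size_mm=spec.voxel_size_mm)
    return masks, maps


def _add_noise(signal: np.ndarray, sd: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return signal
    if model == "gaussian":
        return signal + sd * rng.standard_normal(signal.shape)
    if model == "rician":
        re = signal + sd * rng.standard_normal(signal.shape)
        im = sd * rng.standard_normal(signal.shape)
        return np.hypot(re, im)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_ir_series(
    maps: dict[str, ParameterMap],
    ti_ms=PAPER_TI_MS,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
    inversion_efficiency: float = 1.0,
) -> AcquisitionSeries:
    """Magnitude inversion-recovery series |M0 (1 - 2 eps exp(-TI/T1))| + noise."""
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(ti <= 0):
        raise ValueError("all inversion times must be positive")
    t1 = maps["t1"].data
    m0 = maps["m0"].data
    with np.errstate(divide="ignore"):
        decay = np.where((t1 > 0)[..., None],
                         np.exp(-ti[None, None, None, :]
                                / np.where(t1 > 0, t1, 1.0)[..., None]), 0.0)
    signal = np.abs(m0[..., None] * (1.0 - 2.0 * inversion_efficiency * decay))
    rng = np.random.default_rng(seed)
    return AcquisitionSeries(
        data=_add_noise(signal, noise_sd, noise_model, rng),
        params={"TI_ms": ti},
        voxel_size_mm=maps["t1"].voxel_size_mm,
        meta={"sequence": "inversion_recovery"},
    )


def simulate_dwi_series(
    maps: dict[str, ParameterMap],
    b_values=PAPER_B_VALUES,
    n_directions: int = 3,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
    adc_per_direction: list[np.ndarray] | None = None,
) -> AcquisitionSeries:
    """DWI series S0 exp(-b ADC) + noise; isotropic by default.

    ``adc_per_direction`` (one ADC volume per direction) injects
    anisotropy for validation of the direction-combination step.
    """
    b = np.asarray(b_values, dtype=float)
    s0 = maps["m0"].data
    if adc_per_direction is None:
        adc_dirs = [maps["adc"].data] * n_directions
    else:
        if len(adc_per_direction) != n_directions:
            raise ValueError("need one ADC volume per direction")
        adc_dirs = [np.asarray(a) for a in adc_per_direction]

    vols, b_out, dir_out = [], [], []
    for bv in b:
        for d in range(n_directions):
            vols.append(s0 * np.exp(-bv * adc_dirs[d]))
            b_out.append(bv)
            dir_out.append(d)
    signal = np.stack(vols, axis=-1)
    rng = np.random.default_rng(seed)
    return AcquisitionSeries(
        data=_add_noise(signal, noise_sd, noise_model, rng),
        params={"b_s_mm2": np.array(b_out), "direction": np.array(dir_out)},
        voxel_size_mm=maps["adc"].voxel_size_mm,
        meta={"sequence": "dwi"},
    )


def simulate_mfe_series(
    maps: dict[str, ParameterMap],
    te_ms=PAPER_TE_MS,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> AcquisitionSeries:
    """Multi-echo gradient-echo series S0 exp(-TE/T2*) + noise."""
    te = np.asarray(te_ms, dtype=float)
    if te.size < 3:
        raise ValueError("multi-echo simulation needs at least 3 echoes")
    t2s = maps["t2star"].data
    s0 = maps["m0"].data
    with np.errstate(divide="ignore"):
        decay = np.where((t2s > 0)[..., None],
                         np.exp(-te[None, None, None, :]
                                / np.where(t2s > 0, t2s, 1.0)[..., None]), 0.0)
    signal = s0[..., None] * decay
    rng = np.random.default_rng(seed)
    return AcquisitionSeries(
        data=_add_noise(signal, noise_sd, noise_model, rng),
        params={"TE_ms": te},
        voxel_size_mm=maps["t2star"].voxel_size_mm,
        meta={"sequence": "multi_echo_gre"},
    )


def simulate_asl_pairs(
    maps: dict[str, ParameterMap],
    pld_scheme: dict[int, int] | None = None,
    constants: ASLConstants | None = None,
    noise_sd: float = 0.0,
    noise_model: str = "gaussian",
    seed: int = 0,
    static_fraction: float = 0.3,
) -> tuple[AcquisitionSeries, ParameterMap]:
    """FAIR S/NS pairs whose difference follows the pulsed kinetic model.

    The non-selective volume is a static tissue signal; the selective
    volume adds the ground-truth ΔM from :func:`forward_kinetic` at the
    voxel's perfusion, transit time and bolus duration.  Returns the
    series and the base M0 map.
    """
    scheme = dict(PAPER_PLD_SCHEME if pld_scheme is None else pld_scheme)
    constants = constants or ASLConstants()
    f = maps["perfusion"].data
    att = maps["att"].data
    tau = maps["tau"].data
    m0 = maps["m0"].data
    t1 = maps["t1"].data

    rng = np.random.default_rng(seed)
    static = static_fraction * m0
    vols, labels, plds = [], [], []
    for pld in sorted(scheme):
        dm = forward_kinetic(f, att, tau, float(pld), m0, t1, constants)
        for _ in range(scheme[pld]):
            vols.append(static + dm)
            labels.append("S")
            plds.append(pld)
            vols.append(static.copy())
            labels.append("NS")
            plds.append(pld)
    signal = np.stack(vols, axis=-1)
    series = AcquisitionSeries(
        data=_add_noise(signal, noise_sd, noise_model, rng),
        params={"label": np.array(labels), "PLD_ms": np.array(plds, dtype=float)},
        voxel_size_mm=maps["m0"].voxel_size_mm,
        meta={"sequence": "fair_asl"},
    )
    m0_map = ParameterMap(
        _add_noise(m0.copy(), noise_sd, noise_model, rng), "a.u.", "M0_base",
        voxel_size_mm=maps["m0"].voxel_size_mm)
    return series, m0_map


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

def _default_tissue_baseline() -> dict[str, dict[str, tuple[float, float]]]:
    """(mean, between-subject SD) per measure per group.

    Progressors have higher cortex and medulla T1 and lower cortex
    perfusion at baseline; TKV, ADC, T2* and medulla perfusion do not
    differ between groups.  Magnitudes are package defaults chosen for
    clear separability at pilot-study sample sizes.
    """
    return {
        "tkv": {"stable": (250.0, 35.0), "progressor": (250.0, 35.0)},
        "t1_cortex": {"stable": (1450.0, 40.0), "progressor": (1570.0, 40.0)},
        "t1_medulla": {"stable": (1850.0, 55.0), "progressor": (2000.0, 55.0)},
        "adc_cortex": {"stable": (2.2e-3, 1.0e-4), "progressor": (2.2e-3, 1.0e-4)},
        "adc_medulla": {"stable": (1.9e-3, 1.0e-4), "progressor": (1.9e-3, 1.0e-4)},
        "t2star_cortex": {"stable": (55.0, 4.0), "progressor": (55.0, 4.0)},
        "t2star_medulla": {"stable": (40.0, 4.0), "progressor": (40.0, 4.0)},
        "perfusion_cortex": {"stable": (230.0, 30.0), "progressor": (140.0, 30.0)},
        "perfusion_medulla": {"stable": (80.0, 15.0), "progressor": (80.0, 15.0)},
    }


def _default_drift() -> dict[str, dict[str, float]]:
    """Fractional change per year per measure per group.

    Progressors lose kidney volume, ADC and cortical perfusion and gain
    cortical T1; the stable group shows only a mild TKV decline; T2* does
    not drift in either group.
    """
    drift = {m: {"stable": 0.0, "progressor": 0.0} for m in MEASURES}
    drift["tkv"] = {"stable": -0.02, "progressor": -0.05}
    drift["t1_cortex"]["progressor"] = 0.04
    drift["adc_cortex"]["progressor"] = -0.05
    drift["adc_medulla"]["progressor"] = -0.05
    drift["perfusion_cortex"]["progressor"] = -0.06
    return drift


def _default_session_cv() -> dict[str, float]:
    """Between-session measurement CV of the phantom acquisition chain."""
    return {
        "tkv": 0.015,
        "t1_cortex": 0.02, "t1_medulla": 0.02,
        "adc_cortex": 0.025, "adc_medulla": 0.025,
        "t2star_cortex": 0.03, "t2star_medulla": 0.03,
        "perfusion_cortex": 0.08, "perfusion_medulla": 0.08,
    }


@dataclass
class CohortSpec:
    """Specification of the synthetic two-group CKD cohort."""

    n_progressor: int = 9
    n_stable: int = 13
    egfr_intercept: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stable": (40.0, 10.0), "progressor": (40.0, 10.0)})
    egfr_slope: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stable": (-1.0, 1.0), "progressor": (-8.0, 1.0)})
    creatinine_cv: float = 0.05
    clinical_visit_days: tuple[int, ...] = tuple(range(0, 731, 91))
    mri_visit_years: tuple[float, ...] = (0.0, 1.0, 2.0)
    pcr_log10: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stable": (1.5, 0.45), "progressor": (2.1, 0.35)})
    pcr_visit_sd_log10: float = 0.1
    age_mean_sd: tuple[float, float] = (58.0, 15.0)
    male_fraction: float = 0.7
    black_fraction: float = 0.1
    tissue_baseline: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_tissue_baseline)
    drift_per_year: dict[str, dict[str, float]] = field(default_factory=_default_drift)
    session_cv: dict[str, float] = field(default_factory=_default_session_cv)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progressor < 2 or self.n_stable < 2:
            raise ValueError("need at least 2 subjects per group")
        if np.any(np.diff(self.clinical_visit_days) <= 0):
            raise ValueError("visit schedule must be strictly increasing")


@dataclass
class SyntheticSubject:
    subject_id: str
    group_intended: str
    group_realized: str
    sex: str
    ethnicity_black: bool
    age_baseline: float
    egfr_intercept: float
    egfr_slope_true: float
    egfr_slope_realized: float
    record: clinical.SubjectRecord
    tissue_base: dict[str, float]  # true baseline value per measure
    tissue_truth: pd.DataFrame  # per MRI visit: true (drifted) values
    tissue_measured: pd.DataFrame  # per MRI visit: with session noise


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SyntheticSubject]

    def clinical_table(self) -> pd.DataFrame:
        """Long clinical table (one row per subject × visit)."""
        rows = []
        for s in self.subjects:
            for _, v in s.record.visits.iterrows():
                rows.append({
                    "subject_id": s.subject_id,
                    "visit_date": v["visit_date"],
                    "age": v["age"],
                    "sex": s.sex,
                    "ethnicity_black": int(s.ethnicity_black),
                    "creatinine_umol_L": v["creatinine_umol_L"],
                    "pcr_mg_mmol": v["pcr_mg_mmol"],
                })
        return pd.DataFrame(rows)

    def summary_table(self, measured: bool = True) -> pd.DataFrame:
        """Tidy per-MRI-visit tissue summaries.

        Columns: subject, group (realized), group_intended, visit label,
        visit_year, measure, value.
        """
        frames = []
        for s in self.subjects:
            df = (s.tissue_measured if measured else s.tissue_truth).copy()
            df.insert(0, "subject", s.subject_id)
            df.insert(1, "group", s.group_realized)
            df.insert(2, "group_intended", s.group_intended)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def slopes(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": [s.subject_id for s in self.subjects],
            "group": [s.group_realized for s in self.subjects],
            "egfr_slope": [s.egfr_slope_realized for s in self.subjects],
        })


_VISIT_LABELS = {0.0: "baseline", 1.0: "year1", 2.0: "year2"}


def visit_label(year: float) -> str:
    return _VISIT_LABELS.get(float(year), f"year{year:g}")


def simulate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate the synthetic cohort (clinical series + tissue summaries)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    base_date = pd.Timestamp("2020-01-15")
    subjects: list[SyntheticSubject] = []
    groups = ["progressor"] * spec.n_progressor + ["stable"] * spec.n_stable
    for i, group in enumerate(groups):
        sid = f"SUBJ{i + 1:03d}"
        sex = "M" if rng.random() < spec.male_fraction else "F"
        black = bool(rng.random() < spec.black_fraction)
        age0 = float(np.clip(rng.normal(*spec.age_mean_sd), 20.0, 85.0))
        icpt = float(rng.normal(*spec.egfr_intercept[group]))
        icpt = max(icpt, 12.0)
        slope = float(rng.normal(*spec.egfr_slope[group]))

        t_yr = np.asarray(spec.clinical_visit_days, dtype=float) / 365.25
        egfr_true = np.maximum(icpt + slope * t_yr, 5.0)
        ages = age0 + t_yr
        scr_true = clinical.creatinine_for_egfr(
            egfr_true, ages, np.full(t_yr.size, sex),
            black=np.full(t_yr.size, black), unit="umol/L")
        scr_meas = scr_true * (1.0 + spec.creatinine_cv
                               * rng.standard_normal(t_yr.size))
        scr_meas = np.maximum(scr_meas, 10.0)

        pcr_mu, pcr_sd = spec.pcr_log10[group]
        pcr_base = rng.normal(pcr_mu, pcr_sd)
        pcr = 10.0 ** (pcr_base + spec.pcr_visit_sd_log10
                       * rng.standard_normal(t_yr.size))

        visits = pd.DataFrame({
            "visit_date": [base_date + pd.Timedelta(days=int(d))
                           for d in spec.clinical_visit_days],
            "age": ages,
            "creatinine_umol_L": scr_meas,
            "pcr_mg_mmol": pcr,
        })
        record = clinical.derive_subject(sid, sex, black, visits)

        base_vals = {}
        for m in MEASURES:
            mu, sd = spec.tissue_baseline[m][group]
            base_vals[m] = float(max(rng.normal(mu, sd), 0.05 * mu))
        truth_rows, meas_rows = [], []
        for yr in spec.mri_visit_years:
            for m in MEASURES:
                true_val = base_vals[m] * (1.0 + spec.drift_per_year[m][group] * yr)
                meas_val = true_val * (1.0 + spec.session_cv[m]
                                       * rng.standard_normal())
                row = {"visit": visit_label(yr), "visit_year": yr, "measure": m}
                truth_rows.append({**row, "value": true_val})
                meas_rows.append({**row, "value": meas_val})

        subjects.append(SyntheticSubject(
            subject_id=sid,
            group_intended=group,
            group_realized=record.label,
            sex=sex,
            ethnicity_black=black,
            age_baseline=age0,
            egfr_intercept=icpt,
            egfr_slope_true=slope,
            egfr_slope_realized=record.slope,
            record=record,
            tissue_base=base_vals,
            tissue_truth=pd.DataFrame(truth_rows),
            tissue_measured=pd.DataFrame(meas_rows),
        ))
    return Cohort(spec=spec, subjects=subjects)


def phantom_spec_for_subject(
    subject: SyntheticSubject,
    visit_year: float,
    base_spec: PhantomSpec | None = None,
    noise_sd_frac: float = 0.02,
    seed: int = 0,
) -> PhantomSpec:
    """Phantom spec realising one subject-visit's true tissue parameters.

    Kidney semi-axes are scaled so the analytic phantom TKV matches the
    subject's (drifted) TKV; tissue tables carry the subject's cortex and
    medulla values for that visit.
    """
    base = base_spec or PhantomSpec()
    truth = subject.tissue_truth
    vals = {row["measure"]: row["value"]
            for _, row in truth[truth["visit_year"] == visit_year].iterrows()}
    params = _default_tissue_params()
    for tissue in ("cortex", "medulla"):
        params[tissue]["t1"] = vals[f"t1_{tissue}"]
        params[tissue]["adc"] = vals[f"adc_{tissue}"]
        params[tissue]["t2star"] = vals[f"t2star_{tissue}"]
        params[tissue]["perfusion"] = vals[f"perfusion_{tissue}"]
    ref_tkv = base.analytic_kidney_volume_ml() / base.size_scale**3
    scale = (vals["tkv"] / ref_tkv) ** (1.0 / 3.0)
    return replace(base, tissue_params=params, size_scale=scale,
                   noise_sd_frac=noise_sd_frac, seed=seed)
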