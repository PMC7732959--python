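"""Synthetic dual-time-resolution DCE dataset and cohort generator.

Everything downstream of the scanner is testable against this module: it
produces a geometric digital phantom (fast bolus series + slow leakage
series, T1 map, tissue labels, ground-truth leakage maps) through the same
physical chain the analysis inverts — Patlak forward model, spoiled
gradient-echo signal equation, additive Gaussian noise — plus a synthetic
cohort table with a planted leakage–decline effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .concentration import ConcentrationCurve, VIFCalibration

__all__ = [
    "AcquisitionSchedule",
    "BolusParams",
    "SignalParams",
    "PhantomSpec",
    "PhantomDataset",
    "CohortSpec",
    "make_time_axis",
    "plasma_concentration",
    "simulate_vif",
    "patlak_forward",
    "spgr_signal",
    "concentration_to_signal",
    "synthetic_calibration",
    "default_phantom_spec",
    "generate_phantom_dataset",
    "generate_cohort",
    "BACKGROUND",
    "WHITE_MATTER",
    "GREY_MATTER",
    "HIPPOCAMPUS",
    "SINUS",
    "LABEL_NAMES",
]

# tissue label codes shared across the pipeline
BACKGROUND = 0
WHITE_MATTER = 1
GREY_MATTER = 2
HIPPOCAMPUS = 3
SINUS = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    WHITE_MATTER: "white_matter",
    GREY_MATTER: "grey_matter",
    HIPPOCAMPUS: "hippocampus",
    SINUS: "sinus",
}

#: Cognitive domains carried by the cohort table; Stroop interference is a
#: completion time, so its difference score is sign-reversed downstream.
COGNITIVE_DOMAINS = (
    "immediate_recall",
    "delayed_recall",
    "processing_speed",
    "stroop_interference",
)

# decline-score distribution (mean, sd) and plausible current-score
# distribution (mean, sd) per domain, in native test units
_DOMAIN_DECLINE = {
    "immediate_recall": (2.4, 6.6),
    "delayed_recall": (0.3, 2.9),
    "processing_speed": (5.1, 4.4),
    "stroop_interference": (13.5, 11.0),
}
_DOMAIN_CURRENT = {
    "immediate_recall": (40.0, 8.0),
    "delayed_recall": (10.0, 3.0),
    "processing_speed": (45.0, 9.0),
    "stroop_interference": (50.0, 14.0),
}


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing of a dual-time-resolution dynamic acquisition.

    A fast series (short interval, captures the bolus) is followed, after an
    optional gap, by a slow series (long interval, captures tissue leakage).
    All fields are in seconds; derived time axes are in minutes.
    """

    fast_interval_s: float = 3.2
    fast_n: int = 29
    slow_interval_s: float = 30.5
    slow_n: int = 30
    gap_s: float = 0.0
    bolus_arrival_s: float = 25.6

    def __post_init__(self) -> None:
        if self.fast_interval_s <= 0 or self.slow_interval_s <= 0:
            raise ValueError("scan intervals must be positive")
        if self.fast_n < 2 or self.slow_n < 2:
            raise ValueError("each series needs at least 2 volumes")
        if self.gap_s < 0:
            raise ValueError("inter-sequence gap cannot be negative")
        if self.bolus_arrival_s < 0:
            raise ValueError("bolus arrival cannot be negative")

    @property
    def fast_times_min(self) -> np.ndarray:
        return np.arange(self.fast_n) * self.fast_interval_s / 60.0

    @property
    def slow_times_min(self) -> np.ndarray:
        start = (
            (self.fast_n - 1) * self.fast_interval_s
            + self.gap_s
            + self.slow_interval_s
        )
        return (start + np.arange(self.slow_n) * self.slow_interval_s) / 60.0

    @property
    def bolus_arrival_min(self) -> float:
        return self.bolus_arrival_s / 60.0

    @property
    def n_frames(self) -> int:
        return self.fast_n + self.slow_n


def make_time_axis(schedule: AcquisitionSchedule) -> np.ndarray:
    """Full acquisition time axis in minutes (fast frames then slow frames).

    The first fast frame is at t = 0; the first slow frame follows the last
    fast frame by ``gap_s + slow_interval_s``.
    """
    times = np.concatenate([schedule.fast_times_min, schedule.slow_times_min])
    if not np.all(np.diff(times) > 0):
        raise ValueError("derived time axis is not strictly increasing")
    return times


@dataclass(frozen=True)
class BolusParams:
    """Parametric plasma input: gamma-variate bolus + recirculation tail."""

    amplitude_mM: float = 6.0
    time_to_peak_s: float = 10.0
    shape: float = 3.0
    tail_amplitude_mM: float = 1.0
    tail_rise_s: float = 30.0
    tail_decay_s: float = 360.0

    def __post_init__(self) -> None:
        if self.amplitude_mM < 0:
            raise ValueError("bolus amplitude cannot be negative")
        if self.time_to_peak_s <= 0 or self.shape <= 0:
            raise ValueError("bolus shape parameters must be positive")
        if min(self.tail_rise_s, self.tail_decay_s) <= 0:
            raise ValueError("tail time constants must be positive")
        if self.tail_amplitude_mM < 0:
            raise ValueError("tail amplitude cannot be negative")


def plasma_concentration(
    times_min: np.ndarray, bolus_arrival_min: float, params: BolusParams
) -> np.ndarray:
    """Closed-form plasma concentration (mM) at arbitrary times (minutes).

    Zero before bolus arrival; a gamma-variate peak of height
    ``amplitude_mM`` at ``time_to_peak_s`` after arrival, plus a slow
    washout tail.
    """
    t = np.asarray(times_min, dtype=float) * 60.0 - bolus_arrival_min * 60.0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    u = tp / params.time_to_peak_s
    bolus = params.amplitude_mM * u**params.shape * np.exp(params.shape * (1.0 - u))
    tail = (
        params.tail_amplitude_mM
        * (1.0 - np.exp(-tp / params.tail_rise_s))
        * np.exp(-tp / params.tail_decay_s)
    )
    out[pos] = bolus + tail
    return out


def simulate_vif(
    schedule: AcquisitionSchedule, params: BolusParams = BolusParams()
) -> ConcentrationCurve:
    """Sample the parametric plasma input on the acquisition time axis."""
    times = make_time_axis(schedule)
    if schedule.bolus_arrival_min >= times[-1]:
        raise ValueError("bolus arrives after the end of the acquisition")
    if schedule.bolus_arrival_min >= schedule.fast_times_min[-1]:
        raise ValueError("bolus arrival must fall within the fast series")
    values = plasma_concentration(times, schedule.bolus_arrival_min, params)
    return ConcentrationCurve(times=times, values=values, compartment="plasma")


def patlak_forward(
    vif: ConcentrationCurve, ki_per_min: float, vp: float
) -> ConcentrationCurve:
    """Tissue concentration under the no-reflux (Patlak) model.

    ``C_t(t) = Ki * integral_0^t C_p dtau + vp * C_p(t)`` with the integral
    taken by cumulative trapezoid on the curve's own time axis, matching the
    quadrature used by the fitting stage.
    """
    if ki_per_min < 0:
        raise ValueError("Ki cannot be negative")
    if not 0 <= vp < 1:
        raise ValueError("vp must be in [0, 1)")
    integral = cumulative_trapezoid(vif.values, vif.times, initial=0.0)
    ct = ki_per_min * integral + vp * vif.values
    return ConcentrationCurve(times=vif.times, values=ct, compartment="tissue")


@dataclass(frozen=True)
class SignalParams:
    """Spoiled gradient-echo steady-state signal parameters.

    Defaults use a short TR and near-90-degree flip so the signal is close to
    proportional to R1 over the tissue concentration range, keeping the
    linearised conversion bias well below the noiseless-recovery tolerance.
    """

    relaxivity: float = 5.0
    tr_s: float = 0.0005
    flip_deg: float = 90.0
    m0: float = 1000.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if not 0 < self.flip_deg <= 90:
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.relaxivity <= 0 or self.m0 <= 0:
            raise ValueError("relaxivity and M0 must be positive")


def spgr_signal(r1: np.ndarray, params: SignalParams) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal for relaxation rate ``r1``."""
    e1 = np.exp(-params.tr_s * np.asarray(r1, dtype=float))
    alpha = np.radians(params.flip_deg)
    return params.m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def concentration_to_signal(
    conc_mM: np.ndarray, t10_s: float, params: SignalParams = SignalParams()
) -> np.ndarray:
    """Forward signal model: ``R1(t) = 1/T10 + r1 * C(t)`` through SPGR.

    ``C = 0`` reproduces the pre-contrast signal exactly, and the signal is
    strictly increasing in concentration.
    """
    if t10_s <= 0:
        raise ValueError("T10 must be positive")
    r1 = 1.0 / t10_s + params.relaxivity * np.asarray(conc_mM, dtype=float)
    return spgr_signal(r1, params)


def synthetic_calibration(
    signal_params: SignalParams = SignalParams(),
    t10_blood_s: float = 1.6,
    c_max_mM: float = 40.0,
    fine_step_mM: float = 0.05,
    coarse_step_mM: float = 0.5,
    fine_max_mM: float = 10.0,
) -> VIFCalibration:
    """In-vitro style calibration table generated from the signal model.

    Concentrations run from 0 to ``c_max_mM`` (the dilution series covers
    1–40 mM; a 0 mM anchor is added for baseline normalisation), densely at
    low concentration where the in-vivo blood curve lives.
    """
    conc = np.concatenate(
        [
            np.arange(0.0, fine_max_mM, fine_step_mM),
            np.arange(fine_max_mM, c_max_mM + coarse_step_mM / 2, coarse_step_mM),
        ]
    )
    sig = concentration_to_signal(conc, t10_blood_s, signal_params)
    return VIFCalibration(concentrations=conc, signals=sig)


@dataclass(frozen=True)
class PhantomSpec:
    """Voxel-level description of the digital phantom.

    ``label_map`` assigns each voxel to background / white matter / grey
    matter / hippocampus / sinus; ``true_ki`` (min^-1), ``true_vp``
    (fraction) and ``t10_map`` (seconds) give the ground truth per voxel.
    """

    label_map: np.ndarray
    true_ki: np.ndarray
    true_vp: np.ndarray
    t10_map: np.ndarray
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    noise_sd: float = 0.0
    hematocrit: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_map)
        for name in ("true_ki", "true_vp", "t10_map"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != labels.shape:
                raise ValueError(f"{name} shape does not match label_map")
        object.__setattr__(self, "label_map", labels.astype(np.int16))
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")
        if np.any(self.true_ki < 0):
            raise ValueError("true Ki must be nonnegative")
        if np.any((self.true_vp < 0) | (self.true_vp >= 1)):
            raise ValueError("true vp must be in [0, 1)")
        nonbg = self.label_map != BACKGROUND
        if np.any(self.t10_map[nonbg] <= 0):
            raise ValueError("T10 must be positive in non-background voxels")
        n_sinus = int(np.count_nonzero(self.label_map == SINUS))
        if n_sinus < 20:
            raise ValueError(
                f"sinus label must mark at least 20 voxels, got {n_sinus}"
            )

    @property
    def grid_shape(self) -> tuple:
        return tuple(self.label_map.shape)

    def sinus_voxels(self) -> np.ndarray:
        return np.argwhere(self.label_map == SINUS)


# per-preset ground-truth (Ki min^-1, vp, T10 s) by tissue
_TISSUE_TRUTH = {
    # desk scale: recoverable at modest noise in seconds of CPU
    "desk": {
        WHITE_MATTER: (3.0e-3, 0.010, 0.9),
        GREY_MATTER: (2.0e-3, 0.020, 1.4),
        HIPPOCAMPUS: (4.0e-3, 0.015, 1.4),
    },
    # in-vivo scale: median leakage rates around 1e-6 min^-1
    "invivo": {
        WHITE_MATTER: (1.1e-6, 0.010, 0.9),
        GREY_MATTER: (0.9e-6, 0.020, 1.4),
        HIPPOCAMPUS: (1.7e-6, 0.015, 1.4),
    },
}
_T10_BLOOD_S = 1.6


def default_phantom_spec(
    grid_shape: tuple = (16, 16, 8),
    noise_sd: float = 0.0,
    seed: int = 0,
    preset: str = "desk",
    hematocrit: float = 0.45,
) -> PhantomSpec:
    """Geometric phantom: WM and GM slabs, a hippocampal block, and a sinus
    rod of >= 20 voxels, inside a one-voxel background shell."""
    if preset not in _TISSUE_TRUTH:
        raise ValueError(f"unknown preset {preset!r}")
    nx, ny, nz = grid_shape
    if min(nx, ny, nz) < 6 or nx < 10:
        raise ValueError("grid too small for the default geometry (min 10x6x6)")
    labels = np.zeros(grid_shape, dtype=np.int16)
    interior = (slice(1, nx - 1), slice(1, ny - 1), slice(1, nz - 1))
    labels[interior] = WHITE_MATTER
    labels[nx // 2 : nx - 1, 1 : ny - 1, 1 : nz - 1] = GREY_MATTER
    # hippocampal block inside the grey-matter half
    hx = slice(nx // 2 + 1, min(nx // 2 + 3, nx - 1))
    hy = slice(ny // 2 - 1, min(ny // 2 + 1, ny - 1))
    hz = slice(1, min(3, nz - 1))
    labels[hx, hy, hz] = HIPPOCAMPUS
    # sinus rod along y at the first interior x-plane, >= 20 voxels
    rod = np.zeros(grid_shape, dtype=bool)
    rod[1, 1 : ny - 1, 1 : min(1 + max(2, int(np.ceil(22 / max(ny - 2, 1)))), nz - 1)] = True
    labels[rod] = SINUS
    if np.count_nonzero(labels == SINUS) < 20:
        raise ValueError("grid too small to hold a 20-voxel sinus rod")

    truth = _TISSUE_TRUTH[preset]
    true_ki = np.zeros(grid_shape)
    true_vp = np.zeros(grid_shape)
    t10 = np.zeros(grid_shape)
    for lab, (ki, vp, t10_s) in truth.items():
        m = labels == lab
        true_ki[m] = ki
        true_vp[m] = vp
        t10[m] = t10_s
    t10[labels == SINUS] = _T10_BLOOD_S
    return PhantomSpec(
        label_map=labels,
        true_ki=true_ki,
        true_vp=true_vp,
        t10_map=t10,
        noise_sd=noise_sd,
        hematocrit=hematocrit,
        seed=seed,
    )


@dataclass(frozen=True)
class PhantomDataset:
    """In-memory simulated acquisition plus its ground truth."""

    fast_signal: np.ndarray  # (x, y, z, fast_n)
    slow_signal: np.ndarray  # (x, y, z, slow_n)
    t10_map: np.ndarray
    label_map: np.ndarray
    true_ki: np.ndarray
    true_vp: np.ndarray
    vif_true: ConcentrationCurve
    schedule: AcquisitionSchedule
    spec: PhantomSpec
    signal_params: SignalParams
    bolus_params: BolusParams


def generate_phantom_dataset(
    spec: PhantomSpec,
    schedule: AcquisitionSchedule = AcquisitionSchedule(),
    signal_params: SignalParams = SignalParams(),
    bolus_params: BolusParams = BolusParams(),
) -> PhantomDataset:
    """Simulate the dual-time-resolution acquisition for a phantom.

    Tissue voxels follow ``patlak_forward`` of the true plasma curve through
    the signal equation with the voxel's T10; sinus voxels carry the
    whole-blood signal ``(1 - hematocrit) * C_p``; background is zero signal.
    iid Gaussian noise of sd ``spec.noise_sd`` is added per voxel-frame,
    deterministically from ``spec.seed``.
    """
    vif = simulate_vif(schedule, bolus_params)
    times = vif.times
    cum_cp = cumulative_trapezoid(vif.values, times, initial=0.0)

    labels = spec.label_map
    shape = spec.grid_shape
    n_frames = schedule.n_frames
    signal = np.zeros(shape + (n_frames,), dtype=float)

    tissue = np.isin(labels, (WHITE_MATTER, GREY_MATTER, HIPPOCAMPUS))
    if np.any(tissue):
        ki = spec.true_ki[tissue][:, None]
        vp = spec.true_vp[tissue][:, None]
        ct = ki * cum_cp[None, :] + vp * vif.values[None, :]
        r1 = 1.0 / spec.t10_map[tissue][:, None] + signal_params.relaxivity * ct
        signal[tissue] = spgr_signal(r1, signal_params)

    sinus = labels == SINUS
    if np.any(sinus):
        blood = (1.0 - spec.hematocrit) * vif.values
        r1b = 1.0 / spec.t10_map[sinus][:, None] + signal_params.relaxivity * blood[None, :]
        signal[sinus] = spgr_signal(r1b, signal_params)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    return PhantomDataset(
        fast_signal=signal[..., : schedule.fast_n],
        slow_signal=signal[..., schedule.fast_n :],
        t10_map=spec.t10_map.copy(),
        label_map=labels.copy(),
        true_ki=spec.true_ki.copy(),
        true_vp=spec.true_vp.copy(),
        vif_true=vif,
        schedule=schedule,
        spec=spec,
        signal_params=signal_params,
        bolus_params=bolus_params,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort with a planted standardized leakage–decline effect.

    The delayed-recall decline is generated, on the z-scale, as
    ``sum(covariate betas * z(covariate)) + planted_std_beta *
    z(cbrt(WM Ki)) + residual``; the other three domains get the same
    covariate structure with no leakage effect.  When ``residual_sd`` is
    omitted it is chosen so the z-scale outcome has unit variance, making
    ``planted_std_beta`` the population standardized coefficient.
    """

    n_subjects: int = 57
    age_mean: float = 65.8
    age_sd: float = 10.2
    fraction_male: float = 0.526
    education_probs: tuple = (0.158, 0.544, 0.298)
    planted_std_beta: float = 0.389
    residual_sd: float | None = None
    covariate_std_betas: tuple = (0.20, -0.10, 0.10)  # age, sex, education
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("cohort needs at least 10 subjects")
        if abs(self.planted_std_beta) > 1:
            raise ValueError("|planted_std_beta| must be <= 1")
        probs = np.asarray(self.education_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("education_probs must be 3 nonnegative values summing to 1")
        if not 0 <= self.fraction_male <= 1:
            raise ValueError("fraction_male must be a proportion")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive when given")

    def resolved_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return float(self.residual_sd)
        explained = self.planted_std_beta**2 + float(
            np.sum(np.square(self.covariate_std_betas))
        )
        return float(np.sqrt(max(1.0 - explained, 0.05)))


# lognormal leakage parameters per region: (median Ki, sigma_log),
# matching median/IQR on the 1e-6 min^-1 scale
_COHORT_KI = {
    "wm": (1.1e-6, 0.886),
    "gm": (0.9e-6, 0.853),
    "hippocampus": (1.7e-6, 1.341),
}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(spec: CohortSpec) -> "pandas.DataFrame":
    """Simulate the cohort table consumed by the statistics stage.

    Returns one row per subject with demographics, intracranial volume,
    structural measures, per-region mean leakage parameters and previous /
    current cognitive scores in four domains.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = (rng.random(n) < spec.fraction_male).astype(int)  # 1 = male
    education = rng.choice([1, 2, 3], size=n, p=spec.education_probs)
    icv = rng.normal(1450.0, 120.0, n).clip(min=900.0)

    data = {
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "education": education,
        "icv_cm3": icv,
        "wmh_cm3": np.exp(rng.normal(np.log(2.0), 0.8, n)),
        "hippocampus_cm3": rng.normal(6.5, 0.7, n).clip(min=3.0),
        "cortical_thickness_mm": rng.normal(2.4, 0.15, n),
    }
    for region, (median, sigma) in _COHORT_KI.items():
        data[f"{region}_ki"] = np.exp(rng.normal(np.log(median), sigma, n))
        data[f"{region}_vp"] = np.exp(rng.normal(np.log(0.01), 0.3, n))

    z_age = _zscore(age)
    z_sex = _zscore(sex.astype(float))
    z_edu = _zscore(education.astype(float))
    z_leak = _zscore(np.cbrt(data["wm_ki"]))
    b_age, b_sex, b_edu = spec.covariate_std_betas
    resid_sd = spec.resolved_residual_sd()

    for domain in COGNITIVE_DOMAINS:
        planted = spec.planted_std_beta if domain == "delayed_recall" else 0.0
        z_decline = (
            b_age * z_age
            + b_sex * z_sex
            + b_edu * z_edu
            + planted * z_leak
            + rng.normal(0.0, resid_sd, n)
        )
        mean_d, sd_d = _DOMAIN_DECLINE[domain]
        decline = mean_d + sd_d * z_decline
        mean_c, sd_c = _DOMAIN_CURRENT[domain]
        current = rng.normal(mean_c, sd_c, n)
        if domain == "stroop_interference":
            # time score: larger raw difference = less decline, so the
            # planted decline enters with the reversal already applied
            previous = current - decline
        else:
            previous = current + decline
        data[f"{domain}_previous"] = previous
        data[f"{domain}_current"] = current

    return pd.DataFrame(data)
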