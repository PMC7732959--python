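"""Signal-to-concentration conversion and vascular input function extraction.

Two conversion routes are provided, mirroring how dynamic contrast-enhanced
(DCE) data are handled in practice:

* tissue voxels use a linearised T1 relation driven by the pre-contrast
  relaxation time (the ``T10`` map), and
* the vascular input function (VIF), sampled in a venous sinus, is converted
  through an in-vitro style calibration table that maps scanner signal to
  gadolinium concentration, followed by a hematocrit correction from whole
  blood to plasma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConcentrationCurve",
    "VIFCalibration",
    "ConversionParams",
    "extract_vif",
    "vif_signal_to_concentration",
    "tissue_signal_to_concentration",
]

#: Minimum number of sinus voxels accepted for VIF extraction.
MIN_SINUS_VOXELS = 20


@dataclass(frozen=True)
class ConcentrationCurve:
    """A time-resolved contrast-agent concentration curve.

    Parameters
    ----------
    times : ndarray
        Acquisition times in **minutes**, strictly increasing.
    values : ndarray
        Concentration in mM, one value per time point.
    compartment : {"plasma", "tissue"}
        Which compartment the curve describes.
    """

    times: np.ndarray
    values: np.ndarray
    compartment: str = "tissue"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.size != values.size:
            raise ValueError(
                f"times ({times.size}) and values ({values.size}) differ in length"
            )
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.compartment not in ("plasma", "tissue"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray) -> "ConcentrationCurve":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class VIFCalibration:
    """Signal-vs-concentration calibration table for the blood signal.

    The table plays the role of an in-vitro dilution series: known gadolinium
    concentrations (mM) against the measured signal, acquired with a baseline
    relaxation time comparable to blood.  ``signals`` must be strictly
    monotone over the table so the map is invertible.
    """

    concentrations: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "signals", sig)
        if conc.ndim != 1 or conc.size != sig.size or conc.size < 2:
            raise ValueError("calibration needs matching 1-D arrays of length >= 2")
        if not np.all(np.diff(conc) > 0):
            raise ValueError("calibration concentrations must be strictly increasing")
        d = np.diff(sig)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibration signals must be strictly monotone")

    @property
    def increasing(self) -> bool:
        return bool(self.signals[-1] > self.signals[0])

    def invert(self, signal: np.ndarray) -> np.ndarray:
        """Map signal values to concentration by monotone piecewise-linear
        interpolation, clipping to the calibrated range."""
        sig = self.signals if self.increasing else self.signals[::-1]
        conc = self.concentrations if self.increasing else self.concentrations[::-1]
        signal = np.asarray(signal, dtype=float)
        lo, hi = sig[0], sig[-1]
        if np.any(signal < lo) or np.any(signal > hi):
            warnings.warn(
                "signal outside calibrated range; clipping to table ends",
                stacklevel=2,
            )
            signal = np.clip(signal, lo, hi)
        return np.interp(signal, sig, conc)


@dataclass(frozen=True)
class ConversionParams:
    """Parameters shared by both conversion routes.

    relaxivity
        Contrast-agent longitudinal relaxivity r1 in L mmol^-1 s^-1.
    hematocrit
        Volume fraction of red cells; whole-blood concentration is divided by
        ``1 - hematocrit`` to express it as a plasma concentration.
    pre_contrast_frames
        Number of leading frames averaged for the pre-contrast baseline.
    signal_normalization
        ``"baseline"`` rescales the in-vivo signal so its pre-contrast
        baseline matches the calibration's zero-concentration signal (the
        calibration must then include a 0 mM entry) and subtracts the
        converted baseline; ``"none"`` applies the table as-is.
    """

    relaxivity: float = 5.0
    hematocrit: float = 0.45
    pre_contrast_frames: int = 8
    signal_normalization: str = "baseline"

    def __post_init__(self) -> None:
        if self.relaxivity <= 0:
            raise ValueError("relaxivity must be positive")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must be in [0, 1)")
        if self.pre_contrast_frames < 1:
            raise ValueError("pre_contrast_frames must be >= 1")
        if self.signal_normalization not in ("baseline", "none"):
            raise ValueError("signal_normalization must be 'baseline' or 'none'")


def extract_vif(series: np.ndarray, sinus_voxels) -> np.ndarray:
    """Average the signal time courses of manually selected sinus voxels.

    Parameters
    ----------
    series : ndarray, shape (x, y, z, t)
        4-D signal series.
    sinus_voxels : sequence of (i, j, k)
        Voxel indices inside the venous sinus; at least 20 are required.

    Returns
    -------
    ndarray, shape (t,)
        Frame-wise mean signal over the selected voxels.
    """
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError("series must be a 4-D (x, y, z, t) array")
    idx = np.atleast_2d(np.asarray(sinus_voxels, dtype=int))
    if idx.shape[0] < MIN_SINUS_VOXELS:
        raise ValueError(
            f"VIF extraction requires at least {MIN_SINUS_VOXELS} sinus voxels, "
            f"got {idx.shape[0]}"
        )
    if idx.shape[1] != 3:
        raise ValueError("sinus_voxels must be (n, 3) voxel indices")
    shape = np.asarray(series.shape[:3])
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError("sinus voxel index out of image bounds")
    return series[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)


def vif_signal_to_concentration(
    signal: np.ndarray,
    times_min: np.ndarray,
    calibration: VIFCalibration,
    params: ConversionParams = ConversionParams(),
) -> ConcentrationCurve:
    """Convert the blood-pool signal to a plasma concentration curve.

    The calibration table is inverted by monotone piecewise-linear
    interpolation; the whole-blood concentration is divided by
    ``1 - hematocrit`` to yield the plasma concentration.
    """
    signal = np.asarray(signal, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if signal.shape != times_min.shape:
        raise ValueError("signal and times must have the same length")

    if params.signal_normalization == "baseline":
        if calibration.concentrations[0] > 0:
            raise ValueError(
                "baseline normalization requires a 0 mM calibration entry"
            )
        baseline = signal[: params.pre_contrast_frames].mean()
        if baseline <= 0:
            raise ValueError("non-positive pre-contrast baseline signal")
        cal_zero = calibration.signals[0]  # signal at the 0 mM entry
        scale = cal_zero / baseline
        blood = calibration.invert(signal * scale)
        blood = blood - blood[: params.pre_contrast_frames].mean()
    else:
        blood = calibration.invert(signal)

    plasma = blood / (1.0 - params.hematocrit)
    return ConcentrationCurve(times=times_min, values=plasma, compartment="plasma")


def tissue_signal_to_concentration(
    signal: np.ndarray,
    times_min: np.ndarray,
    t10_s: float,
    params: ConversionParams = ConversionParams(),
    baseline: float | None = None,
) -> ConcentrationCurve:
    """Convert a tissue signal time course to concentration.

    Uses the linearised relation ``dR1(t) = (S(t)/S0 - 1) / T10`` with
    ``C(t) = dR1(t) / r1``, where ``S0`` is the pre-contrast baseline.

    Parameters
    ----------
    baseline
        Pre-contrast signal ``S0``.  When omitted it is estimated as the mean
        of the first ``params.pre_contrast_frames`` frames; pass it explicitly
        for series that contain no pre-contrast frames (e.g. the slow series
        of a dual-time-resolution acquisition).
    """
    signal = np.asarray(signal, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if t10_s <= 0:
        raise ValueError("T10 must be positive")
    s0 = float(baseline) if baseline is not None else float(
        signal[: params.pre_contrast_frames].mean()
    )
    if s0 <= 0:
        raise ValueError("non-positive baseline signal")
    delta_r1 = (signal / s0 - 1.0) / t10_s
    conc = delta_r1 / params.relaxivity
    return ConcentrationCurve(times=times_min, values=conc, compartment="tissue")
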