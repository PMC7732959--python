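"""Patlak-model estimation of leakage rate (Ki) and plasma volume (vp).

The tissue concentration under the no-reflux assumption is a linear
combination of the plasma curve and its running integral,

    C_t(t) = Ki * int_0^t C_p(tau) dtau + vp * C_p(t),

so voxel-wise estimation is ordinary least squares on a two-column design.
Negative estimates are deliberately allowed: the downstream histogram noise
correction relies on the noise distribution extending below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .concentration import ConcentrationCurve
from .phantom import (
    AcquisitionSchedule,
    GREY_MATTER,
    HIPPOCAMPUS,
    WHITE_MATTER,
)

__all__ = [
    "PatlakResult",
    "merge_dual_resolution",
    "integrate_vif",
    "fit_patlak_voxel",
    "fit_patlak_volume",
    "default_onset_min",
    "TISSUE_LABELS",
]

TISSUE_LABELS = (WHITE_MATTER, GREY_MATTER, HIPPOCAMPUS)

_RCOND = 1e-12


@dataclass(frozen=True)
class PatlakResult:
    """Voxel maps from a volume fit; unfitted voxels are NaN."""

    ki_map: np.ndarray  # min^-1
    vp_map: np.ndarray  # fraction
    residual_map: np.ndarray  # rms residual, mM
    n_timepoints_used: int

    def __post_init__(self) -> None:
        if not (self.ki_map.shape == self.vp_map.shape == self.residual_map.shape):
            raise ValueError("result maps must share one grid shape")
        fitted = ~np.isnan(self.residual_map)
        if np.any(self.residual_map[fitted] < 0):
            raise ValueError("residuals must be nonnegative")


def merge_dual_resolution(
    fast: ConcentrationCurve,
    slow: ConcentrationCurve,
    schedule: AcquisitionSchedule | None = None,
    match_offset: bool = False,
) -> ConcentrationCurve:
    """Concatenate fast and slow curves onto one time axis (no resampling).

    With ``match_offset`` the slow curve is shifted so its first frame equals
    the last fast frame, removing any baseline step between the sequences.
    Off by default: with a shared signal chain there is no step to remove,
    and matching would absorb genuine enhancement between the sequences.
    """
    if fast.compartment != slow.compartment:
        raise ValueError("cannot merge curves from different compartments")
    if slow.times[0] <= fast.times[-1]:
        raise ValueError("fast and slow time ranges overlap")
    slow_values = slow.values
    if match_offset:
        slow_values = slow_values + (fast.values[-1] - slow_values[0])
    return ConcentrationCurve(
        times=np.concatenate([fast.times, slow.times]),
        values=np.concatenate([fast.values, slow_values]),
        compartment=fast.compartment,
    )


def integrate_vif(vif: ConcentrationCurve) -> ConcentrationCurve:
    """Cumulative trapezoidal integral of the plasma curve, in mM * min."""
    integral = cumulative_trapezoid(vif.values, vif.times, initial=0.0)
    return ConcentrationCurve(
        times=vif.times, values=integral, compartment=vif.compartment
    )


def default_onset_min(schedule: AcquisitionSchedule) -> float:
    """Default fit-window onset: one fast interval after bolus arrival."""
    return (schedule.bolus_arrival_s + schedule.fast_interval_s) / 60.0


def _design(vif: ConcentrationCurve, onset_min: float) -> tuple[np.ndarray, np.ndarray]:
    sel = vif.times >= onset_min
    if np.count_nonzero(sel) < 3:
        raise ValueError("need at least 3 time points after onset")
    cum = cumulative_trapezoid(vif.values, vif.times, initial=0.0)
    x = np.column_stack([cum[sel], vif.values[sel]])
    s = np.linalg.svd(x, compute_uv=False)
    if s[0] == 0 or s[-1] <= _RCOND * s[0]:
        raise np.linalg.LinAlgError("singular Patlak design (degenerate VIF)")
    return x, sel


def fit_patlak_voxel(
    ct: ConcentrationCurve,
    vif: ConcentrationCurve,
    onset_min: float = 0.0,
) -> tuple[float, float, float]:
    """OLS Patlak fit of one tissue curve; returns ``(ki, vp, rms_residual)``.

    Ki may come out negative in noise-only voxels; this is intentional.
    """
    if ct.times.shape != vif.times.shape or not np.allclose(ct.times, vif.times):
        raise ValueError("tissue curve and VIF must share one time axis")
    x, sel = _design(vif, onset_min)
    y = ct.values[sel]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rms = float(np.sqrt(np.mean(resid**2)))
    return float(beta[0]), float(beta[1]), rms


def fit_patlak_volume(
    conc_4d: np.ndarray,
    times_min: np.ndarray,
    vif: ConcentrationCurve,
    labels: np.ndarray,
    onset_min: float = 0.0,
    fit_labels=TISSUE_LABELS,
) -> PatlakResult:
    """Voxel-wise Patlak fit over a 4-D concentration volume.

    Voxels whose label is not in ``fit_labels`` are excluded and set to NaN
    in all output maps.  Per-voxel results are numerically identical to
    :func:`fit_patlak_voxel` (one shared least-squares solve).
    """
    conc_4d = np.asarray(conc_4d, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if conc_4d.ndim != 4:
        raise ValueError("conc_4d must be 4-D (x, y, z, t)")
    if conc_4d.shape[-1] != times_min.size or times_min.size != vif.times.size:
        raise ValueError("frame count does not match the time axis / VIF")
    if not np.allclose(times_min, vif.times):
        raise ValueError("volume time axis must match the VIF time axis")
    labels = np.asarray(labels)
    if labels.shape != conc_4d.shape[:3]:
        raise ValueError("label volume shape does not match image grid")
    mask = np.isin(labels, np.asarray(fit_labels))
    if not np.any(mask):
        raise ValueError("no voxels selected by the mask")

    x, sel = _design(vif, onset_min)
    y = conc_4d[mask][:, sel].T  # (t_used, n_vox)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rms = np.sqrt(np.mean(resid**2, axis=0))

    shape = labels.shape
    ki_map = np.full(shape, np.nan)
    vp_map = np.full(shape, np.nan)
    residual_map = np.full(shape, np.nan)
    ki_map[mask] = beta[0]
    vp_map[mask] = beta[1]
    residual_map[mask] = rms
    return PatlakResult(
        ki_map=ki_map,
        vp_map=vp_map,
        residual_map=residual_map,
        n_timepoints_used=int(np.count_nonzero(sel)),
    )
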