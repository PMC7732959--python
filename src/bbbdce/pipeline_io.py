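"""End-to-end orchestration: simulate -> convert -> fit -> summarize -> regress.

One :class:`RunConfig` fully determines a run; re-executing from the saved
config and seed reproduces every artifact byte for byte.  Images travel as
NIfTI, tables as CSV, and the run manifest (paths, checksums, summary
metrics) as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cogstats import (
    DOMAINS,
    benjamini_hochberg,
    cube_root,
    decline_score,
    fit_adjusted_regression,
)
from .concentration import (
    ConcentrationCurve,
    ConversionParams,
    VIFCalibration,
    extract_vif,
    vif_signal_to_concentration,
)
from .patlak import (
    PatlakResult,
    default_onset_min,
    fit_patlak_volume,
)
from .phantom import (
    AcquisitionSchedule,
    BolusParams,
    CohortSpec,
    PhantomDataset,
    SignalParams,
    SINUS,
    default_phantom_spec,
    generate_phantom_dataset,
    make_time_axis,
    synthetic_calibration,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "convert_dataset",
    "write_dataset",
    "save_map",
    "load_map",
    "write_curve_csv",
    "read_curve_csv",
    "read_cohort_csv",
    "validate_series",
    "COHORT_REQUIRED_COLUMNS",
]

logger = logging.getLogger("bbbdce")

#: Columns a cohort CSV must provide for the regression stage.
COHORT_REQUIRED_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "education",
    "icv_cm3",
    "wm_ki",
    "gm_ki",
    "hippocampus_ki",
    *(f"{d}_previous" for d in DOMAINS),
    *(f"{d}_current" for d in DOMAINS),
)

_REGIONS = ("wm", "gm", "hippocampus")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass(frozen=True)
class RunConfig:
    """Complete, serialisable description of one pipeline run.

    The global ``seed`` fans out to per-stage substreams (phantom noise,
    cohort) so each stage is individually reproducible.
    """

    seed: int = 0
    grid_shape: tuple = (16, 16, 8)
    noise_sd: float = 0.0
    preset: str = "desk"
    hematocrit: float = 0.45
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)
    bolus: BolusParams = field(default_factory=BolusParams)
    signal: SignalParams = field(default_factory=SignalParams)
    conversion: ConversionParams = field(default_factory=ConversionParams)
    onset_min: float | None = None  # None -> bolus arrival + one fast interval
    match_offset: bool = False
    bins: int | None = None
    n_subjects: int = 57
    planted_std_beta: float = 0.389
    fdr_q: float = 0.05

    def validate(self) -> None:
        """Build every derived spec so invalid settings fail before any
        stage runs."""
        self.phantom_spec()
        self.cohort_spec()
        make_time_axis(self.schedule)
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")

    def phantom_spec(self):
        seeds = np.random.SeedSequence(self.seed).spawn(2)
        return default_phantom_spec(
            grid_shape=tuple(self.grid_shape),
            noise_sd=self.noise_sd,
            seed=int(seeds[0].generate_state(1)[0]),
            preset=self.preset,
            hematocrit=self.hematocrit,
        )

    def cohort_spec(self) -> CohortSpec:
        seeds = np.random.SeedSequence(self.seed).spawn(2)
        return CohortSpec(
            n_subjects=self.n_subjects,
            planted_std_beta=self.planted_std_beta,
            seed=int(seeds[1].generate_state(1)[0]),
        )

    def resolved_onset_min(self) -> float:
        if self.onset_min is not None:
            return float(self.onset_min)
        return default_onset_min(self.schedule)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("schedule", AcquisitionSchedule),
            ("bolus", BolusParams),
            ("signal", SignalParams),
            ("conversion", ConversionParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# format handling


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    return aff


def save_map(path, data: np.ndarray, voxel_size_mm=(2.0, 2.0, 2.0)) -> Path:
    """Write a 3-D/4-D float volume as NIfTI with a diagonal affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_map(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc


def write_curve_csv(path, curve: ConcentrationCurve) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_min": curve.times, "concentration_mM": curve.values}
    ).to_csv(path, index=False)
    return path


def read_curve_csv(path, compartment: str = "plasma") -> ConcentrationCurve:
    df = pd.read_csv(path)
    for col in ("time_min", "concentration_mM"):
        if col not in df.columns:
            raise ValueError(f"curve CSV {path} is missing column {col!r}")
    return ConcentrationCurve(
        times=df["time_min"].to_numpy(),
        values=df["concentration_mM"].to_numpy(),
        compartment=compartment,
    )


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table and check the documented column schema."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing required columns: {missing}")
    return df


def validate_series(series: np.ndarray, schedule: AcquisitionSchedule, which: str) -> None:
    """Check a 4-D series has the frame count the schedule promises."""
    expected = schedule.fast_n if which == "fast" else schedule.slow_n
    series = np.asarray(series)
    if series.ndim != 4:
        raise ValueError(f"{which} series must be 4-D, got {series.ndim}-D")
    if series.shape[-1] != expected:
        raise ValueError(
            f"{which} series has {series.shape[-1]} frames; schedule expects {expected}"
        )


def write_dataset(dataset: PhantomDataset, outdir) -> dict:
    """Write a simulated dataset (images + sidecar) and return its paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = dataset.spec.voxel_size_mm
    paths = {
        "fast": save_map(outdir / "dce_fast.nii", dataset.fast_signal, vs),
        "slow": save_map(outdir / "dce_slow.nii", dataset.slow_signal, vs),
        "t10": save_map(outdir / "t10_map.nii", dataset.t10_map, vs),
        "labels": save_map(outdir / "labels.nii", dataset.label_map, vs),
        "true_ki": save_map(outdir / "true_ki.nii", dataset.true_ki, vs),
        "true_vp": save_map(outdir / "true_vp.nii", dataset.true_vp, vs),
        "vif_true": write_curve_csv(outdir / "vif_true.csv", dataset.vif_true),
    }
    sidecar = {
        "schedule": dataclasses.asdict(dataset.schedule),
        "seed": dataset.spec.seed,
        "noise_sd": dataset.spec.noise_sd,
        "hematocrit": dataset.spec.hematocrit,
        "signal_params": dataclasses.asdict(dataset.signal_params),
        "bolus_params": dataclasses.asdict(dataset.bolus_params),
    }
    p = outdir / "dataset.json"
    p.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = p
    return paths


# ---------------------------------------------------------------------------
# conversion of a simulated dataset


def convert_dataset(
    dataset: PhantomDataset,
    params: ConversionParams | None = None,
    calibration: VIFCalibration | None = None,
    match_offset: bool = False,
):
    """Convert a simulated acquisition to concentration space.

    Returns ``(times_min, conc_4d, vif_curve)`` on the merged dual-resolution
    time axis.  Tissue voxels use the linearised T10 relation with the
    pre-contrast baseline taken from the fast series (the slow series has no
    pre-contrast frames); the VIF is the mean sinus signal converted through
    the calibration table and hematocrit correction.
    """
    if params is None:
        params = ConversionParams(hematocrit=dataset.spec.hematocrit)
    validate_series(dataset.fast_signal, dataset.schedule, "fast")
    validate_series(dataset.slow_signal, dataset.schedule, "slow")
    times = make_time_axis(dataset.schedule)
    signal = np.concatenate([dataset.fast_signal, dataset.slow_signal], axis=-1)

    # VIF: mean sinus signal -> calibration inversion -> plasma curve
    sinus_voxels = np.argwhere(dataset.label_map == SINUS)
    vif_signal = extract_vif(signal, sinus_voxels)
    if calibration is None:
        t10_blood = float(np.median(dataset.t10_map[dataset.label_map == SINUS]))
        calibration = synthetic_calibration(dataset.signal_params, t10_blood)
    vif = vif_signal_to_concentration(vif_signal, times, calibration, params)

    # tissue: per-voxel linearised conversion, baseline from fast pre-bolus
    n_base = params.pre_contrast_frames
    s0 = dataset.fast_signal[..., :n_base].mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t10 = dataset.t10_map
        conc = (signal / s0[..., None] - 1.0) / (
            t10[..., None] * params.relaxivity
        )
    conc[~np.isfinite(conc)] = np.nan

    if match_offset:
        nf = dataset.schedule.fast_n
        offset = conc[..., nf - 1] - conc[..., nf]
        conc[..., nf:] = conc[..., nf:] + offset[..., None]
    return times, conc, vif


# ---------------------------------------------------------------------------
# full run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: simulate, convert, fit, summarize, regress.  Any stage failure
    aborts the run with a :class:`PipelineError` naming the stage.  The
    manifest lists every artifact with a SHA-256 checksum.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    metrics: dict[str, object] = {}
    try:
        config.save(outdir / "config.yaml")
        paths["config"] = outdir / "config.yaml"
        logger.info("resolved configuration: %s", json.dumps(config.to_dict(), sort_keys=True))
        logger.info("fit onset (min): %s", config.resolved_onset_min())

        dataset = _stage("simulate")(_simulate)(config, outdir, paths)
        times, conc, vif = _stage("convert")(_convert)(config, dataset, outdir, paths)
        result = _stage("fit")(_fit)(config, dataset, times, conc, vif, outdir, paths)
        summaries = _stage("summarize")(_summarize)(
            config, dataset, result, outdir, paths, metrics
        )
        _stage("regress")(_regress)(config, outdir, paths, metrics)

        manifest = {
            "bbbdce_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "metrics": metrics,
            "files": {
                key: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                for key, p in sorted(paths.items())
            },
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _simulate(config: RunConfig, outdir: Path, paths: dict) -> PhantomDataset:
    dataset = generate_phantom_dataset(
        config.phantom_spec(), config.schedule, config.signal, config.bolus
    )
    paths.update(write_dataset(dataset, outdir))
    return dataset


def _convert(config: RunConfig, dataset: PhantomDataset, outdir: Path, paths: dict):
    times, conc, vif = convert_dataset(
        dataset, config.conversion, match_offset=config.match_offset
    )
    paths["vif_measured"] = write_curve_csv(outdir / "vif_measured.csv", vif)
    return times, conc, vif


def _fit(config, dataset, times, conc, vif, outdir: Path, paths: dict) -> PatlakResult:
    result = fit_patlak_volume(
        np.nan_to_num(conc, nan=0.0),
        times,
        vif,
        dataset.label_map,
        onset_min=config.resolved_onset_min(),
    )
    vs = dataset.spec.voxel_size_mm
    paths["ki_map"] = save_map(outdir / "ki_map.nii", result.ki_map, vs)
    paths["vp_map"] = save_map(outdir / "vp_map.nii", result.vp_map, vs)
    paths["residual_map"] = save_map(outdir / "residual_map.nii", result.residual_map, vs)
    return result


def _summarize(config, dataset, result: PatlakResult, outdir: Path, paths, metrics):
    summaries = summarize_roi_with_bins(result, dataset.label_map, config.bins)
    rows = [dataclasses.asdict(s) for s in summaries]
    df = pd.DataFrame(rows)
    paths["roi_summary"] = outdir / "roi_summary.csv"
    df.to_csv(paths["roi_summary"], index=False)
    metrics["roi_summary"] = {r["region"]: r["mean_ki_corrected"] for r in rows}
    return summaries


def summarize_roi_with_bins(result: PatlakResult, labels, bins):
    from .roi_leakage import summarize_roi

    return summarize_roi(result, labels, bins=bins)


def _regress(config: RunConfig, outdir: Path, paths: dict, metrics: dict):
    from .phantom import generate_cohort

    cohort = generate_cohort(config.cohort_spec())
    paths["cohort"] = outdir / "cohort.csv"
    cohort.to_csv(paths["cohort"], index=False)

    table = cohort.copy()
    for domain in DOMAINS:
        table[f"{domain}_decline"] = [
            decline_score(p, c, domain).value
            for p, c in zip(table[f"{domain}_previous"], table[f"{domain}_current"])
        ]
    rows = []
    for region in _REGIONS:
        predictor = f"{region}_ki_cbrt"
        table[predictor] = cube_root(table[f"{region}_ki"])
        family = []
        for domain in DOMAINS:
            res = fit_adjusted_regression(table, f"{domain}_decline", predictor)
            family.append(res)
        fdr = benjamini_hochberg([r.p_value for r in family], q=config.fdr_q)
        for i, res in enumerate(family):
            rows.append(
                {
                    "region": region,
                    "outcome": res.outcome,
                    "predictor": res.predictor,
                    "n": res.n,
                    "std_beta": res.standardized_beta,
                    "unstd_beta": res.unstandardized_beta,
                    "p": res.p_value,
                    "fdr_rejected": i in fdr.rejected,
                }
            )
    df = pd.DataFrame(rows)
    paths["regressions"] = outdir / "regressions.csv"
    df.to_csv(paths["regressions"], index=False)
    wm_delayed = df[
        (df.region == "wm") & (df.outcome == "delayed_recall_decline")
    ].iloc[0]
    metrics["wm_delayed_recall_std_beta"] = float(wm_delayed.std_beta)
    metrics["wm_delayed_recall_p"] = float(wm_delayed.p)
    return df
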