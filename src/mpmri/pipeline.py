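"""End-to-end orchestration: simulate → fit → morphometry → records → statistics.

A single :class:`StudyConfig` drives the whole run: phantom geometry and
noise, the longitudinal cohort design (four arms × five timepoints), fitting
options for the three quantitative modules, and the statistics thresholds.
One master seed deterministically derives every stream, so rerunning a config
reproduces all numeric outputs bit-identically.

Cohort mode keeps desk scale by materializing full image series (and fitting
them) only for a configurable subset of subjects; the remaining records come
from the ground-truth trajectory model, which the per-module recovery tests
tie to the fitters' accuracy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .adc import adc_map, radc, region_adc
from .dce import extract_aif, fit_tofts, to_relative_concentration
from .dsc import deconvolve_tsvd, to_delta_r2star
from .io import (
    AcquisitionMeta,
    ValidationError,
    write_masks,
    write_records,
    write_series,
)
from .morphometry import morphometry_record
from .phantom import (
    STUDY_GROUP_SIZES,
    baseline_summary,
    default_geometry,
    default_group_profiles,
    default_truth,
    simulate_cohort,
    simulate_dce,
    simulate_dsc,
    simulate_dwi,
)
from .stats import run_study_analysis

__all__ = ["StudyConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class StudyConfig:
    """Single-file configuration of a full study emulation run."""

    seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 12)
    tumor_radii: tuple[float, float, float] = (8.0, 8.0, 8.0)
    rim_thickness: float = 2.0
    noise_sigma: float = 10.0
    n_per_group: dict[str, int] = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    cv: float = 0.15
    n_image_subjects: int = 1
    adc_method: str = "nonlinear"
    tsvd_threshold: float = 0.2
    aif_mode: str = "measured"
    entry_p: float = 0.05
    exit_p: float = 0.10
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.tumor_radii = tuple(float(v) for v in self.tumor_radii)
        if self.n_image_subjects < 0:
            raise ValidationError("n_image_subjects must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta.from_dict(self.acquisition) if self.acquisition else AcquisitionMeta()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["tumor_radii"] = list(self.tumor_radii)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValidationError(f"config {path} does not parse to a mapping")
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_one_subject(config: StudyConfig, out: Path, stage_log: list[str]) -> dict:
    """Simulate one subject's three series, fit them, and summarize."""
    meta = config.meta()
    masks, _ = default_geometry(config.grid_shape, meta, config.tumor_radii,
                                config.rim_thickness)
    truth = default_truth(masks, noise_sigma=config.noise_sigma, seed=config.seed)

    dwi = simulate_dwi(masks, truth, meta)
    dce = simulate_dce(masks, truth, meta)
    dsc = simulate_dsc(masks, truth, meta)
    write_series(dwi, out / "subject01_dwi.nii.gz", out / "subject01_meta.json")
    write_series(dce, out / "subject01_dce.nii.gz")
    write_series(dsc, out / "subject01_dsc.nii.gz")
    write_masks(masks, out / "subject01_masks.nii.gz")
    stage_log.append("simulate: wrote subject01 dwi/dce/dsc + masks")

    # diffusion
    fit_region = masks.region_mask("tumor") | masks.region_mask("liver")
    amap = adc_map(dwi, mask=fit_region, method=config.adc_method)
    amap.save(out / "subject01_adc.nii.gz")
    tumor_adc = region_adc(amap, masks, "tumor")
    liver_adc = region_adc(amap, masks, "liver")

    # DCE: ROI-mean Tofts fit of the viable rim against the aorta AIF
    rim = masks.region_voxels("viable_rim")
    aorta = masks.region_voxels("aorta")
    nb = meta.baseline_frames
    tissue = to_relative_concentration(
        dce.data[rim].mean(axis=0), nb, meta.dce_frame_duration
    )
    aorta_curve = to_relative_concentration(
        dce.data[aorta].mean(axis=0), nb, meta.dce_frame_duration
    )
    aif = extract_aif(aorta_curve, mode="measured")
    tofts = fit_tofts(tissue, aif)

    # DSC: ROI-mean deconvolution of the viable rim
    tissue_r2 = to_delta_r2star(
        dsc.data[rim].mean(axis=0), nb, meta.echo_time, meta.dsc_frame_duration
    )
    aif_r2 = to_delta_r2star(
        dsc.data[aorta].mean(axis=0), nb, meta.echo_time, meta.dsc_frame_duration
    )
    residue = deconvolve_tsvd(tissue_r2, aif_r2, threshold=config.tsvd_threshold)

    morpho = morphometry_record(masks, meta)
    summary = {
        "tumor_adc": tumor_adc,
        "liver_adc": liver_adc,
        "radc": radc(tumor_adc, liver_adc),
        "ktrans": tofts.ktrans,
        "ve": tofts.ve,
        "tofts_converged": bool(tofts.converged),
        "rbv": residue.rbv,
        "rbf": residue.rbf,
        "mtt": residue.mtt,
        "tumor_volume": morpho.tumor_volume,
        "rim_percent": morpho.rim_percent,
        "necrosis_percent": morpho.necrosis_percent,
    }
    with open(out / "subject01_fitted.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    stage_log.append("fit: wrote subject01 ADC map and fitted summary")
    return summary


def run_pipeline(config: StudyConfig, out_dir: str | Path) -> Path:
    """Run the full study emulation into ``out_dir``; returns the directory.

    Outputs: phantom series + masks + fitted summary for the imaged subject
    subset, the cohort ``records.csv`` and noise-free ``truth.csv``, the
    statistics tables (omnibus and post-hoc CSVs, stepwise JSON), and a
    provenance ``manifest.json`` with the config, seed, version and per-file
    checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []
    meta = config.meta()

    try:
        stage = "geometry"
        masks, _ = default_geometry(config.grid_shape, meta, config.tumor_radii,
                                    config.rim_thickness)
        truth = default_truth(masks, noise_sigma=config.noise_sigma, seed=config.seed)
        baseline = baseline_summary(masks, truth, meta)

        stage = "cohort"
        profiles = default_group_profiles(cv=config.cv)
        records, truth_df = simulate_cohort(
            profiles, config.n_per_group, baseline=baseline, seed=config.seed
        )
        write_records(records, out / "records.csv")
        truth_df.to_csv(out / "truth.csv", index=False)
        stage_log.append(f"cohort: wrote {len(records)} records")

        stage = "imaging"
        if config.n_image_subjects > 0:
            _fit_one_subject(config, out, stage_log)

        stage = "statistics"
        n_map = (config.n_per_group if isinstance(config.n_per_group, dict)
                 else {g: config.n_per_group for g in STUDY_GROUP_SIZES})
        stepwise_feasible = n_map.get("ZdTha", 0) > 7  # 5 candidates + intercept
        analysis = run_study_analysis(
            records, entry_p=config.entry_p, exit_p=config.exit_p,
            run_stepwise=stepwise_feasible,
        )
        omnibus_rows = []
        posthoc_rows = []
        for (ep, tp), res in analysis.comparisons.items():
            omnibus_rows.append(
                {"endpoint": ep, "timepoint": tp, "h_statistic": res.h_statistic,
                 "df": res.df, "p_value": res.p_value}
            )
            for ga, gb, raw, adj in res.posthoc:
                posthoc_rows.append(
                    {"endpoint": ep, "timepoint": tp, "group_a": ga, "group_b": gb,
                     "raw_p": raw, "adjusted_p": adj}
                )
        import pandas as pd

        pd.DataFrame(omnibus_rows).to_csv(out / "omnibus.csv", index=False)
        pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.csv", index=False)
        sw = analysis.stepwise
        if sw is None:
            stepwise_payload = {
                "skipped": "ZdTha group too small for 5 candidate predictors"
            }
        else:
            stepwise_payload = {
                "selected_predictors": sw.selected_predictors,
                "coefficients": sw.coefficients,
                "model_r": sw.model_r,
                "model_r_squared": sw.model_r_squared,
                "final_p_values": sw.final_p_values,
                "entry_p": sw.entry_p,
                "exit_p": sw.exit_p,
                "step_log": sw.step_log,
            }
        with open(out / "stepwise.json", "w") as fh:
            json.dump(stepwise_payload, fh, indent=2, sort_keys=True)
        stage_log.append("statistics: wrote omnibus/posthoc/stepwise outputs")

        stage = "manifest"
        tracked = ["records.csv", "truth.csv", "omnibus.csv", "posthoc.csv",
                   "stepwise.json"]
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "version": __version__,
            "stages": stage_log,
            "checksums": {name: _sha256(out / name) for name in tracked
                          if (out / name).exists()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out
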