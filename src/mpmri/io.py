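"""Shared data model and file I/O for 4D MRI series, ROI label masks and record tables.

Conventions used throughout the package:

* voxel indexing is 0-based; spatial axes are ordered ``(x, y, z)`` and the
  series axis (b-value or dynamic frame) is always last;
* masks live on the image grid — no world-space geometry;
* the per-slice extent used in volumetry is ``slice_thickness + slice_gap``
  (tissue in the gap is attributed to the nearer slice);
* volumes go to NIfTI-1, acquisition metadata to a JSON/YAML sidecar, record
  tables to CSV with a units comment line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionMeta",
    "ImageSeries4D",
    "RoiMaskSet",
    "ParamMap",
    "SubjectTimepointRecord",
    "ValidationError",
    "FormatError",
    "GROUPS",
    "TIMEPOINTS",
    "REGION_ROLES",
    "DEFAULT_LEGEND",
    "read_series",
    "write_series",
    "read_masks",
    "write_masks",
    "read_records",
    "write_records",
]

#: treatment arms of the study design (vascular-disrupting agent Zd6126,
#: antiangiogenic thalidomide, their combination, and vehicle controls)
GROUPS = ("control", "Zd", "Tha", "ZdTha")

#: longitudinal imaging timepoints relative to the first treatment
TIMEPOINTS = ("pre", "4h", "2d", "6d", "12d")

#: semantic roles a mask label may map to
REGION_ROLES = ("background", "tumor", "viable_rim", "necrotic_core", "liver", "aorta")

#: default integer labelling used by the phantom generator
DEFAULT_LEGEND = {
    0: "background",
    1: "liver",
    2: "tumor",
    3: "viable_rim",
    4: "necrotic_core",
    5: "aorta",
}

#: minimum ROI size, in voxels, accepted anywhere a region is consumed
MIN_ROI_VOXELS = 10

#: the ten diffusion weightings of the DWI protocol, s/mm^2
PAPER_B_VALUES = (0.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 500.0, 750.0, 1000.0)


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file's structure disagrees with its sidecar or schema."""


# --------------------------------------------------------------------------- #
# acquisition metadata
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters shared by the three dynamic/diffusion protocols.

    Defaults encode the study protocol: 10 b-values 0–1000 s/mm² for DWI,
    80 DCE frames of 3.7 s and 80 DSC frames of 2 s with the contrast bolus
    injected after the 20th measurement, 2 mm slices with a 0.2 mm gap.

    Parameters
    ----------
    b_values : sequence of float
        Diffusion weightings in s/mm², strictly increasing, starting at 0.
    dce_frame_duration, dsc_frame_duration : float
        Seconds per dynamic frame.
    n_frames : int
        Number of dynamic frames (DCE/DSC).
    baseline_frames : int
        Pre-bolus frames; must be >= 2 and < ``n_frames``.
    echo_time : float
        Echo time in ms (used for the DSC ΔR2* conversion).
    slice_thickness, slice_gap : float
        mm; the volumetric slice extent is their sum.
    in_plane_spacing : (float, float)
        mm per voxel along x and y.
    """

    b_values: tuple[float, ...] = PAPER_B_VALUES
    dce_frame_duration: float = 3.7
    dsc_frame_duration: float = 2.0
    n_frames: int = 80
    baseline_frames: int = 20
    echo_time: float = 46.0
    slice_thickness: float = 2.0
    slice_gap: float = 0.2
    in_plane_spacing: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValidationError(
                "b_values must be strictly increasing and start at 0, got "
                f"{list(self.b_values)}"
            )
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))
        if not (2 <= self.baseline_frames < self.n_frames):
            raise ValidationError(
                f"baseline_frames must satisfy 2 <= baseline < n_frames, got "
                f"{self.baseline_frames} of {self.n_frames}"
            )
        sx, sy = self.in_plane_spacing
        for name, val in [
            ("dce_frame_duration", self.dce_frame_duration),
            ("dsc_frame_duration", self.dsc_frame_duration),
            ("echo_time", self.echo_time),
            ("slice_thickness", self.slice_thickness),
            ("in_plane_spacing[0]", sx),
            ("in_plane_spacing[1]", sy),
        ]:
            if val <= 0:
                raise ValidationError(f"{name} must be > 0, got {val}")
        if self.slice_gap < 0:
            raise ValidationError(f"slice_gap must be >= 0, got {self.slice_gap}")
        object.__setattr__(self, "in_plane_spacing", (float(sx), float(sy)))

    @property
    def slice_extent(self) -> float:
        """Per-slice extent used in volumetry: thickness + gap, mm."""
        return self.slice_thickness + self.slice_gap

    @property
    def voxel_volume(self) -> float:
        """Volumetric voxel size in mm³ (in-plane area × slice extent)."""
        sx, sy = self.in_plane_spacing
        return sx * sy * self.slice_extent

    def frame_duration(self, series_kind: str) -> float:
        if series_kind == "dce":
            return self.dce_frame_duration
        if series_kind == "dsc":
            return self.dsc_frame_duration
        raise ValidationError(f"no frame duration for series kind {series_kind!r}")

    def frame_times(self, series_kind: str) -> np.ndarray:
        """Frame midpoint times in seconds for a dynamic series."""
        dt = self.frame_duration(series_kind)
        return (np.arange(self.n_frames) + 0.5) * dt

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["b_values"] = list(d["b_values"])
        d["in_plane_spacing"] = list(d["in_plane_spacing"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown sidecar keys: {sorted(unknown)}")
        d = dict(d)
        if "b_values" in d:
            d["b_values"] = tuple(d["b_values"])
        if "in_plane_spacing" in d:
            d["in_plane_spacing"] = tuple(d["in_plane_spacing"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in {".yaml", ".yml"}:
                yaml.safe_dump(self.to_dict(), fh)
            else:
                json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "AcquisitionMeta":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in {".yaml", ".yml"}:
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        if not isinstance(d, dict):
            raise FormatError(f"sidecar {path} does not parse to a mapping")
        return cls.from_dict(d)


def default_affine(meta: AcquisitionMeta) -> np.ndarray:
    """Voxel-to-world map: diagonal scaling by spacing, slice centers
    thickness+gap apart."""
    sx, sy = meta.in_plane_spacing
    return np.diag([sx, sy, meta.slice_extent, 1.0])


# --------------------------------------------------------------------------- #
# image series
# --------------------------------------------------------------------------- #

SERIES_KINDS = ("dwi", "dce", "dsc")


@dataclass
class ImageSeries4D:
    """A 4D magnitude-signal series: three spatial axes plus one series axis.

    The series axis is the b-value index for DWI and the dynamic frame index
    for DCE/DSC; it is always the last axis.
    """

    data: np.ndarray
    meta: AcquisitionMeta
    series_kind: str
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"series data must be 4D, got {self.data.ndim}D")
        if self.series_kind not in SERIES_KINDS:
            raise ValidationError(
                f"series_kind must be one of {SERIES_KINDS}, got {self.series_kind!r}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series data contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("series data contains negative signal")
        expected = self.expected_series_length()
        if self.data.shape[-1] != expected:
            raise FormatError(
                f"{self.series_kind} series has {self.data.shape[-1]} volumes but "
                f"metadata specifies {expected}"
            )
        if self.affine is None:
            self.affine = default_affine(self.meta)
        self.affine = np.asarray(self.affine, dtype=float)

    def expected_series_length(self) -> int:
        if self.series_kind == "dwi":
            return len(self.meta.b_values)
        return self.meta.n_frames

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def write_series(series: ImageSeries4D, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a series to NIfTI-1 plus (optionally) its metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    nib.save(img, str(path))
    if sidecar is not None:
        series.meta.save(sidecar)


def read_series(path: str | Path, sidecar: str | Path, series_kind: str) -> ImageSeries4D:
    """Read a 4D NIfTI series and validate it against its metadata sidecar.

    Raises
    ------
    FormatError
        If the file is not 4D or the series length disagrees with the sidecar.
    ValidationError
        If the signal contains negative or non-finite values.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"{path} is {data.ndim}D; a 4D series is required")
    meta = AcquisitionMeta.load(sidecar)
    return ImageSeries4D(data=data, meta=meta, series_kind=series_kind, affine=img.affine)


# --------------------------------------------------------------------------- #
# ROI label masks
# --------------------------------------------------------------------------- #


@dataclass
class RoiMaskSet:
    """Integer label volume plus a legend mapping labels to semantic regions.

    The ``tumor`` region is the union of voxels labelled ``tumor``,
    ``viable_rim`` and ``necrotic_core`` (rim and core partition the tumor
    when both are present).
    """

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"label volume must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label volume must be integer-typed")
        for lab, role in self.legend.items():
            if role not in REGION_ROLES:
                raise ValidationError(f"legend maps {lab} to unknown role {role!r}")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.legend)
        if unknown:
            raise ValidationError(f"labels {sorted(unknown)} missing from legend")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def _labels_for(self, region: str) -> list[int]:
        if region == "tumor":
            roles = {"tumor", "viable_rim", "necrotic_core"}
        else:
            roles = {region}
        return [lab for lab, role in self.legend.items() if role in roles]

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a semantic region (``tumor`` includes rim and core)."""
        if region not in REGION_ROLES:
            raise ValidationError(f"unknown region {region!r}")
        labs = self._labels_for(region)
        return np.isin(self.labels, labs)

    def region_voxels(self, region: str, minimum: int = MIN_ROI_VOXELS) -> np.ndarray:
        """Region mask, enforcing the minimum ROI size used throughout the study."""
        mask = self.region_mask(region)
        n = int(mask.sum())
        if n < minimum:
            raise ValidationError(
                f"region {region!r} has {n} voxels; at least {minimum} required"
            )
        return mask

    def validate_against(self, series: ImageSeries4D) -> None:
        """Check grid compatibility with a series; masks are never resampled."""
        if self.spatial_shape != series.spatial_shape:
            raise ValidationError(
                f"mask grid {self.spatial_shape} does not match series grid "
                f"{series.spatial_shape}"
            )


def write_masks(masks: RoiMaskSet, path: str | Path, legend_path: str | Path | None = None) -> None:
    path = Path(path)
    img = nib.Nifti1Image(masks.labels.astype(np.int16), np.eye(4))
    nib.save(img, str(path))
    if legend_path is None:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        legend_path = path.with_name(stem + ".labels.json")
    with open(legend_path, "w") as fh:
        json.dump({str(k): v for k, v in masks.legend.items()}, fh, indent=2)


def read_masks(path: str | Path, legend_path: str | Path | None = None) -> RoiMaskSet:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise FormatError(f"{path} does not contain integer labels")
    labels = np.round(labels).astype(np.int32)
    if legend_path is None:
        stem = path.name.removesuffix(".gz").removesuffix(".nii")
        legend_path = path.with_name(stem + ".labels.json")
    legend_path = Path(legend_path)
    if legend_path.exists():
        with open(legend_path) as fh:
            legend = {int(k): v for k, v in json.load(fh).items()}
    else:
        legend = dict(DEFAULT_LEGEND)
    return RoiMaskSet(labels=labels, legend=legend)


# --------------------------------------------------------------------------- #
# per-subject records
# --------------------------------------------------------------------------- #

RECORD_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "tumor_volume",
    "radc",
    "ktrans",
    "ve",
    "rbv",
    "rbf",
    "rim_percent",
    "necrosis_percent",
]

RECORD_UNITS = {
    "tumor_volume": "mm^3",
    "radc": "dimensionless",
    "ktrans": "1/min",
    "ve": "fraction",
    "rbv": "a.u.",
    "rbf": "a.u.",
    "rim_percent": "%",
    "necrosis_percent": "%",
}


@dataclass
class SubjectTimepointRecord:
    """Per-animal, per-timepoint imaging summary values."""

    subject_id: str
    group: str
    timepoint: str
    tumor_volume: float
    radc: float
    ktrans: float
    ve: float
    rbv: float
    rbf: float
    rim_percent: float = float("nan")
    necrosis_percent: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not self.tumor_volume > 0:
            raise ValidationError(f"tumor_volume must be > 0, got {self.tumor_volume}")
        if not (0.0 <= self.ve <= 1.0):
            raise ValidationError(f"ve must lie in [0, 1], got {self.ve}")
        for name in ("rim_percent", "necrosis_percent"):
            val = getattr(self, name)
            if np.isfinite(val) and not (0.0 <= val <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {val}")


def records_to_frame(records: Sequence[SubjectTimepointRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Sequence[SubjectTimepointRecord], path: str | Path) -> None:
    """Write records to CSV (fixed column order, units in a header comment).

    Raises
    ------
    ValidationError
        For an empty list or duplicate (subject, timepoint) pairs.
    """
    if not records:
        raise ValidationError("cannot write an empty record table")
    keys = [(r.subject_id, r.timepoint) for r in records]
    if len(set(keys)) != len(keys):
        dups = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate (subject, timepoint) pairs: {dups}")
    frame = records_to_frame(records)
    units = ", ".join(f"{k}: {v}" for k, v in RECORD_UNITS.items())
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# units -- {units}\n")
        frame.to_csv(fh, index=False)


def read_records(path: str | Path) -> list[SubjectTimepointRecord]:
    frame = pd.read_csv(path, comment="#")
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"record table missing columns: {sorted(missing)}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            SubjectTimepointRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                timepoint=str(row["timepoint"]),
                **{c: float(row[c]) for c in RECORD_COLUMNS[3:]},
            )
        )
    return out


# --------------------------------------------------------------------------- #
# fitted parameter maps
# --------------------------------------------------------------------------- #


@dataclass
class ParamMap:
    """Per-voxel map of one fitted quantity; failed voxels are NaN, never 0."""

    data: np.ndarray
    name: str
    units: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(f"parameter map must be 3D, got {self.data.ndim}D")

    def save(self, path: str | Path, affine: np.ndarray | None = None) -> None:
        img = nib.Nifti1Image(
            self.data.astype(np.float32), np.eye(4) if affine is None else affine
        )
        nib.save(img, str(path))
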