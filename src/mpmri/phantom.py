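"""Digital phantoms and longitudinal cohort generation with known ground truth.

Geometry is an ellipsoidal tumor (viable rim shell around a necrotic core)
inside a liver block, with a cylindrical aorta for the arterial input
function. Forward models:

* DWI — ``S(b) = S0·exp(-b·ADC)`` with Rician magnitude noise;
* DCE — two-parameter Tofts tissue kinetics driven by a biexponential
  population AIF, linear enhancement ``S = S0·(1 + α·C)``;
* DSC — tracer-dilution first pass ``C = F·(AIF ⊛ R)`` with a boxcar or
  exponential residue function and ``S = S0·exp(-TE·κ·C)``.

Tissue concentrations are integrated on a fine internal grid (20× frame
rate), deliberately independent of the trapezoidal frame-grid convolution the
fitters use, so the phantom can serve as an oracle for them.

The cohort generator emulates the study design — four treatment arms
(control, Zd6126, thalidomide, combined) × five timepoints (pre, 4 h, 2 d,
6 d, 12 d) — by scaling per-subject baseline truth values with per-group,
per-timepoint effect factors and mean-one lognormal between-subject noise.
Default effect trajectories encode only the signed dynamics reported for
this model (vascular shutdown at 4 h with rebound under the VDA alone but
not under the combination, ADC rise with accumulating necrosis, growth delay
under the combination); magnitudes are configuration.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import DSC_DEFAULT_AIF, AifModel
from .io import (
    DEFAULT_LEGEND,
    GROUPS,
    TIMEPOINTS,
    AcquisitionMeta,
    ImageSeries4D,
    RoiMaskSet,
    SubjectTimepointRecord,
    ValidationError,
)

__all__ = [
    "GeometryError",
    "PhantomTruth",
    "GroupEffectProfile",
    "make_geometry",
    "simulate_dwi",
    "simulate_dce",
    "simulate_dsc",
    "simulate_cohort",
    "default_group_profiles",
    "default_truth",
    "baseline_summary",
    "simulate_correlated_predictors",
    "rician_noise",
]

FINE_SUBSTEPS = 20  # internal integration runs at frame_duration / FINE_SUBSTEPS

#: quantities a group-effect profile scales (all multiplicative on baseline)
EFFECT_QUANTITIES = (
    "volume", "adc", "ktrans", "ve", "rbv", "rbf", "rim_percent", "necrosis_percent",
)


class GeometryError(ValidationError):
    """Raised when a requested phantom geometry is unrealizable."""


# --------------------------------------------------------------------------- #
# ground truth
# --------------------------------------------------------------------------- #


@dataclass
class PhantomTruth:
    """Per-voxel ground-truth parameter maps plus simulation parameters.

    The DSC truth is centrally consistent by construction: wherever
    ``flow_map > 0``, ``bv_map = flow_map × mtt_map``.
    """

    adc_map: np.ndarray  # mm^2/s
    s0_map: np.ndarray  # a.u.
    ktrans_map: np.ndarray  # 1/min
    ve_map: np.ndarray  # fraction
    flow_map: np.ndarray  # a.u. (tissue blood flow F)
    mtt_map: np.ndarray  # s
    aif_params: AifModel = field(default_factory=AifModel)
    dsc_aif_params: AifModel = field(default_factory=lambda: DSC_DEFAULT_AIF)
    noise_sigma: float = 0.0
    seed: int = 0
    bv_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = {
            "adc_map": self.adc_map, "s0_map": self.s0_map,
            "ktrans_map": self.ktrans_map, "ve_map": self.ve_map,
            "flow_map": self.flow_map, "mtt_map": self.mtt_map,
        }
        shape = None
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if shape is None:
                shape = arr.shape
            if arr.shape != shape:
                raise ValidationError(f"{name} shape {arr.shape} != {shape}")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} must be nonnegative and finite")
        if np.any(self.ve_map > 1.0):
            raise ValidationError("ve_map must not exceed 1")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.bv_map is None:
            self.bv_map = self.flow_map * self.mtt_map
        else:
            self.bv_map = np.asarray(self.bv_map, dtype=float)
            perfused = self.flow_map > 0
            if not np.allclose(
                self.bv_map[perfused], (self.flow_map * self.mtt_map)[perfused]
            ):
                raise ValidationError(
                    "central-volume inconsistency: bv_map != flow_map * mtt_map"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc_map.shape


#: default per-region tissue truth (generic soft-tissue/tumor ranges; these
#: are simulator defaults, not measurements)
DEFAULT_REGION_TRUTH = {
    #           adc (mm^2/s)  s0    ktrans  ve    F     mtt (s)
    "liver":        (1.1e-3, 1000.0, 0.10, 0.25, 1.00, 6.0),
    "viable_rim":   (0.9e-3, 1000.0, 0.25, 0.35, 1.50, 4.0),
    "necrotic_core": (2.2e-3, 1000.0, 0.02, 0.60, 0.05, 10.0),
    "aorta":        (3.0e-3, 1000.0, 0.00, 1.00, 0.00, 0.0),
    "tumor":        (1.0e-3, 1000.0, 0.20, 0.40, 1.20, 4.0),
    "background":   (0.0,    0.0,    0.00, 0.00, 0.00, 0.0),
}


def default_truth(
    masks: RoiMaskSet,
    noise_sigma: float = 0.0,
    seed: int = 0,
    region_truth: dict | None = None,
) -> PhantomTruth:
    """Region-constant truth maps from a per-region parameter table."""
    table = dict(DEFAULT_REGION_TRUTH)
    if region_truth:
        table.update(region_truth)
    shape = masks.spatial_shape
    maps = [np.zeros(shape) for _ in range(6)]
    for lab, role in masks.legend.items():
        region = masks.labels == lab
        if not region.any():
            continue
        vals = table[role]
        for m, v in zip(maps, vals):
            m[region] = v
    adc, s0, ktrans, ve, flow, mtt = maps
    return PhantomTruth(
        adc_map=adc, s0_map=s0, ktrans_map=ktrans, ve_map=ve,
        flow_map=flow, mtt_map=mtt, noise_sigma=noise_sigma, seed=seed,
    )


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #


def make_geometry(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    tumor_center: tuple[float, float, float],
    tumor_radii: tuple[float, float, float],
    rim_thickness: float,
    liver_box: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
    aorta_cylinder: tuple[float, float, float] | None = None,
) -> tuple[RoiMaskSet, dict[str, int]]:
    """Digitize the phantom anatomy onto a voxel grid.

    All geometric arguments are in mm (``spacing`` maps voxels to mm; for a
    slice-based protocol the z spacing is slice thickness + gap). The tumor is
    an ellipsoid whose inner ellipsoid (radii reduced by ``rim_thickness``)
    is the necrotic core and whose shell is the viable rim. ``liver_box`` is
    an axis-aligned block of normal liver, ``aorta_cylinder`` a z-aligned
    cylinder ``(center_x, center_y, radius)``.

    Returns the mask set and the voxel count per region.

    Raises
    ------
    GeometryError
        If the tumor or aorta does not fit inside the grid, the rim thickness
        reaches the smallest radius, or any requested region digitizes to
        fewer than 10 voxels (the study's ROI size floor).
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    center = np.asarray(tumor_center, dtype=float)
    radii = np.asarray(tumor_radii, dtype=float)
    if np.any(radii <= 0):
        raise GeometryError(f"tumor radii must be > 0, got {tuple(radii)}")
    if rim_thickness <= 0 or rim_thickness >= radii.min():
        raise GeometryError(
            f"rim thickness {rim_thickness} must lie in (0, min radius "
            f"{radii.min()})"
        )
    extent = np.asarray(shape) * np.asarray(spacing)
    if np.any(center - radii < 0) or np.any(center + radii > extent):
        raise GeometryError(
            f"tumor ellipsoid (center {tuple(center)}, radii {tuple(radii)}) "
            f"does not fit inside the {tuple(extent)} mm grid"
        )

    # voxel-center coordinates in mm
    ax = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")

    def ellipsoid(r: np.ndarray) -> np.ndarray:
        return (
            ((xx - center[0]) / r[0]) ** 2
            + ((yy - center[1]) / r[1]) ** 2
            + ((zz - center[2]) / r[2]) ** 2
        ) <= 1.0

    tumor = ellipsoid(radii)
    core = ellipsoid(radii - rim_thickness)
    rim = tumor & ~core

    labels = np.zeros(shape, dtype=np.int16)
    if liver_box is not None:
        (x0, y0, z0), (x1, y1, z1) = liver_box
        liver = (
            (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1) & (zz >= z0) & (zz < z1)
        )
        labels[liver] = 1
    if aorta_cylinder is not None:
        cx, cy, r = aorta_cylinder
        if cx - r < 0 or cx + r > extent[0] or cy - r < 0 or cy + r > extent[1]:
            raise GeometryError("aorta cylinder does not fit inside the grid")
        aorta = ((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2
        labels[aorta] = 5
    labels[rim] = 3
    labels[core] = 4

    masks = RoiMaskSet(labels=labels, legend=dict(DEFAULT_LEGEND))
    counts: dict[str, int] = {}
    required = ["tumor", "viable_rim", "necrotic_core"]
    if liver_box is not None:
        required.append("liver")
    if aorta_cylinder is not None:
        required.append("aorta")
    for region in required:
        n = int(masks.region_mask(region).sum())
        counts[region] = n
        if n < 10:
            raise GeometryError(
                f"region {region!r} digitizes to {n} voxels; at least 10 required"
            )
    return masks, counts


def default_geometry(
    shape: tuple[int, int, int] = (64, 64, 16),
    meta: AcquisitionMeta | None = None,
    tumor_radii: tuple[float, float, float] = (8.0, 8.0, 8.0),
    rim_thickness: float = 2.0,
    aorta_radius: float = 2.0,
) -> tuple[RoiMaskSet, dict[str, int]]:
    """Desk-scale study geometry: an ellipsoidal tumor with a viable rim in a
    liver block, aorta near the lower-left corner of the field of view."""
    if meta is None:
        meta = AcquisitionMeta()
    sx, sy = meta.in_plane_spacing
    spacing = (sx, sy, meta.slice_extent)
    extent = tuple(n * s for n, s in zip(shape, spacing))
    center = (extent[0] * 0.55, extent[1] * 0.55, extent[2] * 0.5)
    ax = max(extent[0] * 0.12, aorta_radius + 0.5)
    ay = max(extent[1] * 0.12, aorta_radius + 0.5)
    return make_geometry(
        shape=shape,
        spacing=spacing,
        tumor_center=center,
        tumor_radii=tumor_radii,
        rim_thickness=rim_thickness,
        liver_box=((2.0, 2.0, 0.0), (extent[0] - 2.0, extent[1] - 2.0, extent[2])),
        aorta_cylinder=(ax, ay, aorta_radius),
    )


# --------------------------------------------------------------------------- #
# noise and forward models
# --------------------------------------------------------------------------- #


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician magnitude noise: Gaussian perturbation on two quadrature channels."""
    if sigma < 0:
        raise ValidationError(f"noise_sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt(re**2 + im**2)


def _rng_for(truth: PhantomTruth, seed: int | None, stream: int) -> np.random.Generator:
    base = truth.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence(entropy=base, spawn_key=(stream,)))


def simulate_dwi(
    masks: RoiMaskSet,
    truth: PhantomTruth,
    meta: AcquisitionMeta,
    seed: int | None = None,
) -> ImageSeries4D:
    """Forward mono-exponential DWI: one magnitude volume per b-value."""
    _check_grids(masks, truth)
    b = np.asarray(meta.b_values, dtype=float)
    clean = truth.s0_map[..., None] * np.exp(-truth.adc_map[..., None] * b)
    noisy = rician_noise(clean, truth.noise_sigma, _rng_for(truth, seed, 1))
    return ImageSeries4D(data=noisy, meta=meta, series_kind="dwi")


def _fine_times(meta: AcquisitionMeta, kind: str) -> np.ndarray:
    dt = meta.frame_duration(kind)
    n_fine = meta.n_frames * FINE_SUBSTEPS
    return (np.arange(n_fine) + 0.5) * (dt / FINE_SUBSTEPS)


def tofts_concentration_fine(
    ktrans: float,
    ve: float,
    aif: AifModel,
    meta: AcquisitionMeta,
) -> np.ndarray:
    """Tissue concentration at DCE frame midpoints by fine-grid Riemann
    convolution (independent of the fitter's frame-grid quadrature)."""
    if ve <= 0:
        if ktrans > 0:
            raise ValidationError("ve = 0 with ktrans > 0: kinetic kernel undefined")
        return np.zeros(meta.n_frames)
    dt_f = meta.dce_frame_duration / FINE_SUBSTEPS
    tf = _fine_times(meta, "dce")
    cp = aif.plasma_concentration(tf, meta.dce_frame_duration)
    kep_s = (ktrans / ve) / 60.0
    kernel = np.exp(-kep_s * (tf - tf[0]))
    # trapezoid end-correction: the j = 0 kernel sample carries half weight
    conv = (np.convolve(cp, kernel)[: tf.size] - 0.5 * cp * kernel[0]) * dt_f
    conv *= ktrans / 60.0
    frame_times = meta.frame_times("dce")
    return np.interp(frame_times, tf, conv)


def simulate_dce(
    masks: RoiMaskSet,
    truth: PhantomTruth,
    meta: AcquisitionMeta,
    enhancement_alpha: float = 1.0,
    seed: int | None = None,
) -> ImageSeries4D:
    """Forward Tofts DCE series with linear enhancement.

    Tissue voxels follow ``S = S0·(1 + α·C_t)`` with ``C_t`` the Tofts
    convolution of the biexponential AIF; aorta voxels carry the AIF signal
    itself. Pre-bolus frames have zero concentration everywhere.
    """
    _check_grids(masks, truth)
    if np.any((truth.ve_map == 0) & (truth.ktrans_map > 0)):
        raise ValidationError("ve = 0 with ktrans > 0: kinetic kernel undefined")
    aif = truth.aif_params
    frame_times = meta.frame_times("dce")
    cp_frames = aif.plasma_concentration(frame_times, meta.dce_frame_duration)

    conc = np.zeros(truth.shape + (meta.n_frames,))
    pairs = np.stack([truth.ktrans_map.ravel(), truth.ve_map.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    flat = conc.reshape(-1, meta.n_frames)
    for i, (kt, ve) in enumerate(uniq):
        if kt == 0:
            continue
        flat[inverse == i] = tofts_concentration_fine(kt, ve, aif, meta)
    aorta = masks.region_mask("aorta")
    conc[aorta] = cp_frames

    clean = truth.s0_map[..., None] * (1.0 + enhancement_alpha * conc)
    noisy = rician_noise(clean, truth.noise_sigma, _rng_for(truth, seed, 2))
    return ImageSeries4D(data=noisy, meta=meta, series_kind="dce")


def dsc_concentration_fine(
    flow: float,
    mtt: float,
    aif: AifModel,
    meta: AcquisitionMeta,
    residue_model: str = "boxcar",
) -> np.ndarray:
    """First-pass tracer concentration ``F·(AIF ⊛ R)`` at DSC frame midpoints.

    Residue models: ``boxcar`` (plug flow, width MTT) or ``exponential``
    (well-mixed compartment, mean MTT).
    """
    if residue_model not in ("boxcar", "exponential"):
        raise ValidationError(f"unknown residue model {residue_model!r}")
    if flow == 0 or mtt == 0:
        return np.zeros(meta.n_frames)
    dt_f = meta.dsc_frame_duration / FINE_SUBSTEPS
    tf = _fine_times(meta, "dsc")
    cp = aif.plasma_concentration(tf, meta.dsc_frame_duration)
    tau = tf - tf[0]
    if residue_model == "boxcar":
        # one-fine-step ramp at the trailing edge keeps ∫R dt = MTT exactly
        residue = np.clip((mtt - tau) / dt_f + 0.5, 0.0, 1.0)
    else:
        residue = np.exp(-tau / mtt)
    # trapezoid end-correction for the j = 0 kernel sample
    conv = (np.convolve(cp, residue)[: tf.size] - 0.5 * cp * residue[0]) * dt_f
    conv *= flow
    return np.interp(meta.frame_times("dsc"), tf, conv)


def simulate_dsc(
    masks: RoiMaskSet,
    truth: PhantomTruth,
    meta: AcquisitionMeta,
    residue_model: str = "boxcar",
    relaxivity_kappa: float = 1.0,
    seed: int | None = None,
) -> ImageSeries4D:
    """Forward DSC series: susceptibility signal drop during the first pass.

    ``S(t) = S0·exp(-TE·κ·C(t))`` with TE in seconds and κ an arbitrary
    relaxivity constant; aorta voxels carry the AIF concentration.
    """
    _check_grids(masks, truth)
    if residue_model not in ("boxcar", "exponential"):
        raise ValidationError(f"unknown residue model {residue_model!r}")
    aif = truth.dsc_aif_params
    frame_times = meta.frame_times("dsc")
    cp_frames = aif.plasma_concentration(frame_times, meta.dsc_frame_duration)

    conc = np.zeros(truth.shape + (meta.n_frames,))
    pairs = np.stack([truth.flow_map.ravel(), truth.mtt_map.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    flat = conc.reshape(-1, meta.n_frames)
    for i, (f, mtt) in enumerate(uniq):
        if f == 0 or mtt == 0:
            continue
        flat[inverse == i] = dsc_concentration_fine(f, mtt, aif, meta, residue_model)
    aorta = masks.region_mask("aorta")
    conc[aorta] = cp_frames

    te_s = meta.echo_time / 1000.0
    clean = truth.s0_map[..., None] * np.exp(-te_s * relaxivity_kappa * conc)
    noisy = rician_noise(clean, truth.noise_sigma, _rng_for(truth, seed, 3))
    return ImageSeries4D(data=noisy, meta=meta, series_kind="dsc")


def _check_grids(masks: RoiMaskSet, truth: PhantomTruth) -> None:
    if masks.spatial_shape != truth.shape:
        raise ValidationError(
            f"mask grid {masks.spatial_shape} != truth grid {truth.shape}"
        )


# --------------------------------------------------------------------------- #
# longitudinal cohort
# --------------------------------------------------------------------------- #


@dataclass
class GroupEffectProfile:
    """Per-group multiplicative effect trajectory on each truth quantity.

    ``factors[timepoint][quantity]`` scales the subject's baseline value of
    that quantity; pre-treatment factors are all 1. ``cv`` is the coefficient
    of variation of the mean-one lognormal between-subject noise.
    """

    group: str
    factors: dict[str, dict[str, float]]
    cv: float = 0.15

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.cv < 0:
            raise ValidationError(f"cv must be >= 0, got {self.cv}")
        missing = [tp for tp in TIMEPOINTS if tp not in self.factors]
        if missing:
            raise ValidationError(
                f"profile for {self.group!r} missing timepoints {missing}"
            )
        for tp, f in self.factors.items():
            unknown = set(f) - set(EFFECT_QUANTITIES)
            if unknown:
                raise ValidationError(f"unknown effect quantities {sorted(unknown)}")
            for q, v in f.items():
                if v <= 0:
                    raise ValidationError(
                        f"factor {q} at {tp} must be > 0, got {v}"
                    )
        pre = self.factor_row("pre")
        if any(v != 1.0 for v in pre.values()):
            raise ValidationError("pre-treatment factors must all be 1")

    def factor_row(self, timepoint: str) -> dict[str, float]:
        row = {q: 1.0 for q in EFFECT_QUANTITIES}
        row.update(self.factors[timepoint])
        return row


def _traj(values: dict[str, tuple]) -> dict[str, dict[str, float]]:
    """Build a factors dict from per-quantity 5-tuples over the timepoints."""
    out: dict[str, dict[str, float]] = {tp: {} for tp in TIMEPOINTS}
    for q, tup in values.items():
        for tp, v in zip(TIMEPOINTS, tup):
            out[tp][q] = float(v)
    return out


def default_group_profiles(cv: float = 0.15) -> list[GroupEffectProfile]:
    """Default effect trajectories encoding the study's signed dynamics.

    Qualitative shape only: untreated tumors grow steadily; the VDA collapses
    perfusion at 4 h with rebound by 2 d; the combination keeps perfusion and
    permeability suppressed through 6 d, raises ADC as necrosis accumulates,
    and delays growth with a thinner viable rim. Magnitudes are defaults, not
    measurements.
    """
    control = _traj({
        "volume": (1, 1.15, 1.9, 3.5, 6.5),
        "adc": (1, 1.0, 0.97, 0.95, 0.95),
        "ktrans": (1, 1.05, 1.10, 1.05, 1.10),
        "rbv": (1, 0.97, 0.92, 0.88, 0.85),
        "rbf": (1, 1.0, 0.95, 0.92, 0.90),
        "necrosis_percent": (1, 1.0, 1.1, 1.2, 1.3),
    })
    zd = _traj({
        "volume": (1, 1.05, 1.5, 2.8, 5.5),
        "adc": (1, 1.15, 1.05, 0.98, 0.95),
        "ktrans": (1, 0.50, 0.90, 1.05, 1.25),
        "rbv": (1, 0.30, 0.90, 0.90, 0.85),
        "rbf": (1, 0.80, 0.95, 0.95, 0.90),
        "rim_percent": (1, 1.0, 0.9, 1.2, 1.3),
        "necrosis_percent": (1, 1.6, 1.2, 1.0, 0.9),
    })
    tha = _traj({
        "volume": (1, 1.10, 1.8, 3.2, 5.8),
        "adc": (1, 1.0, 1.0, 0.97, 0.96),
        "ktrans": (1, 1.0, 1.05, 1.0, 1.05),
        "rbv": (1, 0.95, 0.90, 0.87, 0.84),
        "rbf": (1, 1.0, 0.97, 0.95, 0.93),
        "necrosis_percent": (1, 1.0, 1.05, 1.1, 1.15),
    })
    zdtha = _traj({
        "volume": (1, 1.0, 1.15, 1.4, 1.9),
        "adc": (1, 1.10, 1.30, 1.35, 1.25),
        "ktrans": (1, 0.40, 0.55, 0.75, 1.0),
        "rbv": (1, 0.30, 0.50, 0.65, 0.90),
        "rbf": (1, 0.85, 0.60, 0.90, 1.0),
        "rim_percent": (1, 1.0, 0.55, 0.50, 0.50),
        "necrosis_percent": (1, 1.7, 1.9, 2.1, 2.2),
    })
    return [
        GroupEffectProfile("control", control, cv),
        GroupEffectProfile("Zd", zd, cv),
        GroupEffectProfile("Tha", tha, cv),
        GroupEffectProfile("ZdTha", zdtha, cv),
    ]


#: study group sizes (44 animals randomized)
STUDY_GROUP_SIZES = {"control": 10, "Zd": 11, "Tha": 11, "ZdTha": 12}

#: default per-subject baseline summary values for cohort simulation
DEFAULT_BASELINE = {
    "tumor_volume": 600.0,  # mm^3
    "tumor_adc": 1.0e-3,  # mm^2/s
    "liver_adc": 1.1e-3,  # mm^2/s
    "ktrans": 0.25,  # 1/min
    "ve": 0.35,
    "rbv": 6.0,  # a.u.
    "rbf": 1.5,  # a.u.
    "rim_percent": 25.0,
    "necrosis_percent": 20.0,
}


def baseline_summary(
    masks: RoiMaskSet, truth: PhantomTruth, meta: AcquisitionMeta
) -> dict[str, float]:
    """Summarize a phantom's truth maps into per-subject baseline values."""
    from . import morphometry  # local import avoids a cycle at module load

    rim = masks.region_voxels("viable_rim")
    liver = masks.region_voxels("liver")
    tumor = masks.region_voxels("tumor")
    return {
        "tumor_volume": morphometry.tumor_volume(masks, meta),
        "tumor_adc": float(truth.adc_map[tumor].mean()),
        "liver_adc": float(truth.adc_map[liver].mean()),
        "ktrans": float(truth.ktrans_map[rim].mean()),
        "ve": float(truth.ve_map[rim].mean()),
        "rbv": float(truth.bv_map[rim].mean()),
        "rbf": float(truth.flow_map[rim].mean()),
        "rim_percent": morphometry.relative_viable_rim(masks, meta),
        "necrosis_percent": morphometry.relative_necrosis_volume(masks, meta),
    }


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_cohort(
    profiles: list[GroupEffectProfile],
    n_per_group: dict[str, int] | int,
    baseline: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[SubjectTimepointRecord], pd.DataFrame]:
    """Generate a longitudinal four-group cohort of summary records.

    Each subject's value of each quantity at each timepoint is
    ``baseline × group factor × lognormal(cv)`` with independent mean-one
    lognormal draws per subject × timepoint × quantity. Returns the record
    list plus a tidy truth table (the noise-free ``baseline × factor``
    values) for recovery checks.
    """
    by_group = {p.group: p for p in profiles}
    missing = [g for g in GROUPS if g not in by_group]
    if missing:
        raise ValidationError(f"profiles missing groups {missing}")
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in GROUPS}
    for g, n in n_per_group.items():
        if n < 2:
            raise ValidationError(f"n_per_group[{g!r}] must be >= 2, got {n}")
    if baseline is None:
        baseline = dict(DEFAULT_BASELINE)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    records: list[SubjectTimepointRecord] = []
    truth_rows = []
    for group in GROUPS:
        profile = by_group[group]
        for i in range(n_per_group[group]):
            subject = f"{group}-{i + 1:02d}"
            for tp in TIMEPOINTS:
                row = profile.factor_row(tp)
                noise = {
                    q: float(_lognormal_factor(rng, profile.cv, None))
                    for q in EFFECT_QUANTITIES
                }
                liver_noise = float(_lognormal_factor(rng, profile.cv, None))
                tumor_adc = baseline["tumor_adc"] * row["adc"] * noise["adc"]
                liver_adc = baseline["liver_adc"] * liver_noise
                values = {
                    "tumor_volume": baseline["tumor_volume"] * row["volume"] * noise["volume"],
                    "radc": tumor_adc / liver_adc,
                    "ktrans": baseline["ktrans"] * row["ktrans"] * noise["ktrans"],
                    "ve": min(1.0, baseline["ve"] * row["ve"] * noise["ve"]),
                    "rbv": baseline["rbv"] * row["rbv"] * noise["rbv"],
                    "rbf": baseline["rbf"] * row["rbf"] * noise["rbf"],
                    "rim_percent": min(
                        100.0,
                        baseline["rim_percent"] * row["rim_percent"] * noise["rim_percent"],
                    ),
                    "necrosis_percent": min(
                        100.0,
                        baseline["necrosis_percent"]
                        * row["necrosis_percent"]
                        * noise["necrosis_percent"],
                    ),
                }
                records.append(
                    SubjectTimepointRecord(
                        subject_id=subject, group=group, timepoint=tp, **values
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": subject,
                        "group": group,
                        "timepoint": tp,
                        "tumor_volume": baseline["tumor_volume"] * row["volume"],
                        "radc": baseline["tumor_adc"] * row["adc"] / baseline["liver_adc"],
                        "ktrans": baseline["ktrans"] * row["ktrans"],
                        "ve": min(1.0, baseline["ve"] * row["ve"]),
                        "rbv": baseline["rbv"] * row["rbv"],
                        "rbf": baseline["rbf"] * row["rbf"],
                        "rim_percent": min(
                            100.0, baseline["rim_percent"] * row["rim_percent"]
                        ),
                        "necrosis_percent": min(
                            100.0,
                            baseline["necrosis_percent"] * row["necrosis_percent"],
                        ),
                    }
                )
    return records, pd.DataFrame(truth_rows)


def simulate_correlated_predictors(
    target_r: float,
    n: int,
    n_decoys: int,
    seed: int = 0,
    response_name: str = "volume_change",
    primary_name: str = "radc_change",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Response depending on one predictor at a target correlation.

    Generates ``y = r·x1 + sqrt(1 - r²)·ε`` with standardized ``x1``, plus
    ``n_decoys`` independent standard-normal decoy candidates — the setting
    for checking that stepwise selection recovers the single informative
    predictor (such as the ADC change driving tumor volume change).
    """
    if not (-1.0 < target_r < 1.0):
        raise ValidationError(f"target_r must lie in (-1, 1), got {target_r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    x1 = rng.normal(size=n)
    eps = rng.normal(size=n)
    y = target_r * x1 + np.sqrt(1.0 - target_r**2) * eps
    candidates = {primary_name: x1}
    for j in range(n_decoys):
        candidates[f"decoy_{j + 1}"] = rng.normal(size=n)
    return y, pd.DataFrame(candidates)
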