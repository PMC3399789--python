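"""Apparent diffusion coefficient mapping from multi-b diffusion MRI.

The signal model is mono-exponential, ``S(b) = S0·exp(-b·ADC)``, fitted over
all acquired b-values. Two fitters are provided:

* ``loglinear`` — weighted least squares of ``ln S`` on ``b`` with weights
  ``S²`` (the classical linearization, exact on noiseless data);
* ``nonlinear`` — damped Gauss–Newton least squares on the exponential model,
  initialized from the log-linear solution. This is the default because the
  log-linear estimate is biased under Rician magnitude noise at high b.

Whole-tumor ADC is the mean over the tumor ROI across all slices; dividing by
the same-examination healthy-liver ADC yields the relative ADC (rADC), and
percent change ``100·(post - pre)/pre`` is the shared longitudinal endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageSeries4D, ParamMap, RoiMaskSet, ValidationError

__all__ = [
    "AdcFitResult",
    "FitError",
    "fit_adc",
    "adc_map",
    "region_adc",
    "radc",
    "percent_change",
]

METHODS = ("loglinear", "nonlinear")


class FitError(ValueError):
    """Raised when a voxel fit cannot be attempted (too few usable points)."""


@dataclass
class AdcFitResult:
    """Result of a single mono-exponential diffusion fit."""

    adc: float  # mm^2/s, clipped at 0
    s0: float  # a.u.
    r_squared: float
    n_points_used: int
    clipped: bool = False  # True when a negative slope was clipped to 0


def _loglinear_vec(signals: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized weighted log-linear fit.

    ``signals`` has shape (n_voxels, n_b). Non-positive samples get zero
    weight (their log is undefined). Returns (s0, adc) arrays; voxels with
    fewer than 3 usable points come back NaN.
    """
    pos = signals > 0
    w = np.where(pos, signals, 0.0) ** 2
    logs = np.where(pos, np.log(np.where(pos, signals, 1.0)), 0.0)
    sw = w.sum(axis=1)
    n_ok = pos.sum(axis=1)
    valid = (n_ok >= 3) & (sw > 0)
    sw = np.where(sw > 0, sw, 1.0)
    mb = (w * b).sum(axis=1) / sw
    my = (w * logs).sum(axis=1) / sw
    cov = (w * (b - mb[:, None]) * (logs - my[:, None])).sum(axis=1)
    var = (w * (b - mb[:, None]) ** 2).sum(axis=1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    adc = -slope
    s0 = np.exp(my - slope * mb)  # intercept at b = 0
    adc = np.where(valid, adc, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return s0, adc


def _gauss_newton_vec(
    signals: np.ndarray,
    b: np.ndarray,
    s0: np.ndarray,
    adc: np.ndarray,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Levenberg–Marquardt refinement of (S0, ADC) per voxel.

    Works on the exponential model directly, so non-positive noisy samples
    still contribute. ADC is constrained non-negative only at the end (the
    caller clips and flags).
    """
    s0 = s0.copy()
    adc = adc.copy()
    lam = np.full(s0.shape, 1e-3)
    model = s0[:, None] * np.exp(-np.outer(adc, b))
    sse = ((model - signals) ** 2).sum(axis=1)
    for _ in range(n_iter):
        e = np.exp(-np.outer(adc, b))
        model = s0[:, None] * e
        r = model - signals
        j_s0 = e
        j_adc = -model * b
        a11 = (j_s0 * j_s0).sum(axis=1)
        a12 = (j_s0 * j_adc).sum(axis=1)
        a22 = (j_adc * j_adc).sum(axis=1)
        g1 = (j_s0 * r).sum(axis=1)
        g2 = (j_adc * r).sum(axis=1)
        d11 = a11 * (1.0 + lam)
        d22 = a22 * (1.0 + lam)
        det = d11 * d22 - a12 * a12
        det = np.where(np.abs(det) > 1e-300, det, np.nan)
        step_s0 = (d22 * g1 - a12 * g2) / det
        step_adc = (d11 * g2 - a12 * g1) / det
        s0_new = s0 - step_s0
        adc_new = adc - step_adc
        model_new = s0_new[:, None] * np.exp(-np.outer(adc_new, b))
        sse_new = ((model_new - signals) ** 2).sum(axis=1)
        better = np.isfinite(sse_new) & (sse_new <= sse)
        s0 = np.where(better, s0_new, s0)
        adc = np.where(better, adc_new, adc)
        sse = np.where(better, sse_new, sse)
        lam = np.where(better, lam * 0.5, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e8)
    return s0, adc


def _fit_batch(
    signals: np.ndarray, b_values: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit many voxels at once; returns (s0, adc_clipped, r_squared)."""
    s0, adc = _loglinear_vec(signals, b_values)
    if method == "nonlinear":
        seed_s0 = np.where(np.isfinite(s0), s0, signals.max(axis=1))
        seed_adc = np.where(np.isfinite(adc), adc, 1e-3)
        s0, adc = _gauss_newton_vec(signals, b_values, seed_s0, seed_adc)
    adc_clipped = np.where(np.isfinite(adc), np.maximum(adc, 0.0), np.nan)
    model = np.where(
        np.isfinite(s0[:, None]),
        np.nan_to_num(s0)[:, None] * np.exp(-np.outer(np.nan_to_num(adc_clipped), b_values)),
        np.nan,
    )
    ss_res = ((signals - model) ** 2).sum(axis=1)
    ss_tot = ((signals - signals.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return s0, adc_clipped, r2


def fit_adc(
    signals: np.ndarray, b_values: np.ndarray, method: str = "nonlinear"
) -> AdcFitResult:
    """Fit the mono-exponential diffusion model to one signal vector.

    Parameters
    ----------
    signals : array of shape (n_b,)
        Magnitude signal per b-value.
    b_values : array of shape (n_b,)
        Diffusion weightings, s/mm².
    method : {"nonlinear", "loglinear"}
        ``nonlinear`` (default) refines the log-linear solution by damped
        Gauss–Newton on the exponential model.

    Returns
    -------
    AdcFitResult
        With ``adc`` in mm²/s, clipped to 0 (and flagged) if the fitted slope
        was negative.
    """
    signals = np.asarray(signals, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if signals.shape != b_values.shape or signals.ndim != 1:
        raise ValidationError("signals and b_values must be matching 1D arrays")
    if not np.all(np.isfinite(signals)):
        raise ValidationError("signals contain non-finite values")
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    n_pos = int((signals > 0).sum())
    if n_pos < 3:
        raise FitError(f"need at least 3 positive signals, got {n_pos}")
    s0, adc = _loglinear_vec(signals[None, :], b_values)
    raw_adc = adc[0]
    if method == "nonlinear":
        s0, adc = _gauss_newton_vec(signals[None, :], b_values, s0, adc)
        raw_adc = adc[0]
    s0v, adcv, r2 = float(s0[0]), float(max(raw_adc, 0.0)), None
    model = s0v * np.exp(-b_values * adcv)
    ss_res = float(((signals - model) ** 2).sum())
    ss_tot = float(((signals - signals.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n_used = signals.size if method == "nonlinear" else n_pos
    return AdcFitResult(
        adc=adcv, s0=s0v, r_squared=r2, n_points_used=n_used, clipped=raw_adc < 0
    )


def adc_map(
    series: ImageSeries4D,
    mask: np.ndarray | None = None,
    method: str = "nonlinear",
) -> ParamMap:
    """Voxel-wise ADC map over a mask (or the whole grid).

    Voxels outside the mask, and voxels whose fit fails (fewer than 3 positive
    samples), are NaN — never silently zero.
    """
    if series.series_kind != "dwi":
        raise ValidationError(
            f"adc_map requires a dwi series, got {series.series_kind!r}"
        )
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    b = np.asarray(series.meta.b_values, dtype=float)
    shape = series.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValidationError(f"mask shape {mask.shape} != grid {shape}")
    out = np.full(shape, np.nan)
    voxels = series.data[mask]  # (n_voxels, n_b)
    if voxels.size:
        usable = (voxels > 0).sum(axis=1) >= 3
        s0, adcs, _ = _fit_batch(voxels[usable], b, method)
        vals = np.full(voxels.shape[0], np.nan)
        vals[usable] = adcs
        out[mask] = vals
    return ParamMap(
        data=out,
        name="adc",
        units="mm^2/s",
        diagnostics={"method": method, "n_fitted": int(np.isfinite(out).sum())},
    )


def region_adc(param_map: ParamMap, masks: RoiMaskSet, region: str) -> float:
    """Mean ADC over the finite voxels of a region, across all slices."""
    if param_map.data.shape != masks.spatial_shape:
        raise ValidationError(
            f"map grid {param_map.data.shape} != mask grid {masks.spatial_shape}"
        )
    mask = masks.region_voxels(region)
    vals = param_map.data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError(f"region {region!r} has no finite fitted voxels")
    return float(vals.mean())


def radc(tumor_adc: float, liver_adc: float) -> float:
    """Relative ADC: tumor ADC normalized to healthy-liver ADC."""
    if not liver_adc > 0:
        raise ValidationError(f"liver ADC must be > 0, got {liver_adc}")
    return float(tumor_adc / liver_adc)


def percent_change(pre_value: float, post_value: float) -> float:
    """Longitudinal percent change ``100·(post - pre)/pre``.

    Shared by the rADC and tumor-volume endpoints.
    """
    if pre_value == 0:
        raise ValidationError("percent change undefined for a zero pre value")
    return float(100.0 * (post_value - pre_value) / pre_value)
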