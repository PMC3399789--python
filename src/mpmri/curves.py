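"""Concentration–time curves and the population arterial input function.

A :class:`ConcentrationCurve` holds a uniformly sampled relative-concentration
series (dimensionless for DCE, 1/s for the DSC ΔR2* curve) on frame-midpoint
times in seconds. An :class:`AifModel` is a biexponentially decaying bolus:
zero before arrival, then ``dose_scale·(a1·e^{-m1 τ} + a2·e^{-m2 τ})`` with
τ the time since arrival and the decay rates in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

__all__ = ["ConcentrationCurve", "AifModel"]


@dataclass
class ConcentrationCurve:
    """Relative concentration sampled on a uniform frame grid.

    Attributes
    ----------
    times : ndarray
        Frame midpoint times, seconds, strictly increasing, uniformly spaced.
    values : ndarray
        Concentration samples (relative units).
    baseline_frames : int
        Number of pre-bolus frames; their mean is ~0 up to noise.
    """

    times: np.ndarray
    values: np.ndarray
    baseline_frames: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValidationError("times and values must be matching 1D arrays")
        dt = np.diff(self.times)
        if self.times.size >= 2 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValidationError("times must be strictly increasing and uniform")
        if not (0 <= self.baseline_frames < self.times.size):
            raise ValidationError(
                f"baseline_frames {self.baseline_frames} out of range for "
                f"{self.times.size} frames"
            )

    @property
    def dt(self) -> float:
        """Frame spacing in seconds."""
        return float(self.times[1] - self.times[0])

    def integral(self) -> float:
        """Trapezoidal integral over the full curve, concentration·seconds."""
        return float(np.trapezoid(self.values, self.times))


@dataclass(frozen=True)
class AifModel:
    """Biexponential bolus model for the arterial plasma concentration.

    ``Cp(t) = dose_scale · (a1·exp(-m1·τ) + a2·exp(-m2·τ))`` for
    ``τ = t - t_arrival >= 0`` and 0 before arrival. Decay rates are in 1/min;
    default amplitudes and rates follow the classical population biexponential
    plasma-clearance parameterization (a1 = 3.99, a2 = 4.78 kg/l;
    m1 = 0.144, m2 = 0.0111 1/min).

    ``bolus_arrival_frame`` is the index of the first post-bolus frame and
    equals the number of baseline frames (the bolus is injected after the
    20th measurement under the default protocol).
    """

    dose_scale: float = 1.0
    a1: float = 3.99
    a2: float = 4.78
    m1: float = 0.144
    m2: float = 0.0111
    bolus_arrival_frame: int = 20

    def __post_init__(self) -> None:
        for name in ("dose_scale", "a1", "a2", "m1", "m2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"AIF parameter {name} must be > 0")
        if self.bolus_arrival_frame < 0:
            raise ValidationError("bolus_arrival_frame must be >= 0")

    def arrival_time(self, frame_duration: float) -> float:
        """Bolus arrival in seconds: the start of the first post-bolus frame."""
        return self.bolus_arrival_frame * frame_duration

    def plasma_concentration(self, times_s: np.ndarray, frame_duration: float) -> np.ndarray:
        """Evaluate Cp at arbitrary times (seconds)."""
        times_s = np.asarray(times_s, dtype=float)
        tau_min = (times_s - self.arrival_time(frame_duration)) / 60.0
        cp = self.dose_scale * (
            self.a1 * np.exp(-self.m1 * np.maximum(tau_min, 0.0))
            + self.a2 * np.exp(-self.m2 * np.maximum(tau_min, 0.0))
        )
        return np.where(tau_min >= 0.0, cp, 0.0)

    def sample(self, times_s: np.ndarray, frame_duration: float) -> ConcentrationCurve:
        """Sample the AIF on a frame grid as a concentration curve."""
        return ConcentrationCurve(
            times=np.asarray(times_s, dtype=float),
            values=self.plasma_concentration(times_s, frame_duration),
            baseline_frames=self.bolus_arrival_frame,
        )


#: default DSC-phantom AIF — same functional form, but with decay rates fast
#: enough (several 1/min) that the first-pass bolus clears within the 160 s
#: acquisition window, as a susceptibility-contrast first pass does.
DSC_DEFAULT_AIF = AifModel(dose_scale=1.0, a1=6.0, a2=2.0, m1=20.0, m2=6.0)
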