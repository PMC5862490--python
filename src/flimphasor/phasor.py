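"""Phasor (polar-plot) coordinates of TCSPC decays.

For a decay histogram :math:`c_i` with bin-center times :math:`t_i`, the
phasor at angular frequency :math:`\\omega = k\\,2\\pi f` (harmonic ``k`` of
the repetition frequency ``f``) is the intensity-normalized Fourier component

.. math::

    g(\\omega) = \\frac{\\sum_i c_i \\cos\\omega t_i}{\\sum_i c_i},\\qquad
    s(\\omega) = \\frac{\\sum_i c_i \\sin\\omega t_i}{\\sum_i c_i}.

Sums run over *all* bins, including any early TAC-truncated region — the
calibration step compensates for instrument-response phase/modulation errors
introduced there. Single-exponential decays fall on the "universal circle"
:math:`(g-1/2)^2 + s^2 = 1/4,\\ s \\ge 0`; any mixture falls inside it at the
fractional-fluorescence-weighted vector sum of its components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .flim_data import (
    AcquisitionMeta,
    DecayHistogram,
    MeasurementPoint,
    PhasorPoint,
    PixelMask,
    TCSPCImage,
)
from .synthetic import LifetimeMixture

__all__ = [
    "CalibrationTransform",
    "PhasorImage",
    "pixel_phasor",
    "phasor_image",
    "single_exp_phasor",
    "mixture_phasor",
    "calibrate",
    "apply_calibration",
    "aggregate_measurement",
    "universal_circle",
]


def single_exp_phasor(tau_ns, omega: float):
    """Closed-form phasor of a single-exponential decay under periodic excitation.

    ``g = 1/(1+(omega*tau)^2)``, ``s = omega*tau/(1+(omega*tau)^2)``; the point
    lies on the universal circle for every ``tau >= 0``. ``tau_ns`` may be an
    array; ``omega`` is in rad/ns.
    """
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be nonnegative")
    if omega <= 0:
        raise ValueError("omega must be positive")
    wt = omega * tau
    denom = 1.0 + wt * wt
    g, s = 1.0 / denom, wt / denom
    if np.isscalar(tau_ns):
        return float(g), float(s)
    return g, s


def mixture_phasor(mixture: LifetimeMixture, omega: float) -> tuple[float, float]:
    """Fractionally-weighted vectorial sum of the component phasors."""
    taus = np.asarray(mixture.lifetimes_ns)
    fracs = np.asarray(mixture.fractions)
    g, s = single_exp_phasor(taus, omega)
    return float(np.dot(fracs, g)), float(np.dot(fracs, s))


def universal_circle(n_points: int = 181) -> np.ndarray:
    """Polyline along the semicircle (g-1/2)^2 + s^2 = 1/4, s >= 0.

    Returned as an ``(n_points, 2)`` array from (0, 0) to (1, 0), for plot
    overlays and distance-to-circle diagnostics.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    theta = np.linspace(np.pi, 0.0, n_points)
    return np.column_stack([0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta)])


def _fourier_weights(meta: AcquisitionMeta, harmonic: int) -> tuple[np.ndarray, np.ndarray]:
    omega = meta.omega(harmonic)
    t = meta.bin_centers_ns()
    return np.cos(omega * t), np.sin(omega * t)


def pixel_phasor(decay: DecayHistogram, harmonic: int = 1) -> PhasorPoint:
    """Phasor of a single decay histogram at the given harmonic."""
    total = decay.total()
    if total <= 0:
        raise ValueError("cannot compute a phasor for an empty histogram")
    cos_w, sin_w = _fourier_weights(decay.meta, harmonic)
    g = float(np.dot(decay.counts, cos_w) / total)
    s = float(np.dot(decay.counts, sin_w) / total)
    return PhasorPoint(g=g, s=s, harmonic=int(harmonic), photons=total)


@dataclass
class PhasorImage:
    """Per-pixel g and s planes at one harmonic; invalid pixels are NaN."""

    g: np.ndarray
    s: np.ndarray
    valid: PixelMask
    harmonic: int
    calibrated: bool = False

    def valid_points(self) -> np.ndarray:
        """(n, 2) array of (g, s) over valid pixels."""
        m = self.valid.include
        return np.column_stack([self.g[m], self.s[m]])


def phasor_image(image: TCSPCImage, valid: PixelMask, harmonic: int = 1) -> PhasorImage:
    """Vectorized per-pixel phasor computation over the valid mask."""
    valid.check_shape(image)
    if valid.n_selected == 0:
        raise ValueError("no valid pixels")
    cos_w, sin_w = _fourier_weights(image.meta, harmonic)
    counts = image.counts.astype(float)
    totals = counts.sum(axis=2)
    ok = valid.include & (totals > 0)
    if not ok.any():
        raise ValueError("no valid pixels with photons")
    g = np.full(totals.shape, np.nan)
    s = np.full(totals.shape, np.nan)
    g[ok] = counts[ok] @ cos_w / totals[ok]
    s[ok] = counts[ok] @ sin_w / totals[ok]
    return PhasorImage(g, s, PixelMask(ok, label="valid"), int(harmonic))


@dataclass(frozen=True)
class CalibrationTransform:
    """Complex correction ``z -> z * scale * exp(i*phase)`` at one harmonic."""

    phase_shift: float
    modulation_scale: float
    harmonic: int

    def __post_init__(self) -> None:
        if self.modulation_scale <= 0:
            raise ValueError("modulation_scale must be positive")

    @property
    def factor(self) -> complex:
        return self.modulation_scale * np.exp(1j * self.phase_shift)

    def apply_point(self, point: PhasorPoint) -> PhasorPoint:
        if point.harmonic != self.harmonic:
            raise ValueError("harmonic mismatch between point and transform")
        z = point.z * self.factor
        return replace(point, g=float(z.real), s=float(z.imag))


def calibrate(
    measured_ref: PhasorPoint,
    reference_model: LifetimeMixture,
    harmonic: int,
    meta: AcquisitionMeta,
    correction: str = "phase_modulation",
) -> CalibrationTransform:
    """Build the calibration transform from a measured reference standard.

    The correction factor maps the measured reference phasor onto the
    theoretical phasor of the reference model (a known lifetime mixture,
    e.g. free NADH in buffer): ``factor = z_theory / z_measured``. With
    ``correction='phase'`` only the angular part is corrected.
    """
    if measured_ref.harmonic != harmonic:
        raise ValueError("measured reference harmonic mismatch")
    z_meas = measured_ref.z
    if abs(z_meas) == 0:
        raise ValueError("measured reference phasor has zero modulus")
    g_th, s_th = mixture_phasor(reference_model, meta.omega(harmonic))
    factor = complex(g_th, s_th) / z_meas
    scale = abs(factor)
    if correction == "phase":
        scale = 1.0
    elif correction != "phase_modulation":
        raise ValueError(f"unknown correction mode {correction!r}")
    return CalibrationTransform(
        phase_shift=float(np.angle(factor)),
        modulation_scale=float(scale),
        harmonic=int(harmonic),
    )


def apply_calibration(phasors: PhasorImage, transform: CalibrationTransform) -> PhasorImage:
    """Complex-multiply every valid pixel by the correction factor."""
    if phasors.harmonic != transform.harmonic:
        raise ValueError("harmonic mismatch between image and transform")
    z = (phasors.g + 1j * phasors.s) * transform.factor
    return PhasorImage(
        g=z.real, s=z.imag, valid=phasors.valid, harmonic=phasors.harmonic,
        calibrated=True,
    )


def aggregate_measurement(
    phasors: dict[int, PhasorImage],
    valid: PixelMask,
    delta_I: float,
    condition: str,
    animal_id: str = "",
    location_id: str = "",
) -> MeasurementPoint:
    """Reduce per-pixel phasors to one measurement row.

    Unweighted mean of g and s over valid pixels at each harmonic (the
    full-field-of-view average), with the intensity change and labels
    attached.
    """
    if valid.n_selected == 0:
        raise ValueError("no valid pixels to aggregate")
    means: dict[int, tuple[float, float]] = {}
    for k, img in phasors.items():
        m = valid.include & img.valid.include
        if not m.any():
            raise ValueError(f"no valid pixels at harmonic {k}")
        means[k] = (float(img.g[m].mean()), float(img.s[m].mean()))
    return MeasurementPoint(
        condition=condition,
        animal_id=animal_id,
        location_id=location_id,
        phasors=means,
        delta_intensity=float(delta_I),
        n_valid_pixels=valid.n_selected,
    )
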