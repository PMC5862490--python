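"""Bivariate dispersion and separability statistics for phasor clusters.

Two tools, both operating on per-measurement (g, s) points:

* **Standard deviational ellipses** summarize the 2-D dispersion of a
  condition's cluster: the ellipse is centered at the bivariate mean, its
  axes are the rotated directions that extremize the standard deviation of
  projected deviations, and the semi-axis lengths are those extremal standard
  deviations. This is computed as the eigen-decomposition of the deviation
  covariance with 1/(n-1) normalization — equivalent to the classical
  rotation criterion ``tan 2θ`` formula, up to the stated normalization.
* **Two-sample Hotelling T²** tests whether a condition's mean (g, s) differs
  from the baseline cluster, with the pooled-covariance statistic converted
  to an F variate: ``F = T² (n_a + n_b - p - 1) / ((n_a + n_b - 2) p)`` with
  ``p = 2`` and degrees of freedom ``(p, n_a + n_b - p - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .flim_data import MeasurementPoint

__all__ = [
    "Ellipse",
    "HotellingResult",
    "std_dev_ellipse",
    "hotelling_t2",
    "separability_report",
]


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # radians, major axis vs. g-axis, in (-pi/2, pi/2]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor >= 0:
            raise ValueError("require semi_major >= semi_minor >= 0")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def boundary(self, n_points: int = 100) -> np.ndarray:
        """(n, 2) polyline of the ellipse boundary, for plotting."""
        t = np.linspace(0, 2 * np.pi, n_points)
        xy = np.column_stack([self.semi_major * np.cos(t), self.semi_minor * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + np.asarray(self.center)


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float

    def __post_init__(self) -> None:
        if self.t2 < 0:
            raise ValueError("T2 must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def std_dev_ellipse(points) -> Ellipse:
    """Standard deviational ellipse of a 2-D point set.

    Requires at least 3 points. An all-identical cloud yields a zero-axes
    ellipse flagged ``degenerate``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for an ellipse")
    center = pts.mean(axis=0)
    dev = pts - center
    if np.allclose(dev, 0.0):
        return Ellipse(tuple(center), 0.0, 0.0, 0.0, degenerate=True)
    cov = dev.T @ dev / (n - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    semi_minor, semi_major = np.sqrt(np.clip(evals, 0.0, None))
    major_vec = evecs[:, 1]
    angle = float(np.arctan2(major_vec[1], major_vec[0]))
    # fold to (-pi/2, pi/2] (axis orientation, not direction)
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return Ellipse(
        (float(center[0]), float(center[1])),
        float(semi_major),
        float(semi_minor),
        angle,
        degenerate=bool(np.isclose(semi_major, 0.0)),
    )


def hotelling_t2(group_a, group_b, allow_singular: bool = False) -> HotellingResult:
    """Two-sample Hotelling T² with pooled covariance, p-value from F.

    A singular pooled covariance raises unless ``allow_singular`` enables a
    pseudo-inverse fallback.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be (n, p) arrays with equal p")
    n_a, n_b = a.shape[0], b.shape[0]
    p = a.shape[1]
    if n_a < 3 or n_b < 3:
        raise ValueError("need at least 3 observations per group")
    if n_a + n_b - p - 1 <= 0:
        raise ValueError("too few observations for the F conversion")
    diff = a.mean(axis=0) - b.mean(axis=0)
    s_a = np.cov(a, rowvar=False)
    s_b = np.cov(b, rowvar=False)
    pooled = ((n_a - 1) * s_a + (n_b - 1) * s_b) / (n_a + n_b - 2)
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        if not allow_singular:
            raise ValueError(
                "singular pooled covariance; pass allow_singular=True for a "
                "pseudo-inverse fallback"
            ) from None
        sol = np.linalg.pinv(pooled) @ diff
    t2 = float(n_a * n_b / (n_a + n_b) * diff @ sol)
    t2 = max(t2, 0.0)
    df1, df2 = p, n_a + n_b - p - 1
    f_stat = t2 * df2 / ((n_a + n_b - 2) * p)
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return HotellingResult(t2=t2, f_stat=float(f_stat), df=(df1, df2), p_value=p_value)


def separability_report(
    measurements: list[MeasurementPoint],
    baseline_label: str = "baseline",
    harmonics: tuple[int, ...] = (1, 2),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per condition x harmonic: Hotelling T² vs. baseline plus ellipse shape.

    Returns a DataFrame with one row per (non-baseline condition, harmonic):
    T², F, p-value, a significance flag at ``alpha``, and the condition
    cluster's standard-deviational-ellipse parameters. No multiple-testing
    correction is applied across conditions.
    """
    by_cond: dict[str, list[MeasurementPoint]] = {}
    for m in measurements:
        by_cond.setdefault(m.condition, []).append(m)
    if baseline_label not in by_cond:
        raise ValueError(f"baseline group {baseline_label!r} missing")
    rows = []
    for cond in sorted(c for c in by_cond if c != baseline_label):
        if len(by_cond[cond]) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 measurements")
        for k in harmonics:
            pts = np.array([m.phasors[k] for m in by_cond[cond]])
            base = np.array([m.phasors[k] for m in by_cond[baseline_label]])
            res = hotelling_t2(pts, base)
            ell = std_dev_ellipse(pts)
            rows.append(
                {
                    "condition": cond,
                    "harmonic": k,
                    "n": len(pts),
                    "t2": res.t2,
                    "f_stat": res.f_stat,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                    "ellipse_g": ell.center[0],
                    "ellipse_s": ell.center[1],
                    "ellipse_semi_major": ell.semi_major,
                    "ellipse_semi_minor": ell.semi_minor,
                    "ellipse_angle": ell.angle,
                }
            )
    return pd.DataFrame(rows)
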