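"""Core data model and file I/O for TCSPC FLIM stacks and measurement tables.

A TCSPC acquisition is an H x W x T stack of photon counts: each pixel holds a
histogram of photon arrival times relative to the excitation pulse, resolved
into ``n_bins`` bins spanning one laser repetition period. Stacks are stored
as multi-page grayscale TIFF (one page per time bin) with a JSON sidecar
carrying the acquisition metadata; per-measurement feature rows go to CSV.

Conventions fixed here and relied on everywhere else:

* time bin ``i`` spans ``[i*dt, (i+1)*dt)`` with ``dt = window/n_bins``; its
  representative time is the bin center ``(i + 0.5)*dt`` (symmetric
  discretization error for the Fourier sums);
* images are row-major, 0-based, pixel ``(0, 0)`` top-left;
* the angular frequency of harmonic ``k`` is always derived as
  ``omega = k * 2*pi * rep_rate`` and never stored.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionMeta",
    "TCSPCImage",
    "PixelMask",
    "DecayHistogram",
    "PhasorPoint",
    "MeasurementPoint",
    "read_tcspc_stack",
    "write_tcspc_stack",
    "read_mask",
    "write_mask",
    "read_measurement_table",
    "write_measurement_table",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry of a TCSPC measurement.

    Parameters
    ----------
    rep_rate : float
        Laser repetition frequency in Hz (default 80 MHz).
    n_bins : int
        Number of time bins per decay (default 256).
    window_ns : float
        Length of the recorded decay window in ns (default 12.5 ns, one
        repetition period at 80 MHz).
    harmonic_default : int
        Harmonic index used when none is given explicitly.
    """

    rep_rate: float = 80e6
    n_bins: int = 256
    window_ns: float = 12.5
    harmonic_default: int = 1

    def __post_init__(self) -> None:
        if not self.rep_rate > 0:
            raise ValueError(f"rep_rate must be positive, got {self.rep_rate}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if not self.window_ns > 0:
            raise ValueError(f"window_ns must be positive, got {self.window_ns}")
        if self.harmonic_default < 1:
            raise ValueError("harmonic_default must be >= 1")

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    @property
    def period_ns(self) -> float:
        """Excitation period in ns (1/rep_rate)."""
        return 1e9 / self.rep_rate

    def bin_centers_ns(self) -> np.ndarray:
        dt = self.bin_width_ns
        return (np.arange(self.n_bins) + 0.5) * dt

    def omega(self, harmonic: int | None = None) -> float:
        """Angular frequency ``k * 2*pi * rep_rate`` in rad/ns."""
        k = self.harmonic_default if harmonic is None else int(harmonic)
        if k < 1:
            raise ValueError(f"harmonic must be >= 1, got {k}")
        return k * 2.0 * np.pi * self.rep_rate * 1e-9

    def to_dict(self) -> dict:
        return {
            "rep_rate": self.rep_rate,
            "n_bins": self.n_bins,
            "window_ns": self.window_ns,
            "harmonic_default": self.harmonic_default,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionMeta":
        return cls(
            rep_rate=float(d["rep_rate"]),
            n_bins=int(d["n_bins"]),
            window_ns=float(d["window_ns"]),
            harmonic_default=int(d.get("harmonic_default", 1)),
        )


def _validate_counts(counts: np.ndarray, n_bins: int, ndim: int) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D count array, got shape {counts.shape}")
    if counts.shape[-1] != n_bins:
        raise ValueError(
            f"time axis has {counts.shape[-1]} bins but metadata says {n_bins}"
        )
    if np.issubdtype(counts.dtype, np.floating):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("photon counts must be integers")
        counts = np.round(counts).astype(np.int64)
    elif not np.issubdtype(counts.dtype, np.integer):
        raise ValueError(f"photon counts must be integer-typed, got {counts.dtype}")
    if counts.min(initial=0) < 0:
        raise ValueError("photon counts must be nonnegative")
    return counts.astype(np.int64, copy=False)


@dataclass
class TCSPCImage:
    """H x W x T photon-count stack plus acquisition metadata."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts, self.meta.n_bins, ndim=3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    def total_photons(self) -> int:
        return int(self.counts.sum())

    def pixel_totals(self) -> np.ndarray:
        """H x W map of per-pixel photon totals."""
        return self.counts.sum(axis=2)

    def decay_at(self, row: int, col: int) -> "DecayHistogram":
        return DecayHistogram(self.counts[row, col].copy(), self.meta)


@dataclass
class PixelMask:
    """Boolean pixel selection; ``include[i, j]`` is True for selected pixels."""

    include: np.ndarray
    label: str = "valid"

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 2:
            raise ValueError("mask must be 2-D")

    def check_shape(self, image: TCSPCImage) -> None:
        if self.include.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {self.include.shape} does not match image "
                f"{image.shape[:2]}"
            )

    @property
    def n_selected(self) -> int:
        return int(self.include.sum())


@dataclass
class DecayHistogram:
    """Single decay histogram (one pixel, a binned region, or a standard)."""

    counts: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("decay histogram must be 1-D")
        if counts.shape[0] != self.meta.n_bins:
            raise ValueError(
                f"histogram has {counts.shape[0]} bins, metadata says "
                f"{self.meta.n_bins}"
            )
        if counts.min(initial=0.0) < 0:
            raise ValueError("histogram entries must be nonnegative")
        self.counts = counts

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PhasorPoint:
    """Calibration-frame phasor coordinates at a stated harmonic.

    For any nonnegative histogram the modulus ``sqrt(g**2 + s**2)`` is bounded
    by 1 (triangle inequality of the normalized Fourier sum); a small tolerance
    covers floating-point roundoff.
    """

    g: float
    s: float
    harmonic: int
    photons: float = 0.0

    MODULUS_TOL = 1e-9

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)


@dataclass
class MeasurementPoint:
    """One imaging session reduced to its per-measurement features.

    ``phasors`` maps harmonic index to the pixel-averaged ``(g, s)`` pair;
    ``delta_intensity`` is the relative intensity change versus baseline
    (dimensionless, >= -1).
    """

    condition: str
    animal_id: str
    location_id: str
    phasors: dict[int, tuple[float, float]]
    delta_intensity: float
    n_valid_pixels: int = 0

    def __post_init__(self) -> None:
        if 1 not in self.phasors:
            raise ValueError("phasors must contain at least harmonic 1")
        if self.delta_intensity < -1:
            raise ValueError("delta_intensity cannot be below -1")

    def features(self, harmonic: int) -> tuple[float, float, float]:
        """(g, s, delta_I) feature triple at a harmonic."""
        if harmonic not in self.phasors:
            raise KeyError(f"measurement has no phasor at harmonic {harmonic}")
        g, s = self.phasors[harmonic]
        return g, s, self.delta_intensity


# ---------------------------------------------------------------------------
# stack / mask I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_tcspc_stack(image: TCSPCImage, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (one page per time bin) + JSON sidecar."""
    path = Path(path)
    planes = np.moveaxis(image.counts, 2, 0)  # T x H x W pages
    tifffile.imwrite(path, planes.astype(np.uint32), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(image.meta.to_dict(), indent=1))
    return path


def read_tcspc_stack(path: str | Path, meta: AcquisitionMeta | None = None) -> TCSPCImage:
    """Read a multi-page TIFF stack; metadata from the sidecar unless given.

    Raises on a missing file, a bin-count mismatch with ``meta``, or negative
    or non-integer counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if meta is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"no metadata sidecar at {sidecar}")
        meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    counts = np.moveaxis(planes, 0, 2)
    if counts.shape[2] != meta.n_bins:
        raise ValueError(
            f"stack has {counts.shape[2]} pages but metadata says {meta.n_bins} bins"
        )
    return TCSPCImage(counts, meta)


def write_mask(mask: PixelMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.include.astype(np.uint8), photometric="minisblack")
    return path


def read_mask(path: str | Path, label: str = "valid") -> PixelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return PixelMask(tifffile.imread(path) > 0, label=label)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

_PHASOR_COL = re.compile(r"^([gs])(\d+)$")


def write_measurement_table(rows: list[MeasurementPoint], path: str | Path) -> Path:
    """Write measurements as CSV with columns
    ``condition,animal_id,location_id,n_valid_pixels,delta_I,g1,s1[,g2,s2,...]``.

    All rows must carry the same harmonic set.
    """
    if not rows:
        raise ValueError("cannot write an empty measurement table")
    harmonics = sorted(rows[0].phasors)
    for r in rows:
        if sorted(r.phasors) != harmonics:
            raise ValueError("rows have inconsistent harmonic sets")
    records = []
    for r in rows:
        rec: dict = {
            "condition": r.condition,
            "animal_id": r.animal_id,
            "location_id": r.location_id,
            "n_valid_pixels": r.n_valid_pixels,
            "delta_I": r.delta_intensity,
        }
        for k in harmonics:
            rec[f"g{k}"], rec[f"s{k}"] = r.phasors[k]
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_measurement_table(path: str | Path) -> list[MeasurementPoint]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"animal_id": str, "location_id": str})
    harmonics = sorted(
        int(m.group(2)) for c in df.columns if (m := _PHASOR_COL.match(c)) and m.group(1) == "g"
    )
    rows = []
    for _, rec in df.iterrows():
        phasors = {k: (float(rec[f"g{k}"]), float(rec[f"s{k}"])) for k in harmonics}
        rows.append(
            MeasurementPoint(
                condition=str(rec["condition"]),
                animal_id=str(rec["animal_id"]),
                location_id=str(rec["location_id"]),
                phasors=phasors,
                delta_intensity=float(rec["delta_I"]),
                n_valid_pixels=int(rec["n_valid_pixels"]),
            )
        )
    return rows
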