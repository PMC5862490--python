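"""Preprocessing chain for TCSPC stacks.

Fixed order, applied before any phasor computation:

1. 3x3 median filter on each time-bin plane;
2. vessel masking (excluded pixels carry no downstream statistics);
3. 3x3 sliding-window decay binning (each pixel's histogram becomes the sum
   over its neighborhood; image dimensions preserved, borders replicated);
4. photon-count validity floor: binned pixels below ``min_photons`` total
   (default 5000) are flagged invalid and excluded downstream.

Binning is neighborhood aggregation per pixel, not block downsampling, so it
conserves nothing globally — its contract is exact agreement with the
brute-force per-pixel neighborhood sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .flim_data import PixelMask, TCSPCImage

__all__ = [
    "median_filter_stack",
    "apply_mask",
    "bin_decays",
    "delta_intensity",
    "PreprocessResult",
    "preprocess_pair",
]


def median_filter_stack(image: TCSPCImage, kernel: int = 3) -> TCSPCImage:
    """Median-filter every time-bin plane independently (border replication)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return TCSPCImage(image.counts.copy(), image.meta)
    filtered = ndimage.median_filter(
        image.counts, size=(kernel, kernel, 1), mode="nearest"
    )
    return TCSPCImage(filtered, image.meta)


def apply_mask(image: TCSPCImage, vessel_mask: PixelMask) -> tuple[TCSPCImage, PixelMask]:
    """Exclude vessel pixels; returns the image untouched plus the valid mask."""
    vessel_mask.check_shape(image)
    valid = PixelMask(~vessel_mask.include, label="valid")
    if valid.n_selected == 0:
        raise ValueError("vessel mask excludes every pixel")
    return image, valid


def bin_decays(
    image: TCSPCImage,
    window: int = 3,
    min_photons: int = 5000,
    valid: PixelMask | None = None,
) -> tuple[TCSPCImage, PixelMask]:
    """Sum each pixel's decay over its ``window x window`` neighborhood.

    Sliding window with border replication; dimensions preserved. Pixels whose
    binned total falls below ``min_photons`` are flagged invalid (intersected
    with any incoming valid mask).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    kernel = np.ones((window, window, 1), dtype=np.int64)
    binned = ndimage.correlate(image.counts, kernel, mode="nearest")
    out = TCSPCImage(binned, image.meta)
    keep = out.pixel_totals() >= min_photons
    if valid is not None:
        valid.check_shape(image)
        keep &= valid.include
    return out, PixelMask(keep, label="valid")


def delta_intensity(
    baseline: TCSPCImage, treated: TCSPCImage, valid: PixelMask
) -> float:
    """Relative intensity change over valid pixels:
    ``(sum treated - sum baseline) / sum baseline``."""
    valid.check_shape(baseline)
    if baseline.shape != treated.shape:
        raise ValueError("baseline and treated stacks must share geometry")
    base_total = float(baseline.counts[valid.include].sum())
    if base_total == 0:
        raise ValueError("baseline has zero photons over valid pixels")
    treat_total = float(treated.counts[valid.include].sum())
    return (treat_total - base_total) / base_total


@dataclass
class PreprocessResult:
    baseline: TCSPCImage
    treated: TCSPCImage
    valid: PixelMask
    delta_I: float
    log: list[str] = field(default_factory=list)


def preprocess_pair(
    baseline: TCSPCImage,
    treated: TCSPCImage,
    vessel_mask: PixelMask,
    median_kernel: int = 3,
    bin_window: int = 3,
    min_photons: int = 5000,
) -> PreprocessResult:
    """Run the full chain on a paired acquisition with a shared valid mask.

    The valid mask is the intersection of both acquisitions' photon floors, so
    the same pixel set enters the phasor average and the intensity ratio.
    """
    log: list[str] = []
    b = median_filter_stack(baseline, median_kernel)
    t = median_filter_stack(treated, median_kernel)
    log.append(f"median_filter kernel={median_kernel}")
    b, valid = apply_mask(b, vessel_mask)
    t, _ = apply_mask(t, vessel_mask)
    log.append(f"vessel_mask excluded={vessel_mask.n_selected} px")
    b, valid_b = bin_decays(b, bin_window, min_photons, valid)
    t, valid_t = bin_decays(t, bin_window, min_photons, valid)
    valid = PixelMask(valid_b.include & valid_t.include, label="valid")
    if valid.n_selected == 0:
        raise ValueError("no pixels survive the photon floor")
    log.append(
        f"bin window={bin_window} floor={min_photons} -> {valid.n_selected} valid px"
    )
    dI = delta_intensity(b, t, valid)
    log.append(f"delta_I={dI:.6f}")
    return PreprocessResult(b, t, valid, dI, log)
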