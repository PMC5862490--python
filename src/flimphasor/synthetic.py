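"""Synthetic TCSPC study generator.

Emulates paired baseline/treated NADH FLIM acquisitions so the full analysis
chain (preprocessing, phasor computation, separability statistics,
classification) can be exercised and validated without access to in vivo
measurements.

Forward model
-------------
Each pixel's decay is a multi-exponential mixture. Component ``i`` has
lifetime ``tau_i`` and *fractional fluorescence* ``f_i`` — the share of total
emitted intensity it contributes (these are the weights of the phasor
vectorial sum, not pre-exponential amplitudes). Under pulsed excitation at
80 MHz the tail of each decay wraps into subsequent periods, so the
noise-free histogram is the periodic summation of the decay, convolved with a
Gaussian instrument response (configurable FWHM and offset), integrated over
each time bin. All of this has a closed form via the exponentially-modified
Gaussian: with ``x = t - mu``,

    h(t)   = (1/2) exp(sigma^2/(2 tau^2) - x/tau) erfc(sigma/(sqrt2 tau) - x/(sqrt2 sigma))
    H(t)   = tau [Phi(x/sigma) - h(t)]

where ``H`` is the antiderivative of the convolved single decay; bin masses
are differences of ``H`` summed over wrap-around periods. Photon noise is
Poisson per bin; early-bin TAC truncation zeroes the first few bins of the
*expected* histogram (those photons are lost, not redistributed).

The numeric preset mixtures shipped here are package configuration chosen to
reproduce the qualitative structure of pharmacological NADH studies (free
vs. enzyme-bound lifetime pools, intensity responses); they are not fitted
values from any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.special import erfcx, ndtr

from .flim_data import AcquisitionMeta, DecayHistogram, PixelMask, TCSPCImage

__all__ = [
    "LifetimeMixture",
    "GaussianIRF",
    "RegionSpec",
    "RegionOverride",
    "SceneSpec",
    "ConditionPreset",
    "DEFAULT_PRESETS",
    "FREE_NADH_REFERENCE",
    "expected_bin_masses",
    "generate_decay",
    "apply_tac_truncation",
    "preset_scene_spec",
    "generate_scene",
    "make_study",
    "StudyEntry",
]

_SQRT2 = np.sqrt(2.0)
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LifetimeMixture:
    """Multi-exponential decay model: lifetimes (ns) with fractional
    fluorescence weights summing to 1."""

    lifetimes_ns: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.lifetimes_ns)
        fracs = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "lifetimes_ns", taus)
        object.__setattr__(self, "fractions", fracs)
        if len(taus) != len(fracs):
            raise ValueError("lifetimes and fractions must have equal length")
        if len(taus) == 0:
            raise ValueError("mixture needs at least one component")
        if any(t <= 0 for t in taus):
            raise ValueError("all lifetimes must be positive")
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)}")

    def reweighted(self, factors: Iterable[float]) -> "LifetimeMixture":
        """Multiply fractions element-wise and renormalize (keeps the simplex)."""
        w = np.asarray(self.fractions) * np.asarray(list(factors), dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("reweighting factors must keep fractions valid")
        return LifetimeMixture(self.lifetimes_ns, tuple(w / w.sum()))

    def fraction_below(self, tau_cut_ns: float) -> float:
        """Summed fractional fluorescence of components with tau < tau_cut
        (the 'free pool' share for a free/bound cut)."""
        return float(
            sum(f for t, f in zip(self.lifetimes_ns, self.fractions) if t < tau_cut_ns)
        )


@dataclass(frozen=True)
class GaussianIRF:
    """Gaussian instrument response: FWHM and temporal offset, both in ns."""

    fwhm_ns: float = 0.2
    offset_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_ns < 0:
            raise ValueError("IRF FWHM must be nonnegative")

    @property
    def sigma_ns(self) -> float:
        return self.fwhm_ns * _FWHM_TO_SIGMA


def _exgauss_cum(t: np.ndarray, tau: float, mu: float, sigma: float) -> np.ndarray:
    """Antiderivative of exp(-(t-mu)/tau)*step(t-mu) convolved with N(0, sigma^2).

    Evaluates tau*(Phi(x/sigma) - h(t)) with the erfcx-stabilized exGaussian;
    for sigma == 0 it reduces to the sharp-onset exponential.
    """
    t = np.asarray(t, dtype=float)
    x = t - mu
    if sigma == 0.0:
        out = np.where(x > 0, tau * (1.0 - np.exp(-np.clip(x, 0, None) / tau)), 0.0)
        return out
    z = sigma / (_SQRT2 * tau) - x / (_SQRT2 * sigma)
    gauss = np.exp(-(x * x) / (2.0 * sigma * sigma))
    # erfcx overflows for large negative z; split on the sign of z.
    h = np.empty_like(x)
    pos = z >= 0
    h[pos] = 0.5 * erfcx(z[pos]) * gauss[pos]
    if np.any(~pos):
        zn = z[~pos]
        a = sigma * sigma / (2.0 * tau * tau) - x[~pos] / tau
        h[~pos] = 0.5 * np.exp(a) * (2.0 - erfcx(-zn) * np.exp(-zn * zn))
    return tau * (ndtr(x / sigma) - h)


def expected_bin_masses(
    mixture: LifetimeMixture,
    meta: AcquisitionMeta,
    irf: GaussianIRF | None = None,
) -> np.ndarray:
    """Noise-free per-bin probability masses of the folded, IRF-convolved mixture.

    The acquisition window is treated as one excitation period; decay tails
    from previous pulses are folded back in (the periodic summation is carried
    until its terms fall below double precision). The result sums to 1 up to
    roundoff: it is the distribution of a detected photon's arrival bin.
    """
    mu = irf.offset_ns if irf is not None else 0.0
    sigma = irf.sigma_ns if irf is not None else 0.0
    period = meta.window_ns
    edges = np.linspace(0.0, period, meta.n_bins + 1)
    masses = np.zeros(meta.n_bins)
    for tau, frac in zip(mixture.lifetimes_ns, mixture.fractions):
        if frac == 0.0:
            continue
        n_wraps = int(np.ceil((mu + 45.0 * tau + 10.0 * sigma) / period)) + 1
        shifts = np.arange(-1, n_wraps + 1) * period
        cum = _exgauss_cum(edges[None, :] + shifts[:, None], tau, mu, sigma)
        masses += frac * np.diff(cum, axis=1).sum(axis=0) / tau
    return np.clip(masses, 0.0, None)


def generate_decay(
    mixture: LifetimeMixture,
    n_photons: float,
    meta: AcquisitionMeta,
    irf: GaussianIRF | None = None,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
) -> DecayHistogram:
    """Simulate one decay histogram.

    ``mode='expected'`` returns the noise-free expectation (total exactly
    ``n_photons``); ``mode='sampled'`` draws independent Poisson counts per
    bin with that expectation.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be nonnegative")
    expected = n_photons * expected_bin_masses(mixture, meta, irf)
    if mode == "expected":
        return DecayHistogram(expected, meta)
    if mode == "sampled":
        if rng is None:
            raise ValueError("sampled mode requires an rng")
        return DecayHistogram(rng.poisson(expected).astype(float), meta)
    raise ValueError(f"unknown mode {mode!r}")


def apply_tac_truncation(decay: DecayHistogram, n_trunc: int) -> DecayHistogram:
    """Zero the first ``n_trunc`` bins (TAC early-nonlinearity blanking)."""
    if not 0 <= n_trunc < decay.meta.n_bins:
        raise ValueError(
            f"n_trunc must be in [0, {decay.meta.n_bins}), got {n_trunc}"
        )
    counts = decay.counts.copy()
    counts[:n_trunc] = 0.0
    return DecayHistogram(counts, decay.meta)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


@dataclass
class RegionSpec:
    """One homogeneous tissue region of a scene."""

    pixels: np.ndarray  # boolean H x W membership
    mixture: LifetimeMixture
    brightness: float  # expected photons per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.brightness <= 0:
            raise ValueError("region brightness must be positive")


@dataclass(frozen=True)
class RegionOverride:
    """Per-region replacements applied to the treated acquisition."""

    mixture: LifetimeMixture | None = None
    brightness: float | None = None


@dataclass
class SceneSpec:
    """Full description of one paired baseline/treated acquisition."""

    height: int
    width: int
    regions: dict[str, RegionSpec]
    vessel_mask: PixelMask
    irf: GaussianIRF | None = None
    tac_truncated_bins: int = 0
    photon_budget_scale: float = 1.0
    treated_overrides: dict[str, RegionOverride] = field(default_factory=dict)
    seed: int = 0
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        shape = (self.height, self.width)
        if self.vessel_mask.include.shape != shape:
            raise ValueError("vessel mask shape does not match scene geometry")
        if self.tac_truncated_bins >= self.meta.n_bins / 4:
            raise ValueError("tac_truncated_bins must be < n_bins/4")
        if self.photon_budget_scale <= 0:
            raise ValueError("photon_budget_scale must be positive")
        cover = np.zeros(shape, dtype=int)
        for name, region in self.regions.items():
            if region.pixels.shape != shape:
                raise ValueError(f"region {name!r} shape mismatch")
            cover += region.pixels
        non_vessel = ~self.vessel_mask.include
        if not np.array_equal(cover, non_vessel.astype(int)):
            raise ValueError("regions must partition the non-vessel field")
        for name in self.treated_overrides:
            if name not in self.regions:
                raise ValueError(f"override for unknown region {name!r}")


def _render_stack(
    spec: SceneSpec,
    regions: Mapping[str, RegionSpec],
    rng: np.random.Generator,
) -> TCSPCImage:
    counts = np.zeros((spec.height, spec.width, spec.meta.n_bins), dtype=np.int64)
    for region in regions.values():
        profile = expected_bin_masses(region.mixture, spec.meta, spec.irf)
        profile = profile.copy()
        profile[: spec.tac_truncated_bins] = 0.0  # truncated photons are lost
        expected = region.brightness * spec.photon_budget_scale * profile
        n_px = int(region.pixels.sum())
        if n_px:
            counts[region.pixels] = rng.poisson(expected, size=(n_px, spec.meta.n_bins))
    return TCSPCImage(counts, spec.meta)


def generate_scene(
    spec: SceneSpec,
) -> tuple[TCSPCImage, TCSPCImage, list[PixelMask], dict]:
    """Render the paired stacks of a scene.

    Returns ``(baseline, treated, masks, truth)`` where ``masks`` holds the
    vessel mask and ``truth`` records the per-region ground-truth mixtures and
    brightness of both acquisitions (for recovery tests). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    treated_regions: dict[str, RegionSpec] = {}
    for name, region in spec.regions.items():
        ov = spec.treated_overrides.get(name, RegionOverride())
        treated_regions[name] = RegionSpec(
            pixels=region.pixels,
            mixture=ov.mixture if ov.mixture is not None else region.mixture,
            brightness=ov.brightness if ov.brightness is not None else region.brightness,
        )
    baseline = _render_stack(spec, spec.regions, rng)
    treated = _render_stack(spec, treated_regions, rng)
    truth = {
        name: {
            "baseline_mixture": spec.regions[name].mixture,
            "baseline_brightness": spec.regions[name].brightness,
            "treated_mixture": treated_regions[name].mixture,
            "treated_brightness": treated_regions[name].brightness,
        }
        for name in spec.regions
    }
    return baseline, treated, [spec.vessel_mask], truth


# ---------------------------------------------------------------------------
# condition presets and the paired study
# ---------------------------------------------------------------------------

# Shared lifetime grid: two short "free NADH" components and two long
# "enzyme-bound" components. Package configuration, not fitted values.
_TAUS = (0.3, 0.8, 2.0, 4.0)
_FREE_CUT_NS = 1.0  # components below this count as the free pool


@dataclass(frozen=True)
class ConditionPreset:
    """Qualitative emulation of one pharmacological condition.

    ``intensity_ratio`` is treated/baseline brightness; the mixture is the
    treated acquisition's decay model (the paired baseline acquisition always
    uses the baseline preset's mixture).
    """

    name: str
    mixture: LifetimeMixture
    intensity_ratio: float = 1.0

    @property
    def free_fraction(self) -> float:
        return self.mixture.fraction_below(_FREE_CUT_NS)


_BASELINE_MIX = LifetimeMixture(_TAUS, (0.12, 0.18, 0.45, 0.25))

DEFAULT_PRESETS: dict[str, ConditionPreset] = {
    "baseline": ConditionPreset("baseline", _BASELINE_MIX, 1.0),
    # glycolysis inhibition leaves the phasor indistinguishable from baseline:
    # a deliberately sub-dispersion perturbation of the free pool (+0.0005,
    # far below the between-replicate scatter)
    "glycolysis_inhibition": ConditionPreset(
        "glycolysis_inhibition",
        LifetimeMixture(_TAUS, (0.1202, 0.1803, 0.44968, 0.24982)),
        1.0,
    ),
    # mitochondrial manipulations shift toward the free-NADH side of the plot
    "tca_inhibition": ConditionPreset(
        "tca_inhibition", LifetimeMixture(_TAUS, (0.16, 0.24, 0.38, 0.22)), 1.15
    ),
    "etc_inhibition": ConditionPreset(
        "etc_inhibition", LifetimeMixture(_TAUS, (0.20, 0.30, 0.32, 0.18)), 1.45
    ),
    "oxphos_uncoupling": ConditionPreset(
        "oxphos_uncoupling", LifetimeMixture(_TAUS, (0.15, 0.22, 0.40, 0.23)), 0.75
    ),
    # seizure-like activity mimics an electron-transport-chain block
    "seizure_like": ConditionPreset(
        "seizure_like", LifetimeMixture(_TAUS, (0.19, 0.29, 0.33, 0.19)), 1.35
    ),
}

# effective single-lifetime model of the free-NADH solution standard used for
# phasor calibration (literature-informed default; configurable)
FREE_NADH_REFERENCE = LifetimeMixture((0.4,), (1.0,))

_preset_invariant = DEFAULT_PRESETS["etc_inhibition"]
assert _preset_invariant.free_fraction > DEFAULT_PRESETS["baseline"].free_fraction
assert _preset_invariant.intensity_ratio > 1.0

DEFAULT_IRF = GaussianIRF(fwhm_ns=0.2, offset_ns=0.5)
DEFAULT_BRIGHTNESS = 1200.0  # expected photons/pixel; 3x3 binning clears 5000
DEFAULT_TRUNCATED_BINS = 5


def _default_vessel_mask(height: int, width: int) -> PixelMask:
    """A vertical vessel stripe covering ~1/8 of the field."""
    include = np.zeros((height, width), dtype=bool)
    stripe = max(1, width // 8)
    start = width // 2 - stripe // 2
    include[:, start : start + stripe] = True
    return PixelMask(include, label="vessel")


def preset_scene_spec(
    preset: ConditionPreset,
    height: int = 24,
    width: int = 24,
    brightness: float = DEFAULT_BRIGHTNESS,
    baseline_mixture: LifetimeMixture = _BASELINE_MIX,
    irf: GaussianIRF | None = DEFAULT_IRF,
    tac_truncated_bins: int = DEFAULT_TRUNCATED_BINS,
    seed: int = 0,
    meta: AcquisitionMeta | None = None,
    vessel_mask: PixelMask | None = None,
) -> SceneSpec:
    """Single-region paired scene: baseline mixture before, preset after."""
    meta = meta or AcquisitionMeta()
    vessel = vessel_mask or _default_vessel_mask(height, width)
    tissue = RegionSpec(~vessel.include, baseline_mixture, brightness)
    return SceneSpec(
        height=height,
        width=width,
        regions={"tissue": tissue},
        vessel_mask=vessel,
        irf=irf,
        tac_truncated_bins=tac_truncated_bins,
        treated_overrides={
            "tissue": RegionOverride(
                mixture=preset.mixture,
                brightness=brightness * preset.intensity_ratio,
            )
        },
        seed=seed,
        meta=meta,
    )


@dataclass
class StudyEntry:
    condition: str
    animal_id: str
    location_id: str
    spec: SceneSpec
    truth: dict


def make_study(
    presets: list[ConditionPreset],
    n_animals: int = 3,
    n_locations: int = 3,
    rng: np.random.Generator | None = None,
    dispersion: float = 0.05,
    height: int = 24,
    width: int = 24,
    brightness: float = DEFAULT_BRIGHTNESS,
    irf: GaussianIRF | None = DEFAULT_IRF,
    tac_truncated_bins: int = DEFAULT_TRUNCATED_BINS,
    meta: AcquisitionMeta | None = None,
) -> list[StudyEntry]:
    """Build a study design: per preset, ``n_animals x n_locations`` paired scenes.

    Biological replicate structure: every measurement location draws
    multiplicative log-normal perturbations (sd ``dispersion``) of the
    mixture fractions (renormalized), the overall brightness, and the treated
    intensity ratio; each animal contributes a smaller shared effect
    (0.1 x ``dispersion``). Location-level variation dominating the animal
    effect keeps the condition's replicates close to exchangeable, which the
    downstream pooled-covariance statistics assume. ``dispersion=0`` gives
    identical truth everywhere.
    """
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_animals < 1 or n_locations < 1:
        raise ValueError("need at least one animal and one location")
    rng = rng if rng is not None else np.random.default_rng(0)
    meta = meta or AcquisitionMeta()
    animal_sigma = 0.1 * dispersion
    loc_sigma = dispersion
    entries: list[StudyEntry] = []
    for preset in presets:
        base_mix = DEFAULT_PRESETS["baseline"].mixture
        for a in range(n_animals):
            n_comp = len(base_mix.fractions)
            animal_frac = np.exp(rng.normal(0.0, animal_sigma, size=n_comp))
            animal_bright = float(np.exp(rng.normal(0.0, animal_sigma)))
            for l in range(n_locations):
                loc_frac = np.exp(rng.normal(0.0, loc_sigma, size=n_comp))
                loc_bright = float(np.exp(rng.normal(0.0, loc_sigma)))
                ratio_jitter = float(np.exp(rng.normal(0.0, dispersion)))
                factors = animal_frac * loc_frac
                b = brightness * animal_bright * loc_bright
                scene_baseline_mix = base_mix.reweighted(factors)
                scene_treated_mix = preset.mixture.reweighted(factors)
                ratio = preset.intensity_ratio * ratio_jitter
                seed = int(rng.integers(0, 2**31 - 1))
                vessel = _default_vessel_mask(height, width)
                spec = SceneSpec(
                    height=height,
                    width=width,
                    regions={"tissue": RegionSpec(~vessel.include, scene_baseline_mix, b)},
                    vessel_mask=vessel,
                    irf=irf,
                    tac_truncated_bins=tac_truncated_bins,
                    treated_overrides={
                        "tissue": RegionOverride(
                            mixture=scene_treated_mix, brightness=b * ratio
                        )
                    },
                    seed=seed,
                    meta=meta,
                )
                truth = {
                    "baseline_mixture": scene_baseline_mix,
                    "treated_mixture": scene_treated_mix,
                    "brightness": b,
                    "intensity_ratio": ratio,
                    "treated_free_fraction": scene_treated_mix.fraction_below(_FREE_CUT_NS),
                }
                entries.append(
                    StudyEntry(preset.name, f"A{a + 1}", f"L{l + 1}", spec, truth)
                )
    return entries
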