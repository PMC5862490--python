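"""End-to-end orchestration: synthetic study -> preprocessing -> calibrated
phasors -> separability statistics -> classification.

A single JSON-serializable :class:`RunConfig` describes a whole run; the
output directory receives the measurement table (CSV), separability report
(CSV), phasor/ellipse plot (PNG + the plotted data as CSV), per-algorithm
cross-validation and held-out prediction reports (JSON), and a manifest
capturing every parameter and seed. Everything downstream of the seed is
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import ALGORITHMS, build_feature_table, kfold_cv_error, predict, train
from .flim_data import (
    AcquisitionMeta,
    DecayHistogram,
    MeasurementPoint,
    PhasorPoint,
    write_measurement_table,
    write_tcspc_stack,
)
from .phasor import (
    CalibrationTransform,
    aggregate_measurement,
    apply_calibration,
    calibrate,
    phasor_image,
    pixel_phasor,
)
from .preprocess import preprocess_pair
from .stats import separability_report
from .synthetic import (
    DEFAULT_BRIGHTNESS,
    DEFAULT_IRF,
    DEFAULT_PRESETS,
    DEFAULT_TRUNCATED_BINS,
    FREE_NADH_REFERENCE,
    GaussianIRF,
    LifetimeMixture,
    StudyEntry,
    apply_tac_truncation,
    generate_decay,
    generate_scene,
    make_study,
    preset_scene_spec,
)

logger = logging.getLogger("flimphasor")

__all__ = ["RunConfig", "RunResult", "run_full_analysis", "make_fixtures",
           "simulate_reference_standard", "measure_study"]

_STUDY_CONDITIONS = (
    "baseline",
    "glycolysis_inhibition",
    "tca_inhibition",
    "etc_inhibition",
    "oxphos_uncoupling",
)
_TEST_CONDITION = "seizure_like"


@dataclass
class RunConfig:
    """Parameters of one full synthetic-study analysis."""

    seed: int = 0
    n_animals: int = 3
    n_locations: int = 3
    dispersion: float = 0.05
    height: int = 24
    width: int = 24
    brightness: float = DEFAULT_BRIGHTNESS
    irf_fwhm_ns: float = DEFAULT_IRF.fwhm_ns
    irf_offset_ns: float = DEFAULT_IRF.offset_ns
    tac_truncated_bins: int = DEFAULT_TRUNCATED_BINS
    conditions: tuple[str, ...] = _STUDY_CONDITIONS
    test_condition: str = _TEST_CONDITION
    harmonics: tuple[int, ...] = (1, 2)
    median_kernel: int = 3
    bin_window: int = 3
    min_photons: int = 5000
    alpha: float = 0.05
    algorithms: tuple[str, ...] = ALGORITHMS
    kfolds: int = 5
    knn_k: int = 3
    reference_photons: float = 1e6
    calibration_correction: str = "phase_modulation"

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("conditions", "harmonics", "algorithms"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("conditions", "harmonics", "algorithms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def irf(self) -> GaussianIRF:
        return GaussianIRF(self.irf_fwhm_ns, self.irf_offset_ns)


@dataclass
class RunResult:
    measurements: list[MeasurementPoint]
    test_measurements: list[MeasurementPoint]
    separability: "object"  # pandas DataFrame
    classification: dict
    calibrations: dict[int, CalibrationTransform]
    manifest: dict
    out_dir: Path | None = None


def simulate_reference_standard(
    config: RunConfig,
    meta: AcquisitionMeta,
    reference_model: LifetimeMixture = FREE_NADH_REFERENCE,
    rng: np.random.Generator | None = None,
) -> DecayHistogram:
    """Simulate the measured free-NADH solution standard.

    The standard passes through the same instrument as the tissue data: the
    reference mixture decay, convolved with the run's IRF, TAC-truncated, and
    Poisson-sampled at the configured photon budget.
    """
    mode = "sampled" if rng is not None else "expected"
    decay = generate_decay(
        reference_model, config.reference_photons, meta, config.irf, mode=mode, rng=rng
    )
    return apply_tac_truncation(decay, config.tac_truncated_bins)


def _calibrations_for(
    config: RunConfig,
    meta: AcquisitionMeta,
    reference_model: LifetimeMixture,
    rng: np.random.Generator,
) -> dict[int, CalibrationTransform]:
    ref = simulate_reference_standard(config, meta, reference_model, rng)
    out = {}
    for k in config.harmonics:
        measured = pixel_phasor(ref, k)
        out[k] = calibrate(
            measured, reference_model, k, meta, correction=config.calibration_correction
        )
    return out


def _measure_entry(
    entry: StudyEntry,
    config: RunConfig,
    calibrations: dict[int, CalibrationTransform],
) -> MeasurementPoint:
    baseline, treated, masks, _ = generate_scene(entry.spec)
    prep = preprocess_pair(
        baseline,
        treated,
        masks[0],
        median_kernel=config.median_kernel,
        bin_window=config.bin_window,
        min_photons=config.min_photons,
    )
    phasors = {}
    for k in config.harmonics:
        img = phasor_image(prep.treated, prep.valid, k)
        phasors[k] = apply_calibration(img, calibrations[k])
    return aggregate_measurement(
        phasors,
        prep.valid,
        prep.delta_I,
        condition=entry.condition,
        animal_id=entry.animal_id,
        location_id=entry.location_id,
    )


def measure_study(
    entries: list[StudyEntry],
    config: RunConfig,
    calibrations: dict[int, CalibrationTransform],
) -> list[MeasurementPoint]:
    """Run preprocessing + calibrated phasor aggregation on every study entry."""
    rows = []
    for entry in entries:
        rows.append(_measure_entry(entry, config, calibrations))
    logger.info("measured %d study entries", len(rows))
    return rows


def run_full_analysis(
    config: RunConfig,
    out_dir: str | Path | None = None,
    reference_model: LifetimeMixture = FREE_NADH_REFERENCE,
) -> RunResult:
    """Execute the whole synthetic-study pipeline deterministically.

    Stages: build the paired study design, simulate + calibrate against the
    reference standard, reduce every paired scene to a measurement row, test
    separability of every condition against baseline at every harmonic, and
    train/evaluate the three classifiers, predicting the held-out
    seizure-like group. Writes all artifacts if ``out_dir`` is given.
    """
    unknown = [c for c in config.conditions if c not in DEFAULT_PRESETS]
    if unknown:
        raise ValueError(f"unknown condition presets: {unknown}")
    if "baseline" not in config.conditions:
        raise ValueError("config must include the 'baseline' condition group")
    root_ss = np.random.SeedSequence(config.seed)
    ss_study, ss_ref, ss_test = root_ss.spawn(3)
    meta = AcquisitionMeta()

    presets = [DEFAULT_PRESETS[c] for c in config.conditions]
    entries = make_study(
        presets,
        n_animals=config.n_animals,
        n_locations=config.n_locations,
        rng=np.random.default_rng(ss_study),
        dispersion=config.dispersion,
        height=config.height,
        width=config.width,
        brightness=config.brightness,
        irf=config.irf,
        tac_truncated_bins=config.tac_truncated_bins,
        meta=meta,
    )
    test_entries = make_study(
        [DEFAULT_PRESETS[config.test_condition]],
        n_animals=config.n_animals,
        n_locations=config.n_locations,
        rng=np.random.default_rng(ss_test),
        dispersion=config.dispersion,
        height=config.height,
        width=config.width,
        brightness=config.brightness,
        irf=config.irf,
        tac_truncated_bins=config.tac_truncated_bins,
        meta=meta,
    )

    calibrations = _calibrations_for(
        config, meta, reference_model, np.random.default_rng(ss_ref)
    )
    measurements = measure_study(entries, config, calibrations)
    test_measurements = measure_study(test_entries, config, calibrations)

    report = separability_report(
        measurements, baseline_label="baseline",
        harmonics=tuple(config.harmonics), alpha=config.alpha,
    )

    classification: dict = {}
    for k in config.harmonics:
        table = build_feature_table(measurements, harmonic=k)
        per_algo = {}
        for algo in config.algorithms:
            hyper = {"n_neighbors": config.knn_k} if algo == "knn" else None
            err = kfold_cv_error(table, algo, hyper, K=config.kfolds, seed=config.seed)
            model = train(table, algo, hyper)
            labels, fractions = predict(model, test_measurements, harmonic=k)
            per_algo[algo] = {
                "cv_error": err,
                "cv_accuracy": 1.0 - err,
                "test_labels": labels,
                "test_class_fractions": fractions,
            }
        classification[f"harmonic_{k}"] = per_algo

    manifest = {
        "package": "flimphasor",
        "version": __version__,
        "config": config.to_dict(),
        "n_measurements": len(measurements),
        "n_test_measurements": len(test_measurements),
        "calibration": {
            str(k): {"phase_shift": t.phase_shift, "modulation_scale": t.modulation_scale}
            for k, t in calibrations.items()
        },
    }

    result = RunResult(
        measurements=measurements,
        test_measurements=test_measurements,
        separability=report,
        classification=classification,
        calibrations=calibrations,
        manifest=manifest,
    )
    if out_dir is not None:
        result.out_dir = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: RunResult, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_measurement_table(
        result.measurements + result.test_measurements,
        out_dir / "measurements.csv",
    )
    result.separability.to_csv(out_dir / "separability.csv", index=False)
    (out_dir / "classification.json").write_text(
        json.dumps(result.classification, indent=1, sort_keys=True)
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True)
    )
    try:  # plots are best-effort, never load-bearing
        from .plotting import phasor_plot

        for k in result.manifest["config"]["harmonics"]:
            phasor_plot(
                result.measurements,
                harmonic=k,
                path=out_dir / f"phasor_h{k}.png",
                csv_path=out_dir / f"phasor_h{k}.csv",
            )
    except Exception as exc:  # pragma: no cover
        logger.warning("plot export failed: %s", exc)
    return out_dir


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(out_dir: str | Path, seed: int = 0, size: int = 16) -> dict:
    """Write small deterministic fixture stacks for every preset.

    One paired scene per condition preset (``size x size x 256``) plus the
    simulated reference-standard decay, with a manifest listing every file
    and its SHA-256. Regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = AcquisitionMeta()
    config = RunConfig(seed=seed, height=size, width=size)
    files: dict[str, str] = {}
    for i, (name, preset) in enumerate(sorted(DEFAULT_PRESETS.items())):
        spec = preset_scene_spec(preset, height=size, width=size, seed=seed + i, meta=meta)
        baseline, treated, _, _ = generate_scene(spec)
        for tag, img in (("baseline", baseline), ("treated", treated)):
            path = out_dir / f"{name}_{tag}.tif"
            write_tcspc_stack(img, path)
            files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    ref = simulate_reference_standard(config, meta)
    ref_path = out_dir / "reference_standard.csv"
    np.savetxt(ref_path, ref.counts, fmt="%.6f")
    files[ref_path.name] = hashlib.sha256(ref_path.read_bytes()).hexdigest()
    manifest = {"seed": seed, "size": size, "files": files}
    (out_dir / "fixtures_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
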