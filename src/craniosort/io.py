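"""File formats, run configuration and pipeline orchestration.

Measurement tables are plain CSV (comma-separated, UTF-8, dot decimal,
millimetres) with one row per individual; meshes are STL or PLY read and
written through trimesh; landmark files are JSON keyed by facet and
anatomical label.  ``run_pipeline`` ties the stages together for the
command-line entry points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh

from . import __version__
from .osteometry import (
    C1_MEASUREMENTS,
    OC_MEASUREMENTS,
    MeasurementSet,
    build_pairwise_dataset,
    measurements_to_frame,
)
from .registration import LandmarkSet, RoiMesh

logger = logging.getLogger("craniosort")

#: Canonical measurement-CSV column order.
CSV_COLUMNS = (
    "individual_id", "sex",
    "AR_OC", "AL_OC", "CR_OC", "CL_OC", "E_OC", "G_OC", "K_OC", "I_OC",
    "BRS_C1", "BLS_C1", "DRS_C1", "DLS_C1", "F_C1", "H_C1", "J_C1", "L_C1",
)


def read_measurement_csv(path) -> list[MeasurementSet]:
    """Read a measurement table into typed per-individual records.

    The header must contain exactly the canonical columns (any order).
    Rows with missing, non-numeric or non-positive cells are rejected with
    a diagnostic naming the row and column.
    """
    frame = pd.read_csv(path, dtype={"individual_id": str, "sex": str},
                        float_precision="round_trip")
    unknown = set(frame.columns) - set(CSV_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    out = []
    numeric = OC_MEASUREMENTS + C1_MEASUREMENTS
    for idx, row in frame.iterrows():
        for col in numeric:
            value = row[col]
            if pd.isna(value):
                raise ValueError(f"{path}: row {idx + 1} has a missing value in column {col}")
            try:
                v = float(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: row {idx + 1}, column {col}: non-numeric value {value!r}"
                ) from exc
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"{path}: row {idx + 1}, column {col}: measurement must be positive, got {v}"
                )
        sex = row["sex"] if pd.notna(row["sex"]) else "unknown"
        out.append(MeasurementSet(
            individual_id=str(row["individual_id"]),
            sex=str(sex),
            oc={k: float(row[k]) for k in OC_MEASUREMENTS},
            c1={k: float(row[k]) for k in C1_MEASUREMENTS},
        ))
    return out


def write_measurement_csv(individuals: Iterable[MeasurementSet], path) -> None:
    """Write a measurement table in the canonical column order, full precision."""
    frame = measurements_to_frame(individuals)
    frame = frame[list(CSV_COLUMNS)]
    frame.to_csv(path, index=False, float_format="%.17g")


def write_pairwise_csv(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False, float_format="%.17g")


def read_landmarks_json(path) -> LandmarkSet:
    """Read a landmark file: ``{"left": {"anterior": [x,y,z], ...}, "right": {...}}``."""
    with open(path) as fh:
        payload = json.load(fh)
    return LandmarkSet(payload)


def write_landmarks_json(landmarks: LandmarkSet, path) -> None:
    payload = {facet: {label: list(map(float, p)) for label, p in pts.items()}
               for facet, pts in landmarks.facets.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_roi_mesh(path, provenance: str = "unknown") -> RoiMesh:
    """Load an STL or PLY articular-surface patch (mm units assumed)."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return RoiMesh(mesh, provenance=provenance)


def save_roi_mesh(roi: RoiMesh, path) -> None:
    roi.mesh.export(str(path))


@dataclass
class RunConfig:
    """Configuration for an end-to-end demo pipeline run.

    ``n_individuals`` individuals are simulated for the osteometric arm
    (measurements -> features -> pairwise classification) and
    ``n_match``/``n_mismatch`` RMS outcomes for the screening arm.  Paths
    may point at a real measurement CSV instead of simulating.
    """

    seed: int = 0
    output_dir: str = "craniosort-output"
    measurement_csv: str | None = None
    n_individuals: int = 150
    classifier_families: tuple[str, ...] = ("linear_discriminant", "quadratic_discriminant")
    cv_folds: int = 10
    n_match: int = 46
    n_mismatch: int = 260
    rtem_threshold: float = 7.5
    alpha: float = 0.05
    verbose: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        payload = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
        return cls(**payload)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the two-arm demo pipeline and write all artifacts.

    Stages: (simulate or load) measurements -> correlation report ->
    pairwise dataset -> classifier cross-validation -> metrics CSV; then
    simulated superimposition RMS -> exclusion screen -> screening JSON
    and scatter plot.  A provenance block records seed, version and
    parameters.  Returns the artifact paths and headline numbers.
    """
    from .classification import PairClassification, correlation_report
    from .screening import ExclusionScreen
    from .simulate import simulate_measurements, simulate_rms

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = logging.DEBUG if config.verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")

    logger.info("stage measurements: %s",
                config.measurement_csv or f"simulating n={config.n_individuals}")
    if config.measurement_csv:
        individuals = read_measurement_csv(config.measurement_csv)
    else:
        individuals = simulate_measurements(n=config.n_individuals, seed=config.seed)
        write_measurement_csv(individuals, out / "measurements.csv")

    logger.info("stage features: building %d^2 pairwise dataset", len(individuals))
    pairs = build_pairwise_dataset(individuals)
    write_pairwise_csv(pairs, out / "pairwise.csv")
    corr = correlation_report(individuals)
    corr.to_csv(out / "correlations.csv", index=False)

    logger.info("stage classification: %s", ", ".join(config.classifier_families))
    clf_results = PairClassification(pairs).fit(
        families=config.classifier_families, k=config.cv_folds, seed=config.seed)
    clf_results.to_csv(out / "classifier_metrics.csv")

    logger.info("stage screening: %d matches, %d mismatches",
                config.n_match, config.n_mismatch)
    rms = simulate_rms(n_match=config.n_match, n_mismatch=config.n_mismatch,
                       seed=config.seed)
    screen_results = ExclusionScreen(rms).fit(alpha=config.alpha)
    screen_results.to_json(out / "screening.json")
    ax = screen_results.plot_rms()
    ax.figure.savefig(out / "rms_scatter.png", dpi=120)

    provenance = {
        "package": "craniosort",
        "version": __version__,
        "seed": config.seed,
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    return {
        "output_dir": str(out),
        "n_individuals": len(individuals),
        "classifier_metrics": clf_results.metrics,
        "threshold_mm": screen_results.threshold,
        "exclusion_fraction_mismatch": screen_results.exclusion_fraction_mismatch,
    }
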