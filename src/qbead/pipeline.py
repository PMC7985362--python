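"""End-to-end orchestration: simulate -> detect -> quantify.

One root seed drives every stage.  Per-sample child seeds are spawned
from the root with :class:`numpy.random.SeedSequence`, so any single
sample can be regenerated independently of the rest of the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .biophysics import CircuitParams, FrequencyPanel, ShellMap
from .detect import DetectorParams, EventTable, detect_events
from .dna_math import SampleSpec, aliquot_quantity
from .io import (
    config_hash,
    load_manifest,
    write_events_csv,
    write_results_json,
    write_traces_h5,
)
from .quantify import (
    QScoreResult,
    detection_call,
    fit_standard_curve,
    q_score,
    quantify_unknown,
)
from .simulate import AcquisitionSettings, simulate_traces

log = logging.getLogger("qbead")


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and sample label."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str | Path
    out_dir: str | Path
    seed: int = 0
    detector: DetectorParams | None = None
    alpha: float = 0.05
    r2_min: float = 0.95
    write_traces: bool = False
    log_level: str = "INFO"


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic per-sample seeds spawned from one root seed (< 2**31)."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]


def _stage(stage: str, label: str):
    def wrap(exc: Exception) -> PipelineError:
        return PipelineError(f"stage '{stage}' failed for sample '{label}': {exc}")

    return wrap


def run_sample(
    spec: SampleSpec,
    circuit: CircuitParams,
    shell_map: ShellMap,
    acq: AcquisitionSettings,
    panel: FrequencyPanel,
    detector: DetectorParams | None = None,
) -> tuple[EventTable, QScoreResult]:
    """Simulate, detect and score a single sample."""
    traces = simulate_traces(spec, circuit, acq, panel, shell_map)
    events = detect_events(traces, detector)
    return events, q_score(events, label=spec.label)


def _acquisition_for(spec: SampleSpec, overrides: dict, seed: int) -> AcquisitionSettings:
    acq = AcquisitionSettings(**overrides, seed=seed)
    # stretch the run until the expected thinned arrival count covers the aliquot
    min_duration = 1.25 * spec.n_beads / max(acq.arrival_rate, 1e-9) + 10 * acq.mean_transit_time
    if acq.duration < min_duration:
        acq = dataclasses.replace(acq, duration=float(np.ceil(min_duration)))
    return acq


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline described by a manifest.

    Simulates every sample in the manifest, detects events, scores each
    sample, calls every DNA-bearing sample against the manifest's control
    (``copies_per_bead == 0``), and — when at least three DNA quantities
    are present — fits a standard curve and quantifies each sample back
    from it.  Writes ``events_<label>.csv`` and ``results.json`` into
    ``config.out_dir`` and returns the results document.
    """
    logging.basicConfig(level=config.log_level)
    manifest = load_manifest(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    samples: list[SampleSpec] = manifest["samples"]
    seeds = child_seeds(config.seed, len(samples))
    provenance = {
        "seed": config.seed,
        "package_version": __version__,
        "config_hash": config_hash(
            {
                "manifest": str(config.manifest),
                "seed": config.seed,
                "alpha": config.alpha,
                "r2_min": config.r2_min,
            }
        ),
        "child_seeds": {s.label: sd for s, sd in zip(samples, seeds)},
    }

    results: list[dict] = []
    scores: dict[str, QScoreResult] = {}
    tables: dict[str, EventTable] = {}
    for spec, seed in zip(samples, seeds):
        acq = _acquisition_for(spec, manifest["acquisition"], seed)
        try:
            traces = simulate_traces(spec, manifest["circuit"], acq, manifest["panel"],
                                     manifest["shell_map"])
        except Exception as exc:
            raise _stage("simulate", spec.label)(exc) from exc
        if config.write_traces:
            write_traces_h5(traces, out_dir / f"traces_{spec.label}.h5")
        try:
            detector = config.detector or DetectorParams.for_transit(acq.mean_transit_time)
            events = detect_events(traces, detector)
        except Exception as exc:
            raise _stage("detect", spec.label)(exc) from exc
        try:
            score = q_score(events, label=spec.label)
        except Exception as exc:
            raise _stage("quantify", spec.label)(exc) from exc
        write_events_csv(events, out_dir / f"events_{spec.label}.csv")
        scores[spec.label] = score
        tables[spec.label] = events
        log.info("sample %s: %d beads, Q = %.4g", spec.label, score.n_beads, score.q_mean)

    controls = [s for s in samples if s.is_control]
    control_score = scores[controls[0].label] if controls else None

    curve = None
    curve_points = [
        (aliquot_quantity(s).total_fmol, scores[s.label]) for s in samples if not s.is_control
    ]
    if len(curve_points) >= 3:
        try:
            curve = fit_standard_curve(curve_points, r2_min=config.r2_min)
        except ValueError as exc:
            log.warning("standard curve not fitted: %s", exc)

    for spec in samples:
        score = scores[spec.label]
        entry = {
            "label": spec.label,
            "n_beads": score.n_beads,
            "q_mean": score.q_mean,
            "q_se": score.q_se,
            "spectrum_mean": tables[spec.label].ipr_matrix().mean(axis=0).tolist(),
            "spectrum_sem": (
                tables[spec.label].ipr_matrix().std(axis=0, ddof=1)
                / np.sqrt(score.n_beads)
            ).tolist(),
            "true_quantity_fmol": aliquot_quantity(spec).total_fmol,
        }
        if control_score is not None and not spec.is_control:
            call = detection_call(score, control_score, alpha=config.alpha)
            entry["detection"] = {
                "detected": call.detected,
                "p_value": call.p_value,
                "margin": call.margin,
                "delta_q": call.delta_q,
            }
        if curve is not None and not spec.is_control:
            est = quantify_unknown(score, curve)
            entry["estimated_fmol"] = est.quantity_fmol
            entry["in_linear_range"] = est.in_linear_range
        results.append(entry)

    doc = {
        "version": "1.0",
        "provenance": provenance,
        "samples": results,
    }
    if curve is not None:
        doc["standard_curve"] = {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "linear_range_fmol": list(curve.linear_range),
            "poly_coeffs": list(curve.poly_coeffs),
        }
    write_results_json(doc, out_dir / "results.json")
    return doc
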