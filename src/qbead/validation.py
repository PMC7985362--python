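"""End-to-end validation studies of the pipeline on synthetic data.

Each study runs the full simulate -> detect -> quantify path at a defined
operating point and reduces it to a small set of performance numbers:
detector recall and false-discovery rate, IPR readout accuracy, standard
curve quality and blinded quantity recovery, spectrum shape and fragment
length ordering, false-positive rate of the detection call, and detection
power under bead subsampling.  They back both the test suite and the
`acceptance` script.

Study sizes default to the assay's nominal scale (about 500 beads per
sample, the aliquot size used throughout); sampling rates are chosen per
study so the transit stays well resolved while runs remain quick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biophysics import CircuitParams, FrequencyPanel, ShellMap, delta_matrix
from .detect import DetectorParams, EventTable, detect_events
from .dna_math import SampleSpec, aliquot_quantity, copies_from_mass
from .pipeline import child_seeds
from .quantify import (
    QScoreResult,
    StandardCurve,
    detection_call,
    fit_standard_curve,
    q_score,
    quantify_unknown,
    subsample_power,
)
from .simulate import AcquisitionSettings, simulate_ipr_table, simulate_traces

#: Copies/bead of the 300 bp reference dilution series: 0.0039 to 0.39 fmol
#: per 500-bead aliquot in six half-decade-ish steps, crossing the bead
#: binding-capacity saturation near the top.
DILUTION_COPIES = tuple(4.75e3 * 10 ** (0.4 * k) for k in range(6))
REFERENCE_N_BEADS = 500
REFERENCE_LENGTH_BP = 300


def _acq(n_beads: int, sampling_rate: float, seed: int, **overrides) -> AcquisitionSettings:
    base = dict(
        sampling_rate=sampling_rate,
        duration=float(np.ceil(1.6 * n_beads / 4.0 + 1.0)),
        mean_transit_time=0.038,
        arrival_rate=4.0,
        noise_sd=1e-5,
        drift_amplitude=2e-4,
        drift_timescale=5.0,
        seed=seed,
    )
    base.update(overrides)
    return AcquisitionSettings(**base)


def _bare_amplitudes(circuit: CircuitParams, panel: FrequencyPanel) -> np.ndarray:
    """Noise-free spectrum of a reference bare bead."""
    return delta_matrix(panel, circuit, [circuit.shell_conductance_base])[0]


def match_events(
    events: EventTable, truth_apex: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy apex-time matching of detected events to ground truth.

    Returns (truth_index per detected event, -1 if unmatched).
    """
    det = np.array([e.apex_time for e in events.events])
    assign = np.full(det.size, -1, dtype=int)
    taken = np.zeros(truth_apex.size, dtype=bool)
    for i in np.argsort(det):
        d = np.abs(truth_apex - det[i])
        d[taken] = np.inf
        j = int(np.argmin(d)) if d.size else -1
        if j >= 0 and d[j] < tol:
            assign[i] = j
            taken[j] = True
    return assign, det


@dataclass(frozen=True)
class DetectorPerformance:
    recall: float
    fdr: float
    n_true: int
    n_detected: int
    median_ipr_rel_err: np.ndarray  # per frequency
    snr: float


def detector_study(
    seed: int,
    n_beads: int = REFERENCE_N_BEADS,
    sampling_rate: float = 5000.0,
    snr: float = 10.0,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
) -> DetectorPerformance:
    """Detector recall/FDR and IPR accuracy on bare beads at a fixed SNR.

    Per-channel noise is set to ``bare amplitude / snr``, so every event
    amplitude equals ``snr`` noise standard deviations on every channel.
    """
    amps = _bare_amplitudes(circuit, panel)
    acq = _acq(
        n_beads, sampling_rate, seed, noise_sd=tuple(float(a) / snr for a in amps)
    )
    spec = SampleSpec("bare", 0, 0.0, n_beads)
    traces = simulate_traces(spec, circuit, acq, panel)
    events = detect_events(traces, DetectorParams.for_transit(acq.mean_transit_time))

    gt = traces.ground_truth
    assign, _ = match_events(events, gt.t_apex.to_numpy(), tol=acq.mean_transit_time)
    tp = int((assign >= 0).sum())
    fp = int((assign < 0).sum())
    recall = tp / len(gt) if len(gt) else 0.0
    fdr = fp / max(len(events), 1)

    true_amps = traces.true_amplitudes()
    matched = assign >= 0
    ipr = events.ipr_matrix(include_doublets=True)[matched]
    truth = true_amps[assign[matched]]
    rel_err = np.abs(ipr - truth) / truth
    return DetectorPerformance(
        recall=recall,
        fdr=fdr,
        n_true=len(gt),
        n_detected=len(events),
        median_ipr_rel_err=np.median(rel_err, axis=0),
        snr=snr,
    )


def _sample_qscore(
    copies: float,
    seed: int,
    n_beads: int,
    sampling_rate: float,
    circuit: CircuitParams,
    panel: FrequencyPanel,
    shell_map: ShellMap,
    length_bp: int = REFERENCE_LENGTH_BP,
    label: str = "",
) -> QScoreResult:
    spec = SampleSpec(label or f"{copies:.3g}cpb", length_bp if copies > 0 else 0, copies, n_beads)
    acq = _acq(n_beads, sampling_rate, seed)
    traces = simulate_traces(spec, circuit, acq, panel, shell_map)
    events = detect_events(traces, DetectorParams.for_transit(acq.mean_transit_time))
    return q_score(events, label=spec.label)


@dataclass(frozen=True)
class DilutionStudy:
    curve: StandardCurve
    quantities_fmol: np.ndarray
    q_means: np.ndarray
    q_ses: np.ndarray


def dilution_curve_study(
    seed: int,
    n_beads: int = REFERENCE_N_BEADS,
    sampling_rate: float = 2000.0,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
) -> DilutionStudy:
    """Simulate the six-point 300 bp dilution series and fit its curve."""
    seeds = child_seeds(seed, len(DILUTION_COPIES))
    points = []
    for copies, child in zip(DILUTION_COPIES, seeds):
        spec = SampleSpec("std", REFERENCE_LENGTH_BP, copies, n_beads)
        fmol = aliquot_quantity(spec).total_fmol
        points.append(
            (fmol, _sample_qscore(copies, child, n_beads, sampling_rate, circuit, panel, shell_map))
        )
    curve = fit_standard_curve(points)
    return DilutionStudy(
        curve=curve,
        quantities_fmol=np.array([p[0] for p in points]),
        q_means=np.array([p[1].q_mean for p in points]),
        q_ses=np.array([p[1].q_se for p in points]),
    )


@dataclass(frozen=True)
class RecoveryStudy:
    fraction_within: float
    factor: float
    true_fmol: float
    estimates_fmol: np.ndarray


def unknown_recovery_study(
    seed: int,
    curve: StandardCurve,
    n_replicates: int = 50,
    true_fmol: float = 0.02,
    n_beads: int = 200,
    sampling_rate: float = 2000.0,
    factor: float = 1.25,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
) -> RecoveryStudy:
    """Quantify blinded synthetic unknowns against a fitted curve.

    Each replicate simulates a fresh unknown sample at ``true_fmol`` (per
    reference 500-bead aliquot), runs detection and scoring, inverts the
    curve, and scores whether the estimate lies within ``factor`` of truth.
    """
    # copies/bead equivalent of the target aliquot quantity
    mass_total = true_fmol * 1e-15 * REFERENCE_LENGTH_BP * 650.0
    copies = copies_from_mass(mass_total, REFERENCE_LENGTH_BP, REFERENCE_N_BEADS)
    estimates = []
    for child in child_seeds(seed + 1, n_replicates):
        q = _sample_qscore(copies, child, n_beads, sampling_rate, circuit, panel, shell_map)
        estimates.append(quantify_unknown(q, curve).quantity_fmol)
    estimates = np.asarray(estimates)
    within = (estimates >= true_fmol / factor) & (estimates <= true_fmol * factor)
    return RecoveryStudy(
        fraction_within=float(within.mean()),
        factor=factor,
        true_fmol=true_fmol,
        estimates_fmol=estimates,
    )


@dataclass(frozen=True)
class SpectrumStudy:
    panel: FrequencyPanel
    spectra: dict  # length_bp -> per-frequency mean IPR
    rising_ok: bool  # strictly increasing 100 kHz -> 5 MHz
    falling_ok: bool  # strictly decreasing 7.5 -> 15 MHz
    ordering_violations: int  # pointwise 613 >= 300 >= 157 failures


def spectrum_study(
    seed: int,
    n_beads: int = REFERENCE_N_BEADS,
    sampling_rate: float = 2000.0,
    copies: float = 4.75e5,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
) -> SpectrumStudy:
    """Mean IPR spectra for 157/300/613 bp beads at equal copies/bead.

    The three samples share one child seed (paired design: identical
    arrival times, per-bead copy numbers and diameters), isolating the
    fragment-length effect on the spectrum.
    """
    lengths = (157, 300, 613)
    spectra = {}
    for bp in lengths:
        spec = SampleSpec(f"{bp}bp", bp, copies, n_beads)
        acq = _acq(n_beads, sampling_rate, seed)
        traces = simulate_traces(spec, circuit, acq, panel, shell_map)
        events = detect_events(traces, DetectorParams.for_transit(acq.mean_transit_time))
        spectra[bp] = events.ipr_matrix().mean(axis=0)

    hz = panel.hz
    rising = np.flatnonzero(hz <= 5e6)
    falling = np.flatnonzero(hz >= 7.5e6)
    rising_ok = all(bool(np.all(np.diff(s[rising]) > 0)) for s in spectra.values())
    falling_ok = all(bool(np.all(np.diff(s[falling]) < 0)) for s in spectra.values())
    violations = int(np.sum(spectra[613] < spectra[300])) + int(
        np.sum(spectra[300] < spectra[157])
    )
    return SpectrumStudy(
        panel=panel,
        spectra=spectra,
        rising_ok=rising_ok,
        falling_ok=falling_ok,
        ordering_violations=violations,
    )


def null_call_study(
    seed: int,
    reps: int = 1000,
    n_beads: int = REFERENCE_N_BEADS,
    alpha: float = 0.05,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
) -> float:
    """Type-I error of the detection call: bare beads against bare beads.

    Uses the event-level generative model (log-normal bead population plus
    extraction noise) to draw independent sample/control pairs from the
    same distribution; returns the fraction called detected.
    """
    rng = np.random.default_rng(seed)
    spec = SampleSpec("null", 0, 0.0, n_beads)
    hits = 0
    for _ in range(reps):
        a = simulate_ipr_table(spec, circuit, panel, seed=rng).to_numpy().sum(axis=1)
        b = simulate_ipr_table(spec, circuit, panel, seed=rng).to_numpy().sum(axis=1)
        qa = QScoreResult(float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size)), a.size, a)
        qb = QScoreResult(float(b.mean()), float(b.std(ddof=1) / np.sqrt(b.size)), b.size, b)
        hits += detection_call(qa, qb, alpha=alpha).detected
    return hits / reps


@dataclass(frozen=True)
class PowerStudy:
    power: float
    n_sub: int
    full_call_detected: bool


def subsample_power_study(
    seed: int,
    n_beads: int = REFERENCE_N_BEADS,
    n_sub: int = 150,
    reps: int = 200,
    copies: float = 4.75e5,
    sampling_rate: float = 2000.0,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
) -> PowerStudy:
    """Detection power when only ``n_sub`` of ~500 beads are used.

    Simulates one well-loaded DNA sample and one bare-bead control at the
    full aliquot size, then repeatedly subsamples both to ``n_sub`` beads
    and re-runs the detection call.
    """
    s_seed, c_seed = child_seeds(seed + 2, 2)
    acq_s = _acq(n_beads, sampling_rate, s_seed)
    acq_c = _acq(n_beads, sampling_rate, c_seed)
    det = DetectorParams.for_transit(acq_s.mean_transit_time)
    sample = detect_events(
        simulate_traces(SampleSpec("dna", REFERENCE_LENGTH_BP, copies, n_beads),
                        circuit, acq_s, panel, shell_map), det
    )
    control = detect_events(
        simulate_traces(SampleSpec("bare", 0, 0.0, n_beads), circuit, acq_c, panel, shell_map),
        det,
    )
    full = detection_call(q_score(sample), q_score(control))
    power = subsample_power(sample, control, n_sub=n_sub, reps=reps, seed=seed)
    return PowerStudy(power=power, n_sub=n_sub, full_call_detected=full.detected)
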