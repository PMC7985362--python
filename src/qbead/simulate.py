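"""Synthetic multi-frequency impedance trace generation.

Produces seeded, ground-truth-annotated trace sets emulating bead transits
through a coplanar-electrode impedance cytometer: each transit is a
double-peak pulse (two narrow lobes riding one broad envelope, from the
bead crossing the two electrodes) whose per-frequency amplitude comes from
the equivalent-circuit model in :mod:`qbead.biophysics`.  Channels are
stored normalized to a unit baseline, with optional slow drift and white
noise.

Per-bead DNA load is drawn log-normally around the population mean
(shape 0.2), so event amplitudes vary bead to bead as in a real
population.  Bead arrivals follow a homogeneous Poisson process thinned so
two beads never overlap within one transit window — mirroring samples
diluted so only a single bead passes the electrodes at a time — except
that with probability ``doublet_probability`` a deliberately overlapping
partner is injected to exercise doublet handling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .biophysics import (
    REFERENCE_DIAMETER,
    CircuitParams,
    FrequencyPanel,
    ShellMap,
    delta_matrix,
    dna_to_shell,
)
from .dna_math import BP_MOLAR_MASS, SampleSpec
from scipy.constants import Avogadro

#: Log-normal shape parameter for per-bead DNA load heterogeneity.
LOAD_SHAPE = 0.2

#: Log-normal shape of per-bead diameter dispersion (~2% CV, typical for
#: monosized paramagnetic beads); gives bare beads a realistic amplitude
#: spread through the cubic volume coupling.
DIAMETER_SHAPE = 0.02

# Template geometry, as fractions of the transit window: one broad
# envelope and two narrow lobes centered on the two electrodes.
ENVELOPE_SIGMA_FRAC = 0.25
LOBE_SIGMA_FRAC = 0.05
LOBE_OFFSET_FRAC = 0.15
LOBE_HEIGHT_RATIO = 0.35 / 0.75  # lobe amplitude relative to envelope

#: Minimum spacing between consecutive single-bead arrivals, in transit
#: windows.  Two windows keeps neighbouring pulses fully separated, as in
#: samples diluted so only one bead occupies the sensing region at a time.
DEAD_TIME_WINDOWS = 2.0


@dataclass(frozen=True)
class AcquisitionSettings:
    """Acquisition and noise parameters of a simulated run.

    ``noise_sd`` and ``drift_amplitude`` are in relative (baseline-
    normalized) units.  ``noise_sd`` may be a scalar or one value per
    panel frequency.
    """

    sampling_rate: float = 10_000.0  # Hz
    duration: float = 30.0  # seconds
    mean_transit_time: float = 0.038  # seconds (~0.05 uL/min flow)
    arrival_rate: float = 4.0  # beads / second before thinning
    noise_sd: float | tuple[float, ...] = 1e-5
    drift_amplitude: float = 2e-4
    drift_timescale: float = 5.0  # seconds
    doublet_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate * self.mean_transit_time < 20:
            raise ValueError(
                "sampling_rate * mean_transit_time must be >= 20 "
                "(transit must be resolvable)"
            )
        if not 0 <= self.doublet_probability < 1:
            raise ValueError("doublet_probability must be in [0, 1)")
        if self.duration <= 0 or self.arrival_rate < 0:
            raise ValueError("duration must be > 0 and arrival_rate >= 0")
        sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if np.any(sd < 0) or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be >= 0")

    def noise_sd_per_channel(self, n_channels: int) -> np.ndarray:
        sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if sd.size == 1:
            return np.full(n_channels, sd[0])
        if sd.size != n_channels:
            raise ValueError("noise_sd length must be 1 or match the panel")
        return sd


@dataclass(frozen=True)
class EventTemplate:
    """Unit-peak transit waveform: two narrow lobes on a broad envelope."""

    waveform: np.ndarray

    def __post_init__(self) -> None:
        w = self.waveform
        if w.ndim != 1 or w.size < 20:
            raise ValueError("waveform must be a 1-d array of >= 20 samples")
        if abs(w.max() - 1.0) > 1e-12 or w.min() < 0:
            raise ValueError("waveform must be non-negative with unit peak")

    def __len__(self) -> int:
        return self.waveform.size


@dataclass
class TraceSet:
    """Time-aligned multi-frequency impedance-magnitude series.

    ``channels[i]`` is the baseline-normalized magnitude at
    ``panel.frequencies[i]``; ``ground_truth`` (if present) logs every
    injected event with its arrival, per-frequency true amplitude and
    bead identity.
    """

    time: np.ndarray
    channels: np.ndarray  # (n_frequencies, n_samples)
    panel: FrequencyPanel
    settings: AcquisitionSettings
    ground_truth: pd.DataFrame | None = None
    source: str = "simulation"

    def __post_init__(self) -> None:
        if self.channels.shape != (len(self.panel), self.time.size):
            raise ValueError("channels must be (n_panel, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def amplitude_columns(self) -> list[str]:
        return [f"amp_{i}" for i in range(len(self.panel))]

    def true_amplitudes(self) -> np.ndarray:
        """Ground-truth amplitude matrix, (n_events, n_frequencies)."""
        if self.ground_truth is None:
            raise ValueError("trace set carries no ground truth")
        return self.ground_truth[self.amplitude_columns].to_numpy()


def make_template(
    transit_time: float,
    sampling_rate: float,
    peak_separation_fraction: float = 2 * LOBE_OFFSET_FRAC,
) -> EventTemplate:
    """Build the double-peak transit waveform.

    The waveform is the sum of one broad Gaussian envelope and two narrow
    Gaussian lobes at ``+- peak_separation_fraction/2`` of the window,
    renormalized to unit peak.  It has exactly two strict local maxima and
    is symmetric about the window center.
    """
    n = int(round(transit_time * sampling_rate))
    if n < 20:
        raise ValueError("transit under-resolved: transit_time * sampling_rate < 20")
    if not 0 < peak_separation_fraction < 1:
        raise ValueError("peak_separation_fraction must be in (0, 1)")
    t = (np.arange(n) - (n - 1) / 2) / n  # symmetric in [-0.5, 0.5)
    off = peak_separation_fraction / 2
    w = np.exp(-(t**2) / (2 * ENVELOPE_SIGMA_FRAC**2))
    w = w + LOBE_HEIGHT_RATIO * (
        np.exp(-((t - off) ** 2) / (2 * LOBE_SIGMA_FRAC**2))
        + np.exp(-((t + off) ** 2) / (2 * LOBE_SIGMA_FRAC**2))
    )
    return EventTemplate(w / w.max())


def _draw_arrivals(
    rng: np.random.Generator, acq: AcquisitionSettings, max_events: int
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson arrivals thinned to one transit window of dead time.

    Returns (start_times, doublet_partner_flag).  With probability
    ``doublet_probability`` a kept arrival receives an overlapping partner
    offset by 30-95% of a transit window; both members are flagged.
    """
    window = acq.mean_transit_time
    t = 0.0
    starts: list[float] = []
    doublet: list[bool] = []
    # leave room for the full window before the trace end
    t_max = acq.duration - window
    while len(starts) < max_events:
        if acq.arrival_rate <= 0:
            break
        t += rng.exponential(1.0 / acq.arrival_rate)
        if t > t_max:
            break
        if starts and t - starts[-1] < window * DEAD_TIME_WINDOWS:
            continue  # thinning: forbid accidental overlap
        if (
            acq.doublet_probability > 0
            and len(starts) + 1 < max_events
            and rng.random() < acq.doublet_probability
        ):
            partner = t + window * rng.uniform(0.3, 0.95)
            if partner <= t_max:
                starts.extend([t, partner])
                doublet.extend([True, True])
                continue
        starts.append(t)
        doublet.append(False)
    return np.asarray(starts), np.asarray(doublet, dtype=bool)


def _drift(rng: np.random.Generator, acq: AcquisitionSettings, n: int) -> np.ndarray:
    """Slow multiplicative baseline drift: low-passed random walk.

    Generated on a coarse grid (20 points per drift timescale) and
    interpolated to the sampling grid; the walk has no power near the
    transit timescale, so this loses nothing.
    """
    if acq.drift_amplitude == 0:
        return np.zeros(n)
    dt_coarse = acq.drift_timescale / 20.0
    n_coarse = max(int(np.ceil(n / acq.sampling_rate / dt_coarse)) + 2, 8)
    walk = np.cumsum(rng.standard_normal(n_coarse))
    slow = gaussian_filter1d(walk, 20.0, mode="nearest")
    sd = slow.std()
    if sd == 0:
        return np.zeros(n)
    slow = acq.drift_amplitude * (slow - slow.mean()) / sd
    t_coarse = np.arange(n_coarse) * dt_coarse
    return np.interp(np.arange(n) / acq.sampling_rate, t_coarse, slow)


def simulate_traces(
    spec: SampleSpec,
    circuit: CircuitParams = CircuitParams(),
    acq: AcquisitionSettings = AcquisitionSettings(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
) -> TraceSet:
    """Simulate one sample's multi-frequency trace set.

    Event amplitudes are ``bead_delta`` evaluated per bead: each bead's
    copy number is drawn log-normally around ``spec.copies_per_bead``
    (bare beads carry exactly zero DNA), converted to mass and then to
    shell conductance.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(acq.seed)
    n = int(round(acq.duration * acq.sampling_rate))
    time = np.arange(n) / acq.sampling_rate
    n_freq = len(panel)

    template = make_template(acq.mean_transit_time, acq.sampling_rate).waveform
    starts, doublet = _draw_arrivals(rng, acq, spec.n_beads)

    # Per-bead DNA load -> per-frequency amplitude
    n_ev = starts.size
    if spec.copies_per_bead > 0:
        copies = spec.copies_per_bead * rng.lognormal(
            -0.5 * LOAD_SHAPE**2, LOAD_SHAPE, n_ev
        )
    else:
        copies = np.zeros(n_ev)
    mass = copies * spec.dna_length_bp * BP_MOLAR_MASS / Avogadro
    diameters = REFERENCE_DIAMETER * rng.lognormal(
        -0.5 * DIAMETER_SHAPE**2, DIAMETER_SHAPE, n_ev
    )
    shells = np.atleast_1d(dna_to_shell(mass, shell_map, base=circuit.shell_conductance_base))
    amps = delta_matrix(panel, circuit, shells, diameters)

    signal = np.zeros((n_freq, n))
    start_idx = np.round(starts * acq.sampling_rate).astype(int)
    keep = start_idx + template.size <= n
    for i in np.flatnonzero(keep):
        sl = slice(start_idx[i], start_idx[i] + template.size)
        signal[:, sl] += amps[i][:, None] * template[None, :]

    drift = _drift(rng, acq, n)
    channels = (1.0 + drift)[None, :] * (1.0 + signal)
    sd = acq.noise_sd_per_channel(n_freq)
    if np.any(sd > 0):
        channels = channels + sd[:, None] * rng.standard_normal((n_freq, n))

    gt = pd.DataFrame(
        {
            "bead_id": np.arange(n_ev)[keep],
            "t_start": starts[keep],
            "t_apex": starts[keep]
            + (start_idx[keep] - starts[keep] * acq.sampling_rate + np.argmax(template))
            / acq.sampling_rate,
            "transit_time": np.full(keep.sum(), template.size / acq.sampling_rate),
            "doublet": doublet[keep],
            "copies": copies[keep],
            "dna_mass": mass[keep],
            "diameter": diameters[keep],
        }
    )
    for j in range(n_freq):
        gt[f"amp_{j}"] = amps[keep, j]

    return TraceSet(time, channels, panel, acq, gt, source=f"sim:{spec.label}")


def simulate_ipr_table(
    spec: SampleSpec,
    circuit: CircuitParams = CircuitParams(),
    panel: FrequencyPanel = FrequencyPanel(),
    shell_map: ShellMap = ShellMap(),
    extraction_noise_sd: float = 3e-6,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Event-level shortcut: draw per-bead IPR vectors without rendering traces.

    Uses the same generative model as :func:`simulate_traces` (log-normal
    load, circuit-model amplitudes) plus additive extraction noise, but
    skips the time-domain rendering and detection steps.  Intended for
    statistical studies that need many replicate samples cheaply.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_beads
    if spec.copies_per_bead > 0:
        copies = spec.copies_per_bead * rng.lognormal(-0.5 * LOAD_SHAPE**2, LOAD_SHAPE, n)
    else:
        copies = np.zeros(n)
    mass = copies * spec.dna_length_bp * BP_MOLAR_MASS / Avogadro
    diameters = REFERENCE_DIAMETER * rng.lognormal(-0.5 * DIAMETER_SHAPE**2, DIAMETER_SHAPE, n)
    shells = np.atleast_1d(dna_to_shell(mass, shell_map, base=circuit.shell_conductance_base))
    ipr = delta_matrix(panel, circuit, shells, diameters)
    if extraction_noise_sd > 0:
        ipr = np.clip(ipr + rng.normal(0, extraction_noise_sd, ipr.shape), 0, None)
    return pd.DataFrame(ipr, columns=[f"ipr_{j}" for j in range(len(panel))])
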