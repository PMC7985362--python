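# Methods

This note documents the models behind `qbead`: the equivalent circuit of
the sensing channel, the DNA-load → surface-conductance mapping, the
synthetic trace generator, the detector and IPR readout, and the
statistics.  It also records the numerical choices and the limits of what
the synthetic validation can show.

## Equivalent circuit of the sensing channel

The electrode pair and electrolyte-filled channel are modeled as a lumped
network with four elements (`qbead.biophysics.CircuitParams`):

- `c_doublelayer` — the electrode–electrolyte interfacial capacitance, in
  series with the channel.  It dominates |Z| at low frequency and
  suppresses the *relative* response to a bead there.
- `r_solution` — the electrolyte resistance of the sensing volume.
- `c_parasitic` — a stray capacitive path in parallel with the channel
  that shunts current at high frequency, so |Z| → 0 as f → ∞ and the
  relative bead response rolls off above a few MHz.
- the bead, when present: a resistor `r_bead` and capacitor `c_bead` in
  series (insulating polystyrene core), in parallel with the solution.

A transiting bead also excludes a fraction α of the conducting volume.
The with-bead solution admittance is therefore

    Y = (1 − α)/r_solution + 1/(r_bead + 1/(jω c_bead)),

and the full impedance is Z = 1/(jω c_dl) + 1/(Y + jω c_par).  The
observable is δ(f) = (|Z_bead| − |Z_baseline|)/|Z_baseline|, which is
non-negative for any bead branch less conductive than the displaced
electrolyte and band-pass in frequency: the double layer kills the low
end, the parasitic path the high end.

**Shell coupling.** DNA binding raises the bead's surface charge and
conductance, and the resulting counterion-cloud polarization *increases*
the dipole perturbation the bead imposes on the field.  We fold this into
the coupling strength:

    α = volume_coupling · (d/2.8 µm)³ · (1 + g_shell / g_ref),

with `g_ref = shell_reference_conductance`.  A more conductive shell thus
produces a larger δ at every frequency, which is the behaviour the assay
relies on (DNA-coated beads give larger IPR than bare beads).  Note this
is deliberately *not* implemented by lowering `r_bead`: adding shell
conductance in parallel with the bead branch would shrink |Z| and
invert the required monotonicity, so the shell term enters the coupling,
not the branch resistance.

**Defaults.** Absolute component values of real devices are never
published and vary chip to chip; the shipped defaults are a synthetic
calibration, frozen once: `r_solution` = 100 kΩ, `c_doublelayer` =
0.796 pF (low corner ≈ 2 MHz), `c_parasitic` = 0.145 pF (high corner
≈ 11 MHz), `volume_coupling` = 0.02.  These place the bare-bead δ peak at
5 MHz on the default panel {0.1, 0.5, 1, 2.5, 5, 7.5, 10, 15} MHz with a
peak amplitude of ≈1.4% of baseline, strictly rising below the peak and
strictly falling from 7.5 to 15 MHz.  The panel itself is configurable
(1–16 tones, 10 kHz–50 MHz); the published instrument states only the
range ("100 kHz to 20 MHz") and plots up to 15 MHz, so the default panel
is a choice, not a measured fact.

## DNA load → shell conductance

Per-bead DNA mass maps to shell conductance through a saturating
isotherm (`ShellMap`):

    g_shell(m) = g_base + gain · u(m),
    u(m) = ln[(1 + m/K_lo)/(1 + m/K_hi)] / ln(K_hi/K_lo),

the closed form of a surface whose binding-site affinities are spread
uniformly in log space between the scales `onset_mass` K_lo and
`capacity_mass` K_hi (a Unilan/Temkin-type heterogeneous-surface
isotherm).  Steric crowding and electrostatic repulsion between strands
make successive strands bind more weakly, which is exactly this kind of
heterogeneity.  u is monotone, strictly concave, bounded by 1, nearly
flat below K_lo, close to **linear in log m** between the two scales, and
saturated above K_hi — reproducing the three regimes a bead-based dose
response shows: a floor below the detection limit, a log-linear dynamic
range of about two decades, and a binding-capacity plateau.  A plain
one-site Langmuir form (linear in m, not log m, below capacity) was tried
first and rejected because it cannot produce a log-linear standard curve;
that lack of fit biased inverted quantities by ~15–20%.

Defaults: `gain` = 1.5 nS, `K_lo` = 8×10⁻¹⁶ g, `K_hi` = 7.4×10⁻¹⁴ g per
bead.  For 300 bp fragments on 500-bead aliquots these place the
log-linear window over roughly 0.004–0.2 fmol with saturation above,
i.e. a ~2-decade dynamic range.  Fragment length enters only through
mass (m = c·L·650/N_A), so at equal copies/bead longer fragments give
larger δ at every frequency — the basis of length discrimination.

## Synthetic trace generator

`simulate_traces` renders baseline-normalized channels

    x_f(t) = (1 + drift(t)) · (1 + Σ_i a_{i,f} · s(t − t_i)) + ε_f(t)

- **Template** s: one broad Gaussian envelope (σ = 0.25 of the transit
  window) plus two narrow lobes (σ = 0.05, centers ±0.15) — the
  double-peak morphology of one bead crossing two electrodes.  Unit peak,
  exactly two strict local maxima, symmetric.
- **Arrivals** t_i: homogeneous Poisson (default 4 beads/s) thinned to a
  dead time of two transit windows, the regime of samples diluted so a
  single bead occupies the sensing region at a time.  With probability
  `doublet_probability` an overlapping partner is injected 0.3–0.95
  windows later to exercise doublet handling.
- **Amplitudes** a_{i,f}: the circuit model evaluated per bead.  Each
  bead draws its copy number log-normally around the population mean
  (shape 0.2 — the instrument reports only population averages, so this
  heterogeneity level is a modeling choice) and its diameter log-normally
  with 2% CV (typical monosized-bead tolerance), giving bare beads a
  realistic ~6% amplitude CV through the cubic volume coupling.
- **Noise** ε: white Gaussian, default sd 1×10⁻⁵ relative units, which
  puts the weakest default-panel channel (δ ≈ 1.2×10⁻⁴ at 100 kHz) at
  ≳10× noise.  **Drift**: a low-passed random walk (default sd 2×10⁻⁴,
  timescale 5 s), generated on a coarse grid (20 points per timescale)
  and interpolated — it has no power at the transit timescale.
- Default transit time 38 ms (from the ~0.05 µL/min flow through a
  30×15 µm channel over the ~70 µm electrode span) and 10 kHz sampling;
  studies in this package run at 2–5 kHz, which keeps ≥76 samples per
  transit while shrinking traces.

Every injected event is logged in a ground-truth table (arrival, true
per-frequency amplitude, copy number, diameter, doublet flag).  With
noise and drift off, the rendered pulse maxima equal the logged
amplitudes to 10⁻⁶ relative.  Identical seeds give bit-identical traces;
multi-sample runs spawn per-sample child seeds from one root seed via
`numpy.random.SeedSequence`.

**What the generator does not emulate:** lock-in demodulation from raw
carriers, fluid-dynamic trajectory variation (off-center transits change
pulse shape, not just amplitude), bead aggregation, electrode fouling,
mains interference, and temperature dependence.  Passing tests therefore
validate the *analysis chain* under the stated signal model, not
instrument hardware.

## Detection and IPR readout

- **Baseline**: centered rolling median per channel (default window
  0.5 s ≥ 10 transits) — robust to sparse pulses, tracks drift with lag
  error ≤ slope·window/2.
- **Reference series**: sum of the normalized channels (transits perturb
  all frequencies simultaneously, so summing maximizes SNR).
- **Noise scale**: 1.4826 × MAD, re-estimated twice on below-threshold
  samples; threshold = `threshold_k` (default 5) × scale.  A zero scale
  is floored at the smallest positive float so noise-free traces still
  threshold cleanly.
- **Events**: supra-threshold runs merged across gaps < `merge_gap`
  (default 0.5 transit — the dip between the two lobes of one pulse never
  splits an event), runs shorter than `min_event_width` (default 0.2
  transit) discarded, boundary-touching runs dropped.  Runs wider than
  1.8× the median width are flagged as doublets (overlapping transits)
  and excluded from bead counts; overlaps offset by less than ~0.8 of a
  window evade this width criterion by construction — the flag is a
  guard, not a deconvolution.
- **IPR**: per-channel maximum over the event window, clipped at 0.  The
  raw maximum of signal+noise is biased high by the noise extremes
  (≈9% median at SNR 20), so channels are smoothed with a
  Savitzky–Golay filter (order 3, window ≈ the narrow-lobe width,
  5.5% of a transit) before the maximum is taken; this cuts the median
  bias to ≈1.4% while distorting the noise-free peak by <10⁻⁴.
  Smoothing is skipped when the measured channel noise is zero, so
  noise-free extraction is exact.  Raising `threshold_k` can only remove
  events, never add them.

## Statistics

- **Q-score**: per-bead Q_b = Σ_f IPR_{b,f}; the sample statistic is the
  mean over non-doublet beads, with SE = sd/√n.  The algebraic identity
  mean-of-sums = sum-of-means is asserted on every call.
- **Detection call** against the same-run bare-bead control: detected iff
  Q̄_sample > Q̄_control + 2·SE_control **and** Welch's unequal-variance
  two-sample test on the per-bead Q values gives p < α (default 0.05).
  The margin criterion operationalizes "above the upper bound (mean+SE)
  of the control by at least one further SE"; the conjunction keeps the
  empirical type-I error below the nominal α (≈2–3% at α = 0.05 in the
  null study).  Degenerate zero-variance ties return p = 1.
- **Standard curve**: OLS of Q̄ on log₁₀(quantity/fmol).  The linear
  range is auto-selected as the longest contiguous run (≥3
  concentrations, in rank order) with r² ≥ `r2_min` (default 0.95), ties
  broken by higher r²; a saturated plateau therefore drops off the top.
  A degree-3 polynomial over the full series is stored for plotting
  only.  Unknowns are inverted through the linear fit,
  q̂ = 10^((Q−b)/m), and flagged when outside the linear range.
- **Length response**: OLS of Q̄ on fragment length at documented equal
  molarity (enforced to 10⁻⁶ relative).
- **Subsampling power**: repeated detection calls on seeded random
  n-bead subsets of sample and control event tables, reporting the
  detected fraction — the "how few beads suffice" analysis (150 of ~500
  by default).

## Validation studies and problem sizes

`qbead.validation` fixes the operating points used by the test suite and
`scripts/acceptance.py`: 500-bead samples (the assay's aliquot size);
detector studies at 5 kHz with per-channel noise pinned to amplitude/SNR
(SNR 10 for recall/FDR, 20 for IPR accuracy); a six-point 300 bp dilution
series 0.0039–0.39 fmol (half-decade-ish steps crossing the capacity
plateau) at 2 kHz; blinded unknowns at 0.02 fmol, 200 beads, 50
replicates; the paired 157/300/613 bp length comparison at 4.75×10⁵
copies/bead, sharing one child seed across lengths so arrivals, copy
numbers and diameters are identical and only length differs; 1000
event-level null replicates for the type-I study; and 200 subsampling
replicates at n = 150.  These sizes make the full study set run in a few
minutes on one core.

## Known limitations

- All circuit values and the shell map are synthetic calibrations; the
  package reproduces the *behaviour* of the assay (spectrum shape,
  dose response, length ordering, detection logic), not absolute ohms.
- IPR extraction reads the event maximum only; alternatives (pulse area,
  apex mean) are not implemented.
- Overlapping transits are flagged by width, not resolved; matched-filter
  deconvolution is out of scope.
- Sequence-specific molar masses (GC content, biotin label,
  single-stranded forms) are ignored: 650 g/mol/bp throughout.
- The control band in simulations reflects bead-size dispersion and
  extraction noise only; day-to-day and device-to-device variation of a
  real instrument is represented solely by the same-run control design,
  not modeled explicitly.
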