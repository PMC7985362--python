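# qbead

Multi-frequency impedance cytometry analysis of DNA-coated microbeads:
event detection, impedance peak response (IPR) spectra, the Q-score
quantification statistic, bare-bead-calibrated detection calls, and
log-linear standard curves — together with a physics-motivated synthetic
trace simulator so the whole pipeline can be exercised and validated
without instrument data.

## The problem

Biotinylated DNA fragments (e.g. purified PCR products) captured on
2.8 µm streptavidin-coated paramagnetic beads change the beads' surface
conductance and permittivity.  When such a bead transits a pair of
coplanar microelectrodes carrying a multi-tone AC excitation (8
frequencies, 100 kHz – 15 MHz), it produces a transient increase in the
impedance magnitude on every demodulated channel — a double-peaked pulse,
one sub-peak per electrode.  The per-frequency maximum of the
baseline-normalized pulse is the **impedance peak response**:

    IPR_f = max_t [ (|Z_f(t)| − |Z_f,baseline|) / |Z_f,baseline| ]

For a sample of N beads the **Q-score** sums the bead-averaged IPR over
the panel of frequencies f₁…f₈:

    Q = Σ_f ( 1/N Σ_b IPR_{b,f} )  =  1/N Σ_b ( Σ_f IPR_{b,f} )

Q grows with the DNA mass per bead and, against a DNA-free bare-bead
control measured in the same run, supports detection calls, log-linear
standard curves (Q vs log₁₀ quantity), quantification of unknowns, and
fragment-length discrimination at equal molarity.  This package
implements that full analysis chain, plus the molecular arithmetic
linking fragment length L (bp), copies per bead c, and aliquot quantities
(mass m = c·L·650 g·mol⁻¹/N_A per bead; moles = c·N/N_A per N-bead
aliquot).

It is intended for researchers developing bead-based electronic nucleic
acid assays who need a tested, seedable reference implementation of the
signal processing and statistics, and a simulator for method studies.

## Worked example

`examples/dilution_300bp.yaml` describes a 300 bp dilution series
(4 concentrations plus a bare-bead control, ~500 beads each).  The
molecular arithmetic alone:

```text
$ qbead quantify-table examples/dilution_300bp.yaml
label       length_bp  copies_per_bead  ng_per_bead  total_ng  total_fmol
control     0          0                0            0         0
dna_4.75e3  300        4.75e+03         1.54e-06     0.000769  0.00394
dna_4.75e4  300        4.75e+04         1.54e-05     0.00769   0.0394
dna_2.4e5   300        2.38e+05         7.69e-05     0.0385    0.197
dna_4.75e5  300        4.75e+05         0.000154     0.0769    0.394
```

Each row converts copies/bead and length into per-bead DNA mass (ng),
total mass, and total molar quantity of a 500-bead aliquot: 4.75×10⁵
copies of a 300 bp fragment is 1.54×10⁻⁴ ng per bead and 0.39 fmol per
aliquot; the 4.75×10³ row is the femtogram regime (1.54 fg/bead,
0.0039 fmol).

The end-to-end pipeline — simulate traces per sample, detect transits,
extract IPR, score, call against the control, fit the standard curve and
re-quantify every sample from it:

```text
$ qbead pipeline --manifest examples/dilution_300bp.yaml --out out/ --seed 7
5 samples -> out/results.json
```

with `out/results.json` containing (abridged):

```text
     control  n=476  Q=0.0618±0.0002
  dna_4.75e3  n=481  Q=0.0838±0.0003  detected=True  est_fmol=0.0035
  dna_4.75e4  n=447  Q=0.1236±0.0004  detected=True  est_fmol=0.047
   dna_2.4e5  n=456  Q=0.1474±0.0005  detected=True  est_fmol=0.223
  dna_4.75e5  n=472  Q=0.1532±0.0005  detected=True  est_fmol=0.325
curve: slope=0.0353 Q/decade, r²=0.992, linear range 0.0039–0.39 fmol
```

Q rises monotonically with DNA quantity and flattens toward the top of
the series as the bead binding capacity saturates; every DNA-bearing
sample is called detected against the control (margin above mean + 2 SE
and Welch test p < 0.05); the recovered quantities track the true values
within the curve's scatter.  Identical seeds give byte-identical results.

Other subcommands: `qbead simulate`, `qbead detect`, `qbead quantify`,
`qbead curve` operate on the individual stages and their files (HDF5
traces, CSV event tables, JSON results).

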