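# 300 bp dilution series on 2.8 um streptavidin beads, plus a DNA-free
# control, mirroring a typical standard-curve run (~500 beads measured
# per sample; copies/bead are population means).
samples:
  - {label: control,  dna_length_bp: 0,   copies_per_bead: 0.0,    n_beads: 500}
  - {label: dna_4.75e3, dna_length_bp: 300, copies_per_bead: 4.75e3, n_beads: 500}
  - {label: dna_4.75e4, dna_length_bp: 300, copies_per_bead: 4.75e4, n_beads: 500}
  - {label: dna_2.4e5,  dna_length_bp: 300, copies_per_bead: 2.375e5, n_beads: 500}
  - {label: dna_4.75e5, dna_length_bp: 300, copies_per_bead: 4.75e5, n_beads: 500}
acquisition:
  sampling_rate: 2000.0
  mean_transit_time: 0.038
  arrival_rate: 4.0
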