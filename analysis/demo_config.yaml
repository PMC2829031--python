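# Demo configuration: a desk-scale instance of the full study design.
# Planted-feature counts are scaled with the probe pool so the expressed
# fraction, the per-contrast DE fractions and the correlated-set sizes stay
# realistic relative to the emulated platform.
sim:
  seed: 42
  n_genes: 200
  n_ncrnas: 100
  n_negative_controls: 40
  template_groups:
    olp_peak: [3, 1]
    mono_up: [3, 1]
    mono_down: [4, 1]
  n_discordant_pairs: 4
  n_concordant_pairs: 4

b_threshold: 1.0
structure_p: 0.9
enrichment_fdr: 0.05
bidirectional_window: 1000
tss_window: 5000
qpcr_n_perm: 2000
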