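# Small end-to-end fixture: ~50 genes, runs in well under two minutes.
seed: 7
sim:
  n_down: 12
  n_up_tss_occlusion: 3
  n_up_roadblock: 4
  n_up_roadblock_bidirectional: 2
  n_up_dse: 3
  n_up_competition_sp1: 3
  n_up_competition_other: 2
  n_unchanged: 21
  n_extra_sites: 8
motifs:
  width: 15
mechanism:
  n_random: 10000
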