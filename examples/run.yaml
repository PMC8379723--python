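# End-to-end demo configuration for `pairforage run`.
# Simulates a small colony, segments and filters the tracks, runs the
# coordination randomisation tests, the co-adjustment models and MRPP.
seed: 1
sim:
  n_pairs: 8
  days: 10.0
  coordination_prob: 0.6
filters:
  min_duration_h: 0.5
  min_distance_km: 1.0
  combiner: either
alpha: 0.05
n_rep: 999
n_perm: 999
stages:
  simulate: true
  coordination: true
  models: true
  similarity: true
  annotate: false
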