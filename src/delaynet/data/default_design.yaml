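# Default synthetic-cohort design.
#
# Four diagnostic groups at the published cohort sizes (81/36/31/18),
# 200 regions, 197 timepoints at TR = 3 s.  Each group's coupling
# template is a directed ring backbone (every region drives its
# n_neighbors clockwise neighbours at lag 1) with a group-specific
# probability of rewiring couplings to random long-range targets.
# Shortcuts raise the global efficiency of the recovered directed
# network, so the rewiring probabilities below plant the
# amyloid-positive efficiency trajectory decrease (CN Abeta+) ->
# increase (MCI Abeta+) -> decrease (AD Abeta+) relative to the
# amyloid-negative baseline.
#
# Stability budget: self_coupling + n_neighbors * strength * (1 + 3 *
# strength_jitter_sd) = 0.10 + 3 * 0.22 * 1.3 = 0.958 < 1, so every
# jittered subject process is provably stable (row-sum bound on the
# companion spectral radius).
n_regions: 200
n_timepoints: 197
tr_seconds: 3.0
groups:
  - name: CN_Abeta_neg
    n_subjects: 81
    backbone: {n_neighbors: 3, rewire_prob: 0.30, strength: 0.22, lag: 1}
    noise_sd: 1.0
    self_coupling: 0.10
    strength_jitter_sd: 0.10
  - name: CN_Abeta_pos
    n_subjects: 36
    backbone: {n_neighbors: 3, rewire_prob: 0.02, strength: 0.22, lag: 1}
    noise_sd: 1.0
    self_coupling: 0.10
    strength_jitter_sd: 0.10
  - name: MCI_Abeta_pos
    n_subjects: 31
    backbone: {n_neighbors: 3, rewire_prob: 0.80, strength: 0.22, lag: 1}
    noise_sd: 1.0
    self_coupling: 0.10
    strength_jitter_sd: 0.10
  - name: AD_Abeta_pos
    n_subjects: 18
    backbone: {n_neighbors: 3, rewire_prob: 0.00, strength: 0.22, lag: 1}
    noise_sd: 1.0
    self_coupling: 0.10
    strength_jitter_sd: 0.10
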