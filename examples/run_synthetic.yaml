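# End-to-end synthetic run on the planted two-cluster scenario: strong
# NE->C and NW->W source flows, a nearly isolated southern population,
# study years 1988-2008 with the standard five temporal classes.
# Swap `planted_two_cluster` for `study_defaults: true` to run the
# corpus-calibrated configuration instead.
synthetic:
  planted_two_cluster: true
  seed: 42
seed: 42
n_permutations: 10000
threshold_km: 5.0
min_age_years: 4
breeding_window: [[4, 15], [7, 15]]
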