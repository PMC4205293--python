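# Fully synthetic end-to-end run: genotypes simulated under the
# mid-Holocene-bottleneck hypothesis, default 13x4x3 suitability stack.
# Scale `replicates` up to 2000 for a full-precision model comparison.
seed: 42
output_dir: pipeline_out
synthetic:
  study:
    n_populations: 20
    n_loci: 11
    inbreeding: 0.21
    truth_scenario: Expansion_6_0
  maps: {}
scenarios:
  - Stability_21_0
  - Retraction_21_6
  - Expansion_21_0
  - Expansion_21_6
  - Expansion_6_0
  - MultipleRefugia_21_0
replicates: 40
permutations: 999
suitability_threshold: 0.3
cutoff: 199
mutation_rate: 0.01
generation_time: 12
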