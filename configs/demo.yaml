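# Demo run: 100 kb reference, 285x pooled coverage, a spread of planted
# variants plus one artifact of each class. Runs in under a minute.
seed: 7

reference:
  length: 100000
  gc_fraction: 0.35

pool:
  n_haplotypes: 10
  variants:
    - {kind: snp, position: 12000, alt: null, frequency: 0.9}   # alt: null -> pick any non-reference base
    - {kind: snp, position: 30000, alt: null, frequency: 0.43}
    - {kind: snp, position: 48000, alt: null, frequency: 0.16}
    - {kind: snp, position: 66000, alt: null, frequency: 0.32}
    - {kind: snp, position: 84000, alt: null, frequency: 0.05}
    - {kind: insertion, position: 20000, sequence: ACGT, frequency: 0.5}
    - {kind: deletion, position: 55000, length: 5, frequency: 0.7}

simulate:
  depth: 285.0
  read_length: 100
  mean_fragment: 230.0
  fragment_sd: 20.0
  per_base_error: 0.001
  artifacts:
    - {kind: strand_biased_cluster, position: 40000, intensity: 0.9}
    - {kind: read_end_only, position: 75000, width: 10, intensity: 1.0}

pileup:
  min_mapping_quality: 20
  min_base_quality: 20

caller: {}
filters: {}
sv:
  min_pairs: 4
annotate:
  promoter_window: 150
evaluate:
  af_tolerance: 0.05
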