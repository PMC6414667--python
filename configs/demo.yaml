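# Reduced survey scenario: full pipeline in ~1 minute.
#   phagetrace run-all --config configs/demo.yaml --seed 1 --outdir results/demo
seed: 1
outdir: results/demo
survey:
  n_contigs: 20
  n_persistent: 4
  contig_length: 8000
  host_length: 8000
  host_expected_reads: 2000.0
  dna_reads_per_sample: 2500
  gp23_reads_per_sample: 600
recruitment:
  min_hit_len_dna: 100
  min_hit_len_rna: 200
  min_identity: 70.0
dynamics:
  trim_fraction: 0.25
  persistence_cov: 0.75
  persistence_min_dates: 3
markers:
  alpha: 1.0
  target_fpr: 1.0e-3
hosts:
  threshold: 0.75
  presence_floor: 0.001
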