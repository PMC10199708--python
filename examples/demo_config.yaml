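# Demo pipeline config: a ~2-Mb three-chromosome genome with one arm
# lacking a telomere, one planted gene cluster and one SNP hotspot.
outdir: scratch_demo_run
seed: 7
simulate:
  chrom_lengths: [700000, 650000, 750000]
  telomeres:
    missing_arms: [[1, left]]
  centromeres:
    array_bp: [80000, 120000]
  genes:
    clusters:
      - accession: NB-ARC
        chrom_index: 0
        n_genes: 8
  snps:
    background_rate: 0.0001
    hotspots: [[chr1, 200000, 400000, 10.0]]
params:
  min_period: 30
  max_period: 500
  min_identity: 0.8
  window: 100000
  top_fraction: 0.05
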