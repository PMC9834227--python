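# Small end-to-end configuration: simulated 3' dataset with a mosaic
# somatic variant near the 3' end of gene 0, an internal poly-A site in
# gene 1, and a null variant that no cell carries.
seed: 11
outdir: dropgeno_out
stages: [simulate, genotype, annotate, mispriming, qc, evaluate, lineage]
simulate:
  n_cells: 250
  n_genes: 5
  kit_end: three_prime
  mosaic_fraction: 0.1
  error_rate: 0.001
  mispriming_rate: 0.05
  internal_polyA:
    - [1, 500, 10]
  variants:
    - [0, -40, somatic_candidate]   # 39 nt from the 3' end (negative = from 3' end)
    - [2, 60, null_set]             # 5'-proximal: invisible to the 3' kit
evaluate:
  detect_threshold: 0.05
lineage:
  min_alt_cells_per_layer: 2
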