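# Comparison report JSON schema

`ascbias compare --out report.json` (and `compare.ComparisonReport.to_json`)
writes one JSON object. Keys are sorted and NaN is serialized as `null`, so
identical inputs and seeds give byte-identical files.

```
{
  "seed": int,                       # replicate-draw seed
  "n_replicates": int,
  "populations": [str, ...],         # population order used throughout
  "reference_n_loci": int,           # loci in the full reference set
  "he_reference": {pop: float},      # mean 2p(1-p) per population, all loci
  "fst_reference": {"popA|popB": float},
  "reference_pca_variance_explained": [float, ...],
  "versions": {
    "<version name>": {
      "n_snps": int,
      "he_spearman_rho": float|null,        # array vs reference He ranks
      "he_regression":  {slope, intercept, r_squared, slope_se,
                         residual_variance},   # array He on reference He
      "fst_regression": {... same fields ...}, # over population pairs
      "frobenius_mean": float,  "frobenius_se": float,
      "partition_mean": float,  "partition_se": float,
      "branch_score_mean": float, "branch_score_se": float,
      "baseline_frobenius":    [float, ...],  # replicate-vs-replicate
      "baseline_partition":    [float, ...],  # distance distributions
      "baseline_branch_score": [float, ...],
      "pca_variance_explained": [float, ...],
      "he_array": {pop: float},
      "fst_array": {"popA|popB": float}
    }, ...
  }
}
```

Mean/SE pairs are over the `n_replicates` reference subsets matched to the
version's SNP count (SE = sd/sqrt(n)); the `baseline_*` lists hold distances
between replicate pairs (all C(n,2) pairs, subsampled to 1,000 with the
seeded stream when larger) and provide the boxplot null distributions.
`ComparisonReport.from_json` round-trips the file.
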