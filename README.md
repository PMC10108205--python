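# moranselect

Bayesian estimation and testing of selection coefficients from
Evolve-and-Resequence (E&R) allele-frequency time series.

`moranselect` models each biallelic locus as a continuous-time Moran chain
over allele copy numbers 0..N (fitness 1+σ on the focal allele, absorbing
boundaries, one generation = N Moran events) observed through binomial or
beta-binomial pool-seq noise. For every locus it:

1. evaluates the hidden-Markov marginal likelihood of the count series
   (forward recursion with matrix-exponential transition kernels computed
   by uniformization),
2. scans a coarse σ grid and refines to five points around the maximum,
3. fits the log posterior to a gamma log-density surface in fitness space
   `x = 1 + σ` by closed-form least squares, and
4. reports the posterior mean σ, the gamma shape/rate, and a log Bayes
   factor — the posterior odds of σ > 0 versus σ < 0 (the conventional
   "very strong evidence" cut-off is log BF ≥ 4.6 ≈ log(0.99/0.01)).

Loci whose observed frequency variance is below 0.01 are statistically
uninformative; they are flagged and retained in the output without
statistics.

A Gillespie simulator of the same Moran chain (plus pool-seq sampling)
generates sync-format test panels, so the entire pipeline is testable
without external data.

## CLI

Inference takes a sync file (`chrom pos ref A:T:C:G:N:del ...`, sample
columns in time-major blocks of replicates by default) and a flat
key-value config:

```
Population_size   300
Prior_parameters  0.001, 0.001
Generations       0, 15, 30, 45, 60
Replicates        5
```

```sh
# simulate a 100-locus panel under the base design (Ne=300, 5 replicates,
# 5 uniform time points over 0.2*Ne generations, 60x coverage)
moranselect simulate --preset base --scaled-sigma 10 --n-loci 100 \
    --seed 1 --out-prefix panel

# estimate selection coefficients and Bayes factors
moranselect infer --config config.txt --input panel.sync --output results.tsv

# self-validation: population-size misspecification + parameter recovery
moranselect validate --n-loci 100 --seed 1 --output report.tsv
```

`results.tsv` has one row per input locus:
`chrom pos mean_sigma log_BF alpha beta filtered degenerate`
(filtered/degenerate rows carry `NA` statistics).

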