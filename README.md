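# tadshift

Detection of **splits and mergers of topologically associating domains
(TADs)** between two Hi-C samples.

Most TAD callers describe a single sample.  `tadshift` asks a
comparative question: given per-chromosome contact matrices from two
biological conditions, which domains in one condition correspond to
*several* contiguous domains in the other?  Such events — one TAD
splitting in two, or two TADs fusing — accompany cell differentiation
and disease, and they are invisible to tools that only list domains per
sample.

## Method in brief

For a contact matrix `M` (`M[i][j]` = contact frequency of bins `i`,
`j`), TADs are called in four stages: per-bin contact *straps*
`S_i = {M[i,t] : L_i <= t <= R_i}` are delimited by change-point
analysis (their edges pile up at domain boundaries); the edge positions
are smoothed into probability profiles `E_L`, `E_R` by kernel density
estimation; each profile is denoised by a Bayesian product-partition
change-point model (Gibbs-sampled) into boundary densities `f_L`,
`f_R`; and a bivariate KDE over `(L_i, R_i)` pairs gives a pairing
density `f_P`, with a candidate domain `[m, n)` scored by

    P(m, n) = sum_{m <= i, j < n}  f_L(i) · f_R(j) · f_P(i, j)

Domains of one condition are then matched to the other condition's
densities by a greedy coding-tree walk, and each matched pair is scored
by the **corner split ratio**

    CSR = | mu_K(1)/mu_S(1) − mu_K(2)/mu_S(2) |

where, per condition, `mu_S` is the mean contact inside the matched
sub-domain squares and `mu_K` the mean over the rest of the big-domain
square (the "corners").  A genuine split/merger changes the corner
contrast; a stable sub-domain hierarchy does not.  Three alternative
scores (stratum-adjusted correlation, Laplacian eigenvector similarity,
average-hash image similarity) are provided, and a built-in Poisson
simulator (`log M[i,j] ~ Poisson(mu / |i−j|)` per domain) with known
merge truth supports ROC benchmarking and false-positive-rate
calibration without any external data.  See `docs/methods.md` for the
full model, parameter defaults, and known limitations.

## Worked example

```sh
# simulate a small two-condition pair with one known merger
tadshift simulate --out-prefix demo --n-tads 6 --size-min 80 \
    --size-max 120 --n-merges 1 --mu-min 3 --mu-max 3 --seed 12

# call TADs in condition 1
tadshift call-tads demo.c1.tsv --out-prefix demo.c1 --seed 1

# compare the two conditions
tadshift compare demo.c1.tsv demo.c2.tsv --out-prefix demo --seed 1 \
    --cutoff 0.05
```

The run above prints (log lines abridged):

```
simulate  | simulated 601-bin pair -> demo.c{1,2}.tsv
call-tads | called 12 TADs -> demo.c1.tads.bed
compare   | called 0 splits and 1 mergers -> demo.scores.tsv
```

`demo.truth.json` shows the merged pair covers bins 105-314 with its
junction at bin 195; the called line of `demo.scores.tsv` is

```
chrom  big_start  big_end  chain            chain_probability  csr        direction  called  split_sites
chr1   1050000    3140000  105-195;195-314  1.76188e-11        0.0767254  merger     1       1950000
```

i.e. the 2.09-Mb domain of condition 2 is matched by a chain of two
condition-1 domains meeting exactly at the true junction (bin 195 =
coordinate 1,950,000), and its corner split ratio 0.077 exceeds the
cutoff, so it is called a merger of condition 2 relative to
condition 1.  On simulated data the appropriate
cutoff comes from null calibration (`--calibrate`, or
`calibrate_cutoff` on `null_csr_scores`); the conventional 0.45 cutoff
for real vanilla-coverage Hi-C dumps is far above the simulation's CSR
scale (see `docs/methods.md`, *Known limitations*).

The same pipeline is available as a library:

```python
from tadshift import (SimulationConfig, simulate_pair, CallerConfig,
                      compare_conditions)
m1, m2, truth = simulate_pair(SimulationConfig(seed=11))
records, tads1, tads2 = compare_conditions(m1, m2, CallerConfig(seed=1))
```

## Benchmark reproduction

`scripts/acceptance.py` recomputes the simulation benchmark from
scratch — no external data, everything simulated at run time:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It simulates 20 replicate condition pairs (20 TADs, 5 adjacent pairs
merged, Poisson log-contact noise; runtime-reduced 100–200-bin TAD
sizes), runs TAD calling, coding-tree matching and all four differential
scores on every reference TAD, and reports the pooled AUROC per scorer
(`t1`–`t4`) plus the empirical false-positive rate of the CSR
classifier at the 0.45 cutoff on 1000 unchanged-TAD null scores (`t5`).
Runtime is roughly 10–15 minutes on one CPU.

## Input formats

* dense TSV contact matrix (n lines x n tab-separated numeric fields),
  or sparse `bin_i TAB bin_j TAB value` triples (mirrored on read);
* TAD calls are written as BED3 (+ probability column) and read back
  from BED, so calls from external TAD callers can be supplied to the
  comparison and Jaccard subcommands;
* split/merger records are written as a documented TSV.
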