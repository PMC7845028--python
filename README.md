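# degrepro

How stable is a list of differentially expressed genes (DEGs)? In
tumor-versus-normal RNA-seq, high biological heterogeneity means that two
labs comparing the *same* conditions on *different* subjects can publish
substantially different DEG lists — even with sample sizes well beyond the
usual n = 3. `degrepro` is a toolkit for quantifying exactly that, aimed at
bioinformaticians designing RNA-seq experiments or auditing the
generalizability of published DE results.

## What it does

The framework repeats one two-group DE analysis four times on **mutually
disjoint** subsets of n tumor and n normal samples (repeats I–IV), across a
grid of replicate numbers n (from 3 up to ⌊pool/4⌋), and measures:

- **Overlap rate** of k ∈ {2, 3, 4} DEG lists,
  `|L₁ ∩ … ∩ L_k| / |L₁ ∪ … ∪ L_k|`, averaged over all C(4, k) combinations;
- **DEG yield**, mean ± SD of the four list sizes per n;
- **Detection power**, the fraction of a reference DEG set — the
  intersection (or union) of the four lists at the maximum n — recovered at
  smaller n, with the remainder split into *matched* and *specific* DEGs;
- **Union/intersection ratio** (≥ 1), how many detected DEGs are
  sample-specific rather than shared;
- **Forensics of non-common DEGs** (genes significant in one repeat but not
  another): per-group %CV = 100·SD/mean of TMM-normalized counts, Tukey-fence
  outlier classification (mild beyond 1.5·IQR, extreme beyond 3·IQR),
  opposite-regulation detection, and an outlier-exclusion re-test that
  removes a gene's outlier samples and re-runs its exact test.

The DE engine is self-contained and edgeR-style: TMM normalization,
CPM-based low-count filtering, negative-binomial dispersion by conditional
maximum likelihood with empirical-Bayes moderation, an exact conditional
test on library-equalized group totals (the NB convolution conditional is a
beta-binomial), Benjamini–Hochberg FDR, and DEG calling at |log₂FC| ≥ 1 and
FDR < 0.05.

A synthetic-data module generates heterogeneous tumor/normal count matrices
with known truth — NB counts with gamma gene-wise dispersions, lognormal
library sizes, group-specific lognormal per-cell heterogeneity (tumor >
normal), and rare large outlier counts scattered independently across
cells — so the whole framework is testable without any data download.

## Worked example

```python
from degrepro import SimConfig, simulate_dataset, run_grid, build_reports

counts, ann, truth = simulate_dataset(SimConfig(seed=1))   # 2000 genes, 60+60 pools
grid = run_grid(counts, ann, n_values=[3, 5, 10], seed=1)
repro, power = build_reports(grid)
print(repro[["deg_count_mean", "deg_count_sd", "overlap_rate_k4",
             "union_over_intersection"]].round(3))
print(power[["power_intersection", "power_union"]].round(3))
```

```
    deg_count_mean  deg_count_sd  overlap_rate_k4  union_over_intersection
n
3            58.75         9.179            0.102                    9.786
5            87.25         4.272            0.190                    5.257
10          134.50         8.813            0.261                    3.826

    power_intersection  power_union
n
3                0.188        0.386
5                0.478        0.515
10               1.000        1.000
```

Reading this: at n = 3 the four disjoint repeats agree on only ~10% of the
DEGs they jointly report, and the union is almost 10× the intersection —
most calls are specific to the samples drawn, not to the conditions. By
n = 10 the overlap rate has more than doubled and the sample-specific excess
has shrunk, but is far from gone. Power is measured against the n = 10
reference here, so it reaches 1 at the top of the grid by construction.

The same pipeline is available from the shell:

```sh
degrepro simulate --seed 1 --out sim/
degrepro repro --counts sim/counts.tsv --annotation sim/annotation.tsv \
    --n-values 3,5,10 --seed 1 --out grid/
degrepro dispersion --grid-dir grid/ --counts sim/counts.tsv \
    --annotation sim/annotation.tsv --repeats II,III --out noncommon.tsv
```

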