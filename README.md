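# clustrep

Region-level ("nontemplate") replication analysis for genome-wide
association studies, built for the common situation where no single SNP
reaches genome-wide significance (p ≈ 1e-8) in every sample — polygenic
architecture, allelic and locus heterogeneity, different genotyping
platforms and sample-to-sample differences in linkage disequilibrium all
conspire against marker-level ("template") replication. Instead of asking
whether the *same SNP* replicates, the method asks whether independent
samples point at the *same chromosomal regions*:

1. **Per-SNP nominal tests.** Each sample yields a per-marker p-value —
   a 1-df allelic χ² on 2×2 minor/major allele counts for individually
   genotyped samples, or a two-sample t-test comparing per-pool
   allele-frequency estimates for DNA-pooling designs (Welch by default) —
   after excluding markers with minor-allele frequency < 0.01–0.02 or
   missing-call rate > 5%.
2. **Cluster scan.** Within each sample, a *cluster* is a maximal run of
   nominally significant markers (p < 0.05) in which every adjacent pair
   lies within 10 kb; clusters with ≥ 4 members tag a chromosomal region
   (≥ 3 within 25 kb is the conventional setting for sparser ~500K
   arrays). The scan is purely positional.
3. **Cross-sample overlap.** Regions tagged in *both* samples (closed
   intervals intersect) are the replicated regions; coverage is compared
   with the independence expectation, reported as
   100 × f_overlap / (f_A × f_B) percent.
4. **Monte Carlo nulls.** Significance is empirical: each trial redraws
   the observed number of "pseudo-positive" markers uniformly from the
   sample's full post-QC marker map, re-runs the scan (and, for the
   overlap null, the intersection), and the p-value is
   (n_exceed + 1)/(n_trials + 1) with ties counted as exceedances — so
   0 exceedances in 10,000 trials is reported as p < 0.0001.
5. **Gene annotation.** A replicated region is assigned to a gene when it
   intersects an exon or lies within 10 kb of either transcript end
   (a whole-gene-body mode is available).

A synthetic-data module generates two-platform datasets (controllable
shared-marker fraction, uniform null p-values, planted risk regions with
Beta(a, 1) p-values, pooled-frequency noise with SD 0.02, HWE genotype
counts) so the entire pipeline is testable without controlled-access
genotypes. The package also bundles the published European-American and
African-American cross-sample region tables from dual-platform
addiction-dependence GWA comparisons; intersecting their gene columns
reproduces the six cross-population genes (CADPS, CDH13, CSMD1, DSCAM,
MTMR7, UBASH3B).

## Worked example

```python
from clustrep import (
    ScanParams, select_nominal, find_clusters, summarize_overlap,
    overlap_regions, mc_overlap_null,
)
from clustrep.simulate import SimConfig, generate_dataset

cfg = SimConfig(seed=42)        # 2 x 100k markers, 10 chromosomes, 20 planted regions
ds = generate_dataset(cfg)
params = ScanParams()           # alpha 0.05, >=4 SNPs, <=10 kb gaps

na = select_nominal(ds.records_a)
nb = select_nominal(ds.records_b)
ra = find_clusters(na, params)
rb = find_clusters(nb, params)
summary = summarize_overlap(ra, rb, cfg.chrom_sizes)
mc = mc_overlap_null(ds.map_a, ds.map_b, params,
                     observed_stat=summary.n_overlap_regions,
                     n_trials=1000, seed=1,
                     n_positive_a=len(na), n_positive_b=len(nb))
```

With seed 42 this prints (via the fields of `summary` and `mc`):

```
positives: 5255 5247            # ~5% of 100k markers per platform
clusters: 59 65                 # per-sample cluster-tagged regions
overlap regions: 22  pairs: 22  # regions tagged in BOTH samples
enrichment: 6282%               # observed overlap vs f_A x f_B by chance
MC overlap: n_exceed 0, empirical p 0.000999   # = 1/1001, the floor at 1000 trials
recovered truth: 20 / 20        # all planted risk regions found
```

The 22 replicated regions cover 0.24% of the synthetic genome where
independence predicts 0.0039% — a 63-fold enrichment — and none of 1,000
marker-resampling trials reaches 22 overlaps, so the overlap null is
rejected at the resolution the trial count allows. Note the per-sample
clustering null is far less decisive (p ≈ 0.11 here): each planted region
adds only one cluster on top of ~50 chance clusters, which is exactly why
the method leans on cross-sample overlap rather than within-sample
clustering.

The same analysis runs from the shell on TSV/BED files:

```bash
clustrep simulate --out-dir sim --seed 42
clustrep cluster sim/assoc_a.tsv --out regions_a.tsv
clustrep cluster sim/assoc_b.tsv --out regions_b.tsv
clustrep overlap regions_a.tsv regions_b.tsv --chrom-sizes sim/chrom.sizes --out overlap.tsv
clustrep mc sim/assoc_a.tsv sim/assoc_b.tsv --out mc.json --n-trials 1000
clustrep annotate overlap.tsv --genes sim/genes.bed --out annotated.tsv
```

or end-to-end from a YAML config with `clustrep run config.yaml`.

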