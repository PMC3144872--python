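# Methods

## The statistical model

The analysis treats a GWAS sample as a marker map (all post-QC autosomal
SNPs with positions) on which each marker carries a per-SNP association
p-value. Three observations motivate region-level replication. First,
under a global null the nominally significant markers (p < α) are an
α-thinning of the map, so runs of significant markers with small gaps are
governed only by marker density. Second, true associations in regions of
linkage disequilibrium produce *locally co-significant* markers — clusters
— even when no single marker is genome-wide significant. Third, two
independent samples share true risk loci but not their stochastic noise,
so intersecting the cluster-tagged intervals of two samples suppresses
both assay artifacts and sample-specific haplotype-frequency noise.

The pipeline never models LD explicitly; clusters are defined purely
positionally, and LD enters only as the physical mechanism expected to
produce them in real data.

### Cluster definition

A cluster is a maximal run of nominally significant markers on one
chromosome in which every adjacent pair lies within `max_gap` bp,
containing at least `min_cluster_size` members. The chain is over
significant markers only: a non-significant marker between two
significant ones neither joins nor breaks a run. This is one of two
defensible readings of "separation from the nearest nominally significant
SNP"; it is adopted because the distance criterion references significant
markers only, and it makes the scan a pure function of the significant
subset (which the Monte Carlo resampling relies on). Gap comparison is
inclusive (a gap of exactly `max_gap` joins); significance is strict
(p = α exactly is *not* significant); two markers at the same position
are both counted. Region boundaries are the outermost member positions,
1-based and closed (BED output converts to 0-based half-open; the
conversion lives in one place in `io.py`).

### Overlap and enrichment

Within-sample regions are disjoint by construction, so the pairwise
intersections between two samples' region sets are themselves disjoint;
they are nevertheless merged into connected components as a safeguard,
and both the component count (`n_overlap_regions`) and the intersecting
pair count (`n_pairs`) are reported, because published counts of
"regions identified in both samples" do not pin down which convention was
used (a single region in one sample can pair with two regions in the
other). The enrichment ratio compares the genome fraction covered by
overlap with the independence expectation f_A × f_B, as a percentage
(100% = chance level). The independence product is the natural null for
two samples whose marker placements and noise are independent; it ignores
edge effects at chromosome ends, which are negligible at
region-size ≪ chromosome-size.

### Monte Carlo nulls

Both empirical nulls resample *labels*, not positions: each trial draws,
uniformly without replacement from the full post-QC marker list of a
sample, exactly as many "pseudo-positive" markers as were observed
significant, then re-runs the cluster scan (clustering null) or the scan
plus intersection in two independently resampled samples (overlap null).
The trial statistic for the clustering null is the cluster count; the
count of clustered SNPs is reported as a secondary statistic since the
notion of "extent of clustering" is not unique. The empirical p-value is
the add-one estimator (n_exceed + 1)/(n_trials + 1) with ties counted as
exceedances: it never returns 0, is conservative under the null, and at
0 exceedances in 10,000 trials equals 1/10,001, matching the conventional
"p < 0.0001" floor. Per-trial RNG substreams are derived from
(master seed, trial index) so results are independent of execution order
and reproducible; trials are vectorized by mapping all chromosomes onto
one global coordinate axis with inter-chromosome offsets larger than
`max_gap`, which makes run-splitting a single `diff` pass.

### Gene annotation

A gene is assigned to a region when the region intersects an exon or
lies within `flank` bp (default 10,000) of either transcript end. The
literal rule excludes intron-only overlaps; because published
region-to-gene tables do not expose exon-level detail, a
`gene_body_mode` switch treats [tx_start − flank, tx_end + flank] as one
interval (always a superset of the literal rule). Both flanks are the
same length, so coordinates suffice and strand is retained only for
reporting. Multiple transcripts per symbol are merged (union of exons,
outermost bounds) before indexing; queries go through an interval tree.

## Statistical units

* **Allelic χ²**: 1-df Pearson χ² on the 2×2 (minor, major) × (case,
  control) allele table, computed by the closed form
  n(ad − bc)²/(r₁r₂c₁c₂), no continuity correction — the standard
  large-sample allelic GWAS test. Monomorphic tables are rejected as
  degenerate and skipped upstream with a logged count.
* **Pool t-test**: two-sample t on per-pool minor-allele frequency
  estimates. The Welch statistic with Welch–Satterthwaite df is the
  default, since case and control pool counts and variances can differ;
  `equal_var=True` selects the pooled-variance Student variant. At small
  equal pool counts (4 vs 4) the Satterthwaite df makes Welch mildly
  conservative (empirical size ≈ 0.042 at α = 0.05 under equal-variance
  Gaussian noise), while the pooled variant is exact there; calibration
  tests therefore assert exactness for the pooled variant and bounded
  (never anticonservative) size for Welch.
* **QC filters**: retain maf ≥ maf_min AND missing_rate ≤ missing_max.
  The MAF threshold is per-sample configuration (0.01 or 0.02 depending
  on population). Records lacking QC fields pass those filters with a
  logged warning, so pre-filtered public association tables flow through.

## The synthetic-data generator

`SimConfig` defaults define the study conditions used throughout the
tests: 10 chromosomes × 20 Mb, 100,000 markers per platform (mean
spacing 2 kb), shared fraction 0.25 (about a quarter of autosomal
markers are shared between the ~900K and ~1M arrays the two designs
use), 20 planted risk regions with at least 6 markers per platform,
risk p-values from Beta(0.1, 1) (per-SNP power 0.05^0.1 ≈ 0.74 at
α = 0.05, closed form), pool noise SD 0.02 (the reported pool-to-pool
variation for validated pooling), 4 pools per group, and 1000 cases /
1000 controls for genotype simulation.

Planted regions are chosen among maximal runs of ≥ k markers *shared by
both maps* with adjacent gaps ≤ `max_gap`: a shared run is simultaneously
a dense chained stretch on each platform, so a planted region is
recoverable on both platforms by construction, without simulating LD.
Runs from the maximal-run decomposition are separated by more than
`max_gap`, giving disjoint, well-separated truth regions. All markers
inside a truth interval are risk markers on their platform.

What the generator deliberately does **not** reproduce: LD (markers are
independent given risk membership — real clusters arise from correlated,
not independent, signals), allele-frequency spectra, population
stratification, platform-specific probe artifacts, and non-uniform
marker spacing (real arrays are gene-dense). Passing tests therefore
demonstrate the *algorithmic* correctness and the *calibration* of the
resampling nulls under the stated generative model, not the power of the
method on any real cohort; recovery thresholds are properties of this
generator, not claims about any study's power.

Two derived configurations appear in the tests, chosen before freezing
the assertions and kept at the generator's 2-kb marker spacing:

* **pure-null calibration**: 2 chromosomes × 2.5 Mb, 10,000 markers per
  platform, no risk regions. At this density the null overlap count has
  useful spread (mean ≈ 16, SD ≈ 4 across datasets), so the empirical
  p-value is informative rather than pinned at 1; across 200 dataset
  pairs × 500 trials its fraction ≤ 0.05 must lie in the 99% binomial
  band around 0.05.
* **planted-signal recovery**: the defaults; the overlap stage must
  recover ≥ 80% of truth regions and the overlap null must return the
  attainable floor 1/(n_trials + 1) at 1,000 trials, across 20 seeds.

## Numerical and design choices

* Chromosome labels are normalized on ingest ("chr1" → "1"); analysis is
  autosome-only by default, with a flag to include other chromosomes.
* Zero-variance pool pairs raise a degenerate-variance error rather than
  returning a p-value; single-pool groups are rejected outright.
* Monte Carlo draws use `Generator.choice(..., replace=False)` on the
  marker index; drawn index sets are sorted so downstream run-splitting
  needs no re-sort of the full map.
* `empirical_p` is monotone non-increasing in the observed statistic for
  fixed trials, and the whole report bundle is a deterministic function
  of (inputs, parameters, seed) — both are asserted in tests.
* Problem sizes in tests and in `scripts/acceptance.py` (200 calibration
  datasets × 500 trials; 10–20 planted-signal seeds × 1,000 trials;
  100,000-marker type-I checks) were chosen so the full validation runs
  in about a minute while keeping binomial bands tight enough to detect
  miscalibration of a percentage point or less.

## Known limitations

* The positional cluster chain cannot distinguish phenotype-driven
  clustering from LD with stochastic case/control haplotype-frequency
  differences within one sample; that is precisely why the overlap null
  across independent samples carries the inferential weight.
* Overlap counting treats regions as replicated wherever they intersect
  by ≥ 1 bp; no reciprocal-overlap fraction is imposed.
* Gene symbols are compared as case-insensitive exact strings; aliases
  are not resolved.
* Meta-analytic combination of p-values and direction-of-effect
  concordance are out of scope by design.
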