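# Methods

This note documents the models, conventions and numerical choices behind
`connectoprs`, the assumptions they rest on, and the limits of what the
synthetic-data tests demonstrate.

## Networks and thresholding

A connectome is a symmetric nonnegative 90 × 90 matrix with zero diagonal
(AAL cerebrum parcellation; hemisphere-paired regions). NS weights are
positive integers (streamline counts), FA weights lie in (0, 1). Matrices
asymmetric beyond a relative tolerance of 1e−8 are rejected rather than
silently symmetrised — asymmetry at that level signals an upstream defect,
not noise.

Thresholding discards NS edges with weight ≤ *t* (default *t* = 5, sweep
1–12). The "≤ *t*" semantics, rather than "< *t*", keeps the default
consistent with the sweep. How a streamline-count rule should apply to
FA-weighted networks is genuinely underdetermined; here FA matrices inherit
the participant's NS-derived edge mask (both weightings describe one
tractogram), via `threshold_with_mask`. Thresholding is idempotent and
monotone, and commutes with subnetwork extraction; all three properties are
tested.

Subnetworks (default-mode 32, limbic 16, visual 16 nodes, both hemispheres)
are principal submatrices; the registry ships as a tab-delimited resource
and is validated at load.

## Graph metrics

Distances use lengths *l* = 1/*w* — stronger connections are shorter, the
standard convention for NS/FA connectomes. Implementation notes:

* **Shortest paths**: Dijkstra (scipy.sparse.csgraph) for distance matrices.
* **Betweenness**: Brandes-style accumulation over the shortest-path DAG
  derived from the distance matrix. Ties between path lengths are detected
  with relative tolerance 1e−9 (float sums of reciprocals make exact-length
  ties inexact, e.g. 1/6 + 1/3 vs 1/2). Values are unnormalised path counts
  with fractional credit for tied geodesics, endpoints excluded, each
  unordered pair counted once; means over nodes are taken afterwards.
* **Clustering**: geometric-mean triangle form on weights normalised by the
  network maximum — the de facto weighted-undirected standard, which reduces
  exactly to the edges-among-neighbours ratio on binary graphs. Degree < 2
  scores 0.
* **Characteristic path length** excludes infinite (disconnected) pairs and
  reports their count alongside the mean; a fully disconnected network is an
  error. Thresholded subnetworks *can* disconnect, and silent infinities
  would poison cohort means.
* **Global efficiency** averages 1/*d* over ordered pairs with disconnected
  pairs contributing 0; **local efficiency** is the global efficiency of the
  neighbour-induced subgraph (0 for degree < 2).

Every metric is validated against exhaustive path-enumeration oracles on
hundreds of ≤ 6-node graphs (agreement within 1e−9), against networkx on
larger graphs, and against scale/permutation invariance properties:
multiplying weights by *c* leaves clustering, betweenness and degree
unchanged, scales strength and efficiency by *c*, and path length by 1/*c*.

**Redundancy screen.** Pairwise Pearson correlations of the five summary
metrics across participants; metrics are visited in the priority order
strength, clustering, betweenness, path length, global efficiency, and kept
only if |*r*| < 0.85 with everything already kept. The priority order is a
tie rule the source procedure leaves open; this one keeps the metric set
that such screens typically retain (path length and global efficiency
correlate near −1 and lose to strength). Constant columns give undefined
correlations, reported as NaN and never triggering a drop.

## Hubness and connectivity classes

Hubness is the per-participant average of degree, strength, betweenness and
local efficiency, each divided by its across-node maximum so the four
ingredients weigh equally. A complete graph has identically zero
betweenness; the all-zero ingredient contributes zero (with a warning)
rather than erroring, so symmetric graphs stay well defined. Hubs are nodes
whose participant-mean hubness is ≥ mean + 1 SD across nodes; the SD is the
sample (n−1) standard deviation (unspecified upstream; fixed here and
documented). Zero variance across nodes yields an empty hub set with a
warning. Hub sets are computed per weighting on the default-thresholded
whole-brain network.

Edge classes partition all node pairs — rich-club (hub–hub), feeder
(hub–non-hub), local — and class connectivities are per-participant weight
sums. Conservation (rich + feeder + local = total weight) is asserted
exactly in tests for every participant, weighting and threshold.

In large simulation runs the hubness average uses a subsample of
participants (30–60 in the shipped experiments) before class connectivities
are computed for everyone; hub sets are stable under subsampling (the planted community is
recovered exactly from 8–30 participants in tests), and this keeps the
betweenness/local-efficiency cost of 562-participant replicates manageable.

## Polygenic scores

QC keeps records with MAF ≥ 0.1 and INFO ≥ 0.9. Clumping is greedy by
ascending p (position and id break ties, making the scan deterministic):
each index SNP removes unprocessed SNPs within ±500 kb on the same
chromosome with dosage *r*² ≥ 0.1. The *r*² cutoff is configurable — the
source recipe fixes only the window — and a cutoff > 1 disables clumping
entirely (tested). The APOE exclusion interval defaults to
chr19:44,400,000–46,500,000 (GRCh37 convention), configurable.

Scoring uses the mean-per-allele convention
score*ᵢ* = Σ*ⱼ* dosage*ᵢⱼ*·β*ⱼ* / (2·*mᵢ*), with *mᵢ* the individual's
non-missing SNP count; a sum convention is available by flag. Effect sizes
are re-oriented to the panel's counted allele during alignment (β negated
for swapped records), which makes scores exactly invariant to how the input
file orients its allele columns; strand-ambiguous (A/T, C/G) records are
dropped. Individual-level QC (call rate ≥ 95%, heterozygosity ±3 SD, HWE
p > 5 × 10⁻⁷) is provided as an optional pre-filter, not a core stage.

The grid is 20 definitions (genome-wide + nine pathways, each with and
without APOE) × 8 thresholds = 160 columns, each with its SNP count.

## Association scan

Each test is a partial Pearson correlation between a phenotype and a score,
residualising both on sex and scan type; p-values use the t-distribution
with n − k − 2 df. Cook's distances come from the OLS regression of the
phenotype on score + covariates (the covariate-adjusted model — the
alternative bivariate form is the looser reading of an underdetermined
procedure), removed in a single pass at D > 3 × mean(D), independently per
test pair. BH-FDR runs within each threshold's family (all phenotypes ×
the 10 APOE-included scores). minP permutes participant rows of the
phenotype (scores stay attached to covariates), recomputes the 8-threshold
scan per permutation, and corrects each observed p against the permutation
distribution of the minimum; the default 10,000 permutations shrink to
1,000 in the calibration experiments. Two-sided p-values throughout. The
Cook's filter is *not* re-run inside permutations: refiltering would break
the exchangeability of the permuted samples, and the observed-data filter
is part of the statistic being calibrated, not of the null resampling.

### Known property: trim-then-test is anticonservative

Removing the most influential observations and then testing at unadjusted
df inflates evidence: on clean null data at n = 562 the filtered test
rejects at ~12% for nominal 5%, and a true partial r = −0.19 is estimated
around −0.22 (the filter removes exactly the points that weaken a fit; the
distances themselves agree with statsmodels to machine precision). Two
consequences for this package:

* calibration experiments that validate the *error control of BH-FDR and
  minP* run with the filter disabled (`run_scan(cooks_factor=None)`), so the
  procedures receive valid p-values — with the filter on, the measured
  family error reflects the trimming, not the corrections;
* recovery experiments that run the full filtered scan detect planted
  effects reliably but report estimates biased away from zero by ≈ 0.03–0.04
  at n = 562. Users analysing clean data should prefer `cooks_factor=None`;
  the filter is a robustness device for data with genuine gross outliers.

## Synthetic data

The generator emulates the study conditions, not anatomy: 562 participants
(62% male, 39% sixty-direction scans), 90-node connectomes from a
stochastic block model in which a 13-node hub community receives inflated
connection propensity (×2.5 per hub endpoint, rescaled to an overall edge
density of 0.30) and inflated NS weight (×1.6 per hub endpoint). NS weights
are log-normal (median 25, σ = 0.8) rounded to integers ≥ 1; FA weights are
Beta(8, 8) shifted up slightly on hub edges, sharing the NS edge support.
Sixty-direction scans multiply NS weights by 1.05 so covariate adjustment is
testable. Effect planting mixes the phenotype's rank-based normal scores
with independent noise (Gaussian copula), giving exact control of the
target correlation for arbitrary phenotype marginals. Genotype panels place
blocks 2 Mb apart; within a block every SNP copies a latent block haplotype
with probability *r*²^(1/4) per haplotype, giving every pair the same
expected dosage *r*². Summary statistics are marginal regressions of a
standardised liability (heritability 0.5) computed on the panel itself, so
effect sizes and p-values are mutually consistent, and non-causal SNPs have
uniform p-values by construction. All randomness descends from one integer
seed via `numpy.random.SeedSequence` spawning in a fixed order (hubs,
covariates, participants).

What the generator does **not** reproduce: anatomical edge geometry,
realistic LD maps or allele-frequency spectra, distance-dependent
connection probability, site/motion artefacts, or the empirical NS/FA
weight distributions of any real cohort (these are unpublished for the
motivating study; the defaults above are field-plausible choices, fixed
once). Passing tests therefore demonstrate *procedural* correctness and
statistical calibration at realistic effect sizes and sample sizes — not
that any particular anatomical claim would replicate.

### Simulated score panels

Large calibration experiments bypass genotypes and simulate the 160-column
score grid directly: per definition a base Gaussian vector, mixed with
fresh noise per threshold (r ≈ 0.9 to the base, emulating the strong
dependence of scores across thresholds) and attenuated copies for the
APOE-excluded variants (r ≈ 0.95). Planted definitions carry the planted
vector exactly at every threshold. Genotype-backed scoring is exercised
separately by the PRS tests and the pipeline's `score_source: genotypes`
mode.

## Problem sizes in shipped experiments

Calibration and recovery experiments use: 500 replicates (tests) / 200
(acceptance script) for null error rates with 1,000 permutations for minP;
50 seeds (tests) / 30 (script) for planted-effect recovery at n = 562 with
an 11–12-phenotype × 10-score family at the top threshold; a
100-participant cohort for conservation across all 12 thresholds; 200
random ≤ 6-node graphs for oracle equivalence. These sizes give Monte-Carlo
standard errors comfortably below the margins being asserted while keeping
a full run in minutes on one CPU.

## Known limitations

* The AAL-90 registry is the only atlas shipped (the registry format is
  extensible).
* LD in synthetic panels is block-uniform; clumping behaviour near block
  boundaries with realistic LD decay is untested.
* The minP observed p-values come from the Cook's-filtered scan while the
  permutation distribution is unfiltered (see above); with the filter
  disabled the two coincide.
* Pathway SNP lists are user-supplied; no gene-to-SNP mapping is bundled.
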