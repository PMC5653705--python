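# Methods

`gggqtl` implements the statistical pipeline of a *generalized genetical
genomics* (GGG) experiment on seed metabolomes: a biparental RIL population
is split across developmental conditions with balanced allele frequencies,
so that genetic (G), environmental/developmental (E) and interaction (G×E)
effects on every metabolite and germination phenotype are estimable from a
single experiment. This note records the models, the defaults and the design
choices made where the procedure was genuinely open.

## Synthetic study generator

The generator emulates the statistical skeleton of a tomato seed-germination
study: ~100 F8 RILs from a *S. lycopersicum* ('MM') × *S. pimpinellifolium*
('Pimp') cross, genotyped at 865 markers on 12 chromosomes, assayed by
GC-TOF/MS for ~167 metabolites (66 identified) in two conditions — dry seed
and 6 h imbibed — with each line measured in exactly one condition (50/50).

* **Map** (`simulate_map`): markers distributed near-equally over
  chromosomes, positions uniform-ordered; default 12 chromosomes × 120 cM.
* **Genotypes** (`simulate_ril_genotypes`): each line is a homozygous mosaic
  generated by a Markov walk per chromosome. Adjacent-marker recombination
  uses the Haldane map function (no interference),
  r = (1 − e^(−2d/100))/2, expanded for RIL-by-selfing to
  r_RIL = 2r/(1+2r). Residual F8 heterozygosity (~0.8%) is not modelled;
  markers are biallelic, coded +1 (MM) / −1 (Pimp). The symmetric coding
  makes the interaction column orthogonal to the main effects under a
  balanced design.
* **Metabolome** (`plant_metabolome`): log2-scale abundances from
  y = β₀ + β_E·e + β_G·g + β_G×E·e·g + λ_b·u_b + ε, with e ∈ {0,1}
  (dry = 0), g ∈ {±1}, ε ~ N(0, σ²). Pathway modules are emulated by
  per-block latent factors u_b shared across metabolites of a block, with
  loading λ = σ·√(ρ/(1−ρ)) so the within-block correlation of null
  metabolites is ≈ ρ (default six blocks of 10 at ρ = 0.7). Missingness is
  completely at random (the study reports no mechanism). The generating
  truth table is returned for recovery tests.
* **Phenotypes** (`plant_phenotypes`): germination traits (Gmax, t10⁻¹,
  t50⁻¹, MGR, AUC) are sparse linear combinations of metabolite columns
  (≤ 20% nonzero weights) plus Gaussian noise; Gmax is affinely squashed and
  clipped into [0,1]. Weights are recorded for canonical-weight recovery
  tests.

The generator reproduces the *statistical* structure only: no
chromatography, retention indices, segregation distortion, or mechanistic
seed biology. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not agreement with any real
metabolome.

## Balanced allocation

A GGG design confounds line and condition unless allele frequencies are
balanced. `design_score` sums, over markers, the squared discrepancies
between the MM-allele frequencies of the two subpopulations and the whole
population: Σ_m (f_A−f_B)² + (f_A−f_pop)² + (f_B−f_pop)². The published
procedure states the balance goal without printing an objective; this
squared-discrepancy form is the simplest function that is zero exactly at
the stated ideal. `allocate` minimizes it by restarted pairwise-swap
hill-climbing from random balanced starts (default 10 restarts), accepting
any strictly improving swap in seeded random order; on ≤ 12 lines it matches
exhaustive enumeration in ≥ 9/10 trials (tested). Genome-weighted or
marker-of-interest designs are out of scope.

## Preprocessing

Order fixed as: log2 transform → per-metabolite median centering (the
log-scale equivalent of dividing by the metabolite's median across the
sample set) → single-pass Z-score outlier removal (|Z| > 3; note a lone
outlier among n points has |Z| ≤ (n−1)/√n, so tiny vectors cannot lose
points) → sequential-KNN imputation. Sequential KNN orders variables by
missingness (least first) and imputes each from the k (default 10) nearest
complete-or-imputed variables by Euclidean distance on the target's
observed samples, 1/distance-weighted. The chain is idempotent on its own
output (tested).

Differential abundance between conditions: the two-group unpaired **rank
product** (geometric mean of fold-change ranks over between-group sample
pairings, subsampled to 100 pairings for large groups) with a
label-permutation null — condition labels shuffled, RP recomputed, pooled —
giving a permutation p and a false-positive-proportion estimate
pfp = E[null count ≤ RP]/rank(RP); and per-metabolite one-way ANOVA with
Benjamini–Hochberg correction. BH is the multiple-testing procedure
everywhere an FDR is mentioned.

## QTL scan

Per trait × marker, ordinary least squares of
y = β₀ + β₁e + β₂g + β₃(e:g) + ε. Each term's significance is the partial
F test of dropping that single 1-df term from the full model, which equals
the squared t of its coefficient; LOD = −log10(p), p floored at 1e−15
(LOD ceiling 15). Allele effects per condition follow from the coding:
effect_dry = β₂, effect_imbibed = β₂+β₃; the reported *normalized* effect is
the allele effect divided by the trait's observed range (the published
sentence inverts this ratio, which diverges for small effects; no numeric
equivalence with the published effect tables is claimed). The scan is
vectorized via batched normal equations over markers and traits and is
numerically identical (≤ 1e−8) to the per-pair loop; markers monomorphic
within a condition yield NaN without aborting.

**Permutation threshold.** Genotype line labels are shuffled *within*
condition — preserving the E structure under the null of no G/G×E — and the
genome-wide max LOD over the G and G×E terms is recorded per trait; the
threshold is the empirical (1−α) quantile of the pooled maxima (default
α = 0.01, 1000 permutations), shared across all traits of a matrix. The E
term is excluded from the null family because the shuffle preserves it by
construction.

At the study's dimensions this procedure yields a threshold near 4.8–4.9,
not the oft-quoted LOD 3: per-marker null LODs are exactly uniform (tested),
and an Ornstein–Uhlenbeck crossing-rate bound for a dense ~1440 cM RIL
genome puts the α = 0.01 genome-wide quantile at ≈ 4.9. A 99th-percentile
max-LOD of ≈ 3 would correspond to only ~10–12 effectively independent
tests (one per chromosome). LOD 3 instead sits near the *median* of the
same null max-LOD distribution, or arises from count-based permutation-FDR
schemes whose threshold depends on the observed signal richness; the
package deliberately ships the distribution-quantile definition and exposes
the full null sample (`ThresholdResult.null_max_lod`) so any summary can be
recomputed.

QTL calls merge supra-threshold markers per chromosome (one call per
trait × term × chromosome: peak marker, 1.5-LOD support interval, signed
effect, elevating allele). Hotspots bin peaks in 10 cM windows and flag bins
above the 95th percentile of per-bin trait counts; mQTL/phQTL overlap counts
metabolite peaks within 10 cM of each phenotype peak. Interval mapping,
multi-QTL models and epistasis are out of scope.

## Correlation network

All-pairs Spearman with average ranks on pairwise-complete observations
(≥ 4 shared samples), t-approximation p-values, BH over unique pairs.
Networks keep edges with |Rs| ≥ threshold (default 0.5; absolute values —
whether the published network used signed or absolute correlations is
unstated, so this is config-switchable) that are also BH-significant at
0.05. Heat-map ordering is average-linkage agglomerative clustering on
1 − Rs. PCA is a column-centered SVD. The threshold sweep rebuilds the
|Rs|-network on a 0–1 grid and reports density, clustering coefficient,
average degree, within-component average path length, component and edge
counts, for the observed matrix and for column-permuted randomizations
(destroying correlation, preserving marginals; default 100 replicates).

## DPClus clustering and enrichment

DPClus grows clusters from the highest-degree seed of the working graph,
admitting the highest-priority neighbour while the cluster keeps density
d = 2|E|/(|N|(|N|−1)) ≥ d_in and the entrant's cluster property
cp = e_nk/(d·|N|) ≥ cp_in (defaults 0.5/0.5; the published study fixes
d = 0.5 but never prints its cp, so no numeric equivalence with its six
clusters is claimed — the six-block *synthetic* recovery is what the tests
assert). Priority is: edges into the cluster, then shared neighbours with
the cluster periphery, then degree, then node id. The shared-neighbour key
matters: without it, a bridge node adjacent to a high-degree seed is
admitted while the admission criteria are still vacuous (cluster size 1)
and two cliques weld together. Overlapping mode removes only a cluster's
internal edges, letting periphery nodes seed later clusters (metabolic
pathways overlap); non-overlapping mode removes the nodes. Emitted clusters
have size ≥ 2 and density ≥ d_in, and each is maximal with respect to the
working graph it was extracted from (`working_edges` snapshots).

Enrichment is the one-sided hypergeometric upper tail per
(cluster, pathway), sizes restricted to the declared universe, BH across
all tested pairs. Pathway sets are local GMT files; no online database
access.

## Integration

Pairwise metabolite–trait association uses Spearman (matching the
correlation sections) with BH over all pairs, reported with
pct_variance = 100·Rs². CCA maximizes corr(Xa, Yb) via orthonormal bases
(SVD) of the centered blocks and an SVD of their cross-product; canonical
correlations are reported with 100·ρ² as variance explained. Because the
study regime has more metabolites than samples (167 > 100) — where raw CCA
is vacuous (ρ₁ = 1) — X is first reduced to its leading principal
components capturing a configured variance fraction (default 0.9) and the
weights are mapped back to metabolite space; ridge-regularized CCA would be
an alternative but is not the default. CCA on raw values (the classical
Pearson-based formulation); rank-transforming first is possible upstream.
PLS regression (NIPALS, via scikit-learn) with seeded K-fold
cross-validation reports PRESS, RMSEP and Q² = 1 − PRESS/TSS per component
count, as the out-of-sample check on the in-sample CCA correlation.

## Numerical conventions

* p-values floored at 1e−15 before −log10 (LOD ceiling 15).
* Quantiles are empirical (`numpy.quantile`, linear interpolation);
  α = 1 gives the minimum of the null maxima.
* Ties: average ranks everywhere; DPClus ties broken as above; optimizer
  swap order is a seeded shuffle.
* Empty graphs report 0 for density/degree/edge counts and NaN for path
  length; all-missing metabolite columns are dropped with a warning;
  monomorphic markers yield NaN fits, never aborts.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline driver spawns per-stage child seeds from one master seed and
  records them in the run manifest.

## Problem sizes used in the test and acceptance suites

Unit tests run on small synthetic instances (tens of lines/markers).
The statistical suites use: 5 seeds × 1000 permutations at the full study
dimensions for the threshold; 100 replicates for planted-QTL recovery
(β_G = σ, detection = significant call within 10 cM with correct sign);
200 null traits for genome-wide false-positive control; 100/30 replicates
for BH and rank-product null control; and a 6-block × 6-metabolite,
100-sample model for structure recovery.

## Known limitations

* The generator's residual variances and effect sizes are free parameters,
  not estimates from real data; the published study deposits no raw
  matrices, so its specific correlations, QTL maps and cluster memberships
  are not reproducible here and are not claimed.
* The permutation threshold definition is the field-standard genome-wide
  quantile; see above for why this lands near 4.9 rather than 3 at these
  dimensions.
* Sequential KNN is a deterministic stand-in for the loosely specified
  imputation of the original workflow.
* DPClus cluster membership can depend on tie-breaking in near-symmetric
  graphs; determinism is guaranteed, uniqueness of the optimum is not.
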