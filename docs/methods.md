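# Methods

This note documents the statistical models behind each panelforge stage,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that affect
results.

## Synthetic data

**Structured populations.** Population structure is simulated under the
Balding–Nichols model: for each locus an ancestral frequency *p* is drawn
Uniform over `ancestral_maf_range` (default 0.05–0.5, matching the MAF
floor applied during filtering so that simulated panels resemble filtered
real panels), and each population's frequency is a Beta draw with shapes
`p(1−F)/F` and `(1−p)(1−F)/F`, whose among-population variance corresponds
to a fixation index of `F = fst_target`. Genotypes are Hardy–Weinberg
binomial draws within populations. A configurable fraction of loci
instead receives frequencies that increase linearly with normalised
longitude across the population coordinates, giving the spatial signal
exploited by the continuous assignment stage. Multi-locus Weir–Cockerham
θ on these simulations recovers `fst_target` within ±20% relative at
5,000 loci (tested at F ∈ {0.02, 0.05, 0.2}).

**Pedigrees.** Founders are HWE draws from a supplied frequency table;
offspring inherit one uniformly chosen allele per parent. Genotyping
error is a per-allele channel: each stored allele is independently
replaced, with probability `genotyping_error`, by a random population
allele. This makes the parent–offspring opposing-homozygote rate an exact
function of (p, e) that the tests verify by enumeration. Missingness
masks calls uniformly at `missing_rate`.

**X-linked loci.** Diagnostic loci plant the canonical felid sexing
pattern: every female homozygous for the reference allele, every male
carrying at least one alternative allele. Males are emitted as ordinary
diploid calls — hemizygosity is *not* modelled, consistent with
diploid-called male genotypes at X loci in real panel data.

**What the generator does not emulate:** sequencing reads and base
quality, allelic dropout correlated with depth, linkage (loci are
independent given population frequencies), recombination maps, admixed
individuals, and ascertainment bias. Passing tests therefore demonstrate
correctness of the estimators and the selection/assignment machinery
under idealized sampling, not performance on any particular real dataset.

## Filtering

Steps run in a fixed order: INFO hard filters → biallelic → QUAL →
depth → MAF → site missingness → sample missingness → LD pruning →
repeat-interval exclusion → exact HWE. The order follows the narrative
sequence of the standard VCFtools/PLINK cascade; sample missingness is
evaluated after the site filters so that a sample is judged on the loci
that survive. Thresholds are strict (`≥ 5%` site missingness removes a
site at exactly 5%).

The HWE test is the exact conditional test: all heterozygote counts
compatible with the observed allele totals are enumerated and the
configurations no more probable than the observed one are summed
(two-sided point-probability tail, no mid-p correction). It equals a
full-enumeration oracle for every table with n ≤ 10.

LD pruning slides a window of `ld_window` loci advanced by `ld_step`;
while any surviving pair inside the window has r² above `ld_r2_max`, the
lower-MAF member of the currently worst pair is removed (tie → later
genomic position). The victim rule is the common PLINK-style convention;
since tools differ in tie-breaking, it is stated here and pinned by a
brute-force-oracle test. Pairs with an undefined r² (constant vector)
exert no pruning pressure.

Coordinates: VCF positions are 1-based, BED intervals half-open 0-based;
a site at position *pos* is excluded when `start < pos ≤ end`.

## Population-genetic statistics

Expected heterozygosity is Nei gene diversity 2pq without sample-size
correction, so a balanced biallelic locus attains exactly 0.5 — this
convention pins the attainable range maximum. Weir–Cockerham variance
components use the two-level (population / individual / within) 1984
estimator; pairwise tables report both the weighted multi-locus
θ = Σa/Σ(a+b+c) and the arithmetic mean of per-site θ, since published
"mean F_ST" tables do not always state which estimator variant they use.
Loci with fewer than two typed diploids in either group are skipped for
that pair.

p-distances are mean |dᵢ − dⱼ|/2 over co-typed loci (pairwise-complete
missing handling). The Mantel statistic is the Pearson correlation of
strict upper triangles, with one-sided p = (1 + #{r_perm ≥ r_obs}) /
(n_perm + 1) under joint row/column permutation; its type-I error and
p-value uniformity are verified by simulation, and the statistic is
cross-checked against scikit-bio. Haversine distances use the IUGG mean
Earth radius 6371.0088 km. Windowed heterozygosity counts heterozygous
calls per non-overlapping window (default 200 kb) divided by window
length — a genotype-count substitute for SFS-based estimators, adequate
for comparing individuals on a common call set but not calibrated for
absolute genome-wide heterozygosity when calls are sparse.

## Panel selection

Top-N selection ranks loci by per-site θ within each group pair
(descending, ties broken by genomic order for determinism), keeps the top
N (default 50) per pair and deduplicates the union while recording every
(pair, rank, θ) membership. The reduced-subset search draws uniform
subsets and scores each by the mean silhouette coefficient of the true
labels on the first two principal components of the subset genotypes — a
label-aware formalisation of "strongest group differentiation in a PCA";
the scorer is a plain function and can be swapped. The sexing rule
returns *all* loci where every typed female is homozygous for one shared
allele and every typed male carries the other allele; narrowing to loci
near known sex-linked genes is annotation work outside this package's
scope.

## Forensic power

PIC, PID and PIDsibs are the standard plug-in functions of allele
frequencies given above; no small-sample (unbiased) corrections are
applied, because the attainable endpoint values of the uncorrected
formulas (0.375 / 0.59375 / 0.375 at p = 0.5) are the ones conventionally
printed for SNP panels. Non-exclusion probabilities are computed by exact
enumeration of Mendelian-compatible genotype configurations under HWE —
the same quantities as the Jamieson–Taylor closed forms — and verified
against an independent allele-level enumeration on a frequency grid.
Combined panel values are products across loci (independence is assumed;
LD pruning upstream is what makes that defensible). Cumulative identity
curves sort loci most-informative-first by default (configurable to input
order); the reported count is the smallest k whose product falls strictly
below the cutoff (default 10⁻⁴).

## Assignment

PCA standardises dosages (per-locus mean imputation of missing calls,
unit variance) and fixes component signs by making the largest-magnitude
loading positive. The cluster-number scan runs k-means (10 restarts,
fixed seed) for k = 1..k_max and minimises BIC(k) = n·ln(WSS_k/n) +
k·ln(n); the formula is stated because reference implementations differ.
The scan should be fed ~20 retained PCs: in very low dimension the WSS
gain from splitting a true cluster can exceed the ln(n) penalty, biasing
k upward, while in higher dimension the penalty dominates (the pipeline
uses min(20, n−1)).

DAPC-style classification fits linear discriminants on retained PCs and
reports in-sample reassignment; with many PCs relative to samples this
estimate is optimistic (the null tests use few PCs for exactly that
reason). Leave-one-out likelihood self-assignment recomputes group
frequencies without the query, floors frequencies at 1/(2n+1) to keep
unseen alleles finite, sums log HWE genotype probabilities and applies a
uniform prior; an assignment is "robust" above a 0.8 posterior. Because
the posterior is relative across represented groups, samples from an
unrepresented population can still look confident — the tests assert only
that their posterior support is systematically weaker than members'.

Continuous assignment replaces an MCMC sampler with a kernel-smoothed
grid likelihood honouring the same contract (reference allele
frequencies + geography + spatial smoothing → per-sample location
posterior): cell frequencies are Gaussian-kernel weighted averages of
reference dosages on Haversine distance (default bandwidth 250 km, with a
1-ref/1-alt pseudocount), the query's HWE likelihood over cells is
normalised into a posterior, and the MAP cell centre (posterior-mean
coordinate on exact ties) is the point estimate. An optional cell mask
supports excluding non-habitat (e.g. ocean) cells. The bandwidth should
exceed the grid cell size; as it shrinks toward the inter-sample spacing,
cell frequencies approach the nearest reference's genotype.

## Kinship

Identity matching declares two profiles the same individual at ≥ 90%
co-typed loci and ≤ 5% mismatches among them. Parentage LOD scores use
Mendelian transmission probabilities with a class-II error
simplification: with probability e the offspring genotype is a random
HWE draw, so the H1 likelihood is (1−e)·T + e·P_HWE and opposing
homozygotes yield −∞ only at e = 0. Natural log is the default base
(configurable to log₁₀). Critical Δ values are simulated: offspring from
HWE parent pairs, candidate pools of 5 with the true parent present at
`prop_parents_sampled` (default 0.2), error rate 1%, and the threshold is
the smallest Δ at which the precision of accepted assignments reaches the
stated confidence (strict 0.95, relaxed 0.80). The default simulation
size is 10,000 offspring — a scaled-down counterpart of the 100,000
conventionally used, which Monte-Carlo stability tests show reproduces
thresholds to well within 20% across seeds.

Relationship classification evaluates the four k-coefficient categories
U (1,0,0), HS (0.5,0.5,0), FS (0.25,0.5,0.25), PO (0,1,0) with the
standard unordered-pair likelihood tables, the same error mixing, and a
simulation-based consistency test (1,000 pairs per alternative category,
α = 0.05). HS/FS confusions are expected at realistic locus counts; the
tests assert only that FS wins most often for true sibs and never ranks
below U. No continuous relatedness estimator or sibship-partitioning
reconstruction is provided.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → filter → F_ST → select → power →
assign → kinship, writing per-stage TSV/JSON artifacts and a manifest
with parameters, seed, version and sha256 checksums; identical configs
reproduce identical checksums. All randomness flows from the single
config seed. Default simulated problem sizes (5 populations × 12
samples, 2,000 loci; 10,000 simulated offspring) were chosen as the
smallest sizes at which the panel-scale properties above are stable.

## Known limitations

* Loci are treated as independent everywhere downstream of LD pruning.
* F_ST confidence intervals (jackknife) are not implemented.
* The continuous assigner is a smoothed-likelihood approximation, not a
  spatial CAR-prior posterior; its absolute km errors are not comparable
  to published MCMC-based results.
* Forensic statistics use population frequencies without θ-correction
  (no NRC-II subpopulation adjustment).
* X-linked male hemizygosity is not modelled.
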