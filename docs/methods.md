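# Methods

This note documents the models and numerical choices behind strmix: what is
assumed, what the defaults mean, and what the synthetic-data tests do and do
not demonstrate about real data.

## The admixture model and its sampler

The clustering model is the standard admixture model for unlinked
multi-allelic loci. With K clusters, L loci and J_l alleles at locus l:

- cluster allele frequencies p_kl ~ Dirichlet(λ, ..., λ) per cluster and
  locus (λ = 1 by default: a flat prior);
- individual ancestry q_i ~ Dirichlet(α, ..., α) (symmetric);
- each of the 2L allele copies of individual i has a latent origin
  z ~ Categorical(q_i) and the observed allele is a draw from p_{z,l}.

The Gibbs sampler cycles the three full conditionals (origins, frequencies,
ancestries). In the no-admixture variant a single origin cluster is sampled
per individual from its marginal genotype likelihood, and q_i is the
indicator of that cluster. Missing calls contribute to no count and no
likelihood term. The per-sweep data log-likelihood is the mixture likelihood
log P(X | P, Q) with origins integrated out, recorded before the sweep's
updates.

**α (admixture concentration).** Default 1.0, fixed. Low α says most genomes
are unadmixed; α > 1 says most are admixed. With `infer_alpha=True` a
symmetric Metropolis step on log α (uniform prior on (0, 10], proposal sd
0.3 on the log scale) updates α each sweep. On data dominated by pure
individuals the posterior concentrates near zero, which sharpens pure
individuals' posterior-mean ancestry onto the corners; with α fixed at 1 the
Dirichlet mean (α + n)/(Kα + 2L) keeps even a perfectly assigned individual
about 1/(2L + 2) away from a corner. Parameter-recovery analyses in the test
suite and acceptance script therefore run with α inference enabled; the
library default stays fixed because inference is the more expensive and more
opinionated choice.

**Run length.** Defaults are desk-scale: 500 sweeps with 200 burn-in
(300/100 in the recovery tests). These are the package's chosen working
sizes for the synthetic datasets it ships with, where traces equilibrate
within tens of sweeps; production runs on real data should scale `sweeps`
and `burnin` up through the config (the sampler is O(N·L·K) per sweep).

**Model choice.** L(K) is estimated from the post-burn-in trace as
mean − var/2 (sample variance), the usual trace-based approximation to the
model log-probability. ΔK is the mean absolute second difference of L(K)
across replicates divided by the replicate standard deviation at K; it is
undefined at the boundary K values and reported as +inf (with a warning)
when replicates are identical. ΔK cannot endorse K = 1; the L(K) table is
emitted alongside so a flat likelihood profile can be recognised directly.

**Label alignment.** Replicate runs are aligned to a reference by the
cluster permutation maximising Σ_i q_i^ref · q_i^perm, enumerated over all
K! permutations (exact; practical for the K ≤ 8 this package targets).

## Ordination

Correspondence analysis operates on the individuals × alleles dosage table
(0/1/2 copies). Rows and columns are weighted by their masses; the SVD of
the standardised residual matrix (P − rc^T)/√(rc^T) yields principal row
coordinates and eigenvalue (inertia) percentages. Missing calls simply
contribute no dosage, so individuals with more missing data carry less row
mass. Axis signs are fixed by forcing the largest-magnitude column loading
positive, which makes outputs reproducible across runs and platforms;
orientation remains arbitrary in the statistical sense. Whether a classical
genetics implementation weights per allele or per locus is not standardised;
the package uses the canonical CA row/column-mass weighting.

## Distances and trees

The chord distance per locus is d_l = √(2(1 − Σ_j √(p_Aj p_Bj))); loci are
combined by root-mean-square. The classical 2/π angular normalisation is
available via `angular=True` but off by default — the variant choice does
not affect relative comparisons or tree topology, only the scale. The chord
distance satisfies symmetry and identity but is not guaranteed to satisfy
the triangle inequality after RMS combination; it is treated as a
dissimilarity, not a metric.

Neighbor joining follows the Saitou–Nei agglomeration with the standard
Q-matrix and branch-length formulas. Negative branch-length estimates (a
known NJ artifact on non-additive input) are clamped to zero with the
deficit shifted to the sister edge, preserving the pairwise path length
between the joined taxa. On additive input the algorithm is exact, which the
tests verify on a four-taxon tree. Locale-level allele frequencies for the
distance matrix use the union allele set per locus; a group with no data at
a locus receives a uniform vector (no information) rather than failing.

## Shannon information content

For a locus with frequency vectors p₁, p₂ in two source populations and a
mixed population with proportion m of population-1 ancestry,

    SIC(m) = H(m p₁ + (1−m) p₂) − [m H(p₁) + (1−m) H(p₂)]

with H the base-2 entropy and 0·log 0 = 0. This is the mutual information
between an allele and its origin — the reduction in uncertainty about origin
from observing one allele, in bits. The allele (not genotype) is taken as
the information channel; a diploid genotype of two independent copies
carries up to twice the per-allele value, which affects no ranking. The form
has the properties that drive marker selection: it is zero iff p₁ = p₂,
bounded by log₂(number of alleles), concave in m, symmetric under
(m, p₁, p₂) → (1−m, p₂, p₁), scores alleles rare in one population highly
(centrality), and peaks off m = 0.5 exactly when a locus distinguishes one
population inside the other better than vice versa. The default m grid is 99
points at 0.01 spacing; ties in the grid argmax resolve toward 0.5.

Panel evaluation assigns each test individual to the population maximising
the product over panel loci of its genotype likelihood under
Hardy–Weinberg within-population proportions, with zero frequencies floored
at 1/(2n + 1) (n = training sample size) so unseen alleles are improbable
rather than impossible. Ties are broken uniformly at random with a seed.

## Locus QC

The Hardy–Weinberg test is Monte-Carlo exact: alleles at a locus are pooled
and re-paired uniformly at random, conditioning on allele counts. The test
statistic is the conditional probability of the genotype array,
P = n! · 2^h · Π_a m_a! / ((2n)! · Π_g n_g!), valid for sparse multi-allelic
tables where chi-square approximations fail; p is add-one corrected so it is
never zero. The null-allele estimate is the homozygote-excess closed form
r = (He − Ho)/(1 + He), floored at zero. The linkage screen is a G-test on
the two-locus genotype contingency table with a permutation null; degenerate
tables return p = 1 with a warning. All QC outcomes are reported as flags;
no locus is ever silently dropped — exclusion lists belong in the caller's
configuration. Raw and Bonferroni-adjusted linkage p-values are reported
side by side since no single multiple-testing convention dominates for this
screen.

## The synthetic-data generator

The generator emulates a two-species contact system with sex-biased
introgression and known ground truth:

- **Gene pools.** Ancestral allele frequencies per locus are broken-stick
  Dirichlet(1) draws over 2–20 alleles (allele counts uniform in the
  configured range; default (2, 20), spanning near-diagnostic and
  near-uninformative loci as real STR panels do). Each pool's frequencies
  are Dirichlet draws with concentration p_anc · (1 − F)/F — the
  Balding–Nichols parameterisation, whose mean is the ancestral vector and
  whose single parameter F acts as an FST-like divergence. Default F = 0.3,
  a deep split with substantial residual allele sharing.
- **Design.** 5 forest, 17 savanna and 1 mixed-habitat locale by default,
  24 individuals per locale (the sampling geometry of the motivating
  continent-wide survey); savanna locales alternate between southern and
  eastern region labels.
- **Hybrids are constructed, not sampled.** Each mixed locale contains
  exactly round(n × hybrid_fraction) hybrid-lineage individuals (default
  fraction 0.3), with backcross generation cycling 0..`backcross_generations`
  (default 2); generation 0 is an F1. A hybrid lineage descends from a
  forest female repeatedly mated to savanna males, so its expected forest
  nuclear ancestry is (1/2)^(g+1) and its mtDNA is F-clade regardless of g.
  The mixed locale's non-hybrid background is pure forest, making the mixed
  locale forest-skewed overall. An optional `hybrid_fraction_savanna`
  places hybrid lineages inside savanna locales.
- **mtDNA.** Forest individuals and all hybrid-lineage descendants carry
  F-clade; pure savanna individuals carry introgressed F-clade with
  probability `savanna_Fclade_rate` (default 0.20), else S-clade. S-clade
  in a forest locale is structurally impossible, not merely improbable.
- **Missingness** is completely at random (default 2%), since no mechanism
  is specified for the data this emulates.
- **Determinism.** One integer seed spawns per-stage and per-locale
  substreams (`numpy` SeedSequence), so regenerating any locale is stable
  under changes elsewhere.

What passing tests on this generator do **not** show: real STR data have
genotyping artifacts (stutter, null alleles, allele dropout correlated with
sample quality), within-species isolation by distance, locale-specific
sample sizes, and mutation processes none of which are modelled here. Tests
against the generator validate the estimators' statistical behaviour under
the assumed model, not robustness to those artifacts.

## Numerical and interface choices

- Allele pairs are stored unordered (sorted); phase is never used.
- Missing sentinel is −9 in memory and in STRUCTURE files, 00/000 in
  GenePop files, matching each dialect exactly.
- Fragment-size binning fits a ladder of spacing = repeat motif by grid
  search of the offset over [0, motif) at 0.1-base resolution, minimising
  total absolute deviation; sizes farther than motif/2 from every rung are
  flagged unbinnable and set missing. Binning integer codes is a fixed
  point.
- The exact 2×2 test enumerates all tables with the observed margins using
  log-gamma arithmetic (exact at any realistic N); the two-tailed p sums
  probabilities of tables no more probable than the observed one, with a
  1e-12 relative slack on the tie comparison. Mixed-habitat locales group
  with non-forest in the habitat association, and a locale counts as
  S-present with ≥ 1 classified S individual. Counting units follow
  locale-level presence; surveys sometimes mix locale and sample counts, and
  this choice is the one stated here.
- Pipeline stage seeds derive from the top-level seed by stable hashing, so
  disabling one stage never changes another's output.

## Known limitations

- Independent-frequencies prior only; no correlated-frequencies (F-model)
  variant, no linkage model, no use of prior population information.
- ΔK inherits its known biases (cannot select K = 1, favours the uppermost
  hierarchical level); inspect the L(K) table, not only the vote.
- The FCA returns all non-trivial axes; no significance testing of axes.
- Assignment accuracy assumes the training frequencies come from the same
  populations as the test individuals; panel accuracies are optimistic when
  train and test overlap in families or locales.
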