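# Methods

## Data model

Genotypes are unordered pairs of allele states, stored sorted ascending;
an allele state is an absolute fragment size in nucleotides, as capillary
electrophoresis reports it. Repeat-count arithmetic happens only inside
the coalescent simulator, so single-nucleotide indel (SNI) offsets —
off-ladder alleles — are representable throughout. Missing genotypes are
whole-genotype (both alleles), encoded `0` in the GenAlEx-style CSV
dialect and `-9` in STRUCTURE output. No missing-data filter is applied
by default; operations use missing-aware denominators (allele counts over
scored genotypes) and pairwise locus deletion where distances are summed.

## Estimator conventions

* **He** is the biased estimator 1 − Σp² (the GenAlEx convention); the
  unbiased 2n/(2n−1) variant is available via `unbiased=True` but is not
  the default.
* **Population F<sub>IS</sub>** is the mean of per-locus (He − Ho)/He over
  polymorphic loci, with the SE across loci; monomorphic loci are excluded
  (F<sub>IS</sub> is undefined where He = 0). Averaging per-locus ratios,
  not ratio-of-means, matches the "value ± SE" table layout.
* **Pairwise/global F<sub>ST</sub>** defaults to (H̄<sub>T</sub> −
  H̄<sub>S</sub>)/H̄<sub>T</sub>, where H<sub>S</sub> is the unweighted
  mean within-population He and H<sub>T</sub> comes from the unweighted
  mean of the population frequency vectors, both averaged over loci before
  the ratio. Weir–Cockerham θ (multi-allele a/b/c components, loci and
  alleles pooled) is available under `estimator="wc"`. Which of the two an
  external toolkit reports is often unrecoverable from a paper's methods
  line, so both are implemented and the default is documented.
* **N<sub>m</sub>** = (1/F<sub>ST</sub> − 1)/4 is undefined (NaN) for
  F<sub>ST</sub> ≤ 0.
* **AMOVA** operates on individual-level Smouse–Peakall squared codominant
  distances (half squared Euclidean distance between allele-count vectors,
  summed over loci with pairwise deletion). One level: df = (k−1, N−k,
  N−1); the among component uses the unequal-sample-size coefficient
  n₀ = (N − Σnᵢ²/N)/(k−1). P-values permute individuals across populations
  with the (hits+1)/(perms+1) correction; 999 permutations by default.
  Report tables round percentages to integers and statistics to 3
  decimals.
* **Nei (1978) unbiased distance** uses per-locus unbiased identities
  (2nΣp² − 1)/(2n − 1), averaged over loci before the ratio. A pair with
  zero shared identity would be at infinite distance; it is encoded as the
  sentinel 1e9 (with a logged warning) so UPGMA stays defined.
* **PCoA** double-centers −d²/2 (Gower) and eigendecomposes; coordinates
  are eigenvectors scaled by √λ for positive eigenvalues only, negative
  eigenvalues are reported but never embedded. Three axes by default.
* **UPGMA** places each merge at half the average-linkage distance, so the
  tree is ultrametric by construction. Ties merge the lexicographically
  smallest label pair, making output stable across runs; Newick branch
  lengths carry 6 decimals.
* **Evanno ΔK** = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate
  runs; needs ≥ 3 consecutive K and ≥ 2 replicates per K. A zero replicate
  sd yields an explicit undefined value with a flag, never a silent
  infinity. The clustering program itself is external; this module only
  consumes its log-likelihood table (columns K, run, L).

## Synthetic data

`make_study_fixture` emulates the survey shape: 11 populations at the
published sample sizes (26, 26, 22, 22, 29, 21, 13, 25, 24, 19, 15;
N = 242), 15 dinucleotide loci, 6–8 alleles per locus. Allele frequencies
are hierarchical Dirichlet draws: a global vector per locus, a
species-group perturbation (concentration 8, giving between-species
F<sub>ST</sub> near 0.1), and a population-level perturbation
(concentration 30, within-species F<sub>ST</sub> of a few percent) — for
Dirichlet(c·p) the expected fixation index is ≈ 1/(c+1). Each population
carries one inbreeding parameter f drawn uniformly from [0, 0.2],
matching the single per-population F<sub>IS</sub> a summary table
reports. Genotype sampling draws one allele and duplicates it with
probability f, else two independent alleles, which gives exactly
P(hom i) = pᵢ² + f·pᵢ(1−pᵢ) and E[Ho] = (1−f)He. The fixture is a pure
function of its seed.

What the generator does **not** emulate: the study's actual allele
frequency spectra (the raw genotypes are unavailable), missing data,
null alleles, linkage, or spatial structure. Tests that pass on the
fixture therefore validate the estimators and the pipeline plumbing, not
any claim about the real populations.

## Coalescent simulator

Per locus, a continuous-time structured coalescent runs backward in time:
within a deme of diploid size N each lineage pair coalesces at rate
1/(2N); waiting times are exponential (exact in the N ≫ sample regime of
the priors). Demographic events are an ordered schedule: merges move all
lineages of one deme into another, the admixture event sends each lineage
of group 3 to group 2 with probability ra else to group 4, and a resize
sets the ancestral size NA. The three scenarios over groups Pop1–Pop4:

1. Pop3→Pop2 at t1, Pop2→Pop1 at t2, Pop1→Pop4 at t3, size→NA at t4.
2. As scenario 1 but Pop3 originates by admixture (ra from Pop2, 1−ra
   from Pop4) at t1.
3. All four groups merge into the ancestral population of size NA at t1
   (the t4 resize exists only if explicitly configured).

Mutations are Poisson on branches with per-locus rate μ<sub>l</sub>.
Each mutation steps the repeat count by a geometric magnitude
(P(|step| = k) = (1−P)P^(k−1), sign symmetric); P → 0 recovers the strict
stepwise model. Alleles live on a bounded ladder of 40 contiguous repeat
states centred on the founding state (20); steps that would leave the
ladder are redrawn (up to 100 attempts, then the mutation is dropped).
SNI events are Poisson with their own per-locus rate and shift the allele
by ±1 nucleotide; allele size in nt = 100 + motif·repeats + offset, motif
2 nt by default. Diploids pair consecutive haploids (exchangeable, hence
random pairing). The per-locus kernel is numba-compiled with a
pure-Python fallback.

Priors: sizes integer-uniform on [10, 20000] with every group size ≥ NA;
times integer-uniform on [10, 10000] with t1 ≤ t2 ≤ t3 ≤ t4 for scenarios
1–2 (nested events) and a single t1 for scenario 3; ra uniform on (0,1).
Constraints are enforced by rejection; a joint acceptance rate below 1e−4
raises a configuration error. Mutation hyper-priors: mean rate uniform on
[1e−4, 1e−3], mean P on [0.1, 0.3], mean SNI rate on [1e−8, 1e−4];
per-locus values are Gamma(shape 2) around each mean, redrawn into
[1e−5, 1e−2], [0.01, 0.9], [1e−9, 1e−3] respectively. A per-locus
geometric coefficient cannot exceed 1, so the per-locus P band is read as
[0.01, 0.9].

Verified against closed forms and an independent simulator: mean pairwise
coalescence time 2N; equilibrium He = 1 − (1+2θ)^(−1/2) under SMM
(Ohta–Kimura, θ = 4Nμ); E[(δμ)²] = 2μt for a two-population split; TMRCA
distribution against msprime on a size-change history; scale invariance
of F<sub>ST</sub> under joint doubling of sizes and times; scenario 2
with ra → 1 indistinguishable from the pure-merge topology.

## ABC

Summary statistics per group: mean alleles/locus (A), mean genic
diversity H = 1 − Σp², mean allele-size variance in repeat units (V),
mean Garza–Williamson M = alleles/(repeat range + 1). Per group pair:
F<sub>ST</sub> (as above, on the two groups), the shared-allele distance
DAS = 1 − mean proportion of shared alleles over cross-group diploid
pairs, and (δμ)² = squared difference of mean allele size in repeat
units, averaged over loci. Sizes are binned to repeat units by rounding,
which absorbs SNI offsets. Loci where a group is entirely missing drop
from that group's means with a warning. The exact statistic set a given
external ABC tool uses is generally configurable; this fixed vector is
the package's documented choice.

Rejection keeps the ⌈tolerance·rows⌉ simulations closest to the observed
vector in Euclidean distance on statistics standardized by the reference
table sd (zero-variance statistics excluded with a warning).

Scenario choice pools the per-scenario tables, takes the n_closest
simulations, and fits a multinomial logistic regression of scenario label
on the standardized statistics, evaluated at the observed point. The fit
carries a small L2 penalty (λ = 0.01) because well-separated scenarios
routinely produce complete separation, under which the unpenalized MLE
diverges; confidence intervals come from the penalized-Hessian covariance
by the delta method, clipped to [0,1]. If the regression is degenerate
(fewer than two scenarios among the closest simulations, singular
design), the rejection frequencies with Wilson intervals are reported
instead, and a scenario absent from the closest set is floored at
probability 0 with a warning. The CI construction is a documented
stand-in: reference ABC tools do not specify theirs.

Parameter adjustment is Beaumont-style local-linear regression with
Epanechnikov weights in the rejection distance; sizes and times are
log-transformed first and back-transformed after. By default the
standardized statistics are reduced to 3 supervised PLS components fitted
jointly against all transformed parameters before the regression.
Rationale: with ~25 correlated statistics and a few hundred accepted
rows, the full-statistics regression overfits and produces overconfident
posteriors — in coverage experiments at the recovery design below its
95% intervals covered a fixed truth only ~40–60% of the time, versus
19–20/20 for the PLS variant. `n_components=None` restores the classic
full-statistics regression. A rank-deficient design falls back to the
unadjusted rejection posterior with a warning.

Model checking projects the observed vector into a PCA of the
standardized simulated statistics and reports the fraction of simulations
with smaller radius (percentile radius).

Calendar conversion: age (ka BP) = generations × generation time / 1000,
generation time 100 years by default (long-lived trees).

## Problem sizes

Reference tables default to 10,000 draws per scenario in the validation
experiments and are configurable upward for real analyses (tools of this
kind typically use 10⁵–10⁶). The test suite's ABC experiments use four
groups of 10 diploids at 15 loci — the study's group structure at reduced
sample size — with 10,000 draws/scenario (tolerance 1%) for scenario
choice over 50 replicate observed datasets, and 20,000 scenario-1 draws
(tolerance 1%) for parameter recovery over 20 replicates; reference
tables are built once and shared across replicates, with the observed
dataset varying. The recovery experiment fixes the observed mean
stepwise rate at 1.5e−4, the low end of the prior band: at rates several
times higher, θ = 4Nμ ≈ 10 saturates heterozygosity and effective size
becomes unidentifiable at these sample sizes, so a coverage experiment
there would measure prior behaviour rather than inference. The
acceptance script runs the full pipeline at the complete study size
(N = 242, four ABC groups of 59/44/81/58) with 1,500 draws per scenario.

## Known limitations

* The discrete-generation coalescent is approximated in continuous time;
  distortion appears only when sample sizes approach 2N.
* The bounded 40-state ladder slightly compresses allele-size variance
  for θ ≫ 10 or very deep histories.
* Scenario 2 with ra near 0 or 1 is topologically identical to nested
  splits, so scenario posteriors genuinely overlap there.
* Effective sizes and mutation rates are confounded through θ; posteriors
  for N are wide whenever the mutation hyper-prior spans a decade.
* One AMOVA level (among/within populations); no region-within-species
  nesting, no HWE/linkage exact tests, no null-allele correction.
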