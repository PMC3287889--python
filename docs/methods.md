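# Methods notes

## Model and procedure

The unit of inference is a fixed-size subset S (|S| = k, default 20) of the
variants in a region. The per-individual burden score is
sigma_I(S) = sum_{i in S} w_i c_{I,i}, and association is measured by the
squared Pearson correlation r² between sigma(S) and the quantitative trait.
Keeping |S| fixed is a deliberate guard against overfitting: a richer subset
always fits at least as well, so comparing subsets of equal size keeps the
search honest, and the permutation test prices in whatever optimism remains.

The MCMC sampler targets the Boltzmann distribution pi(S) ∝ exp(ℓ(S)) with
ℓ(S) = −(n/2) ln(1 − r²(S)). This is the profile log-likelihood of the
simple linear model trait = a + b·sigma(S) + e, e ~ N(0, s²), after
maximizing over (a, b, s²), up to an additive constant that cancels in the
Hastings ratio. The assumptions behind it — linearity of the trait mean in
the score and normal residuals — are conventions of the model, not verified
properties of any data set; the permutation test does not depend on them.

### Weight schemes

* `LL`: w_i = 1. The aggregated score is the raw count of minor alleles.
* `MB`: w_i = 1/MAF_i with the in-sample minor-allele frequency. This is the
  plain inverse-frequency form; the classical 1/sqrt(n q (1−q)) variant is
  available as `classical_mb=True`. Monomorphic variants get weight 0 (they
  cannot contribute) with a warning.
* `ME`: w_i = |b_i| with b_i the univariate OLS slope (quantitative traits)
  or the carrier/non-carrier log odds ratio with 0.5 continuity correction
  (binary traits). The absolute value keeps all weights non-negative so the
  score retains its burden interpretation; `signed_me=True` exposes the
  signed alternative. ME weights are a function of the phenotype and are
  therefore recomputed for every permuted phenotype inside the permutation
  test — the weight is part of the statistic, so the null must re-derive it.

Missing genotypes contribute 0 to every score (treated as reference
homozygote). This is the simplest conservative convention; missingness is
otherwise preserved in the stored count matrix.

## Samplers

### Metropolis-coupled MCMC

Five chains (configurable) run at temperatures T_j = 1/(1 + 0.2 j). The
ladder is a mild harmonic spacing chosen to keep adjacent-rung swap
acceptance high at five chains; nothing in the method depends on its exact
form. Each sweep applies one proposal per chain — remove a uniformly chosen
member, add a non-member drawn with probability proportional to the kernel
weight — followed by one swap attempt between a random adjacent pair.

The proposal kernel weight of variant i is its marginal association r² with
the (adjusted) trait plus a floor of (max marginal r²)/100. Without the
floor, variants with zero marginal association would be unreachable and the
chain would not be ergodic over all k-subsets. The Hastings correction
accounts for the non-member renormalization on both sides of the move, so
the cold chain's stationary distribution is exactly pi; this is verified
against exhaustive enumeration (28-subset instance, total-variation
distance ≲ 0.02 at 50k sweeps).

A remove+add pair is the only size-preserving elementary move, given the
fixed subset size. Defaults of 20,000 sweeps with 4,000 burn-in are sized
for a few hundred variants per region; the tiny-instance posterior checks
converge orders of magnitude faster. Posterior inclusion frequencies are
accumulated from the cold chain after burn-in (they sum to k by
construction); the best subset ever visited in *any* chain is reported as
the point solution.

Under a fixed null trait the posterior legitimately concentrates on the
chance-best subset — ℓ scales with n, so even chance r² differences become
large Boltzmann factors. Concentration on a single null trait is therefore
not a bug signal; lack of *recurrence* across independent null traits is,
and that is what the test suite checks.

### Genetic algorithm

A population (default 100) of k-subsets evolves for a default 200
generations: the single best member is carried over unchanged (elitism 1,
which makes the best-fitness trace monotone and hence testable), and the
remainder are produced by roulette selection proportional to r², a
size-preserving crossover (the child inherits all variants the two parents
share and fills up uniformly from their symmetric difference), and per-slot
mutation to a uniform non-member (rate 0.05). All values are configuration
knobs; none is canonical. The initial population uses the same
association-weighted sampling as the MCMC chains.

## PC adjustment for stratification

Principal components are computed once per genotype matrix from the
column-standardized counts (sample standard deviation, 1/(n−1); monomorphic
variants are dropped from the PCA but stay in the search space), using all
polymorphic variants — common-variant-only PCA is a reasonable alternative
not taken here. Each trait replicate is residualized on [intercept,
PC1..PC10]; 10 PCs is the default throughout and is deliberately not tuned
per replicate. Permutation operates on the residualized trait with the PCA
held fixed: genotypes (hence PCs) do not change under phenotype permutation,
so permuting the residual is equivalent under the null.

## Significance

p = (1 + #{null ≥ observed}) / (1 + B), which is positive by construction
and attains 1/(1+B) at best (0.001 at the default B = 1000). Every
permutation reruns the *identical* configured search with an independently
drawn seed, so observed and null runs are exchangeable under the null — this
exactness is what the calibration tests verify. A `perm_effort < 1` option
shrinks per-permutation search effort for desk-scale exploration; it breaks
that exchangeability (observed run at full effort against weaker nulls) and
is logged prominently as an anti-conservative approximation. It is never
used in tests.

Causal-recovery diagnostics pool (variant, replicate) selection events
across replicates into one 2×2 table (selected × causal) and apply a 1-df
Pearson chi-square without continuity correction (pooled counts are large).
A `unique_snps` mode counting each variant once is exposed as an
alternative reading.

## Synthetic data

The generator emulates a mini-exome benchmark: one fixed genotype panel,
many trait replicates.

* Ancestral MAFs: min + (max−min)·Beta(shape, 1) with defaults
  (0.001, 0.5, 0.1), putting ~80% of variants below MAF 0.05 — the
  rare-variant dominance of exome panels.
* Structure: Balding–Nichols — subpopulation frequencies drawn from
  Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral p, genotypes
  Binomial(2, subpop frequency). This is the simplest standard model
  producing the confounding of interest; no LD, haplotypes, or coalescent
  realism. Variants monomorphic in sample are redrawn up to 20 times, then
  kept with a warning (deeply rare variants under strong drift can stay
  monomorphic; they simply never contribute).
* Traits: y = Σ effect_i·count_i + structure_effect·subpop_label +
  N(0, noise_sd), noise fresh per replicate, genotypes shared.

Presets (defaults chosen from the emulated study design, with n sized for
desk-scale runs):

* `q1_like`: 600 individuals × 300 variants, 15 causal variants at ancestral
  MAF ≤ 0.05 in three clusters of five, slope 1.2 each — heritability ≈ 0.4,
  matching the canonical many-rare-causal-variant quantitative trait.
* `q2_like`: 8 causal variants, slope 0.5 — a weaker polygenic signal.
* `q4_like`: 200 × 150, no causal variant, Fst 0.05 between two
  subpopulations, trait mean shifted by 1.5 per subpopulation (~36% of trait
  variance) — a structured null that makes unadjusted analysis grossly
  anti-conservative, which is the phenomenon the PC adjustment exists to fix.
  200 trait replicates by default everywhere.

What passing tests on these data do **not** show: behavior under linkage
disequilibrium (a causal variant's LD partners can be selected in its
place), under case-control ascertainment, with genotyping error, or at
genome scale. The generator's independence across variants makes causal
recovery easier than on real sequence data.

## Numerical choices

* r² is clamped to 1 − 1e-12 before ℓ = −(n/2)ln(1−r²); a constant score
  vector (common for rare-variant subsets in small samples) gets r = 0
  rather than an error so the samplers can traverse such states.
* Chain scores are updated incrementally (one column subtract/add per move);
  double-precision drift over 10⁵ sweeps is far below all test tolerances,
  and cache coherence is tested explicitly.
* All randomness flows from one master seed through named substreams
  (`numpy` SeedSequence keyed by component tags), so the simulation, each
  search, and each permutation are independently reproducible.
* Ties in selection and crossover are resolved by the RNG, never by index
  order; weighted sampling without replacement is sequential
  cumulative-sum inversion.

## Scale of the shipped checks

The statistical checks run at sizes one CPU handles in minutes, chosen as
the smallest instances where each property is informative: 220-subset
enumeration for optimizer recovery (20 seeded runs), 28 subsets × 50k sweeps
for posterior accuracy, 100 replicates × 200 (or 99) permutations for
calibration and stratification rescue with a reduced-effort searcher
(2 chains × 120 sweeps — calibration of the permutation construction does
not depend on search effort), and 20 replicates at full k = 20 for causal
recovery.

## Known limitations

* Joint search over an entire exome/genome is out of scope; the region is a
  configuration choice and chromosome-scale panels are the intended use.
* The likelihood approximation ignores uncertainty in the weights (ME) and
  the selection of S itself; it is a search guide, not a basis for direct
  inference — all inference goes through the permutation test.
* Binary traits are supported only through the log-odds-ratio weight option;
  the fitness measure and permutation machinery assume a quantitative trait.
* Mixed-model (kinship) correction, MAF thresholding, variant-quality
  filtering, and multiple-testing correction across regions are deliberately
  not provided.
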