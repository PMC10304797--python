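# Methods

This note records the statistical models behind `phona`, the defaults and
why they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical choices that a maintainer would
otherwise have to reverse-engineer from the code.

## SparCC association inference

Counts are treated as a compositional observation of latent absolute
abundances `w_i`. For fractions `x`, the pairwise log-ratio variance

    T_ij = Var log(x_i / x_j) = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j

depends only on ratios and is therefore closure-free. Under the sparsity
assumption that most basis correlations vanish, summing over partners gives
the linear system `Σ_{j≠i} (ω_i² + ω_j²) = Σ_{j≠i} T_ij`, solved directly
(`numpy.linalg.solve`, least-squares fallback if exclusions make it
singular). Correlations follow from the displayed identity and are clipped
to [−1, 1].

* **Zeros / count uncertainty.** Fractions are drawn from a
  Dirichlet(counts + 1) posterior per sample; the final estimate is the mean
  over `n_iterations = 20` draws. Twenty draws is the conventional depth at
  which the Monte-Carlo error of the mean is well below the sampling error
  across samples for the table sizes used here.
* **Strong pairs.** Each draw runs up to `n_exclusion_rounds = 10` exclusion
  rounds: the strongest remaining |ρ| above `exclusion_threshold = 0.1` is
  removed from the sums and the system re-solved, because a strongly
  correlated pair violates the sparsity assumption that justified dropping
  the cross terms.
* **Degenerate solutions.** Basis variances solved ≤ 0 are floored at 1e−12
  and the OTU's correlations are zeroed with a warning; this happens on
  tiny, nearly-deterministic tables where the system is barely determined.
* **Edge significance.** The bootstrap null resamples each OTU's counts over
  samples independently (with replacement), which destroys all inter-OTU
  association while preserving marginal distributions. p = (1 + #{null |ρ|
  ≥ |ρ_obs|}) / (1 + B) with B = 500, two-sided, so the smallest attainable
  p is 1/501. Null SparCC uses a single Dirichlet draw per bootstrap; the
  Dirichlet jitter is small relative to across-sample variation at
  realistic depths, and the measured null calibration (fraction of p < 0.05
  ≈ 0.02–0.05 on 20-OTU null tables) confirms the 20-vs-1 iteration
  asymmetry costs only mild conservatism.
* **Edge filter.** |ρ| strictly greater than 0.5 and p strictly below 0.05;
  OTUs with no surviving pair are absent from the network.

## Phenotype selection

Predictors are relative abundances standardized to mean 0, sd 1 — the lasso
penalty is scale-sensitive, and without standardization abundant OTUs would
be penalised less per unit of association. Standardization uses the full
data set; with fold sizes of 20+ samples the leakage this introduces into
CV error estimates is negligible compared with the error differences being
compared.

The penalty grid holds 100 log-spaced values from `λ_max` (the smallest λ
with an all-zero solution, `max_j |x_jᵀ(y − ȳ)|/n`) down to `1e−4 λ_max`.
Cross-validation repeats k-fold splitting `n_repeats` times (defaults 5 and
500) and records the mean and variance of held-out squared error per λ.

Three selection rules are implemented, because the choice genuinely
matters:

* `min_mean` (default): λ minimising mean CV error. This is the standard
  rule but it **overselects under a null**: a chance whole-sample
  correlation (of order √(2 ln p / n) ≈ 0.29 at n = 100, p = 60) is a
  property of the realised data set and therefore appears in *every* fold,
  so the CV curve can genuinely dip at interior λ no matter how many
  repeats are averaged. Measured on pure-noise responses, min-mean selects
  a non-empty support in roughly a third of data sets.
* `one_se`: the sparsest model within one standard error of the minimum —
  the standard guard against exactly that overselection. On pure-noise
  responses it returns the empty support in ~90% of data sets while still
  recovering planted high-SNR supports in 20/20 seeded runs.
* `min_variance`: λ with the most stable CV error, provided because the
  source analysis tuned "the λ with lowest variance"; it is non-standard
  and not recommended (worse null sparsity than `one_se` in our
  measurements).

Ties break toward larger λ (the grid is stored descending), i.e. toward the
sparser model. The OTUs with nonzero coefficients, ranked by |standardized
coefficient|, are refit with an intercept in a Gaussian identity-link GLM;
the coefficient sign labels the phenotype link and the Wald p-value its
strength. Aliased columns are dropped greedily (earlier-ranked kept) with a
warning. There is no train/test split by default: with the small per-subset
sample sizes this pipeline targets, a holdout would cost more in selection
stability than it buys in honesty, and the CV table already reports
generalisation error.

## PhONA graph and analytics

The graph has exactly one phenotype node. OTU–OTU edges carry the SparCC ρ
as weight and its sign; phenotype links carry the GLM coefficient and sign.
OTUs selected by the lasso but absent from the association network are kept
as otherwise-isolated nodes linked to the phenotype
(`retain_isolated_predictive`, default on) — dropping them would silently
hide predictive taxa that simply lack strong OTU partners.

* **Attributes** (computed on the OTU layer only): node degree is
  edges/nodes — the convention of the per-treatment summary tables this
  mirrors, half the usual mean degree, which is exported separately as
  `mean_degree`; density is edges over unordered pairs n(n−1)/2; the
  negative:positive ratio is reported as NA when no positive edges exist.
  Report rounding is 1 decimal for degree, 2 for density and ratio.
* **Modules**: Newman–Girvan modularity on the unsigned, unweighted
  skeleton, maximised by simulated annealing: single-node moves (80%
  proposed into a random neighbour's module, which mixes far faster on
  sparse graphs than uniform proposals), 2% module merges, geometric
  cooling (t0 = 1.0, factor 0.995 per sweep of n proposals, 10⁴·n proposals
  total), followed by a greedy single-node polish from the best state
  visited. Q is recomputed through networkx on the returned partition, so
  the incremental bookkeeping inside the annealer is cross-checked on every
  call. Deterministic given the seed.
* **Roles**: within-module degree z-score (sample sd over module members,
  ddof = 1; sd = 0 ⇒ z = 0) and participation coefficient
  P = 1 − Σ_s (k_is/k_i)² (isolated nodes get P = 0). Thresholds z ≥ 2.5
  and P ≥ 0.62, boundary inclusive, following the Guimerà–Amaral
  convention. Signs are ignored throughout the role analysis.

## Community statistics

* **Alpha diversity**: observed richness and Shannon entropy in nats
  (`scipy.stats.entropy` on the count vector). Intended for rarefied
  tables; H ≤ ln(richness) with equality at uniformity.
* **Bray–Curtis**: `scipy` pairwise distances; an all-zero sample pair is
  defined as distance 0 with a warning (it is a semimetric either way).
* **PERMANOVA**: sequential (type-I) partition via hat matrices on the
  Gower-centered squared distances — the adonis construction — with
  pseudo-F per term and p from free permutation of sample labels
  (default 1000). The single-factor pseudo-F is identical to scikit-bio's
  PERMANOVA (checked to 1e−10 in the tests). Block-restricted permutation
  is not implemented; with blocked designs the free-permutation p is
  approximate.
* **Differential abundance**: per OTU and contrast, counts of the two
  groups are modelled as NB2 with log link and log-library-size offset.
  The dispersion is estimated per OTU by **Cox–Reid adjusted** profile
  maximum likelihood (bounded scalar optimisation of
  `ℓ(α, β̂) − ½ log det XᵀWX`, fallback: df-corrected Pearson moments).
  Plain profile ML at n = 20 underestimates α in a way that is negatively
  correlated with the test statistic — fitting the group split absorbs
  chance variation twice — which inflates the deep null tail about
  eight-fold and breaks FDR control at q < 0.01; the CR adjustment removes
  most of that (measured null fraction p < 0.05 ≈ 0.07, p < 0.001 ≈ 0.004).
  No information is shared across OTUs. The group effect is tested by
  likelihood ratio at the fitted dispersion; q-values are BH-adjusted
  within each contrast family, status is enriched/depleted at q < 0.01 by
  the sign of the log2 fold change, and non-convergent OTUs are flagged and
  excluded from the family.

## Synthetic data generator

`synthdata` produces data with exactly the structure the estimators assume,
so every stage is testable without sequencing data.

* **Compositional mode** (default): basis log-abundances are multivariate
  normal with user-planted pairwise correlations (means N(0,1), log-sds
  uniform on [0.5, 1.5], both drawn once from the seed — a couple of orders
  of magnitude of abundance spread and strong per-OTU variability, typical
  of rarefied amplicon tables); counts are multinomial at fixed depth on
  the normalised basis. Observing only the closure is what biases
  Pearson-on-proportions, so this mode genuinely exercises the
  compositional correction — the planted-pair benchmark measures SparCC's
  error *against* Pearson's on the same draws. Infeasible correlation
  specs are repaired by eigenvalue flooring with a warning.
* **Negative-binomial mode**: expected proportions are fixed per treatment
  group (no log-normal layer), so the only between-sample variation is the
  NB dispersion itself — the clean setting for validating the
  differential-abundance machinery at a known dispersion. Planted fold
  changes multiply the basis abundance of designated OTUs; those OTUs are
  pinned to a subdominant baseline proportion (default 0.1%) so the planted
  effect survives compositional dilution — enriching a dominant slice of
  the community 4-fold mostly depresses everyone else's proportions, which
  a library-size-offset model correctly, but uninformatively, reports as a
  shrunken fold change for the planted taxa themselves.
* **Phenotype**: y = Σ β_k · (standardized relative abundance of OTU k) +
  N(0, σ). Ground truth (planted pairs, betas, signs, fold changes) is
  always returned alongside; the tests treat generator parameters as the
  oracle and never re-derive truth from data.

What the generator does **not** emulate: taxon-specific mean-variance
relationships, sample-depth heterogeneity (multinomial mode fixes depth),
phylogenetic correlation structure, blocked/nested field designs, and
zero-inflation beyond what the multinomial induces. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to every failure mode of real amplicon data.

## Problem sizes and defaults in the checks

The automated checks run at desk scale, chosen so the full suite completes
in minutes on one core while keeping each comparison statistically sharp:
planted-correlation recovery at n = 200 samples × 22 OTUs (depth 5000);
lasso support recovery over 20 data sets of n = 100 × p = 60 with 50 CV
repeats; bootstrap calibration on 20-OTU null tables with the full 500
bootstraps; PERMANOVA type-I error over 200 replicates of 10 + 10 samples
with 199 permutations; differential abundance at 20 planted 4-fold
enrichments among 200 OTUs, 10 + 10 samples, dispersion 0.5, library size
100,000 (unrarefied-run scale, at which the per-OTU Poisson term 1/μ is
negligible next to the dispersion). Pipeline-level checks use smaller
iteration counts through the config file; the config defaults themselves
(20 SparCC iterations, 500 bootstraps, |ρ| > 0.5, p < 0.05, 500 × 5-fold
CV, FDR 0.01, role thresholds 2.5/0.62, 1000 permutations, rare-OTU
threshold 10, rarefaction depth 6698) mirror the reference analysis this
package re-implements.

## Known limitations

* SparCC assumes a sparse true correlation structure; dense ecological
  networks bias the basis-variance solution.
* The bootstrap null keeps per-OTU marginals but not any sample-level
  structure (e.g. depth gradients); with strongly varying library sizes the
  null is slightly optimistic.
* CV-min lasso overselects (see above); use `one_se` when a conservative
  OTU list is the goal.
* Per-OTU dispersion estimation without sharing is noisy at n ≈ 20; the CR
  adjustment fixes the bias, not the variance. Methods with cross-OTU
  shrinkage are more powerful on real tables.
* Module counts from simulated annealing are stochastic optima; different
  seeds can return different near-optimal partitions on weakly modular
  graphs (Q is reproducible to the seed, the labels are not meaningful
  beyond the partition).
* PERMANOVA permutes labels freely; blocked designs need restricted
  permutation for exact validity.
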