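# Methods

## Model

Line cross analysis treats the observed cohort means of a trait as noisy
realizations of a linear model over composite genetic effects,

    mean_j ~ Normal( mu + (C beta)_j , SE_j^2 ),

where `C` is the cohorts × effects coefficient matrix, `beta` the effect
vector in trait units, and `SE_j` the cohort's reported standard error,
treated as a *known* measurement SD. Ten effects are supported: autosomal
additive (Aa), autosomal dominance (Ad), cytotype additive (Ca), maternal
additive/dominance (Mea/Med), and the five two-way epistatic products
AaAa, AaAd, AdAd, AaCa, AdCa. Higher-order epistasis is rejected rather
than ignored: a five-cohort design carries no information about it.

### Coefficient derivation

Coefficients use the parental ±1 scale (P1 = +1, P2 = −1; some LCA
literature uses a ±½ scale — estimates differ by a factor of two, pooled
proportions do not). For a pedigree terminating at the two founders:

- θ(P1) = 1, θ(P2) = 0, θ(child) = (θ(sire) + θ(dam))/2; `Aa = 2θ − 1`.
- `Ad` is the expected heterozygosity under independent gamete draws:
  Ad(founder) = 0, Ad(child) = θ_s(1−θ_d) + θ_d(1−θ_s). This assumption is
  exact for any cross among founders, F1 and their combinations (F2,
  backcrosses, reciprocals) — the supported pedigree class. It ignores
  linkage and within-cohort selection.
- `Ca` is +1 iff the strict dam lineage ends at P1; selfing preserves
  cytotype, and a founder's cytotype is its own.
- `Mea`, `Med` are the dam's `Aa`, `Ad`; a selfed founder is its own dam.
- An epistatic coefficient is the product of its constituent base
  coefficients.

## Model space and fitting

A model is any subset of effects (the intercept is always present). A
subset is estimable when the design `[1 | C_subset]` has full column rank,
judged by singular values above 1e-8 × the largest — the exact linear
dependencies of the five-cohort design (e.g. Ad ∝ AdAd ∝ AdCa;
Ca = Mea − Med; AaCa = 1 − Aa + Ca) are rational numbers far from this
cutoff, so the filter is insensitive to its precise value. Subsets up to
n_cohorts − 1 effects are enumerated (size, then lexicographic order). For
the five-cohort × ten-effect design this yields **243 estimable models**,
pinned as a regression value.

Each model is fit by weighted least squares (weights 1/SE²) with parameter
covariance `(X' W X)^{-1}` — no residual-variance rescaling, consistent
with SEs being known. The log-likelihood is the known-variance Gaussian
one, `−½[wRSS + Σ ln(2π SE_j²)]`, so models of different size are
comparable and a saturated model is well defined. Scores are

    AICc = −2 loglik + 2K + 2K(K+1)/(n − K − 1),   K = 1 + |effects|.

When `n − K − 1 ≤ 0` (K ≥ 4 at n = 5) AICc is +∞: the model stays in the
report but gets zero weight. Enumeration and weighting are deliberately
decoupled — the model *space* is larger than the set of weightable models.

## Averaging and inclusion

Akaike weights are `w_i ∝ exp(−Δ_i/2)` over finite-AICc models. The
confidence set is the smallest prefix of weight-ranked models (ties broken
by model order, a stable deterministic rule) reaching the confidence level
(default 0.95). Averaging uses the confidence set with renormalized
weights and zero substitution: absent effects contribute 0 with SE 0. The
unconditional SE is the standard model-averaging form
`Σ w_i sqrt(se_i² + (β_i − β̄)²)`. Variable importance is the summed
renormalized weight of confidence-set models containing the effect;
whether averaging should instead use full-set weights is not settled, so
`scope="all"` is available as a switch.

An effect enters the reported architecture when VI > 0.5 (strict) and
|estimate| > m × unconditional SE with m = 1 by default — the literal
reading of "a standard error that excludes zero"; m is configurable (e.g.
1.96). Included effects are pooled by category and scaled by |estimate| to
sum to one; with nothing included every proportion is NaN. Proportions are
never rounded internally.

## Cohort summaries

The cohort mean is the unweighted mean of plant means, so plants with
unequal replicate counts contribute equally. The SE is
`sqrt(Σ_i σ_i²/s_i)` with σ_i the within-plant sample SD (denominator
n − 1) and s_i the replicate count. Two consequences worth knowing:

- As printed this is the SE of the *sum* of plant means, not of their
  mean. `se_of_mean_of_means` (divided by n) is provided but is never the
  default, because downstream weights must match however the input SEs
  were produced. A corollary: adding plants *inflates* this SE while
  adding replicates per plant shrinks it, so statistical power tracks
  replicates per plant, not plant count (verified by Monte Carlo in the
  test suite).
- A single-measurement plant has no sample SD; it contributes σ = 0 with a
  logged warning. Traits measured on unnested units (individually weighed
  seeds) are treated as one-observation "plants" unless a plant column is
  supplied, folding all variability into the plant level.
- Between-plant variance does not enter the SE at all — only within-plant
  scatter does. Real cohort means are therefore overdispersed relative to
  their nominal SEs whenever plants differ; the generator reproduces this.

## Synthetic data

`simulate_cohorts` draws, per cohort, plant effects ~ N(0, σ_plant²) and
replicate noise ~ N(0, σ_obs²) around `mu + (C beta)_j`. Defaults mirror
the emulated study design: five cohorts (P1, P2, F2, BC1, rBC2), two
plants each, 23/14/13/14/21 leaves split (12,11)/(7,7)/(7,6)/(7,7)/(11,10).
Each cohort consumes an independent child stream of the single seed, so
datasets are byte-reproducible and cohorts independent. The generator does
**not** simulate linkage, segregation-variance inflation in F2/backcross
cohorts, non-Gaussian noise, or G×E — so passing recovery tests certify
the inference machinery under its own assumptions, not robustness to those
violations on real data.

`recovery_experiment` repeats simulate → summarize → fit → average →
include over seeded replicates (replicate r uses seed + r) and reports
per-effect mean estimate, bias, and inclusion fraction; for truly-zero
effects the latter is the spurious-inclusion rate.

### Power of the five-cohort design

Two Monte-Carlo facts about this design worth stating. A purely additive
signal ~8× its induced SE is recovered (Aa included, architecture 100%
additive) in ≈99% of replicates, with ≤a few percent spurious inclusions
under a null truth — the K-dependent AICc penalty at n = 5 is severe
(the correction term alone is 24 at K = 3), which makes the procedure
conservative. The same penalty cuts both ways: for a two-effect
{Aa, AaAa} truth, the only contrast separating AaAa from the mutually
proportional Ad/AdAd/AdCa column family lives in the backcross rows at a
quarter of the nominal effect, so reliable joint recovery needs that
*contrast* — not just the raw effect — to clear ~5 SEs.

## Numerical choices and degenerate inputs

- Zero or negative cohort SEs are refused with instructions (weights 1/SE²
  cannot absorb them); exactly-noiseless simulations therefore cannot be
  fed back into the fitter, by design.
- Rank tolerance 1e-8 (relative, SVD); tie-breaks everywhere are stable
  and documented (model order; size-then-lexicographic enumeration).
- All randomness flows from one integer seed via spawned substreams.
- Problem sizes in the shipped tests (200 replicates for recovery rates,
  60 for directional comparisons) put Monte-Carlo SEs on reported
  fractions at ~1–4 points, adequate for the thresholds tested.

## Limitations

- Only two-founder pedigrees resolvable to the P1/P2 founders; no sex
  chromosomes, ploidy variation, or three-way epistasis.
- Cohort SEs are taken at face value; there is no mixed-model or
  individual-level likelihood, and no modeling of between-plant variance
  in the SE (see above).
- The estimability filter is a pure rank criterion; other software may
  apply additional degrees-of-freedom rules and hence count the model
  space slightly differently.
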