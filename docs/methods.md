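# Methods

`metgain` analyzes series of international wheat yield trials for genetic
gain. This note records the models, the synthetic-data generator, the
numerical choices, and the limits of what the simulation experiments show.

## Models

### Single-location model

Each location-year is an α-lattice trial. Plot yield is modeled as

    y_ijk = μ + R_j + SB_k(R_j) + G_i + ε_ijk,

with replicates `R_j` and genotypes `G_i` fixed, sub-blocks within
replicates `SB_k(R_j) ~ N(0, σ²_sb)` random, and residuals
`ε ~ N(0, σ²_ε)`. Variance components are estimated by REML; genotype
adjusted means are the generalized-least-squares fixed-effect solutions
averaged over replicates (equivalently, the sum-to-zero solutions plus the
overall mean).

Heritability needs a genotype variance, which a fixed-genotype model does
not provide, so a companion refit treats genotypes as random
(`G_i ~ N(0, σ²_g)`; replicates stay fixed). Line-mean heritability is

    h² = σ²_g / (σ²_g + σ²_ε / r),

with `r` the average number of replications per entry (2 in the standard
design). Whether a plot-basis or line-mean basis is meant in practice is a
genuine ambiguity; line-mean is the entry-mean definition used for
selecting among lines, and the formula is exposed so either convention can
be computed from the stored components. Location-years with `h²` below a
threshold (default 0.05) are dropped from combined analyses, with a reason
code (`low_h2` or `not_converged`) recorded.

**A caution on the filter.** At 50 entries × 2 replicates, the estimate
ĥ² at a site with no genetic signal has an F(49,50)-driven null
distribution: a pure-noise site lands below 0.05 only ~56% of the time.
The filter removes the worst sites on average but is *not* a reliable
detector of individual degenerate sites at this design size; users wanting
a strict screen need a larger threshold or replication.

### Multi-environment model

Across the `s` retained locations of one trial-year,

    y = X b + Z_r u_r + Z_g u_g + Z_ge u_ge + e,

with fixed site means `b`; replicate-within-site effects
`u_r ~ N(0, σ²_r_j)` heterogeneous across sites; genotype main effects
`u_g ~ N(0, σ²_g I)` (lines treated as unrelated — no pedigree or genomic
kinship); interaction effects `u_ge` with per-genotype across-site
covariance `Σ_ge`; and homogeneous residuals `e ~ N(0, σ²_e I)`
(a per-site residual variance is available via
`MetSpec(per_site_residual=True)`). `Σ_ge` takes one of four structures:

| variant    | Σ_ge                | parameters |
|------------|---------------------|------------|
| `fa`       | ΛΛ' + Ψ             | s·k − k(k−1)/2 loadings + s specific variances |
| `diagonal` | diag(ψ₁…ψ_s)        | s |
| `cs`       | ψ·I                 | 1 |
| `no_gxe`   | term dropped        | 0 |

The factor-analytic (FA) order defaults to k=1 (k=2 available); k must be
well below s for the site counts in this kind of series, and REML-AIC is
exposed (`MetFit.aic`) for order selection without being the default. Λ is
identified by zeroing its strict upper triangle; every reported quantity
depends on Λ only through Σ_ge, so the rotation fix has no scientific
content. "Not modeling G×E" is interpreted as dropping the `u_ge` term
(variant `no_gxe`); `cs` is the compound-symmetry-style alternative.

### REML evaluation and optimization

The restricted likelihood is defined on an orthonormal basis of error
contrasts,

    ℓ_R = −½[(n−p)·log 2π + log|V| + log|X'V⁻¹X| − log|X'X| + y'Py],

which is invariant to the contrast basis, so independent evaluation
strategies agree exactly. The general evaluator uses the Woodbury identity
on V = σ²_e·I + Z·D·Z' (cost governed by the number of random-effect
columns). For *complete balanced* data the likelihood factorizes exactly:
within-cell genotype contrasts are independent of site-replicate means,
giving (g−1) i.i.d. rows with the small (s·r)×(s·r) covariance
C = σ²_g·J + Σ_ge⊗J_r + σ²_e·I, plus per-site replicate-mean contrasts
from which each σ²_r_j profiles out in closed form. This fast path has
analytic gradients and is what makes the replicated simulation experiments
affordable; its equality with the Woodbury path (and with a dense
null-space oracle) is asserted to 1e-8 in the tests.

Optimization is bound-constrained L-BFGS-B on log-variances and raw
loadings. Variants are fitted as a nested chain (`no_gxe` → `diagonal` →
`fa`), each warm-started from the previous optimum (loadings enter at 1e-4
because Λ=0 is a stationary point), plus a method-of-moments start
(eigendecomposition of the cell-mean covariance) and seeded jitters
(default 5 starts for the multimodal FA surface, 2 otherwise). The chain
construction guarantees the optimized log-likelihoods respect the nesting
order up to numerical slack. A fit is declared converged when a start the
optimizer itself marked converged reaches the overall best value within
tolerance; an unconverged FA fit falls back to the diagonal variant
(flagged `fallback_from_fa`, and logged by the pipeline), mirroring how a
practitioner proceeds when the FA surface defeats the optimizer.
Variance components are bounded below at ~1e-10 and reported as exactly 0
below 1e-8.

BLUPs come from the mixed-model identity û = M⁻¹Z'R⁻¹(y − Xb̂) at the
REML optimum. With site indicators in X, genotype BLUPs sum to zero
exactly, and interaction BLUPs sum to zero within each site.

### Gains

Within each trial-year and scope (all locations, one megaenvironment, or
one country), the 10% highest-yielding lines (HYL) are the
⌈0.10 × n_test⌉ non-check entries with the highest BLUP-predicted yield
(ties broken by label; with 50 entries of which 2 are checks this is 5
lines). Their mean predicted yield is expressed as a percentage of the
long-term check cultivar and of the local check. The local check is a
single entry whose scope-level BLUP is the denominator (per-site ratios
averaged is available via `relative_yield` per site). Ordinary least
squares of the percentages on the trial-year index (1…T; slopes are
invariant to affine relabeling of years) gives the gain in % yr⁻¹; a
parallel OLS of the absolute HYL−check difference gives kg ha⁻¹ yr⁻¹ —
both are reported because the %→kg conversion convention is not unique.
Trials are unweighted (no weighting by location count).

**Attenuation.** The gain statistic regresses *predicted* yields, so BLUP
shrinkage attenuates the measured slope by roughly
κ = σ²_g / (σ²_g + V̄), where V̄ is the per-genotype prediction variance at
the scope level (interaction plus residual noise divided by the number of
sites). With few sites and strong G×E, κ can be far below 1 and measured
gains understate true gains; with many sites or dominant genetic
main-effect variance, κ ≈ 1. This is a property of the statistic itself,
not of the implementation, and drives the choice of simulation regime
below.

### Megaenvironment classification

Deterministic rules on site metadata, in order: late sowing → ME5
(management-induced heat stress); irrigated with coolest-quarter minimum
temperature in [3, 11) °C and normal sowing → ME1; rainfed with
wettest-quarter precipitation in [100, 400] mm → ME4; coolest-quarter
minimum temperature in [11, 16] °C → ME5; otherwise unclassified. ME1's
temperature interval is closed-below/open-above so that exactly 11 °C goes
to ME5. Each assignment records the rule that fired. A k-means (k=2)
clustering of site mean yields then refines the labels: a climatically-ME1
site in the low-yield cluster whose irrigation cannot be confirmed is
relabeled ME4 (`cluster_refined=True`, logged). The refinement policy is
one concrete, auditable choice; thresholds and the protection rule are
arguments. ME2/ME3/ME6 are out of scope.

### Site regression (SREG/GGE)

The genotype × environment table (environments = countries, built as
unweighted means of per-site BLUP predictions within country) is centered
by environment and, by default, standardized by environment ("scaled";
centered-only via `scaling="centered"`), then decomposed by SVD. The first
two components explain 100·(σ₁²+σ₂²)/Σσᵢ² of the processed variation.
Scores use symmetric singular-value partitioning (both sides scaled by
√σᵢ); genotype- and environment-metric partitionings are one flag away in
the score construction. Axis signs are fixed so each axis's environment
scores sum to ≥ 0 (genotype scores are centered, so their mean cannot
orient an axis), making output deterministic across linear-algebra
backends. The which-won-where polygon is the convex hull of genotype
scores; an environment's sector winner is the hull vertex with the largest
inner product with the environment score, which equals the rank-2
reconstructed best performer. Environment correlations are Pearson
correlations of genotype means with two-sided t-distribution p-values
(n−2 df); pairs sharing fewer than 3 genotypes are reported missing.

## Synthetic data

The generator emulates an ESWYT-like series: each trial-year distributes a
fresh set of 50 entries — entry 1 a site-specific local check, one entry
the long-term check — to a fixed network of locations across ME1/ME4/ME5,
grown as an α-lattice (2 replicates × 5 sub-blocks of 10 plots, entries
permuted per replicate by seeded permutation; no attempt at optimal
α-design concurrence, since the analysis model rather than design
optimality is under test).

Yields are site mean + replicate effect + sub-block effect + genotype
effect + interaction + residual, floored at 0.01 Mg ha⁻¹. Test lines
entering trial t draw effects from N(δ·t·μ_ref/100, σ²_g), where δ is the
configured trend and μ_ref the site-count-weighted midpoint of the ME site
mean ranges — so the check-relative gain statistic recovers δ directly.
The long-term check's effect is 0 in every trial; the local check sits
near the top decile of contemporary test lines with site-to-site wobble of
0.2·σ_g. Interaction effects per trial are drawn with covariance ΛΛ'+Ψ
(loadings N(0, loading_scale²), specific variances uniform in psi_range).
Optional pathologies: dropping genotype×site cells (checks are never
dropped), and "failed" sites with the residual SD inflated 20-fold.

Defaults (units Mg ha⁻¹): 8 trials; 22/9/7 sites in ME1/ME4/ME5 with site
means uniform in (4,7)/(1.5,3.5)/(2.5,4.5); trend 1.67% yr⁻¹; σ_g 0.2;
loading_scale 0.7; Ψ ∈ (0.02, 0.10); σ_rep 0.10; σ_sb 0.15; σ_e 0.40;
no missing cells or failed sites. The default interaction magnitude
(per-site interaction SD ≈ 0.5–0.9) deliberately represents the
strong-crossover situation of a series spanning irrigated, drought- and
heat-stressed megaenvironments, where G×E exceeds the genetic variance of
elite material — the regime factor-analytic modeling exists for, and the
only regime in which a rank-1 Σ_ge is statistically recoverable from 50
genotypes at 6 sites (an information-floor analysis with a noise-free
maximum-likelihood oracle gives a median relative Frobenius error of
≈0.27 under weak loadings, ≈0.16–0.19 under strong).

What the generator does **not** emulate: spatial field trends within
replicates beyond sub-blocks, year-to-year site turnover (the network is
fixed), genetic relatedness among lines, non-normal yield distributions,
and informative missingness. Passing tests therefore show correctness of
the estimation machinery under the stated model, not robustness to those
departures.

## Validation experiments (problem sizes)

The experiments in `metgain.benchmarks` (run by `scripts/acceptance.py`
and the acceptance tests) use these sizes, chosen as the smallest that
leave the measured property clearly identified:

* **Oracle agreement** — 20 random instances of ≤ 60 plots, 2–4 sites;
  both model likelihoods vs the dense null-space oracle (|Δ| < 1e-8).
* **Covariance recovery** — 25 single-trial datasets, 6 sites × 50
  genotypes × 2 reps, rank-1 truth, strong-crossover regime; median
  relative Frobenius error of Σ̂_ge ≈ 0.21 in the default seeds, and the
  nested likelihood ordering holds on every dataset.
* **Heritability** — 500 sites at σ_g=0.5, σ_e=0.3 without interaction;
  mean ĥ² within 0.02 of 0.847. The 20×-inflated-σ_e filter experiment
  (200 sites) measures the drop rate honestly; per the F-null analysis
  above it plateaus near 0.56–0.60, not near 1.
* **Gain recovery** — 8-trial series at 8 sites (4 ME1 / 2 ME4 / 2 ME5),
  50 entries, gain-measurement regime (σ_g=0.5, σ_e=0.3, loading 0.15,
  Ψ ∈ (0.005, 0.02), κ ≈ 0.97): 40 seeds each at trends 1.67 and 2.7%
  yr⁻¹, 150 seeds at trend 0 for the type-I rate of the slope t-test.
* **SREG identities** — 10 constructed rank-2 tables; exact (1e-9)
  identities and winner agreement.
* **Determinism** — a 3-trial pipeline run twice with one seed;
  byte-identical CSVs.

## Known limitations

* The FA REML surface is multimodal; multi-start with a moments warm start
  is a mitigation, not a guarantee. The nested-chain construction bounds
  the likelihood ordering but not global optimality.
* The unbalanced-data path uses numerical gradients and is intended for
  small-to-moderate problems (up to roughly 50 sites × 200 genotypes as a
  practical ceiling, well below that when many cells are missing).
* Measured gains are attenuated by BLUP shrinkage (see above); the package
  reports what the statistic yields and does not attempt a deattenuation
  correction.
* The h² filter is noisy at standard design sizes (see above).
* Site-specific local-check behaviour is intentionally outside the
  exchangeable-genotype model; local-check-relative gains inherit that
  model misfit, as they do with real data.
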