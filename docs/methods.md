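# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-data generator, and the numerical and design choices behind
`nlmsem`.

## Model family

The package implements one fixed model family: a balanced two-level SEM
with, at each level (within groups, between groups),

* two exogenous latent predictors ξ₁, ξ₂ with three indicators each
  (x₁–x₃ and x₄–x₆),
* one latent product term ξ₁ξ₂ with three matched-pair product indicators
  (x₁x₄, x₂x₅, x₃x₆ — indicators paired by reliability, each used once),
* one endogenous latent η with three indicators (y₁–y₃),
* the structural equation η = γ₁ξ₁ + γ₂ξ₂ + γ₃·ξ₁ξ₂ + ζ.

Identification follows the unconstrained product-indicator convention:
the first loading of every latent variable — including the product term —
is fixed to 1 and latent variances are free.  The covariances of ξ₁ξ₂
with ξ₁ and ξ₂ are fixed to 0; they vanish exactly for jointly normal,
zero-mean predictors (third-order moments), and freeing them would change
the degrees-of-freedom accounting below.  The mean structure is saturated
throughout, so all fit information comes from covariance restrictions.

A level can instead be *saturated* (all 78 = 12·13/2 covariance elements
free).  Free-parameter counts per level: 28 structured with the
interaction free (8 non-anchor loadings, 12 residual variances, 4 latent
(co)variances, γ₁, γ₂, γ₃, Var ζ), 27 with γ₃ fixed to zero, 78
saturated.  Hence df = 100 for the complete two-level model with both
interactions free, 101 with one interaction fixed, 50/51 for partially
saturated models, matching the saturated-minus-target convention.

## Data decomposition and product construction

Observed indicators decompose as x_ij = x_Bj + x_Wij with independent
between and within components.  The between component of each indicator
is estimated by the empirical-Bayes prediction from a one-way
random-intercept model, x̂_Bj = μ̂ + w(x̄_j − μ̂) with
w = τ̂²/(τ̂² + σ̂²/NS).  For a balanced design the ML variance components
have closed forms (σ̂² = SSW/(N−J), τ̂² = max(0, c·Σ(x̄_j−x̄)²/J − σ̂²)/c
with profiled grand mean), so no iterative mixed-model fit is needed; the
closed form is verified against a general mixed-model ML fit in the test
suite.  The within component is the observed value minus the between
estimate, so the decomposition reconstructs the data exactly.  A
raw-group-mean mode (w = 1) is available as a sensitivity switch and
produces practically identical test behaviour in this design.

Between components are centered at their grand mean before
multiplication.  Product indicators built from *estimated* components are
not identical to products of the true components: subtracting (shrunken)
group means attenuates product moments by roughly (1 − 1/NS)², about 6%
at NS = 30.  Because every product-term measurement parameter is free,
this attenuation is absorbed by the loadings/variances and does not bias
the structural interaction effects (mean γ̂₃ ≈ 0.200 at both levels in the
recovery tests) nor, appreciably, the fit statistics.

## Likelihood

With J groups of size c (N = Jc), 12 within-varying variables (y, x, and
the within products) and 3 between-only variables (the between products),
the sufficient statistics are the pooled within-group covariance S_PW
(divisor N−J) and the covariance S_B (divisor J−1) of the 15-dimensional
group-level vector (group means of the 12, plus the between products).
The deviance is the exact profiled-mean Gaussian log-likelihood,

    -2lnL = (N−J)[ln|Σ_W| + tr(S_PW Σ_W⁻¹)]
            + J ln|Σ_g| + (J−1) tr(S_B Σ_g⁻¹)
            + (N·12 + J·3) ln 2π + J·12·ln c,

where Σ_g embeds Σ_B on the (y, x, between-product) coordinates and adds
Σ_W/c on the within-varying coordinates; within-only products contribute
only Σ_W/c, between-only products only Σ_B, and their cross-covariance is
structurally zero.  The J vs J−1 weighting reproduces the raw-data
likelihood exactly (the tests verify equality with a direct per-group
multivariate-normal density evaluation to 1e-8, constants included).
Note the implied minimizer of the unstructured group-level term is
((J−1)/J)·S_B, which matters when injecting exact population moments in
tests.

Even the "saturated" model is iterative here: Σ_W appears in both terms,
and the group-level matrix is 15×15 (120 moments) while the model carries
only 156 parameters.  Saturated levels start at the moment estimators
(S_PW, and S_B minus the within contamination, eigenvalue-floored);
structured levels start at unit loadings, half-variance uniquenesses,
anchor-moment latent variances, and least-squares structural coefficients
from block-average factor-score proxies.

Optimization is L-BFGS with analytic gradients (matrix-calculus chain
rule through the loading/latent structure).  Non-positive-definite
proposals return +∞ and the line search backtracks; the ln|Σ| barrier
keeps iterates interior.  Convergence is declared when the max gradient
entry falls below max(1e-3, 5e-7·|deviance|) — the relative term reflects
that the deviance error near the optimum is O(|g|²/N), far below the 0.01
resolution relevant to any statistic.  One same-point restart (fresh
L-BFGS curvature memory) and one perturbed restart are attempted
otherwise.  Admissibility (non-negative variance estimates, positive
definite implied matrices) is checked after fitting and inadmissible
solutions are flagged and excluded from Monte Carlo tallies, never
constrained away, so Heywood cases remain observable.

## Test statistics

**Overall and level-specific tests.**  T_ML is the deviance difference
between a target model and the fully saturated model; its df is the
free-parameter difference.  Partially saturated tests structure one level
and saturate the other, isolating level-specific misfit (df 50/51).

**Robust rescaling.**  Product indicators are leptokurtic even under
Gaussian inputs, which inflates T_ML.  The rescaled statistic divides by
a sandwich scaling factor with groups as the i.i.d. units:

    c = [ tr(A₁⁻¹B₁) − tr(A₀⁻¹B₀) ] / df,

where, for each model, A is the observed information (central differences
of the analytic gradient) and B the outer-product sum of per-group score
vectors; the per-group scores are a single linear map of each group's
moment contributions and sum to zero at the optimum.  The baseline term
does not drop out because the saturated two-level model itself restricts
the group-level moments (the within-product block of Σ_g is tied to
Σ_W/c).  An asymptotically equivalent moment-space form
c = tr((U_target − U_baseline)·Γ̂)/df — residual normal-theory weights
against the empirical covariance of per-group moment contributions — is
implemented as `method="moment"` and used as a cross-check; both forms
converge to 1 on exactly normal two-level data.  The score form is the
production default because its finite-sample behaviour is markedly better
calibrated here: the moment-space trace carries an upward finite-J bias
in the high-kurtosis (product) directions of Γ̂ and in the inverse-based
weights, over-correcting T_MLR and costing power at J ≤ 1000, while the
observed-information form tracks the realized inflation (ĉ ≈ 1.14 at
J = 200 in the complete-model cell, against a measured asymptotic
inflation of ≈ 1.12).

**Difference tests.**  Single interaction effects are tested by nested
model comparison.  The production statistic is the raw deviance
difference divided by the *full* model's scaling factor,
Δ = (T_ML,restricted − T_ML,full)/ĉ_full, referred to a central χ² with
the free-parameter difference as df; no Satorra–Bentler difference
correction is applied.  Differencing two independently rescaled
statistics instead adds noise of order T·Δ(1/ĉ) (T ≈ 100 here), which
measurably inflates the Type-I error of small-df differences; a single
common factor avoids this, and the full model's factor is used because
the full model is correctly specified under both hypotheses.  The raw
(unscaled) ML difference remains available and carries the non-negativity
invariant; when optimizer noise produces a negative difference, the
restricted model is refit from the full model's projected solution.

Rejection is at p < α strictly, α = 0.05.

## Synthetic-data generator

The generator is the study-conditions oracle, not a convenience fixture.
Population values: loadings (1, √0.8, √0.8) and error variances
(0.25, 0.20, 0.20) at both levels — each indicator has reliability
exactly 0.80 (√0.8 ≈ 0.894 is the conventionally printed value); latent
predictor variances 1 with correlation φ₂₁ ∈ {0, 0.30} shared by both
levels; γ₁ = γ₂ = 0.30; interaction effects γ₃W, γ₃B ∈ {0, 0.20} define
the four population models (M_W0B0, M_WIB0, M_W0BI, M_WIBI); residual
variances ζ chosen so Var(η) = 1 at each level,
ζ = 1 − [γ₁² + γ₂² + 2γ₁γ₂φ₂₁ + γ₃²(1 + φ₂₁²)], i.e. 0.82 with no
interaction down to 0.7224 with interaction and correlated predictors.
Equal population values at both levels give every indicator an intraclass
correlation of 0.50.  The latent product term is centered (equivalently,
the between intercept is α = −γ₃B·φ₂₁ and the within equation uses
ξ₁ξ₂ − φ₂₁) so all indicators have mean zero.  Group sizes are balanced
at NS = 30; numbers of groups 200/500/1000.

Per-replication generators derive deterministically from
(master seed, design-cell identifier, replication index), so any single
replication is reproducible in isolation and identical configurations
yield byte-identical outputs.  A truth channel optionally retains the
latent draws for recovery and oracle tests.

What the generator does **not** emulate: unbalanced group sizes,
non-normal latent or error distributions, cross-level interactions,
missing data, level-specific model structures that differ between levels,
and real measurement artifacts (floors, ceilings, ordinal items).
Passing tests therefore demonstrate the behaviour of the fit statistics
under the idealized design above, not robustness to those features.

## Monte Carlo scale

The study grid is 4 population models × NG ∈ {200, 500, 1000} ×
φ₂₁ ∈ {0, 0.30}.  The default desk-scale profile runs 200 replications
per cell (the `full` profile 500): at 200 replications the binomial
standard error of a rejection percentage is 1.5–3.5 points, enough to
bracket the operating characteristics of interest.  The acceptance script
uses 150–200 replications per quantity and reports each rate with its
effective replication count; non-converged or inadmissible replications
are excluded and counted.  Replications are independent and evaluated
sequentially in index order, which makes the reduction deterministic.

## Known limitations

* The aggregation step (per-indicator empirical-Bayes decomposition) is
  an approximation to a joint latent-decomposition fit; its product-moment
  attenuation is absorbed by free parameters but is visible in raw moment
  comparisons (documented in the tests).
* The scaling factor ĉ is itself an estimate; at J = 200 its sampling
  noise (sd ≈ 0.03) slightly widens the T_MLR distribution relative to
  χ²(df).
* Only the matched-pair product strategy and balanced designs are
  implemented; all-pair products, unbalanced designs, and distributional
  estimators for the interaction (e.g. mixture-based ML) are out of scope.
* The uncorrected T_ML tail converges slowly: at NG = 200 its rejection
  rate fluctuates several points between 150-replication batches, so
  desk-scale estimates of the ML Type-I error carry noticeable Monte
  Carlo error (the robust statistic is far more stable).
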