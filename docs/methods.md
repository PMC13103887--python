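# Methods

This note documents the statistical models implemented in `datediag`, the
choices made where the design was genuinely open, and the limits of what
the simulation-based tests demonstrate.

## Setting

A *dated* phylogeny `D` is a rooted tree whose nodes carry calendar dates
(decimal years); branch `i` has duration `d_i = date(child) − date(parent)`.
An *undated* phylogeny `L` has the same topology with branch lengths `l_i`
in substitutions (integer counts under the discrete clock models, per-genome
expected substitutions otherwise).  The package diagnoses whether a dated
tree — a posterior sample from Bayesian dating, or a point estimate — is
consistent with the undated tree it was inferred from under the clock model
used for the inference.

## Clock models

Four interchangeable branch models, all with mean `d·μ`:
Poisson(dμ) and Gamma(shape dμ, scale 1) for the strict clock (variance
dμ), and NegBin(r = dμ/ω, p = 1/(1+ω)) and Gamma(shape dμ/(1+ω), scale
1+ω) for the additive relaxed clock (variance dμ(1+ω)).  The negative
binomial is parametrized by number of successes and success probability;
this is the convention that reproduces the stated moments.  ω = 0 relaxed
models are defined as their strict limits.  A branch of zero duration
carries unit mass at `l = 0`.  A non-integer substitution value presented to
a discrete model (which arises from the root split below, or from
substitution-scaled input trees) is scored under the same-moment continuous
model; an integer value is always scored by the discrete mass.

## Branch correspondence and the root split

Branches of `D` and `L` are matched by the tip bipartition they induce
(child order and tip-label permutations are irrelevant; polytomies are
accepted, each edge matched independently).  The two branches `a`, `b`
incident to the root of `D` jointly correspond to the root-spanning branch
of `L` (an unrooted tree cannot distinguish them); their pooled
substitutions `l_x` are divided proportionally to durations,
`l_a = l_x·d_a/(d_a+d_b)`, with a 50/50 split if both durations are zero.
Trees that disagree topologically beyond the root raise an error listing
the offending bipartitions — no reconciliation is attempted.

## Residual analysis

For each branch the uniform residual is `u_i = F_i(l_i) = P(L_i ≤ l_i |
d_i)`.  For the discrete families the probability integral transform is
randomized to restore exact uniformity:

    u_i ~ Uniform(P(L_i ≤ l_i − 1), P(L_i ≤ l_i)),

i.e. uniform on the probability interval whose width is `P(L_i = l_i)`.
(The interval `(F(l), F(l+1))`, which carries the mass of `l+1`, does not
yield Uniform(0,1) residuals; the implemented interval provably does, as
the calibration tests verify by simulation.)  Residuals are clipped to
`[1e-12, 1−1e-12]` before the normal quantile `n_i = Φ⁻¹(u_i)`; the clip
bound only matters for astronomically extreme branches.

Normality of the `n_i` against the fully specified N(0,1) is tested with
the Anderson–Darling simple-hypothesis statistic

    A² = −k − (1/k) Σ (2i−1)[ln z₍ᵢ₎ + ln(1 − z₍ₖ₊₁₋ᵢ₎)],  z = Φ(n) sorted,

with the p-value from the Marsaglia & Marsaglia (2004) series for the
asymptotic null distribution, without finite-sample correction; Monte-Carlo
checks put the size at 5.0 ± 0.5% for samples of 200.  Testing `n` against
N(0,1) is identical to testing `u` against Uniform(0,1).  A composite test
(Shapiro–Wilk) would be wrong here: the null fully specifies mean 0 and
variance 1, and underdispersion is precisely one of the signals of
interest.

The analysis is repeated for every retained posterior draw — each with its
own dated tree, clock parameters, and independent PIT randomization —
producing a posterior distribution of p-values summarized by its median and
the proportion below 0.05.  At most 1,000 draws are used (evenly
subsampled).

## Posterior predictive checks

`S` replicate undated trees are simulated by drawing posterior samples with
replacement (a point estimate is reused for every replicate) and applying
the inference clock model to the drawn dated tree.  Observed and simulated
trees are compared on the mean, sample variance (n−1 divisor, used
identically on both sides so the choice cancels), maximum of branch
lengths, and stemminess (internal branch length over total; the
root-adjacent branches count as internal when their child is an internal
node).  Each statistic gets a two-sided empirical p-value with add-one
correction,

    p = min(1, 2·min[(1+#{sim ≤ obs}), (1+#{sim ≥ obs})]/(S+1)),

which is strictly positive and super-uniform under exchangeability.  The
four p-values are Benjamini–Hochberg adjusted and their minimum is the
combined p-value (a harmonic-mean combination is available as an option);
the verdict is "issue" below α = 0.05.  `S` defaults to 1,000.  Two-sided
p-values were chosen because both inflated and deflated statistics indicate
misfit; the choice is conservative for one-sided alternatives.

## Outlier detection

*Root-to-tip*: OLS of tip-to-root distance on sampling date; the implied
root date is the x-intercept.  The 95% expected envelope around the line is
the central Poisson interval with mean `slope·(date − x-intercept)` — the
strict-clock generative expectation; tips outside are flagged.  *Date
randomization*: `p = (1 + #{permuted R² ≥ observed})/(B+1)` under random
permutation of tip dates (B = 10,000 by default; the slope can be used as
the statistic instead).  *Per-branch test*: each branch's count gets a
two-sided tail probability under the fitted clock model,
`2·min(P(L ≤ l), P(L ≥ l))` capped at 1, BH-adjusted, flagged at q < 0.05.
This is an explicit stand-in for treedater's per-branch likelihood
comparison, whose exact statistic is not public; the tail formulation has
the advantage of exact finite-sample meaning under the fitted model.

## Bayesian dating engine

The posterior is coalescent prior × clock likelihood × parameter priors on
a fixed topology.  The heterochronous constant-Ne coalescent log-density is
`−Σ k(k−1)Δt/(2Ne) − (n−1)·ln Ne` over the inter-event intervals of the
lineage-count curve.  Priors: μ ~ Exponential with mean equal to the
root-to-tip slope (floored at 1e-6), ω ~ Exponential(1), and the improper
1/Ne density on Ne.  Proposals are a random scan (90% single internal-node
date moves by truncated normal walk, 10% multiplicative log-normal walks on
the free parameters, with the Jacobian in the acceptance ratio); step sizes
adapt toward 25% acceptance during burn-in and are frozen afterwards, so
the retained sample targets the exact posterior.  Defaults: 200,000
proposals, half burn-in, thinned to ≤ 1,000 draws.  Initial node dates come
from a postorder pass placing each internal node `max(l, 0.5)/μ₀` years
older than its children at the regression-slope rate μ₀.  Any of
{root date, μ, ω, Ne} can be held fixed.  Correctness is verified against a
fine-grid numerical posterior on a three-tip problem (total variation
< 0.05) and by parameter-recovery coverage (95% CIs for μ cover the truth
in ≥ 17/20 replicates).

DIC uses the variance form, `DIC = mean(deviance) + var(deviance)/2` with
deviance `−2·log clock likelihood`; the variant choice only shifts both
models equally in the comparisons made here.

Estimators: `μ̂ = Σl/Σd` (the exact profile maximizer for the strict
models); the coalescent rate `α̂ = Σk(k−1)Δt / (2(n−1))`, whose posterior
under the improper inverse-gamma prior is `1/α ~ Gamma(n−1, rate
Σk(k−1)Δt/2)`.  (The shape/scale printed elsewhere for this posterior is
dimensionally inconsistent with the estimator being its mean; the
implemented parametrization is the one consistent with it, verified by the
closed-form median check in the tests.)

## Point estimates and the pseudo-posterior

ML-style dating maximizes the clock likelihood over node dates at a fixed
rate (a convex problem with linear ordering constraints, solved by SLSQP
with analytic gradients) alternating with the closed-form rate update
`μ̂ = Σl/Σd` until stationary.  The fully joint maximum is degenerate — the
profile likelihood grows without bound as μ → ∞ while the tree collapses —
but the block ascent converges to a self-consistent interior optimum, which
is the behavior practical ML daters exhibit.  The resulting durations track
the observed counts too closely; residuals computed directly against such a
point estimate are distorted by this overfitting (the conjugate
Gamma-Poisson toy model in `conjugate_toy` reproduces the effect exactly:
plug-in residuals are underdispersed, posterior-resampled residuals are
uniform).

The pseudo-posterior bridges the gap: the point-estimate durations are
scaled by μ̂ into a continuous "data" tree, and a short MCMC runs under the
continuous strict clock with μ fixed at μ̂ and Ne fixed at α̂, sampling
node dates only.  One numerical choice matters: ML estimates set
zero-count branches to zero duration, and a continuous Gamma density
assigns such a branch zero likelihood for every positive duration, freezing
the sampler.  Branches carrying less than half a substitution are therefore
treated as zero-count branches with the discrete model's point mass
`exp(−dμ)` (`exp(−(dμ/ω)·ln(1+ω))` for the relaxed family).  In validation
on replicate strict-clock datasets the pseudo-posterior residual p-value
summaries track full-posterior ones closely (per-dataset medians averaging
≈ 0.39 vs ≈ 0.46 for the full posterior, proportions below 0.05 averaging
≈ 9% vs ≈ 6%), with a small anticonservative remainder attributable to the
continuous scoring of the rate-redistributed point-estimate tree; both
summaries have large dataset-to-dataset spread (sd of the median ≈ 0.2), so
single-dataset values should be read accordingly.

## Simulators

The heterochronous coalescent is simulated backward in time: with `k`
active lineages the next coalescence has hazard `k(k−1)/(2N(t))`,
interleaved with the fixed sampling events.  Time-varying `N(t)` uses
time-rescaling with the integrated hazard inverted per interval (closed
form for constant and logistic trajectories, bracketed Brent otherwise,
tolerance 1e-12).  The logistic clonal-expansion trajectory
`N(t) = M(t−s)²/(h² + (t−s)²)·1[t ≥ s]` starts at zero, reaches `M/2` at
`s+h`, and saturates at `M`; its diverging inverse size at `s` guarantees
every component coalesces after its origin.

Scenario defaults are the study conditions used throughout the tests and
the acceptance script: 100 tips uniform on 2010–2020, constant Ne·g = 1
year, μ = 10 substitutions/year, ω = 5 for relaxed data, 5 outlier tips
with +20 substitutions.  The structured (confounded) scenario joins three
components of 50 tips, sampled in 2000/2010/2020, each growing logistically
(M = 2, h = 3 years) from 10 years before its sampling date, onto a
backbone with divergences at 1948 and a root at 1946; with these defaults
roughly a quarter of replicates show the confounding signature (regression
slope well above μ with a root estimate decades too recent), matching the
reported "about a third" ballpark.  Divergence-date joining of
independently simulated components is an explicit substitute for a full
structured-coalescent simulation, which is out of scope.

## What the tests do and do not show

All validation data come from the package's own simulators, under exactly
the model families the diagnostics assume, with an infinite-sites reading
of substitution counts.  Passing tests therefore demonstrate internal
calibration and power under correctly- and incorrectly-specified clock
models — not robustness to recombination, rate variation along the genome,
sequencing error, finite-sites saturation, or misrooted input trees, none
of which the simulators emulate.  Problem sizes in the test suite are
scaled for a single CPU (50–100 tips, 20 replicates where a protocol calls
for 100); rejection-rate checks use exact binomial bands at those sizes.
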