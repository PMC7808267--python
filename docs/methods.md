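# Methods

## Data model

A two-stage SMART records, for patient i, the trajectory
{O1ᵢ (optional), A1ᵢ, O2ᵢ, A2ᵢ, Yᵢ}: stage-1 treatment A1 randomized
with probabilities π₁, an intermediate response category O2 (0-based;
binary in both worked designs but any R ≥ 1 per arm is supported),
stage-2 treatment A2 randomized within the (A1, O2) branch with
probabilities π₂, and a final outcome Y (continuous "gaussian" family or
0/1 "binomial" family). A *branch* with a single stage-2 option is
degenerate: no re-randomization, π₂ = 1. A baseline category O1 is
accepted in data files but treated as a single stratum (stage-1
assignment non-adaptive), matching both worked designs.

An adaptive treatment strategy D = (a1; a2(r) for each response
category r) has value θ = E[Y | follow D]. Strategies are enumerated
arm by arm as the Cartesian product of the branch option sets, last
category varying fastest, so G = Σ_arms Π_r |options(a1, r)|. Display
codes `(a1;a2_r0,a2_r1,…)` use the raw treatment codes.

## Degrees of freedom of the global test

Within one arm, the achievable strategy values are a bilinear function
of the branch-level choices, so they span a space of dimension
Σ_r |options| − R + 1, not Π_r |options|. The global contrast space
therefore has rank

    ν = [ Σ_arms ( Σ_r |options(a1,r)| − R(a1) + 1 ) ] − 1,

which the package uses as the reference df (5 for the canonical
2-arm × binary-response × 2-option design, where G − 1 would be 7). A
degenerate branch contributes nothing. This is also, verifiably, the
numerical rank of CΣCᵀ for any positive-variance configuration — the
property that makes Q asymptotically χ²_ν — and the package tests it
against a brute-force rank oracle over randomized designs. Note that the
rank of Σ itself is ν + 1 per connected piece of overlap structure; it
is the *contrast* covariance whose rank equals ν.

## Estimators

**G-computation.** With p̂_r the arm's empirical response-category
proportions and Ȳ_seq the per-sequence outcome means,
θ̂_g = Σ_r p̂_r Ȳ(a1, r, a2_g(r)). The covariance is the delta-method
plug-in: for strategies g, g′ in the same arm,

    Cov(θ̂_g, θ̂_g′) = Σ_r p̂_r² σ̂²_seq / n_seq · 1{a2_g(r) = a2_g′(r)}
                     + Σ_r Σ_r′ Ȳ_g(r) Ȳ_g′(r′) · p̂_r(1{r=r′} − p̂_r′)/n_arm,

and exactly zero across arms (disjoint patients). The two terms are the
sequence-mean sampling variability and the multinomial response-rate
variability; the cross term vanishes because Ȳ is conditionally
independent of the counts. `common=True` pools σ̂² across all sequences
of the trial, weighted by n_seq − 1 (pooled proportion for the binomial
family); pooling across the whole trial rather than within arm was a
deliberate choice, matching the per-family homoskedasticity reading of a
"common variance" option. A sequence with a single record yields a
missing variance (propagated as a missing standard error, with a logged
warning) rather than an error, so point estimates remain available.

**IPW.** θ̂_g is the weighted mean of Y over strategy-consistent
patients, weights w = 1/(π₁π₂) (design probabilities, or empirical
frequencies on request). The covariance comes from the empirical
cross-products of influence functions
IF_i(g) = 1{consistent} w_i (Y_i − θ̂_g) / mean(1{consistent} w),
Σ̂ = IFᵀIF/n². Consistent sets for different arms are disjoint, so the
block-diagonal structure is exact here too.

The same two forms evaluated at the design parameters (q_seq = π₁P2π₂
in place of n_seq/n, P2 in place of p̂) give the design-stage Θ*, Σ*
used in sizing. At the canonical design the G-computation form
reproduces the hand-derivable per-subject variance n·Var(θ̂₁) = 450
(0.25·(100/0.125)·2 + 0.5·(11−1)²), and Monte Carlo simulation of the
estimator confirms both the variance and the implied noncentrality
E[Q] ≈ ν + nΔ, so sizing and analysis are self-consistent: simulating at
the computed N yields the targeted power (checked at 2000 replicates in
the acceptance suite).

## Inference

Q = (CΘ̂)ᵀ(CΣ̂Cᵀ)⁻(CΘ̂) with C = (1 | −I) and the Moore–Penrose
pseudoinverse (relative singular-value cutoff 1e-8); Σ̂ is on the
estimator scale so no further n factor appears. The pseudoinverse is
essential, not cosmetic: CΣ̂Cᵀ is singular by construction whenever
ν < G − 1. Q is invariant to strategy order and to the choice of
reference strategy (tested to 1e-8). The p-value uses the central χ²_ν
with the *design* df; if the numerical rank of CΣ̂Cᵀ differs (degenerate
data), both are reported and a warning logged. Pairwise comparisons use
z = (θ̂_j − θ̂_k)/se with se² = Σ̂_jj + Σ̂_kk − 2Σ̂_jk, simultaneous
CIs at quantile z_{1−α/(2n_p)} (n_p = G(G−1)/2 or a caller-supplied
`ntest`), and *unadjusted* two-sided p-values — the Bonferroni
adjustment lives in the interval width and the decision threshold
α/n_p, mirroring how such tables are conventionally reported. The
global test is a gate-keeper: the pairwise block is only interpreted
when it rejects.

Confidence intervals use normal, not t, quantiles throughout: all
guarantees are large-sample.

## Noncentrality solver

λ* solves "power at level α with ν df equals 1 − β". The solver treats
the tolerance `d` (default 1e-4) as a cap on the attained type-II-error
gap |P(χ²_ν(λ) ≤ χ²_{ν,1−α}) − β| and returns the infimum of the
acceptance set — the value a monotone upward search stepping by `d`
would stop at — located by bracket expansion plus bisection, so the
result is independent of the `start` argument. At ν = 5, α = 0.05,
β = 0.20 this gives 12.8248; shrinking `d` converges to the exact
power-equation root 12.8276. Sample sizes are rounded up, e.g.
12.8249/0.1213 = 105.7 → 106.

Pairwise sizing uses the two-independent-sample normal approximation
without multiplicity adjustment by default (an optional `ntest` divides
α), reproducing e.g. 20 patients per strategy at d = 0.90.

## Synthetic data

`simulate_trial` draws each column in the fixed order A1 → O2 → A2 → Y
from one `numpy.random.default_rng` stream; a fixed seed reproduces a
dataset byte-for-byte within this implementation (the contract across
implementations is distributional, not bytewise). Degenerate branches
assign with probability one. `make_codiacs_like` fixes a SIM emulating a
stepped-care depression SMART — 2 arms, binary response, all
probabilities 0.5, sequence means spanning ≈1.5–14.5 and SDs 7–10, the
ranges typical of six-month depression-score reductions — and simulates
108 patients with a default seed chosen so that every sequence is
populated. It is labelled synthetic everywhere: it exercises the full
pipeline structurally but does not (and is not meant to) reproduce any
published trial's numbers.

What the simulator does *not* emulate: dropout and missing outcomes,
covariate-dependent randomization or response, non-normal /
heteroskedastic-within-sequence outcomes beyond the per-sequence SD, and
stage-1 adaptivity to O1. Passing tests therefore certify the estimators
and tests under the design's own sampling model, not robustness to those
departures.

## Monte Carlo study sizes and numerical conventions

Calibration checks use 2000 replicates at the computed N for power and
5000 replicates of n = 500 for type-I error (binomial SE ≈ 0.9% and
0.3%); parameter recovery uses 500 trials of n = 500 with 3-MC-SE bias
bounds; distributional checks (variance oracle, noncentrality oracle)
use 300–400 replicates with 3–4 SE bands. These sizes make the
stochastic assertions sharp enough to catch a wrong variance term while
keeping the default suite quick. Probability-sum validation uses a 1e-8
absolute tolerance; rank decisions use a 1e-8 relative singular-value
cutoff; the Monte Carlo loop estimates with the pooled (`common=True`)
variance so that small simulated trials with singleton sequences remain
estimable. The `digits` arguments round display output only, never
computation.

## Known limitations

- Two treatment stages only; no continuous tailoring variables; no
  re-randomization on baseline covariates beyond a single O1 stratum.
- No missing-data handling; every record must be a completed patient.
- The design-stage IPW covariance is the influence-function
  approximation; it is conservative relative to G-computation
  (never smaller on the diagonal), which is the expected efficiency
  ordering.
- Q-learning/A-learning style regression estimators and closed-testing
  multiplicity procedures are out of scope.
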