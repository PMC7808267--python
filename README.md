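# smartats

Design and analysis of **sequential multiple assignment randomized
trials (SMARTs)** for comparing **adaptive treatment strategies (ATSs)**.

A SMART randomizes each patient twice: at baseline among the stage-1
treatments, and again — after an intermediate evaluation O2 — among the
stage-2 options open to that arm/response history. One trial therefore
embeds a whole family of strategies, each a decision rule
`(a1; a2 per response category)`, and a patient's observed path
(A1, O2, A2) contributes to every strategy that agrees with it. That
overlap makes the strategy-value estimates correlated and their joint
covariance singular, which is what the analysis here is built around.

`smartats` is for trial statisticians and clinical investigators who
need to take a SMART from design to final report:

- **Sample size** — the global route solves the noncentral chi-squared
  power equation χ²-power(λ*) = 1 − β at the design's degrees of freedom
  ν, forms the standardized overall effect size
  Δ = (CΘ*)ᵀ(CΣ*Cᵀ)⁻(CΘ*) from design assumptions, and returns
  n = ⌈λ*/Δ⌉; the pairwise route uses the classic
  n = ⌈2(z₁₋α/₂ + z₁₋β)²/d²⌉ per strategy.
- **Estimation** — strategy values θ̂ by G-computation
  (θ̂_g = Σ_r p̂_r Ȳ(a1, r, a2_g(r))) or inverse-probability weighting,
  with the full covariance matrix Σ̂ (delta-method or
  influence-function), block-diagonal across stage-1 arms.
- **Inference** — the generalized-inverse Wald statistic
  Q = (CΘ̂)ᵀ(CΣ̂Cᵀ)⁻(CΘ̂), asymptotically χ²_ν under
  H0: θ₁ = … = θ_G, used as a gate-keeper before all-pairs comparison
  with Bonferroni simultaneous confidence intervals.
- **Exploration** — per-sequence descriptive statistics, design
  diagrams, box/bar summaries, and forest plots.
- **Simulation** — a seeded trial generator and a Monte Carlo harness
  for power and type-I error of a planned design.

## Worked example

The package ships a synthetic 108-patient two-stage depression-management
trial (two stage-1 arms coded 0/1, binary early response, re-randomization
between the same two options, outcome = depression-score reduction at six
months):

```python
from smartats import (codiacs_like_sim, make_codiacs_like, parse_design,
                      smartest, smartsize)

design = parse_design(codiacs_like_sim())
data = make_codiacs_like()
report = smartest(data, design, method="gcomp", alpha=0.05, adjust="bon")
gt = report.global_test
print(f"Q = {gt.statistic:.2f} on {gt.df} df, p = {gt.p_value:.4f}")
```

prints

```
Q = 9.31 on 5 df, p = 0.0974
```

Q is the global Wald statistic over the 8 embedded strategies. The
degrees of freedom are 5 — not G − 1 = 7 — because strategy overlap
imposes exact linear constraints on the estimates (within each
full-factorial arm, θ̂₀₀ − θ̂₀₁ − θ̂₁₀ + θ̂₁₁ = 0 identically). With
p = 0.097 the gate-keeping test does not reject at the 5% level, so no
strategy selection would be made from these (synthetic) data; the
pairwise block (28 contrasts, per-test threshold 0.05/28 = 0.0018)
documents all simultaneous intervals regardless.

Sizing the same design prospectively:

```python
print(smartsize(global_=True, df=5, alpha=0.05, beta=0.20, delta=0.1213).to_dict())
# {'NCP': 12.824814085520302, 'delta': 0.1213, 'df': 5, 'N': 106}
print(smartsize(global_=False, delta=0.90).to_dict())
# {'delta': 0.9, 'n_per_ats': 20}
```

i.e. a noncentrality of ≈12.825 is needed for 80% power at 5 df, and an
assumed effect size of 0.1213 translates into 106 patients in total; a
pairwise comparison powered for a standardized difference of 0.90 needs
20 patients per strategy.

The `examples/` directory holds one short script per capability
(sample size, descriptives, estimation, testing, operating
characteristics); each prints its results with a note on what they mean.
A thin CLI mirrors the library: `smartats size|ncp|seqmeans|atsmeans|
test|simulate|oc --help`.

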