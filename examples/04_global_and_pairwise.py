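"""Gate-keeping comparison of strategies.

The global Wald test Q = (C theta)' (C Sigma C')^- (C theta) asks whether
any strategies differ at all; its reference distribution is chi-squared
with df determined by the design (5 here, not G-1=7, because overlap
imposes exact linear constraints).  Only if it rejects does one read the
pairwise table, whose simultaneous confidence intervals are Bonferroni
adjusted over all 28 contrasts.
"""

from smartats import codiacs_like_sim, make_codiacs_like, parse_design, smartest

data = make_codiacs_like()
design = parse_design(codiacs_like_sim())

report = smartest(data, design, method="gcomp", alpha=0.05, adjust="bon")

gt = report.global_test
print(f"Global test: Q = {gt.statistic:.2f} on {gt.df} df, "
      f"p = {gt.p_value:.4f} (N = {gt.n_total}, G = {gt.G})")
# p < 0.05 would license strategy selection; otherwise stop here.

print(f"\nPairwise: {report.pairwise.n_p} contrasts, per-test threshold "
      f"{0.05 / report.pairwise.n_p:.4f}")
print(report.pairwise.table.round(3).head(10).to_string(index=False))
# Each row: difference in strategy values, its simultaneous CI (covers
# zero -> not distinguishable at the family level), Z and unadjusted p.
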