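"""Sample-size calculation for a two-stage SMART, three ways.

A SMART comparing G adaptive treatment strategies is powered through a
global chi-squared test: solve the noncentrality lambda* that gives the
targeted power, form the standardized overall effect size Delta from the
design assumptions, and take n = ceil(lambda*/Delta).  A pairwise route
sizes the trial like a classic two-arm comparison instead.
"""

from smartats import codiacs_like_sim, get_ncp, smartsize

# Route 1: explicit effect size and df (as a statistician would supply)
res = smartsize(global_=True, df=5, alpha=0.05, beta=0.20, delta=0.1213)
print("global test, delta given:", res.to_dict())
# NCP ~ 12.825 is the chi-squared shift needed for 80% power at 5 df;
# N = 106 patients in total.

# Route 2: from a sequence information matrix (design assumptions only)
sim = codiacs_like_sim()
res2 = smartsize(sim=sim)
print("global test, from SIM:   ", res2.to_dict())
# Here df and Delta are derived from the SIM itself; N is the total
# enrollment that gives 80% power for *this* configuration of sequence
# means, SDs, response rates and randomization probabilities.

# Route 3: pairwise, for a targeted standardized difference of 0.90
res3 = smartsize(global_=False, delta=0.90)
print("pairwise:                ", res3.to_dict())
# 20 patients per strategy, as in a two-arm z-test comparison.

# The noncentrality parameter alone:
print("lambda* at df=5:", round(get_ncp(5, 0.05, 0.20, d=1e-4, start=5), 4))
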