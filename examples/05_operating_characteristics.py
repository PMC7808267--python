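"""Monte Carlo check of a planned design.

Before committing to a sample size, simulate the trial at that size and
confirm the analysis behaves: about 80% rejections under the assumed
alternative, about 5% under a null configuration.
"""

from smartats import codiacs_like_sim, operating_characteristics, smartsize

sim = codiacs_like_sim()
n = smartsize(sim=sim).n_total
print(f"computed total sample size: {n}")

power = operating_characteristics(sim, n=n, reps=500, alpha=0.05, seed=1)
print("power at the computed N:", power)
# 'power' should sit near the targeted 0.80, within ~2 binomial SEs.

null = sim.copy()
null["MEAN"] = 5.0  # no strategy differs
size = operating_characteristics(null, n=n, reps=500, alpha=0.05, seed=2)
print("type-I error under the null:", size)
# should sit near the nominal 0.05.
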