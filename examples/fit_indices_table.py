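"""Posterior predictive fit indices for a well- and a mis-specified model.

For each kept iteration the chi-square discrepancy of the observed data and
of a same-size replicate dataset are compared (PPP), and per-iteration
BRMSEA / BCFI realizations are formed with the effective parameter count pD
from the marginalized deviance.  A PPP near 0.5 indicates adequate fit; the
mis-specified one-factor model is flagged with PPP ~ 0 and a large BRMSEA.
"""

import pandas as pd

import bayescfa as b

gp = b.default_generating_parameters()
rm = b.generate_responses(gp, n=1500, mode="continuous", seed=21)
sm = b.compute_sample_moments(rm)
specs = b.mspss_specs()

kw = dict(n_chains=3, n_warmup=500, n_kept=500)
indep = b.fit_independence_model(sm, seed=22, **kw)

rows = []
for name in ("one_factor", "three_factor"):
    draws = b.run_chains(sm, specs[name], seed=23, **kw)
    fp = b.assess_fit(draws, indep, sm, specs[name], seed=24)
    rows.append(b.summarize_fit(fp, model=name))

print(pd.DataFrame(rows).round(3).to_string(index=False))
print("\nthe one-factor row shows decisive misfit (ppp ~ 0, brmsea >> 0.08);")
print("the three-factor row, fitted to its own generating structure, shows")
print("ppp near 0.5, brmsea near 0 and bcfi near 1.")
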