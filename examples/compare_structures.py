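"""Bayes-factor dimensionality test across the five candidate structures.

Log marginal likelihoods are approximated by the Laplace method at the
posterior mode (on the unconstrained scale, Jacobian-corrected); pairwise
Bayes factors follow by subtraction and are reported on the log10 scale,
where values above 2 are conventionally read as decisive.
"""

import bayescfa as b

gp = b.default_generating_parameters()
rm = b.generate_responses(gp, n=1500, mode="continuous", seed=31)
sm = b.compute_sample_moments(rm)

out = b.compare_models(sm, b.mspss_specs(), n_starts=3, seed=32)
print("log marginal likelihood per structure:")
for name, lml in out["log_marginal"].items():
    print(f"  {name:18s} {lml:12.1f}")

bf = out["log10_bf"]["three_factor"]
print("\nlog10 Bayes factors, three-factor over:")
for other, v in bf.items():
    if other != "three_factor":
        print(f"  {other:18s} {v:8.1f}  ({'decisive' if v > 2 else 'not decisive'})")
print("\nhundreds of log10 units reflect the same order of decisiveness as the")
print("astronomically large factors reported for this instrument's validation.")
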