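# bayescfa

Bayesian confirmatory factor analysis (CFA) for psychometric scale
validation, built around the workflow used to validate multidimensional
questionnaire instruments such as the 12-item perceived social-support
scale (three 4-item subscales: Significant Other, Family, Friends):

* **Marginal-likelihood CFA by MCMC** under vague priors — the measurement
  model `y = ν + Λη + ε` with `η ~ N(0, Φ)`, `ε ~ N(0, Θ)` and the latent
  factors integrated out, so `y ~ N(ν, ΛΦΛ′ + Θ)`; unit loading
  identification (first item per factor fixed to 1), three chains with
  PSRF and batch-means MCSE convergence checks.
* **Posterior predictive model checking** with the likelihood-ratio χ²
  discrepancy: the posterior predictive p-value PPP (≈ 0.5 for adequate
  fit), and per-iteration Bayesian fit indices

  BRMSEA_i = √( max(0, D_i^obs − p*) / ((p* − pD) · N) ),
  BCFI_i = 1 − max(0, D_{H,i}^obs − p*) / (D_{0,i}^obs − p*),

  with `p* = p(p+3)/2` unique sample moments and `pD` the effective number
  of parameters from the marginalized deviance.
* **Dimensionality testing** by Bayes factors from Laplace-approximated log
  marginal likelihoods, reported on the log10 scale for the astronomically
  large factors this kind of comparison produces.
* **Reliability** as Bayesian McDonald's Ω_H = (Σλ)²ψ / ((Σλ)²ψ + Σθ),
  evaluated at every MCMC iteration to give a posterior distribution of
  subscale reliability.
* **Criterion validity** by tie-corrected Kendall's τ-b with a uniform
  [−1, 1] prior: truncated-normal posterior and Savage–Dickey Bayes factor.
* A **synthetic-data generator** parameterized by the published
  posterior-mean estimates, so the whole pipeline is testable without
  access to the original survey data.

The package is a library: import it from Python, or start from the
narrative scripts in `examples/` (one per capability).

## Worked example

Fit the three-factor model to synthetic study-scale data and reproduce the
reliability analysis:

```python
import bayescfa as b
from bayescfa.reliability import omega_posterior

gp = b.default_generating_parameters()          # published truth set
rm = b.generate_responses(gp, n=3868, mode="continuous", seed=11)
sm = b.compute_sample_moments(rm)
spec = b.mspss_specs()["three_factor"]

draws = b.run_chains(sm, spec, seed=12)          # 3 chains, 1000+1000
print(b.convergence_report(draws).passed)        # True

rp = omega_posterior(draws, spec, "SO")
print(round(rp.posterior_mean, 3), [round(v, 3) for v in rp.ci95])
```

Output:

```
True
0.947 [0.944, 0.95]
```

`True` confirms the chains converged (all PSRF < 1.1, all MCSE below 5% of
the posterior SD); 0.947 is the posterior-mean Ω_H of the Significant Other
subscale — the proportion of its total-score variance attributable to the
common factor — with a tight 95% credible interval, i.e. excellent
reliability.  `examples/fit_indices_table.py` prints the corresponding fit
table (PPP, BRMSEA, BCFI) and `examples/compare_structures.py` the Bayes
factors that decisively favor the three-factor structure over one- and
two-factor alternatives.

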