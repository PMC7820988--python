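"""Estimands vs resampling estimators, at reduced scale.

Approximates the model-selection-frequency estimand of the true 8-predictor
model at N=750 over Q=200 simulated datasets, then measures how well four
resampling schemes estimate it from a single dataset (B=100 resamples
each, over 50 datasets).

Reading the output: subsampling with the largest proportion (S_0.8) comes
closest to the estimand while the bootstrap underestimates it badly —
bootstrap resamples duplicate observations, which changes selection
behaviour, so sampling without replacement is the right tool for selection
frequencies.  Monte-Carlo SEs show the precision of this reduced-scale run.
"""

from selstab import (approximate_estimands, bootstrap_plan,
                     default_covariate_config, default_outcome_config,
                     evaluate_estimators, subsample_plan)

cov, out = default_covariate_config(), default_outcome_config()

est = approximate_estimands(cov, out, N=750, Q=200, seed=10)
print(f"MSF estimand of the true model at N=750: {est.msf:.3f} "
      f"(MC SE {est.msf_mcse:.3f})")

plans = {"S_0.5": subsample_plan(0.5, B=100),
         "S_0.632": subsample_plan(0.632, B=100),
         "S_0.8": subsample_plan(0.8, B=100),
         "bootstrap": bootstrap_plan(B=100)}
perf = evaluate_estimators(cov, out, N=750, Q=50, plans=plans,
                           estimands=est, seed=11)
print("mean MSF estimate by scheme:")
for lab in plans:
    row = perf.row("msf", lab, "model")
    print(f"  {lab:<10s} {row['mean']:.3f} (MC SE {row['mean_mcse']:.3f}, "
          f"RMSE {row['rmse']:.3f})")
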