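"""Fit all four estimators to one simulated cost sample.

Generates a single gamma-distributed cost sample (shape 2, n = 200, marginal
mean standardized to 1), fits each estimator, and prints the fitted slope and
the original-scale prediction errors.  MPE near 0 means unbiased mean-cost
prediction; MAPE measures individual-level accuracy.  The Cox slope lives on
the log-hazard scale, so it is not comparable to the generating slope 1.
"""

from skewcost import DGPSpec, ESTIMATORS, fit, generate, mape, mpe

spec = DGPSpec("gamma", 2.0, beta1=1.0, n=200)
data = generate(spec, seed=42)
print(f"scenario: {spec.family}, shape {spec.param}, n = {spec.n}, "
      f"beta0 = {spec.beta0:.4f} (so that E[y] = 1)\n")

print(f"{'estimator':<12} {'beta1_hat':>9} {'MPE':>9} {'MAPE':>7}")
for est in ESTIMATORS:
    fr = fit(data, est)
    print(f"{est:<12} {fr.beta1_hat:>9.4f} {mpe(data.y, fr.yhat):>9.4f} "
          f"{mape(data.y, fr.yhat):>7.4f}")

print("\nThe gamma fit is correctly specified here, so its slope is close to 1")
print("and its MPE is essentially 0 (the log-link score equations force the")
print("weighted residuals to zero).  The Cox prediction is a restricted mean")
print("from the Breslow baseline, and its slope estimates a hazard contrast.")
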