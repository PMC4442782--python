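"""Run a reduced Monte Carlo grid and print the summary table.

A scaled-down version of the full study: one scenario per family, two sample
sizes, 200 replications.  Each table row aggregates one (scenario, sample
size, estimator) cell: bias (MPE), accuracy (MAPE), slope precision
(MSE(b1)) and the 95% simulation interval for the slope.
"""

from skewcost import SimulationConfig, run_grid

config = SimulationConfig(
    families={"lognormal": (1.0,), "gamma": (0.5,), "weibull": (5.0,)},
    sample_sizes=(50, 500),
    replications=200,
    root_seed=7,
)
table = run_grid(config)

cols = ["family", "param", "n", "estimator", "mpe", "mape", "mse_beta",
        "ci_lower", "ci_upper", "mean_beta1"]
with_fmt = table.cell_rows[cols].round(4)
print(with_fmt.to_string(index=False))

print("\nReading the table: gamma-GLM MPE is ~0 everywhere (unbiased mean");
print("prediction); the Cox rows show slopes on the hazard scale (about")
print("-alpha under the Weibull scenario) and hence large MSE about the")
print("generating slope 1; MSE shrinks from n=50 to n=500 for every")
print("consistent estimator.")
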