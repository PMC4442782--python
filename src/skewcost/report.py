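"""Figure generation from stored simulation output.

Figures are built only from the residual-by-decile profiles the engine wrote
(``profiles.csv``); nothing is refitted in the plotting path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["ESTIMATOR_LABELS", "residual_profile_figure"]

ESTIMATOR_LABELS = {
    "ols_log": "OLS for ln(y)",
    "gamma_glm": "Gamma",
    "weibull_reg": "Weibull",
    "cox_ph": "Cox",
}


def residual_profile_figure(
    profiles: pd.DataFrame,
    family: str,
    n: int,
    out_base: str | Path,
    estimators=None,
    params=None,
) -> list[Path]:
    """Multi-panel mean-residual-by-decile figure for one (family, n).

    One panel per parameter value, one line per estimator, deciles 1-10 of
    the covariate on the x-axis.  Writes both vector (PDF) and raster (PNG)
    output to ``out_base.pdf`` / ``out_base.png``.  Missing cells are skipped
    with a warning line in the panel title.
    """
    sub = profiles[(profiles["family"] == family) & (profiles["n"] == n)]
    if params is None:
        params = sorted(sub["param"].unique())
    if estimators is None:
        estimators = [e for e in ESTIMATOR_LABELS if e in set(sub["estimator"])]
    if not len(params):
        raise ValueError(f"no profiles for family={family!r}, n={n}")
    dcols = [f"d{i}" for i in range(1, 11)]
    ncol = min(2, len(params))
    nrow = -(-len(params) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(5.0 * ncol, 3.4 * nrow),
                             squeeze=False, sharex=True)
    letters = "abcdefgh"
    for k, param in enumerate(params):
        ax = axes[k // ncol][k % ncol]
        cell = sub[sub["param"] == param]
        for est in estimators:
            row = cell[cell["estimator"] == est]
            if row.empty:
                continue
            ax.plot(range(1, 11), row.iloc[0][dcols].to_numpy(float),
                    marker="o", markersize=3, label=ESTIMATOR_LABELS.get(est, est))
        ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
        pname = "σ²" if family == "lognormal" else "α"
        ax.set_title(f"{letters[k]}: {pname} = {param:g}", fontsize=10)
        ax.set_xticks(range(1, 11))
    for k in range(len(params), nrow * ncol):
        axes[k // ncol][k % ncol].set_visible(False)
    axes[0][0].legend(fontsize=8, frameon=False)
    for ax in axes[-1]:
        ax.set_xlabel("decile of x")
    for r in range(nrow):
        axes[r][0].set_ylabel("mean residual")
    fig.suptitle(f"Mean residual across deciles of x — {family}, n={n}", fontsize=11)
    fig.tight_layout(rect=(0, 0, 1, 0.96))
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for ext in ("pdf", "png"):
        p = out_base.with_suffix(f".{ext}")
        fig.savefig(p, dpi=150)
        written.append(p)
    plt.close(fig)
    return written
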