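"""Per-replication and per-cell comparison statistics.

MPE (mean prediction error, signed) measures bias of the original-scale cost
predictions; MAPE (mean absolute prediction error) measures individual
accuracy; MSE(b1) measures precision of the slope across replications; the
"95% simulation interval" follows the convention
``mean(b1_hat) +/- 1.96 * sd(b1_hat) / sqrt(n)`` with ``n`` the
*per-replication sample size* (not the replication count).  A decile-of-
prediction chi-square adapts the Hosmer-Lemeshow test to continuous costs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2

__all__ = [
    "CellSummary",
    "DescriptiveRow",
    "mpe",
    "mape",
    "mse_beta",
    "sim_interval",
    "hl_test",
    "residual_decile_profile",
    "descriptive_stats",
    "sample_moments",
]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 1:
        raise ValueError("y and yhat must be 1-d arrays of equal length >= 1")
    return y, yhat


def mpe(y, yhat) -> float:
    """Mean prediction error ``mean(y - yhat)`` (signed; bias)."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(y - yhat))


def mape(y, yhat) -> float:
    """Mean absolute prediction error ``mean(|y - yhat|)`` (not a percentage)."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mse_beta(beta1_hats, beta1_true: float) -> float:
    """Mean squared deviation of the slope estimates from the generating value."""
    b = np.asarray(beta1_hats, dtype=float)
    if b.size < 1:
        raise ValueError("need at least one estimate")
    return float(np.mean((b - beta1_true) ** 2))


def sim_interval(beta1_hats, n_sample: int) -> tuple[float, float]:
    """Simulation interval ``mean +/- 1.96 * sd / sqrt(n_sample)``.

    ``n_sample`` is the per-replication sample size; the between-replication
    sd uses the n-1 denominator.  Degenerate spread yields a zero-width
    interval.
    """
    b = np.asarray(beta1_hats, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two estimates")
    if n_sample < 2:
        raise ValueError("n_sample must be >= 2")
    m = float(np.mean(b))
    s = float(np.std(b, ddof=1))
    half = 1.96 * s / math.sqrt(n_sample)
    return (m - half, m + half)


def hl_test(y, yhat, variance_fn) -> float:
    """Decile-of-prediction goodness-of-fit chi-square (Hosmer-Lemeshow style).

    Observations are grouped into deciles of ``yhat``; the statistic is
    ``sum_g (O_g - E_g)^2 / V_g`` with ``O_g = sum(y)``, ``E_g = sum(yhat)``
    and ``V_g = sum(variance_fn(yhat_i))`` (a model-based variance for each
    prediction), referred to chi-square with ``groups - 2`` degrees of
    freedom (8 for the full 10 deciles).  This is an explicit adaptation of
    the binary-outcome test to continuous costs and is approximate.

    ``variance_fn`` maps the prediction vector to a variance vector; pass a
    closure ignoring its argument to use externally computed variances.
    """
    y, yhat = _pair(y, yhat)
    n = len(y)
    if n < 20:
        raise ValueError("need n >= 20 (10 groups of >= 2)")
    edges = np.unique(np.quantile(yhat, np.linspace(0.1, 0.9, 9)))
    idx = np.searchsorted(edges, yhat, side="left")
    groups = np.unique(idx)
    if len(groups) < 10:
        warnings.warn(
            f"fewer than 10 distinct prediction groups ({len(groups)}); merging",
            stacklevel=2,
        )
    if len(groups) < 3:
        return math.nan
    v = np.asarray(variance_fn(yhat), dtype=float)
    stat = 0.0
    for g in groups:
        m = idx == g
        O, E, V = float(np.sum(y[m])), float(np.sum(yhat[m])), float(np.sum(v[m]))
        diff = O - E
        if V <= 0:
            if abs(diff) > 1e-12:
                return 0.0
            continue
        stat += diff * diff / V
    df = len(groups) - 2
    return float(_chi2.sf(stat, df))


def residual_decile_profile(x, y, yhat) -> np.ndarray:
    """Mean raw residual ``y - yhat`` within each decile of ``x``.

    Deciles are formed from the empirical quantiles of ``x``; values tied
    with an edge fall in the lower decile.  Empty deciles (possible with
    heavily tied x) yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y, yhat = _pair(y, yhat)
    if len(x) != len(y) or len(x) < 10:
        raise ValueError("need matching x with n >= 10")
    edges = np.quantile(x, np.linspace(0.1, 0.9, 9))
    idx = np.searchsorted(edges, x, side="left")
    resid = y - yhat
    out = np.full(10, np.nan)
    for d in range(10):
        m = idx == d
        if np.any(m):
            out[d] = float(np.mean(resid[m]))
    return out


def sample_moments(y) -> dict[str, float]:
    """Sample mean, sd (n-1), moment skewness g1 and raw (non-excess)
    kurtosis b2 of one replication; skew/kurtosis are NaN for constant y."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    m = float(np.mean(y))
    sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
    c = y - m
    m2 = float(np.mean(c * c))
    if m2 <= 0:
        return {"mean": m, "sd": sd, "skewness": math.nan, "kurtosis": math.nan}
    skew = float(np.mean(c**3)) / m2**1.5
    kurt = float(np.mean(c**4)) / (m2 * m2)  # Pearson, tends to 3 for normal
    return {"mean": m, "sd": sd, "skewness": skew, "kurtosis": kurt}


@dataclass
class DescriptiveRow:
    """Averages of per-replication sample statistics for one (family, param, n)."""

    family: str
    param: float
    n: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n_replications: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CellSummary:
    """All metrics for one (family, param, n, estimator) cell.

    Core columns follow the study's table layout (MPE, MAPE, MSE(b1),
    simulation interval, mean AIC, HL rejection rate); supplementary fields
    carry the percentile interval across replications, the PH-scale slope
    truth for Cox under Weibull data, the PH-test rejection rate, and the
    replication-averaged residual-by-decile profile used for figures.
    """

    family: str
    param: float
    n: int
    estimator: str
    mpe: float
    mape: float
    mse_beta: float
    ci_lower: float
    ci_upper: float
    mean_aic: float
    hl_rejection_rate: float
    mean_beta1: float
    n_replications: int
    n_converged: int
    sd_beta1: float = math.nan
    pct_lower: float = math.nan
    pct_upper: float = math.nan
    mse_beta_ph: float = math.nan
    ph_rejection_rate: float = math.nan
    flagged: bool = False
    decile_profile: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d.pop("decile_profile")
        return d


def descriptive_stats(datasets) -> DescriptiveRow:
    """Average per-replication sample moments over a collection of datasets
    sharing one generating scenario."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    spec = datasets[0].spec
    ns = {d.n for d in datasets}
    if len(ns) != 1:
        raise ValueError("datasets must share one sample size")
    rows = [sample_moments(d.y) for d in datasets]
    agg = {k: float(np.nanmean([r[k] for r in rows])) for k in rows[0]}
    return DescriptiveRow(
        family=spec.family if spec else "",
        param=spec.param if spec else math.nan,
        n=ns.pop(),
        mean=agg["mean"],
        sd=agg["sd"],
        skewness=agg["skewness"],
        kurtosis=agg["kurtosis"],
        n_replications=len(rows),
    )
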