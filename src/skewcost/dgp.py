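"""Mean-standardized skewed cost data generators.

Healthcare expenditures are strongly right-skewed, and simulation studies of
cost regressions conventionally draw outcomes from the log-normal, gamma and
Weibull families with a log-linear scale in a single covariate:

* log-normal:  ``y = exp(b0 + b1*x + e)`` with ``e ~ N(0, sigma2)``;
* gamma:       ``y ~ Gamma(shape=a, scale=exp(b0 + b1*x))``, mean ``a*b``;
* weibull:     ``y ~ Weibull(shape=a, scale=exp(b0 + b1*x))``, mean
  ``b*Gamma(1 + 1/a)`` — the one family here whose log-linear scale implies
  exactly proportional hazards.

The covariate ``x`` is uniform on (0, 1).  Every process is *standardized*:
the intercept ``b0`` is solved in closed form so that the marginal mean cost
``E(y)`` (over both the outcome noise and the covariate) equals 1.  That puts
bias metrics for different families and skewness levels on a common scale.

The module also exposes the closed-form truth used as oracles elsewhere:
solved intercepts, marginal mean/sd, conditional (given ``x``) skewness, and
the population Cox log-hazard-ratio implied by the Weibull process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import gamma as _gammafn

__all__ = [
    "FAMILIES",
    "DGPSpec",
    "Dataset",
    "NotProportionalHazardsError",
    "solve_intercept",
    "solve_intercept_numeric",
    "generate",
    "theoretical_moments",
    "true_cox_coefficient",
    "read_dataset",
]

FAMILIES = ("lognormal", "gamma", "weibull")


class NotProportionalHazardsError(ValueError):
    """A proportional-hazards quantity was requested for a family where the
    hazard ratio implied by the log-linear scale is not constant in time."""


def _validate_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _validate_param(param: float, beta1: float) -> None:
    if not (np.isfinite(param) and param > 0):
        raise ValueError(f"family parameter must be finite and > 0, got {param!r}")
    if not np.isfinite(beta1):
        raise ValueError(f"beta1 must be finite, got {beta1!r}")


def _slope_factor(beta1: float) -> float:
    """``E[exp(beta1 * x)]`` for ``x ~ Uniform(0, 1)``, i.e. (e^b1 - 1)/b1.

    The removable singularity at ``beta1 = 0`` is replaced by its limit 1.
    """
    if abs(beta1) < 1e-12:
        return 1.0
    return math.expm1(beta1) / beta1


def _mean_factor(family: str, param: float) -> float:
    """``E[y | x] / exp(b0 + b1*x)`` — the family-specific mean multiplier."""
    if family == "lognormal":
        return math.exp(param / 2.0)
    if family == "gamma":
        return param
    return float(_gammafn(1.0 + 1.0 / param))  # weibull


def solve_intercept(family: str, param: float, beta1: float = 1.0) -> float:
    """Intercept ``b0`` making the marginal mean cost equal 1.

    With ``E(y|x) = c(family, param) * exp(b0 + b1*x)`` and ``x ~ U(0,1)``,
    ``E(y) = c * exp(b0) * (e^b1 - 1)/b1``, hence

    ``b0 = -ln(c) - ln((e^b1 - 1)/b1)``.

    Parameters
    ----------
    family : {"lognormal", "gamma", "weibull"}
    param : float
        sigma^2 for the log-normal family; the shape ``a`` for gamma/weibull.
    beta1 : float
        Slope of the log-linear scale (the study design uses 1).
    """
    _validate_family(family)
    _validate_param(param, beta1)
    return -math.log(_mean_factor(family, param)) - math.log(_slope_factor(beta1))


def solve_intercept_numeric(family: str, param: float, beta1: float = 1.0) -> float:
    """Quadrature fallback for :func:`solve_intercept` (arbitrary ``beta1``).

    Integrates ``E(y | x, b0=0)`` over ``x in (0, 1)`` and returns minus the
    log of the integral.  Used to cross-check the closed forms.
    """
    _validate_family(family)
    _validate_param(param, beta1)
    c = _mean_factor(family, param)
    val, _ = integrate.quad(lambda x: c * math.exp(beta1 * x), 0.0, 1.0)
    return -math.log(val)


@dataclass(frozen=True)
class DGPSpec:
    """One data-generating scenario.

    Attributes
    ----------
    family : str
        One of ``"lognormal"``, ``"gamma"``, ``"weibull"``.
    param : float
        sigma^2 (log-normal) or shape (gamma/weibull); must be > 0.
    beta1 : float
        Slope on the log scale (default 1, the study design value).
    n : int
        Sample size per replication (>= 3).
    beta0 : float
        Derived intercept enforcing ``E(y) = 1``; never passed by callers.
    """

    family: str
    param: float
    beta1: float = 1.0
    n: int = 100

    def __post_init__(self) -> None:
        _validate_family(self.family)
        _validate_param(self.param, self.beta1)
        if int(self.n) != self.n or self.n < 3:
            raise ValueError(f"n must be an integer >= 3, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def beta0(self) -> float:
        return solve_intercept(self.family, self.param, self.beta1)

    def scale(self, x: np.ndarray) -> np.ndarray:
        """exp(b0 + b1*x), the log-linear scale at covariate ``x``."""
        return np.exp(self.beta0 + self.beta1 * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Dataset:
    """One replication's sample, with its generating truth attached.

    ``spec`` and ``seed`` are ``None`` for user-supplied data read from disk.
    """

    x: np.ndarray
    y: np.ndarray
    spec: DGPSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if self.spec is not None and len(y) != self.spec.n:
            raise ValueError(f"length {len(y)} does not match spec.n = {self.spec.n}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y, "x": self.x})

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text with header ``y,x`` (decimal point)."""
        self.to_frame().to_csv(path, index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Read a delimited table with header ``y,x`` (extra covariate columns are
    currently rejected: the study exercises a single covariate)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["y", "x"] or len(cols) != 2:
        raise ValueError(f"expected header 'y,x', got {list(df.columns)!r}")
    return Dataset(x=df.iloc[:, 1].to_numpy(float), y=df.iloc[:, 0].to_numpy(float))


def generate(spec: DGPSpec, seed: int) -> Dataset:
    """Draw one replication under ``spec``.

    The covariate is drawn first, then the outcome noise, so a given seed
    reproduces the sample bit-identically.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, spec.n)
    b = spec.scale(x)
    if spec.family == "lognormal":
        y = b * np.exp(rng.normal(0.0, math.sqrt(spec.param), spec.n))
    elif spec.family == "gamma":
        y = rng.gamma(spec.param, scale=b)
    else:  # weibull
        y = b * rng.weibull(spec.param, spec.n)
    return Dataset(x=x, y=y, spec=spec, seed=int(seed) if np.isscalar(seed) else None)


def _second_moment_factor(family: str, param: float) -> float:
    """``E(y^2|x) / E(y|x)^2``, constant in x for all three families."""
    if family == "lognormal":
        return math.exp(param)
    if family == "gamma":
        return (param + 1.0) / param
    g1 = float(_gammafn(1.0 + 1.0 / param))
    g2 = float(_gammafn(1.0 + 2.0 / param))
    return g2 / (g1 * g1)


def _covariate_mixture_factor(beta1: float) -> float:
    """``E[m(x)^2]`` for the standardized conditional mean ``m(x)`` with
    ``E[m(x)] = 1``: equals ((e^{2b1}-1)/(2b1)) * (b1/(e^{b1}-1))^2."""
    if abs(beta1) < 1e-12:
        return 1.0
    return _slope_factor(2.0 * beta1) / _slope_factor(beta1) ** 2


def conditional_skewness(family: str, param: float) -> float:
    """Skewness of ``y`` at fixed ``x`` (scale drops out).

    log-normal: ``(e^{s2} + 2) * sqrt(e^{s2} - 1)``; gamma: ``2/sqrt(a)``;
    weibull: the standardized third central moment of a shape-``a`` Weibull.
    """
    _validate_family(family)
    _validate_param(param, 0.0)
    if family == "lognormal":
        es = math.exp(param)
        return (es + 2.0) * math.sqrt(es - 1.0)
    if family == "gamma":
        return 2.0 / math.sqrt(param)
    g1 = float(_gammafn(1.0 + 1.0 / param))
    g2 = float(_gammafn(1.0 + 2.0 / param))
    g3 = float(_gammafn(1.0 + 3.0 / param))
    var = g2 - g1 * g1
    return (g3 - 3.0 * g1 * g2 + 2.0 * g1**3) / var**1.5


def theoretical_moments(spec: DGPSpec) -> dict[str, float]:
    """Closed-form marginal mean and sd, and conditional-on-x skewness.

    The marginal second moment mixes the within-x second moment with the
    spread of the conditional mean over the uniform covariate:
    ``E(y^2) = C(beta1) * K(family, param)`` with ``E(y) = 1``, so
    ``sd = sqrt(C*K - 1)``.
    """
    K = _second_moment_factor(spec.family, spec.param)
    C = _covariate_mixture_factor(spec.beta1)
    return {
        "mean": 1.0,
        "sd": math.sqrt(C * K - 1.0),
        "conditional_skewness": conditional_skewness(spec.family, spec.param),
    }


def true_cox_coefficient(spec: DGPSpec) -> float:
    """Population Cox log-hazard-ratio implied by the generating process.

    Only the Weibull family has exactly proportional hazards: with scale
    ``b = exp(b0 + b1*x)`` the hazard is ``a t^{a-1} exp(-a(b0 + b1*x))``, so
    the coefficient on ``x`` in a Cox model is ``-a * b1``.  For the other
    families the hazard ratio varies with time and no single value exists.
    """
    if spec.family != "weibull":
        raise NotProportionalHazardsError(
            f"the Cox log-hazard-ratio is not defined under the {spec.family} "
            "family: proportional hazards holds exactly only for weibull"
        )
    return -spec.param * spec.beta1
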