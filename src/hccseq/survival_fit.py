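"""Parametric time-to-event laws for the decision model.

Everything downstream of curve reconstruction runs on two-parameter Weibull
laws, S(t) = exp(-(t/scale)^shape), with time in months.  Three entry points
produce them:

* :func:`fit_weibull_mle` — right-censored maximum likelihood on individual
  patient data;
* :func:`weibull_from_quantiles` — exact inversion of a published
  median/interquartile-range summary, for treatments where only the summary
  statistics are available;
* :func:`classify_hazard_shape` — a screen on the fitted hazard of candidate
  families, used to justify restricting the model to monotone-increasing
  hazards (the clinically expected pattern for progressing advanced cancer).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .km_reconstruct import IPDSet

__all__ = [
    "WeibullParams",
    "WeibullFit",
    "HazardShape",
    "fit_weibull_mle",
    "weibull_from_quantiles",
    "weibull_quantile",
    "weibull_cdf",
    "classify_hazard_shape",
]

_LN2 = math.log(2.0)
_LN4 = math.log(4.0)
_LN43 = math.log(4.0 / 3.0)

# shape bracket for the quantile solver; IQR/median ratios outside the values
# attained on this bracket are rejected as un-Weibull-like
_SHAPE_LO = 0.05
_SHAPE_HI = 50.0


@dataclass(frozen=True)
class WeibullParams:
    """Scale (months) and shape of one Weibull time-to-event law."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        for name in ("scale", "shape"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"Weibull {name} must be positive and finite, got {v}")

    @property
    def median(self) -> float:
        return weibull_quantile(self, 0.5)

    @property
    def iqr(self) -> float:
        return weibull_quantile(self, 0.75) - weibull_quantile(self, 0.25)

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(-((np.maximum(t, 0.0) / self.scale) ** self.shape))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale * rng.weibull(self.shape, size=n)


@dataclass(frozen=True)
class WeibullFit:
    """MLE result: point estimates plus curvature-based standard errors."""

    params: WeibullParams
    se_scale: float
    se_shape: float
    loglik: float
    n: int
    n_events: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.se_scale < 0 or self.se_shape < 0:
            raise ValueError("standard errors must be non-negative")
        if self.n_events > self.n:
            raise ValueError("n_events cannot exceed n")


class HazardShape(str, enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    DOME = "dome"
    CONSTANT = "constant"
    BATHTUB = "bathtub"


def weibull_quantile(params: WeibullParams, p: float) -> float:
    """Closed-form quantile: scale * (-ln(1-p))^(1/shape)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie in (0, 1), got {p}")
    return params.scale * (-math.log1p(-p)) ** (1.0 / params.shape)


def weibull_cdf(params: WeibullParams, t: float) -> float:
    if t <= 0:
        return 0.0
    return -math.expm1(-((t / params.scale) ** params.shape))


def _iqr_over_median(shape: float) -> float:
    inv = 1.0 / shape
    return (_LN4**inv - _LN43**inv) / _LN2**inv


def weibull_from_quantiles(median: float, iqr: float) -> WeibullParams:
    """Solve the unique Weibull law with the given median and IQR.

    The ratio IQR/median is scale-free and strictly decreasing in the shape
    parameter, so the shape is found by a bracketed 1-D root-find and the
    scale recovered from the median.  A forward check guarantees the returned
    parameters reproduce both inputs to 1e-6 relative accuracy.
    """
    if not (median > 0 and math.isfinite(median)):
        raise ValueError(f"median must be positive, got {median}")
    if not (iqr > 0 and math.isfinite(iqr)):
        raise ValueError(f"iqr must be positive, got {iqr}")
    ratio = iqr / median
    lo, hi = _iqr_over_median(_SHAPE_HI), _iqr_over_median(_SHAPE_LO)
    if not lo < ratio < hi:
        raise ValueError(
            f"IQR/median ratio {ratio:.4g} outside the attainable Weibull range "
            f"({lo:.4g}, {hi:.4g}) for shapes in [{_SHAPE_LO}, {_SHAPE_HI}]"
        )
    shape = brentq(lambda k: _iqr_over_median(k) - ratio, _SHAPE_LO, _SHAPE_HI, xtol=1e-12)
    scale = median / _LN2 ** (1.0 / shape)
    params = WeibullParams(scale=scale, shape=shape)
    if abs(params.median - median) > 1e-6 * median or abs(params.iqr - iqr) > 1e-6 * iqr:
        raise ValueError("quantile solver failed forward verification")  # pragma: no cover
    return params


def fit_weibull_mle(ipd: "IPDSet") -> WeibullFit:
    """Right-censored Weibull MLE on individual patient data.

    Delegates the likelihood maximization to lifelines' Weibull fitter, which
    uses the same S(t) = exp(-(t/scale)^shape) parameterization and reports
    standard errors from the observed information matrix.
    """
    from lifelines import WeibullFitter

    times = np.asarray([r[0] for r in ipd.records], dtype=float)
    events = np.asarray([r[1] for r in ipd.records], dtype=bool)
    n_events = int(events.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events to fit a Weibull law, got {n_events}")
    wf = WeibullFitter()
    try:
        wf.fit(times, event_observed=events)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Weibull MLE did not converge: {exc}") from exc
    se = wf.summary["se"] if "se" in wf.summary else wf.summary["se(coef)"]
    return WeibullFit(
        params=WeibullParams(scale=float(wf.lambda_), shape=float(wf.rho_)),
        se_scale=float(se.loc["lambda_"]),
        se_shape=float(se.loc["rho_"]),
        loglik=float(wf.log_likelihood_),
        n=len(times),
        n_events=n_events,
    )


def weibull_loglik(params: WeibullParams, ipd: "IPDSet") -> float:
    """Right-censored log-likelihood of a Weibull law on IPD."""
    t = np.asarray([r[0] for r in ipd.records], dtype=float)
    e = np.asarray([r[1] for r in ipd.records], dtype=bool)
    z = t / params.scale
    log_h = np.log(params.shape / params.scale) + (params.shape - 1.0) * np.log(z)
    return float(np.sum(e * log_h) - np.sum(z**params.shape))


_FAMILIES = ("weibull", "gamma", "generalized_gamma", "lognormal", "loglogistic", "exponential")


def _hazard_on_grid(family: str, params: Sequence[float], grid: np.ndarray) -> np.ndarray:
    if family == "weibull":
        scale, shape = params
        dist = stats.weibull_min(shape, scale=scale)
    elif family == "exponential":
        (scale,) = params
        dist = stats.expon(scale=scale)
    elif family == "gamma":
        a, scale = params
        dist = stats.gamma(a, scale=scale)
    elif family == "generalized_gamma":
        a, c, scale = params
        dist = stats.gengamma(a, c, scale=scale)
    elif family == "lognormal":
        mu, sigma = params
        dist = stats.lognorm(sigma, scale=math.exp(mu))
    elif family == "loglogistic":
        c, scale = params
        dist = stats.fisk(c, scale=scale)
    else:
        raise ValueError(f"unsupported family {family!r}; choose one of {_FAMILIES}")
    sf = dist.sf(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = dist.pdf(grid) / sf
    return h


def classify_hazard_shape(
    family: str,
    params: Sequence[float],
    grid: Sequence[float] | None = None,
    flat_tol: float = 1e-3,
) -> HazardShape:
    """Classify the hazard h(t)=f(t)/S(t) of a fitted family on a time grid.

    The sign pattern of successive hazard differences (with a relative
    flatness tolerance) maps to one of: increasing, decreasing, dome
    (rise-then-fall), bathtub (fall-then-rise) or constant.  Used to screen
    candidate distributions: laws whose hazards cannot increase monotonically
    are unsuitable for a progressing-cancer state.
    """
    if grid is None:
        grid = np.linspace(0.25, 60.0, 240)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 50:
        raise ValueError("hazard grid needs at least 50 points")
    h = _hazard_on_grid(family, params, grid)
    ok = np.isfinite(h) & (h > 0)
    h = h[ok]
    if h.size < 10:
        raise ValueError("hazard not finite on the supplied grid")
    diffs = np.diff(h)
    scale = np.maximum(np.abs(h[:-1]), np.abs(h[1:]))
    rel = diffs / np.where(scale > 0, scale, 1.0)
    sign = np.zeros_like(rel, dtype=int)
    sign[rel > flat_tol] = 1
    sign[rel < -flat_tol] = -1
    nonzero = sign[sign != 0]
    if nonzero.size == 0:
        return HazardShape.CONSTANT
    changes = np.flatnonzero(np.diff(nonzero) != 0)
    if changes.size == 0:
        return HazardShape.INCREASING if nonzero[0] > 0 else HazardShape.DECREASING
    # one sign change: rising-then-falling is a dome, the reverse a bathtub
    first = nonzero[0]
    return HazardShape.DOME if first > 0 else HazardShape.BATHTUB
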