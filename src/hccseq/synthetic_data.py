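"""Synthetic inputs with known ground truth for every pipeline stage.

No patient-level data from the source trials is redistributable, so testing
the reconstruction -> fitting -> simulation chain requires fixtures drawn
from known laws: Weibull individual patient data with uniform administrative
censoring, digitized step-curves with number-at-risk tables (emulating what
curve-digitizing software extracts from a published figure), and trial
covariate catalogs whose median progression-free survival is a noisy linear
function of population covariates (emulating the summary table a
meta-regression consumes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .km_reconstruct import DigitizedCurve, IPDSet, RiskTable, km_estimate, survival_at
from .survival_fit import WeibullParams

__all__ = [
    "GroundTruth",
    "gen_weibull_ipd",
    "digitize_km",
    "gen_trial_catalog",
    "default_trial_catalog",
    "DEFAULT_CATALOG_COEFFICIENTS",
    "CATALOG_COLUMNS",
]

CATALOG_COLUMNS = (
    "trial_id",
    "n",
    "prev_hbv",
    "prev_hcv",
    "prev_mavi_ehd",
    "prev_ecog1",
    "median_pfs",
)

# intercept + slopes (HBV, HCV, MaVI/EHD, ECOG-PS1) -> median PFS in months.
# Chosen so poor-prognosis covariates (MaVI/EHD, ECOG1, HBV) shorten PFS and
# baseline predictions sit in the 4-9 month range of first-line trials.
DEFAULT_CATALOG_COEFFICIENTS = (10.0, -3.0, 2.0, -5.0, -3.0)


@dataclass(frozen=True)
class GroundTruth:
    """Known generating law for one synthetic trial arm."""

    weibull: WeibullParams
    censor_rate: float = 0.0
    n: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError(f"censor_rate must lie in [0, 1), got {self.censor_rate}")


def _censor_cap(params: WeibullParams, target: float) -> float:
    """Upper limit c of Uniform(0, c) censoring achieving the target rate.

    With event time T ~ Weibull and independent C ~ Uniform(0, c), the
    censoring probability P(C < T) = (1/c) * integral_0^c S(t) dt, which
    decreases from 1 at c=0; solved by bisection.
    """
    if target <= 0:
        return math.inf

    def p_cens(c: float) -> float:
        t = np.linspace(0.0, c, 2049)
        return float(np.trapezoid(params.survival(t), t) / c)

    hi = params.scale
    while p_cens(hi) > target:
        hi *= 2.0
        if hi > 1e6 * params.scale:  # pragma: no cover
            raise ValueError("cannot achieve requested censor_rate")
    return brentq(lambda c: p_cens(c) - target, 1e-9 * params.scale, hi, xtol=1e-10)


def gen_weibull_ipd(truth: GroundTruth) -> IPDSet:
    """Draw per-patient (time, event) records from a known Weibull law.

    Censoring is independent Uniform(0, c) with c solved so the expected
    censored fraction equals ``truth.censor_rate`` — the pattern produced by
    staggered trial entry with a common cutoff date.  Byte-identical output
    under a fixed seed.
    """
    rng = np.random.default_rng(truth.seed)
    t_event = truth.weibull.sample(truth.n, rng)
    if truth.censor_rate > 0:
        cap = _censor_cap(truth.weibull, truth.censor_rate)
        t_cens = rng.uniform(0.0, cap, size=truth.n)
        times = np.minimum(t_event, t_cens)
        events = t_event <= t_cens
    else:
        times, events = t_event, np.ones(truth.n, dtype=bool)
    times = np.maximum(times, 1e-9)  # guard the positive-time invariant
    return IPDSet(
        [(float(t), bool(e)) for t, e in zip(times, events)],
        meta=f"synthetic weibull(scale={truth.weibull.scale:.4g}, shape={truth.weibull.shape:.4g})",
    )


def digitize_km(
    ipd: IPDSet,
    grid: Sequence[float] | None = None,
    risk_interval: float = 6.0,
) -> tuple[DigitizedCurve, RiskTable]:
    """Emulate reading a published KM figure: curve on a grid + risk table.

    The curve is the KM estimate of ``ipd`` evaluated at the grid points
    (monthly by default, mirroring the model's cycle length); the risk table
    counts patients still at risk at multiples of ``risk_interval``.
    """
    if len(ipd) == 0:
        raise ValueError("cannot digitize an empty IPD set")
    km = km_estimate(ipd)
    t_max = float(ipd.times.max())
    if grid is None:
        grid = np.arange(0.0, math.floor(t_max) + 1.0)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0 or grid[0] < 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and start at >= 0")
    surv = survival_at(km, grid)
    curve = DigitizedCurve(zip(grid, surv))
    if risk_interval <= 0:
        raise ValueError("risk_interval must be positive")
    risk_times = np.arange(0.0, t_max + risk_interval, risk_interval)
    risk_times = risk_times[risk_times <= grid[-1]]
    n_at_risk = [(float(t), int(np.sum(ipd.times >= t))) for t in risk_times]
    # drop trailing zero-at-risk entries: published tables stop at the last patient
    while len(n_at_risk) > 1 and n_at_risk[-1][1] == 0:
        n_at_risk.pop()
    return curve, RiskTable(n_at_risk)


def gen_trial_catalog(
    k_trials: int,
    coefficients: Sequence[float] = DEFAULT_CATALOG_COEFFICIENTS,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_range: tuple[int, int] = (100, 1000),
) -> pd.DataFrame:
    """Simulate a catalog of trial-level covariate prevalences and median PFS.

    Prevalences are Uniform(0, 1); median PFS is the linear predictor plus
    Gaussian noise, truncated below at 0.5 months; per-trial sample sizes are
    uniform integers over ``n_range``.  The noise emulates the sampling error
    of a trial-level median, so its standard deviation scales as 1/sqrt(n):
    ``noise_sd`` is the value for a trial of the midpoint size.  This is
    exactly the error structure that justifies weighting the downstream
    regression by sample size.
    """
    if k_trials <= 5:
        raise ValueError(
            f"need at least 6 trials to identify a 5-coefficient regression, got {k_trials}"
        )
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (5,):
        raise ValueError("coefficients must be (intercept + 4 slopes)")
    rng = np.random.default_rng(seed)
    prev = rng.uniform(0.0, 1.0, size=(k_trials, 4))
    linpred = coefficients[0] + prev @ coefficients[1:]
    n = rng.integers(n_range[0], n_range[1] + 1, size=k_trials)
    n_ref = (n_range[0] + n_range[1]) / 2.0
    sd = noise_sd * np.sqrt(n_ref / n)
    pfs = np.maximum(linpred + rng.normal(0.0, 1.0, size=k_trials) * sd, 0.5)
    return pd.DataFrame(
        {
            "trial_id": [f"trial_{i:03d}" for i in range(k_trials)],
            "n": n,
            "prev_hbv": prev[:, 0],
            "prev_hcv": prev[:, 1],
            "prev_mavi_ehd": prev[:, 2],
            "prev_ecog1": prev[:, 3],
            "median_pfs": pfs,
        }
    )


def default_trial_catalog() -> pd.DataFrame:
    """The packaged synthetic catalog used by the sensitivity analyses."""
    return gen_trial_catalog(k_trials=24, noise_sd=0.8, seed=20)


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"trial catalog missing column(s) {missing}")
    prev_cols = ["prev_hbv", "prev_hcv", "prev_mavi_ehd", "prev_ecog1"]
    if ((catalog[prev_cols] < 0) | (catalog[prev_cols] > 1)).any().any():
        raise ValueError("prevalences must lie in [0, 1]")
    if (catalog["n"] <= 0).any():
        raise ValueError("trial sample sizes must be positive")
    if (catalog["median_pfs"] <= 0).any():
        raise ValueError("median PFS must be positive")
    return catalog
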