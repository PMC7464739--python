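"""Deterministic and probabilistic sensitivity machinery.

Three analyses probe the robustness of the base case:

* a one-way tornado — each input varied alone to its low/high bound
  (population covariates by +/-30 percentage points, capped to [0, 1];
  Weibull parameters by +/-2 standard errors), re-running the pipeline and
  recording the induced outcome range;
* a two-way plane for the incremental safety-effectiveness ratio, varying
  the SAE difference and the LYG difference jointly against a
  willingness-to-risk threshold (the toxicity analogue of a
  willingness-to-pay threshold);
* a two-step probabilistic analysis: a sample-size-weighted meta-regression
  links trial-level covariate prevalences to median progression-free
  survival; sampled covariate profiles are translated into proportional
  Weibull scale shifts (a proportional-hazards property of the Weibull) and
  pushed through the microsimulation.

Covariates propagate to survival only through the meta-regression, which is
the single covariate-to-survival link the model defines; covariates absent
from it (sex, ethnicity, stage) therefore produce zero-width tornado bars.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .markov_model import SimConfig, StrategySpec, simulate_cohort
from .outcomes import median_os
from .survival_fit import WeibullParams
from .synthetic_data import validate_catalog

__all__ = [
    "MetaRegModel",
    "PopulationProfile",
    "ISERPlane",
    "fit_meta_regression",
    "profile_to_scale_shift",
    "one_way_tornado",
    "two_way_iser_plane",
    "probabilistic_analysis",
]

log = logging.getLogger(__name__)

META_COVARIATES = ("prev_hbv", "prev_hcv", "prev_mavi_ehd", "prev_ecog1")


@dataclass(frozen=True)
class MetaRegModel:
    """Weighted meta-regression: covariate prevalences -> median PFS (months)."""

    coefficients: np.ndarray  # intercept + 4 slopes
    cov: np.ndarray  # coefficient covariance
    se: np.ndarray
    n_trials: int
    weights: np.ndarray

    def predict(self, profile: "PopulationProfile") -> float:
        x = np.array([1.0, profile.hbv, profile.hcv, profile.mavi_ehd, profile.ecog1])
        return float(x @ self.coefficients)


@dataclass(frozen=True)
class PopulationProfile:
    """Prevalences of the trial-population characteristics, as fractions."""

    male: float = 0.84
    asian: float = 0.50
    hcv: float = 0.30
    hbv: float = 0.45
    mavi_ehd: float = 0.88
    ecog1: float = 0.37
    bclc_c: float = 0.82

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence {name}={v} outside [0, 1]")

    def replace(self, **kw) -> "PopulationProfile":
        return dc_replace(self, **kw)


@dataclass(frozen=True)
class ISERPlane:
    """Favored-region summary of the two-way sensitivity grid."""

    threshold: float
    delta_sae_range: tuple[float, float]
    lyg_range: tuple[float, float]
    favored_fraction: float
    quadrant_fractions: Mapping[str, float]
    grid_shape: tuple[int, int]


def fit_meta_regression(catalog: pd.DataFrame) -> MetaRegModel:
    """Sample-size-weighted least squares of median PFS on four prevalences."""
    catalog = validate_catalog(catalog)
    if len(catalog) < 6:
        raise ValueError(f"meta-regression needs >= 6 trials, got {len(catalog)}")
    X = sm.add_constant(catalog[list(META_COVARIATES)].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design matrix rank-deficient (rank {rank} < {X.shape[1]}); "
            f"most collinear columns: {META_COVARIATES[i]}, {META_COVARIATES[j]}"
        )
    w = catalog["n"].to_numpy(dtype=float)
    fit = sm.WLS(catalog["median_pfs"].to_numpy(dtype=float), X, weights=w).fit()
    return MetaRegModel(
        coefficients=np.asarray(fit.params),
        cov=np.asarray(fit.cov_params()),
        se=np.asarray(fit.bse),
        n_trials=len(catalog),
        weights=w,
    )


def profile_to_scale_shift(
    model: MetaRegModel,
    baseline: PopulationProfile,
    varied: PopulationProfile,
    base: WeibullParams,
) -> WeibullParams:
    """Translate a covariate change into a proportional Weibull scale shift.

    The predicted median under the varied profile, relative to the baseline
    prediction, multiplies the scale parameter; the shape is untouched, so
    every quantile shifts by the same factor.
    """
    pred_base = model.predict(baseline)
    pred_var = model.predict(varied)
    if pred_base <= 0 or pred_var <= 0:
        raise ValueError(
            f"meta-regression predicts non-positive median PFS "
            f"(baseline {pred_base:.3g}, varied {pred_var:.3g})"
        )
    return WeibullParams(scale=base.scale * pred_var / pred_base, shape=base.shape)


@dataclass(frozen=True)
class TornadoVariable:
    """One bar of the tornado: a covariate or a Weibull parameter.

    kind 'covariate': ``name`` is a :class:`PopulationProfile` field varied by
    +/-``rel`` percentage points of prevalence (capped to [0, 1]).
    kind 'scale'/'shape': the parameter of ``target`` ('first' or 'second')
    varied to explicit ``low``/``high`` values (typically +/-2 SE).
    """

    name: str
    kind: str = "covariate"
    rel: float = 0.30
    target: str = "first"
    low: float | None = None
    high: float | None = None


def _apply_variable(
    var: TornadoVariable,
    strategy: StrategySpec,
    model: MetaRegModel,
    baseline: PopulationProfile,
    value_is_high: bool,
) -> StrategySpec:
    if var.kind == "covariate":
        base_val = getattr(baseline, var.name)
        raw = base_val + (var.rel if value_is_high else -var.rel)
        capped = min(max(raw, 0.0), 1.0)
        if capped != raw:
            log.info(
                "tornado: %s %s bound capped from %.2f to %.2f",
                var.name, "high" if value_is_high else "low", raw, capped,
            )
        varied = baseline.replace(**{var.name: capped})
        new_first = profile_to_scale_shift(
            model, baseline, varied, strategy.first_line.ttev
        )
        return dc_replace(
            strategy,
            first_line=dc_replace(strategy.first_line, ttev=new_first),
        )
    if var.kind not in ("scale", "shape"):
        raise ValueError(f"unknown tornado variable kind {var.kind!r}")
    value = var.high if value_is_high else var.low
    if value is None:
        raise ValueError(f"{var.name}: parameter bars need explicit low/high bounds")
    value = max(value, 1e-6)
    which = strategy.first_line if var.target == "first" else strategy.second_line
    new_params = WeibullParams(
        scale=value if var.kind == "scale" else which.ttev.scale,
        shape=value if var.kind == "shape" else which.ttev.shape,
    )
    profile = dc_replace(which, ttev=new_params)
    return dc_replace(
        strategy,
        **{("first_line" if var.target == "first" else "second_line"): profile},
    )


def one_way_tornado(
    strategy: StrategySpec,
    reference: StrategySpec,
    variables: Sequence[TornadoVariable],
    cfg: SimConfig,
    model: MetaRegModel,
    baseline: PopulationProfile | None = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity of LYG versus a reference sequence.

    Each variable is set to its low then high bound with everything else at
    base; covariate shifts apply to the first-line laws of both sequences
    (the population changes, not one arm).  Bars are sorted by width
    descending.
    """
    baseline = baseline or PopulationProfile()
    ref_cohort = simulate_cohort(reference, cfg)
    base_median_ref = median_os(ref_cohort)
    rows = []
    for var in variables:
        vals = {}
        for is_high in (False, True):
            s_v = _apply_variable(var, strategy, model, baseline, is_high)
            if var.kind == "covariate":
                r_v = _apply_variable(var, reference, model, baseline, is_high)
                m_ref = median_os(simulate_cohort(r_v, cfg))
            else:
                m_ref = base_median_ref
            m = median_os(simulate_cohort(s_v, cfg))
            vals["high" if is_high else "low"] = (m - m_ref) / 12.0
        lo, hi = vals["low"], vals["high"]
        rows.append(
            {
                "variable": var.name,
                "kind": var.kind,
                "lyg_low": lo,
                "lyg_high": hi,
                "width": abs(hi - lo),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("width", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def two_way_iser_plane(
    delta_sae_range: tuple[float, float],
    lyg_range: tuple[float, float],
    threshold: float = 30.0,
    grid: int = 201,
) -> ISERPlane:
    """Favored fraction of option A over the (delta SAE, LYG) rectangle.

    A grid point favors A iff delta_sae / lyg <= threshold, i.e. the extra
    toxicity per life-year gained stays within the willingness-to-risk.
    Points with lyg == 0 are excluded (undefined ratio); negative-LYG points
    never favor A unless A is also safer (dominance by sign).  Quadrants are
    split at the midpoint of each axis range.
    """
    if threshold <= 0:
        raise ValueError("willingness-to-risk threshold must be positive")
    (s_lo, s_hi), (l_lo, l_hi) = delta_sae_range, lyg_range
    if not (s_hi > s_lo and l_hi > l_lo):
        raise ValueError("plane ranges must be non-degenerate")
    ds = np.linspace(s_lo, s_hi, grid)
    ly = np.linspace(l_lo, l_hi, grid)
    S, L = np.meshgrid(ds, ly, indexing="ij")
    valid = L != 0.0
    # net-benefit half-plane: for lyg > 0 this is delta_sae/lyg <= threshold;
    # for lyg < 0 it requires toxicity savings to buy back the lost years at
    # the same exchange rate
    favored = (S <= threshold * L) & valid
    frac = float(favored.sum() / valid.sum())
    s_mid, l_mid = (s_lo + s_hi) / 2.0, (l_lo + l_hi) / 2.0
    quads = {
        "high_lyg_low_sae": (L >= l_mid) & (S < s_mid),
        "high_lyg_high_sae": (L >= l_mid) & (S >= s_mid),
        "low_lyg_low_sae": (L < l_mid) & (S < s_mid),
        "low_lyg_high_sae": (L < l_mid) & (S >= s_mid),
    }
    qfrac = {
        name: float(favored[m & valid].sum() / max((m & valid).sum(), 1))
        for name, m in quads.items()
    }
    return ISERPlane(
        threshold=threshold,
        delta_sae_range=(s_lo, s_hi),
        lyg_range=(l_lo, l_hi),
        favored_fraction=frac,
        quadrant_fractions=qfrac,
        grid_shape=(grid, grid),
    )


def probabilistic_analysis(
    model: MetaRegModel,
    ranges: Mapping[str, tuple[float, float]],
    strategies: Sequence[StrategySpec],
    reference: StrategySpec,
    cfg: SimConfig,
    n_draws: int = 1000,
    baseline: PopulationProfile | None = None,
) -> pd.DataFrame:
    """Monte Carlo over covariate uncertainty: exceedance versus a reference.

    Each draw samples the four meta-regression prevalences uniformly within
    ``ranges``, converts the predicted median PFS into a shared proportional
    first-line scale shift (the whole simulated population changes, so the
    same factor applies to every sequence), simulates each strategy and the
    reference with independent noise, and records whether the strategy's
    median OS exceeds the reference's (ties on the monthly grid count 1/2).
    Returns per-strategy exceedance fractions with binomial-normal 95%
    intervals.
    """
    baseline = baseline or PopulationProfile()
    for name in ranges:
        lo, hi = ranges[name]
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"range for {name} must satisfy 0 <= low <= high <= 1")
    rng = np.random.default_rng(cfg.seed)
    pred_base = model.predict(baseline)
    if pred_base <= 0:
        raise ValueError("baseline meta-regression prediction must be positive")

    factors = np.empty(n_draws)
    for d in range(n_draws):
        varied = baseline
        for name, (lo, hi) in ranges.items():
            varied = varied.replace(**{name: rng.uniform(lo, hi)})
        factors[d] = max(model.predict(varied), 1e-6) / pred_base

    def medians_for(strategy: StrategySpec) -> np.ndarray:
        out = np.empty(n_draws)
        for d in range(n_draws):
            shifted = dc_replace(
                strategy,
                first_line=dc_replace(
                    strategy.first_line,
                    ttev=WeibullParams(
                        scale=strategy.first_line.ttev.scale * factors[d],
                        shape=strategy.first_line.ttev.shape,
                    ),
                ),
            )
            seed = int(rng.integers(0, 2**31 - 1))
            out[d] = median_os(simulate_cohort(shifted, dc_replace(cfg, seed=seed)))
        return out

    ref_medians = medians_for(reference)
    rows = []
    for strat in strategies:
        med = medians_for(strat)
        wins = np.mean((med > ref_medians) + 0.5 * (med == ref_medians))
        se = math.sqrt(max(wins * (1 - wins), 1e-12) / n_draws)
        rows.append(
            {
                "strategy": strat.label,
                "reference": reference.label,
                "exceedance": float(wins),
                "ci_low": max(0.0, float(wins - 1.96 * se)),
                "ci_high": min(1.0, float(wins + 1.96 * se)),
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(rows)


def default_psa_ranges(catalog: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Min-max prevalence ranges observed across a trial catalog."""
    mapping = {"prev_hbv": "hbv", "prev_hcv": "hcv",
               "prev_mavi_ehd": "mavi_ehd", "prev_ecog1": "ecog1"}
    return {
        field: (float(catalog[col].min()), float(catalog[col].max()))
        for col, field in mapping.items()
    }
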