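"""Effectiveness and safety measures for simulated treatment sequences.

Per sequence: the Kaplan-Meier median overall survival, 36-month milestone
survival, life-years gained (LYG) against the least effective sequence,
number needed to treat (NNT) from the milestone survival difference, and the
severe-adverse-event rate weighted by simulated state occupancy.  Across
sequences: the incremental safety-effectiveness ratio (ISER) — the extra
percentage points of severe adverse events paid per life-year gained when
choosing one sequence over another — and a rank-sum power scan for the
minimum trial size that would separate two sequences.

Medians are reported on the model's monthly grid; LYG and ISER are computed
from the unrounded internal values, never from the rounded table entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .markov_model import CohortResult, SimConfig, StrategySpec, simulate_cohort

__all__ = [
    "MedianUnreachedError",
    "ISERResult",
    "median_os",
    "milestone_survival",
    "lyg",
    "nnt",
    "weighted_sae",
    "iser",
    "min_sample_size_for_significance",
    "rank_strategies",
    "summarize_cohort",
]


class MedianUnreachedError(ValueError):
    """More than half the cohort is still alive at the horizon cap."""


@dataclass(frozen=True)
class ISERResult:
    """Incremental safety-effectiveness ratio between two sequences."""

    delta_sae: float  # percentage points of SAEs
    delta_lyg: float  # years
    iser: float  # % SAEs per LYG; nan when delta_lyg == 0
    dominant: str | None = None  # set when one option wins on both axes


def median_os(cohort: CohortResult) -> float:
    """KM median of the simulated death times, in months.

    All deaths inside the horizon are observed events; trajectories capped at
    the horizon are censored there.  With no censoring this is the smallest
    time by which half the cohort has died.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    t, dead = cohort.t_death, ~cohort.horizon_censored
    order = np.argsort(t, kind="stable")
    t, dead = t[order], dead[order]
    uniq = np.unique(t[dead])
    s = 1.0
    for ti in uniq:
        n_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & dead))
        s *= 1.0 - d / n_risk
        if s <= 0.5:
            return float(ti)
    raise MedianUnreachedError(
        f"{cohort.label}: survival still {s:.3f} at the horizon; median not reached"
    )


def milestone_survival(cohort: CohortResult, t: float = 36.0) -> float:
    """Percentage of the cohort alive beyond month ``t``."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if t < 0:
        raise ValueError("milestone time must be non-negative")
    return 100.0 * float(np.mean(cohort.t_death > t))


def lyg(median_a: float, median_ref: float) -> float:
    """Life-years gained over the reference: (median_a - median_ref)/12."""
    for m in (median_a, median_ref):
        if not math.isfinite(m):
            raise MedianUnreachedError("LYG undefined when a median is unreached")
    return (median_a - median_ref) / 12.0


def nnt(os_a: float, os_ref: float) -> int | None:
    """Number needed to treat from milestone survival percentages.

    Reciprocal of the absolute risk difference, rounded to the nearest
    integer; ``None`` (printed "-") when the difference is zero.  The
    absolute value makes the measure symmetric for sequences below the
    reference.
    """
    for v in (os_a, os_ref):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"milestone survival must lie in [0, 100], got {v}")
    diff = abs(os_a - os_ref) / 100.0
    if diff == 0.0:
        return None
    return int(round(1.0 / diff))


def weighted_sae(cohort: CohortResult, sae_first: float, sae_second: float) -> float:
    """SAE rate of a sequence, weighted by simulated state occupancy.

    Every patient enters first line; only those progressing enter second
    line, so the sequence-level rate is the mean of the two line-specific
    trial rates weighted by the simulated transit counts.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    for v in (sae_first, sae_second):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"SAE rates must lie in [0, 100], got {v}")
    n1, n2 = cohort.n_transited_first, cohort.n_transited_second
    return (n1 * sae_first + n2 * sae_second) / (n1 + n2)


def iser(sae_a: float, sae_b: float, lyg_a: float, lyg_b: float) -> ISERResult:
    """ISER of option A versus option B: (SAE_a - SAE_b)/(LYG_a - LYG_b).

    Symmetric in the order of comparison (both differences flip sign).  When
    the LYG difference is zero the ratio is undefined and the result reports
    dominance instead; dominance is also flagged whenever one option is at
    least as good on both axes.
    """
    d_sae = sae_a - sae_b
    d_lyg = lyg_a - lyg_b
    dominant = None
    if d_lyg >= 0 and d_sae <= 0 and (d_lyg > 0 or d_sae < 0):
        dominant = "a"
    elif d_lyg <= 0 and d_sae >= 0 and (d_lyg < 0 or d_sae > 0):
        dominant = "b"
    value = d_sae / d_lyg if d_lyg != 0 else math.nan
    return ISERResult(delta_sae=d_sae, delta_lyg=d_lyg, iser=value, dominant=dominant)


def min_sample_size_for_significance(
    strategy_a: StrategySpec,
    strategy_b: StrategySpec,
    sizes: Sequence[int],
    cfg: SimConfig,
    alpha: float = 0.05,
    reps: int = 20,
) -> dict:
    """Smallest simulated trial size separating two sequences by rank-sum test.

    At each candidate size both cohorts are simulated ``reps`` times with
    fresh seeds and the two-sided Mann-Whitney (Wilcoxon rank-sum) test is
    applied to the overall-survival samples; the first size whose rejection
    frequency exceeds 0.5 is returned.  If none reaches significance the
    largest size tested is reported with ``reached=False``.
    """
    sizes = list(sizes)
    if any(n2 <= n1 for n1, n2 in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly increasing")
    ss = np.random.SeedSequence(cfg.seed)
    result = {"reached": False, "n": sizes[-1] if sizes else None, "rejection_freq": {}}
    for n in sizes:
        rejections = 0
        for _ in range(reps):
            sa, sb = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
            ca = simulate_cohort(strategy_a, dc_replace(cfg, n_patients=n, seed=sa))
            cb = simulate_cohort(strategy_b, dc_replace(cfg, n_patients=n, seed=sb))
            p = mannwhitneyu(ca.t_death, cb.t_death, alternative="two-sided").pvalue
            rejections += p <= alpha
        freq = rejections / reps
        result["rejection_freq"][n] = freq
        if freq > 0.5:
            result.update(reached=True, n=n)
            break
    return result


def summarize_cohort(
    cohort: CohortResult, sae_first: float, sae_second: float, milestone: float = 36.0
) -> dict:
    """Raw (unrounded) per-sequence summary used to build the outcome table."""
    return {
        "sequence": cohort.label,
        "median_os_mo": median_os(cohort),
        "os36_pct": milestone_survival(cohort, milestone),
        "sae_pct": weighted_sae(cohort, sae_first, sae_second),
        "n_transited_second": cohort.n_transited_second,
    }


def rank_strategies(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble the ranked outcome table from per-sequence summaries.

    Rows (dicts from :func:`summarize_cohort`) are sorted by median OS
    descending; LYG and NNT are computed against the worst (last) row, which
    reports LYG 0 and NNT ``None``.  Unrounded columns are kept alongside the
    table-style rounded ones.
    """
    if len(rows) < 1:
        raise ValueError("need at least one sequence summary")
    df = pd.DataFrame(list(rows)).sort_values(
        ["median_os_mo", "os36_pct"], ascending=False, kind="stable"
    )
    df = df.reset_index(drop=True)
    ref = df.iloc[-1]
    df["lyg_yr"] = [lyg(m, ref["median_os_mo"]) for m in df["median_os_mo"]]
    df["nnt"] = pd.Series(
        [
            None if i == len(df) - 1 else nnt(v, ref["os36_pct"])
            for i, v in enumerate(df["os36_pct"])
        ],
        dtype=object,
    )
    df["median_os_mo_rounded"] = df["median_os_mo"].round().astype(int)
    df["lyg_yr_rounded"] = df["lyg_yr"].round(2)
    df["os36_pct_rounded"] = df["os36_pct"].round(1)
    df["sae_pct_rounded"] = df["sae_pct"].round(1)
    return df
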