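"""Kaplan-Meier estimation and individual-patient-data reconstruction.

Published trials report survival as KM curves plus number-at-risk tables, not
patient-level records.  :func:`reconstruct_ipd` inverts that summary: within
each interval between consecutive risk-table times it solves for event and
censoring counts such that (i) the KM estimate recomputed from the output
tracks the digitized curve and (ii) the implied number at risk matches the
published table exactly.  The scheme follows the standard iterative
reconstruction algorithm for digitized curves: censorings are spread
uniformly over each interval and the censoring total is adjusted until the
risk constraint is met.

:func:`km_estimate` is a plain product-limit estimator kept deliberately
dependency-free so that third-party KM implementations can serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "IPDSet",
    "InfeasibleCurveError",
    "km_estimate",
    "reconstruct_ipd",
    "survival_at",
]

# survival rises up to this much are treated as digitization jitter and
# clamped to the running minimum; larger rises are rejected
_JITTER_TOL = 0.005


class InfeasibleCurveError(ValueError):
    """Raised when curve/risk-table inputs cannot come from any KM process."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM curve.

    A (0, 1) anchor is inserted if absent; small non-monotonicities from
    digitization are clamped to the running minimum.
    """

    points: tuple[tuple[float, float], ...]

    def __init__(self, points: Iterable[tuple[float, float]]):
        pts = [(float(t), float(s)) for t, s in points]
        if not pts:
            raise ValueError("curve needs at least one point")
        if pts[0][0] > 0:
            pts.insert(0, (0.0, 1.0))
        times = [t for t, _ in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InfeasibleCurveError("curve times must be strictly increasing")
        cleaned: list[tuple[float, float]] = []
        run_min = 1.0
        for i, (t, s) in enumerate(pts):
            if not 0.0 <= s <= 1.0 + _JITTER_TOL:
                raise InfeasibleCurveError(f"survival {s} at t={t} outside [0, 1]")
            if s > run_min + _JITTER_TOL:
                raise InfeasibleCurveError(
                    f"survival rises from {run_min:.4f} to {s:.4f} at t={t} (point {i})"
                )
            run_min = min(run_min, min(s, 1.0))
            cleaned.append((t, run_min))
        object.__setattr__(self, "points", tuple(cleaned))

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["time_months", "survival"])

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        _require_columns(df, ("time_months", "survival"), path)
        return cls(zip(df["time_months"], df["survival"]))


@dataclass(frozen=True)
class RiskTable:
    """Number-at-risk table printed under a published KM curve."""

    entries: tuple[tuple[float, int], ...]

    def __init__(self, entries: Iterable[tuple[float, int]]):
        ent = [(float(t), int(n)) for t, n in entries]
        if not ent:
            raise ValueError("risk table needs at least one entry")
        for (t1, n1), (t2, n2) in zip(ent, ent[1:]):
            if t2 <= t1:
                raise InfeasibleCurveError("risk-table times must be strictly increasing")
            if n2 > n1:
                raise InfeasibleCurveError(
                    f"number at risk rises from {n1} (t={t1}) to {n2} (t={t2})"
                )
        if any(n < 0 for _, n in ent):
            raise InfeasibleCurveError("number at risk must be non-negative")
        object.__setattr__(self, "entries", tuple(ent))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["time_months", "n_at_risk"])

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        _require_columns(df, ("time_months", "n_at_risk"), path)
        return cls(zip(df["time_months"], df["n_at_risk"]))


@dataclass
class IPDSet:
    """Per-patient (time, event) records; event=True means the endpoint occurred."""

    records: list[tuple[float, bool]]
    meta: str = field(default="")

    def __post_init__(self) -> None:
        if any(not (t > 0 and math.isfinite(t)) for t, _ in self.records):
            raise ValueError("all IPD times must be positive and finite")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([e for _, e in self.records], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_months": self.times, "event": self.events.astype(int)}
        )

    @classmethod
    def from_csv(cls, path, meta: str = "") -> "IPDSet":
        df = pd.read_csv(path)
        _require_columns(df, ("time_months", "event"), path)
        return cls([(float(t), bool(e)) for t, e in zip(df["time_months"], df["event"])], meta=meta)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")


def km_estimate(ipd: IPDSet) -> DigitizedCurve:
    """Product-limit survival estimate, as a step function anchored at (0, 1).

    Ties between events and censorings at the same time follow the usual
    convention: events happen first, censored patients remain at risk through
    the event.
    """
    if len(ipd) == 0:
        raise ValueError("cannot estimate survival from an empty IPD set")
    times, events = ipd.times, ipd.events
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events])
    points = [(0.0, 1.0)]
    s = 1.0
    for t in uniq:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        points.append((float(t), s))
    return DigitizedCurve(points)


def survival_at(curve: DigitizedCurve, t) -> np.ndarray:
    """Evaluate a step-function curve at arbitrary times (right-continuous)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(curve.times, t, side="right") - 1
    idx = np.clip(idx, 0, len(curve.points) - 1)
    return curve.survival[idx]


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
) -> IPDSet:
    """Recover patient-level (time, event) records from a digitized curve.

    Within each risk interval the number censored is found iteratively:
    censoring times are spread uniformly across the interval, event counts at
    each digitized drop follow from the running KM product, and the censoring
    total is adjusted until the number still at risk at the interval's end
    equals the published value.  Events are placed at the digitized time of
    each survival drop (step-function semantics).  If ``total_events`` is
    given, the event total is adjusted in the final interval by converting
    the latest censorings to events (or vice versa).
    """
    rt = list(risk.entries)
    ct, cs = curve.times, curve.survival
    if ct[0] > rt[0][0] or ct[-1] < rt[-1][0]:
        raise InfeasibleCurveError(
            f"curve [{ct[0]}, {ct[-1]}] does not span the risk table "
            f"[{rt[0][0]}, {rt[-1][0]}]"
        )
    n_total = rt[0][1]
    if n_total <= 0:
        raise InfeasibleCurveError("no patients at risk at the first risk-table time")
    # open-ended final interval up to the end of the digitized curve
    boundaries = [t for t, _ in rt] + ([ct[-1] + 1e-9] if ct[-1] > rt[-1][0] else [])
    targets = [n for _, n in rt[1:]]

    event_times: list[float] = []
    censor_times: list[float] = []
    n_entering = n_total
    s_km = 1.0  # running KM value of the reconstruction
    for j in range(len(boundaries) - 1):
        lo, hi = boundaries[j], boundaries[j + 1]
        mask = (ct > lo) & (ct <= hi)
        sub_t, sub_s = ct[mask], cs[mask]
        has_target = j < len(targets)
        n_target = targets[j] if has_target else 0
        max_loss = n_entering - (n_target if has_target else 0)
        if max_loss < 0:
            raise InfeasibleCurveError(
                f"risk table infeasible in interval [{lo}, {hi}]: "
                f"{n_target} at risk exceeds the {n_entering} entering"
            )
        # iterate on the censoring total for this interval; the open tail
        # past the last risk entry gets no intra-interval censoring —
        # survivors are censored at the curve's end instead
        c_hat = 0
        best = None
        for _ in range(40):
            d_times, d_counts, s_end = _allocate_events(
                n_entering, s_km, sub_t, sub_s, lo, hi, c_hat
            )
            n_end = n_entering - sum(d_counts) - c_hat
            if has_target:
                gap = n_end - n_target
                if best is None or abs(gap) < abs(best[0]):
                    best = (gap, c_hat, d_times, d_counts, s_end)
                if gap == 0:
                    break
                c_hat = int(np.clip(c_hat + gap, 0, max_loss))
            else:
                best = (0, c_hat, d_times, d_counts, s_end)
                break
        gap, c_hat, d_times, d_counts, s_end = best
        if has_target and gap != 0:
            # absorb any residual in the censoring count (earliest sub-interval
            # semantics: extra censorings are placed uniformly like the rest)
            c_hat = int(np.clip(c_hat + gap, 0, max_loss - sum(d_counts)))
            if n_entering - sum(d_counts) - c_hat != n_target:
                raise InfeasibleCurveError(
                    f"cannot match number at risk {n_target} at t={hi}"
                )
        for t, d in zip(d_times, d_counts):
            event_times.extend([t] * d)
        censor_times.extend(_spread(lo, hi, c_hat))
        n_entering -= sum(d_counts) + c_hat
        s_km = s_end

    # survivors past the last boundary are censored there
    censor_times.extend([boundaries[-1]] * n_entering)

    if total_events is not None:
        event_times, censor_times = _match_total_events(
            event_times, censor_times, total_events
        )

    records = [(t, True) for t in event_times] + [(t, False) for t in censor_times]
    records.sort()
    return IPDSet(records, meta="reconstructed")


def _spread(lo: float, hi: float, c: int) -> list[float]:
    """c censoring times spread uniformly over (lo, hi]."""
    if c <= 0:
        return []
    return [lo + (hi - lo) * (i + 0.5) / c for i in range(c)]


def _allocate_events(
    n_entering: int,
    s_km: float,
    sub_t: np.ndarray,
    sub_s: np.ndarray,
    lo: float,
    hi: float,
    n_censor: int,
):
    """Walk the digitized drops in one interval given a censoring total.

    Censorings are assumed uniform over the interval, so between consecutive
    digitized points a proportional share of them leaves the risk set.
    Returns event times, event counts and the interval-end KM value.
    """
    cens_t = np.array(_spread(lo, hi, n_censor))
    d_times: list[float] = []
    d_counts: list[int] = []
    n = n_entering
    s_run = s_km
    prev_t = lo
    for t, s in zip(sub_t, sub_s):
        n -= int(np.sum((cens_t > prev_t) & (cens_t <= t)))  # censored before this drop
        if n <= 0 or s_run <= 0:
            break
        # rounding is self-correcting: s_run tracks the *reconstructed* KM, so
        # the next drop targets the input curve relative to what was allocated
        d = int(max(0, min(round(n * (1.0 - s / s_run)), n)))
        if d > 0:
            s_run *= 1.0 - d / n
            d_times.append(float(t))
            d_counts.append(d)
            n -= d
        prev_t = t
    return d_times, d_counts, s_run


def _match_total_events(
    event_times: list[float], censor_times: list[float], total_events: int
):
    """Convert latest censorings<->events so the event total matches."""
    if total_events < 0:
        raise ValueError("total_events must be non-negative")
    deficit = total_events - len(event_times)
    if deficit > 0:
        censor_times = sorted(censor_times)
        move, censor_times = censor_times[-deficit:], censor_times[:-deficit]
        event_times = event_times + move
    elif deficit < 0:
        event_times = sorted(event_times)
        move, event_times = event_times[deficit:], event_times[:deficit]
        censor_times = censor_times + move
    return event_times, censor_times
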