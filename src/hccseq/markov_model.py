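"""Three-state semi-Markov microsimulation of sequential systemic therapy.

States: (1) advanced hepatocellular carcinoma on first-line therapy,
(2) first progression, on second-line therapy, (3) dead.  The model is
semi-Markov: the time-to-event law of each state is clocked from state entry,
so hazards may rise with time in state — continuous event times are sampled
from the parametric laws and then binned to monthly cycles (events are
recorded at the end of the cycle containing them), which is exact where
per-cycle transition probabilities would approximate.

First-line exit is a progression/death split: with probability
``delta_death_first_line`` the first-line event is a death (the patient never
reaches second line), otherwise the patient progresses and a second-line
post-progression survival time is drawn from progression.  Background
(non-cancer) mortality competes independently via an age-indexed life table,
with age advancing along the simulation clock from 60.  Risks and benefits
are not discounted: the cohort's life expectancy is short.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .survival_fit import WeibullParams

__all__ = [
    "TherapyProfile",
    "StrategySpec",
    "LifeTable",
    "SimConfig",
    "CohortResult",
    "monthly_background_hazard",
    "simulate_patient",
    "simulate_cohort",
    "load_life_table",
    "default_life_table",
]

EXIT_PROGRESSION = "progression"
EXIT_HCC_DEATH = "hcc_death"
EXIT_BACKGROUND_DEATH = "background_death"


@dataclass(frozen=True)
class TherapyProfile:
    """One treatment's time-to-event law and toxicity.

    ``ttev`` is the progression-free survival law for first-line treatments
    and the post-progression overall survival law for second-line treatments;
    ``sae_pct`` is the trial-reported rate of grade >= 3 adverse events.
    """

    name: str
    line: str
    ttev: WeibullParams
    sae_pct: float

    def __post_init__(self) -> None:
        if self.line not in ("first", "second"):
            raise ValueError(f"line must be 'first' or 'second', got {self.line!r}")
        if not 0.0 <= self.sae_pct <= 100.0:
            raise ValueError(f"sae_pct must lie in [0, 100], got {self.sae_pct}")


@dataclass(frozen=True)
class StrategySpec:
    """An ordered first-line -> second-line treatment sequence."""

    first_line: TherapyProfile
    second_line: TherapyProfile
    label: str = ""

    def __post_init__(self) -> None:
        if self.first_line.line != "first":
            raise ValueError(f"{self.first_line.name} is not a first-line profile")
        if self.second_line.line != "second":
            raise ValueError(f"{self.second_line.name} is not a second-line profile")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.first_line.name}-{self.second_line.name}"
            )


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age."""

    ages: tuple[int, ...]
    q: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.q) or not self.ages:
            raise ValueError("life table needs matching, non-empty age and q columns")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise ValueError("life-table ages must be contiguous integers")
        if any(not 0.0 <= qi <= 1.0 for qi in self.q):
            raise ValueError("annual death probabilities must lie in [0, 1]")

    def annual_q(self, age_years: float) -> float:
        idx = int(math.floor(age_years)) - self.ages[0]
        if idx < 0 or idx >= len(self.q):
            raise ValueError(
                f"age {age_years} outside the life table range "
                f"[{self.ages[0]}, {self.ages[-1] + 1})"
            )
        return self.q[idx]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings (defaults are the base case)."""

    n_patients: int = 2000
    cycle_months: float = 1.0
    start_age: float = 60.0
    horizon_cycles: int = 480
    delta_death_first_line: float = 0.08
    seed: int = 0
    life_table: LifeTable | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.cycle_months <= 0:
            raise ValueError("cycle_months must be positive")
        if not 0.0 <= self.delta_death_first_line <= 1.0:
            raise ValueError("delta_death_first_line must lie in [0, 1]")
        if self.life_table is None:
            object.__setattr__(self, "life_table", default_life_table())


@dataclass
class CohortResult:
    """Per-patient trajectory summaries for one simulated sequence."""

    label: str
    t_exit_first: np.ndarray  # months, cycle grid
    exit_type: np.ndarray  # EXIT_* strings
    t_death: np.ndarray  # months, cycle grid
    reached_second_line: np.ndarray  # bool
    horizon_censored: np.ndarray = field(default=None)  # death beyond horizon cap

    def __post_init__(self) -> None:
        if self.horizon_censored is None:
            self.horizon_censored = np.zeros(len(self.t_death), dtype=bool)
        if np.any(self.t_death < self.t_exit_first):
            raise ValueError("t_death < t_exit_first violates the trajectory order")
        if not np.array_equal(self.reached_second_line, self.exit_type == EXIT_PROGRESSION):
            raise ValueError("reached_second_line must coincide with progression exits")

    def __len__(self) -> int:
        return len(self.t_death)

    @property
    def n_transited_first(self) -> int:
        return len(self.t_death)

    @property
    def n_transited_second(self) -> int:
        return int(self.reached_second_line.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(len(self.t_death)),
                "t_exit_first": self.t_exit_first,
                "exit_type": self.exit_type,
                "t_death": self.t_death,
            }
        )

    def state_counts(self, cycle: int) -> tuple[int, int, int]:
        """(on first line, post-progression, dead) occupancy at a cycle index."""
        t = float(cycle)
        on_first = int(np.sum(self.t_exit_first > t))
        dead = int(np.sum(self.t_death <= t))
        post = len(self.t_death) - on_first - dead
        return on_first, post, dead


def monthly_background_hazard(table: LifeTable, age_years: float) -> float:
    """Constant-within-year monthly hazard: -ln(1 - q(floor(age)))/12."""
    q = table.annual_q(age_years)
    if q >= 1.0:
        return math.inf
    return -math.log1p(-q) / 12.0


from functools import lru_cache


@lru_cache(maxsize=32)
def _hazard_schedule(table: LifeTable, start_age: float, horizon_months: int):
    months = np.arange(horizon_months)
    hazards = np.array(
        [monthly_background_hazard(table, start_age + m / 12.0) for m in months]
    )
    cum = np.concatenate([[0.0], np.cumsum(hazards)])
    return hazards, cum


def _background_death_times(
    table: LifeTable, start_age: float, horizon_months: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise-exponential inversion of the life table from start_age.

    Returns continuous months-from-start; values past the horizon are left at
    +inf (the caller caps them).
    """
    hazards, cum = _hazard_schedule(table, start_age, horizon_months)
    u = rng.exponential(size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    out = np.full(n, np.inf)
    inside = idx < horizon_months
    h = hazards[idx[inside]]
    with np.errstate(divide="ignore"):
        frac = np.where(h > 0, (u[inside] - cum[idx[inside]]) / h, np.inf)
    out[inside] = idx[inside] + np.minimum(frac, 1.0)
    return out


def simulate_cohort(strategy: StrategySpec, cfg: SimConfig) -> CohortResult:
    """Simulate ``cfg.n_patients`` independent trajectories for one sequence.

    Deterministic under a fixed ``cfg.seed``.  Continuous times are drawn
    per patient, ordering is resolved in continuous time, and both the
    first-line exit and the death are then binned to the end of the
    containing cycle.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    horizon = cfg.horizon_cycles * cfg.cycle_months

    t1 = strategy.first_line.ttev.sample(n, rng)
    die_first = rng.random(n) < cfg.delta_death_first_line
    t2 = strategy.second_line.ttev.sample(n, rng)
    t_bg = _background_death_times(
        cfg.life_table, cfg.start_age, cfg.horizon_cycles, n, rng
    )

    t_disease_death = np.where(die_first, t1, t1 + t2)
    t_death_cont = np.minimum(t_disease_death, t_bg)
    t_exit_cont = np.minimum(t1, t_death_cont)

    exit_type = np.full(n, EXIT_PROGRESSION, dtype=object)
    exit_type[die_first & (t1 <= t_bg)] = EXIT_HCC_DEATH
    exit_type[t_bg < t1] = EXIT_BACKGROUND_DEATH

    def to_grid(t: np.ndarray) -> np.ndarray:
        cycles = np.ceil(np.minimum(t, horizon) / cfg.cycle_months)
        return np.maximum(cycles, 1.0) * cfg.cycle_months

    horizon_censored = t_death_cont > horizon
    t_death = to_grid(t_death_cont)
    t_exit = np.minimum(to_grid(t_exit_cont), t_death)

    return CohortResult(
        label=strategy.label,
        t_exit_first=t_exit,
        exit_type=np.asarray(exit_type),
        t_death=t_death,
        reached_second_line=np.asarray(exit_type == EXIT_PROGRESSION),
        horizon_censored=horizon_censored,
    )


def simulate_patient(
    strategy: StrategySpec, cfg: SimConfig, rng: np.random.Generator | int | None = None
):
    """Simulate a single trajectory; returns one row of :class:`CohortResult`.

    Accepts an explicit generator (or seed) so callers can stream patients.
    """
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31 - 1))
    elif rng is None:
        seed = cfg.seed
    else:
        seed = int(rng)
    one = replace(cfg, n_patients=1, seed=seed)
    cohort = simulate_cohort(strategy, one)
    return {
        "t_exit_first": float(cohort.t_exit_first[0]),
        "exit_type": str(cohort.exit_type[0]),
        "t_death": float(cohort.t_death[0]),
        "reached_second_line": bool(cohort.reached_second_line[0]),
    }


def load_life_table(path) -> LifeTable:
    df = pd.read_csv(path, sep="\t")
    if "age" not in df.columns or "annual_death_prob" not in df.columns:
        raise ValueError(f"{path}: life table needs 'age' and 'annual_death_prob' columns")
    return LifeTable(
        ages=tuple(int(a) for a in df["age"]),
        q=tuple(float(v) for v in df["annual_death_prob"]),
    )


def default_life_table() -> LifeTable:
    """Packaged synthetic male life table (Gompertz: q(60)=0.011, doubling
    every 8 years); replace via :class:`SimConfig` for country-specific runs."""
    with resources.files("hccseq.data").joinpath("life_table_male.tsv").open() as fh:
        return load_life_table(fh)


def zero_mortality_life_table(span: int = 80) -> LifeTable:
    """All-zero background mortality, for isolating the disease process."""
    return LifeTable(ages=tuple(range(60, 60 + span)), q=(0.0,) * span)
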