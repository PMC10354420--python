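"""Five-state Markov cohort model with half-cycle correction and discounting.

States, in fixed matrix order: CKD stage 3, CKD stage 4, CKD stage 5 without
hemodialysis, CKD stage 5 on hemodialysis, and death.  Progression is
irreversible; the cohort starts in stage 3.  Mass leaving stage 4 for stage
5 splits between the two stage-5 states by the hemodialysis uptake fraction
(base case 89.1%).  Within a cycle, death competes first and progression
applies to survivors (the ordering is a config switch).

Rewards are accumulated on the occupancy trace.  With the half-cycle
correction (default), boundary occupancies at t = 0 and t = horizon receive
weight 1/2 and interior boundaries weight 1 — the trapezoid approximation to
mid-cycle events.  Without it, rewards land at end-of-cycle boundaries
t = 1..horizon, the convention under which a constant unit utility stream at
discount rate r reproduces the closed-form annuity (1 - (1+r)^-T)/r.
Discounting at boundary t is (1+r)^-t.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InfeasibleMatrixError

__all__ = [
    "STATES",
    "Payoffs",
    "ModelConfig",
    "Strategy",
    "CohortTrace",
    "CEResult",
    "annual_drug_cost",
    "build_matrix",
    "run_trace",
    "evaluate_strategy",
    "compare",
]

#: fixed state order for matrix indexing
STATES = ("ckd3", "ckd4", "ckd5_nohd", "ckd5_hd", "death")
_IDX = {s: i for i, s in enumerate(STATES)}


def annual_drug_cost(
    unit_price: float,
    tablets_per_pack: int,
    daily_tablets: float,
    compliance: float,
    days: float = 365.0,
) -> float:
    """Drug cost per cycle: unit price x daily dosage x cycle x compliance.

    ``unit_price`` is CNY per pack of ``tablets_per_pack`` tablets.
    """
    if not (0.0 < compliance <= 1.0):
        raise ConfigError(f"compliance must be in (0, 1], got {compliance}")
    if min(unit_price, tablets_per_pack, daily_tablets, days) <= 0:
        raise ConfigError("drug-cost inputs must be positive")
    return (unit_price / tablets_per_pack) * daily_tablets * days * compliance


@dataclass(frozen=True)
class Payoffs:
    """Per-state annual cost (CNY) and utility weight (QALY, in [0,1]).

    Death is pinned to zero cost and zero utility.
    """

    costs: Mapping[str, float]
    utilities: Mapping[str, float]

    def __post_init__(self) -> None:
        costs = {s: float(self.costs.get(s, 0.0)) for s in STATES}
        utils = {s: float(self.utilities.get(s, 0.0)) for s in STATES}
        costs["death"] = 0.0
        utils["death"] = 0.0
        for s in STATES:
            if costs[s] < 0:
                raise ConfigError(f"cost for {s} must be >= 0")
            if not 0.0 <= utils[s] <= 1.0:
                raise ConfigError(f"utility for {s} must be in [0, 1]")
        object.__setattr__(self, "costs", costs)
        object.__setattr__(self, "utilities", utils)

    def cost_vector(self) -> np.ndarray:
        return np.array([self.costs[s] for s in STATES])

    def utility_vector(self) -> np.ndarray:
        return np.array([self.utilities[s] for s in STATES])

    def with_extra_cost(self, extra: Mapping[str, float]) -> "Payoffs":
        costs = dict(self.costs)
        for s, v in extra.items():
            costs[s] = costs[s] + v
        return Payoffs(costs=costs, utilities=dict(self.utilities))


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings of the cohort model."""

    horizon: int = 20
    cycle_years: float = 1.0
    discount_rate: float = 0.05
    hd_fraction: float = 0.891
    wtp: float = 80_976.0
    half_cycle: bool = True
    ordering: str = "death_first"  # or "progression_first"

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise ConfigError("discount rate must be >= 0")
        if not 0.0 <= self.hd_fraction <= 1.0:
            raise ConfigError("hd_fraction must be in [0, 1]")
        if self.ordering not in ("death_first", "progression_first"):
            raise ConfigError(f"unknown ordering {self.ordering!r}")


def build_matrix(
    p_3to4: float,
    p_4to5: float,
    mortality: Mapping[str, float],
    hd_fraction: float = 0.891,
    ordering: str = "death_first",
) -> np.ndarray:
    """Annual transition matrix over the five states.

    ``mortality`` maps state -> annual death probability.  Under
    "death_first" progression applies to cycle survivors,
    p_move = p * (1 - m); under "progression_first" the stay probability is
    1 - m - p, which must be non-negative.
    """
    probs = {"p_3to4": p_3to4, "p_4to5": p_4to5, "hd_fraction": hd_fraction}
    for name, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise InfeasibleMatrixError(f"{name}={p} outside [0, 1]")
    m = {s: float(mortality.get(s, 0.0)) for s in STATES[:4]}
    for s, v in m.items():
        if not 0.0 <= v <= 1.0:
            raise InfeasibleMatrixError(f"mortality[{s}]={v} outside [0, 1]")

    def split(p_die: float, p_prog: float) -> tuple:
        if ordering == "death_first":
            move = p_prog * (1.0 - p_die)
        else:
            if p_die + p_prog > 1.0:
                raise InfeasibleMatrixError(
                    f"mortality {p_die} + progression {p_prog} > 1"
                )
            move = p_prog
        stay = 1.0 - p_die - move
        if stay < -1e-12:
            raise InfeasibleMatrixError("negative stay probability")
        return max(stay, 0.0), move, p_die

    M = np.zeros((5, 5))
    stay, move, die = split(m["ckd3"], p_3to4)
    M[_IDX["ckd3"], _IDX["ckd3"]] = stay
    M[_IDX["ckd3"], _IDX["ckd4"]] = move
    M[_IDX["ckd3"], _IDX["death"]] = die

    stay, move, die = split(m["ckd4"], p_4to5)
    M[_IDX["ckd4"], _IDX["ckd4"]] = stay
    M[_IDX["ckd4"], _IDX["ckd5_hd"]] = move * hd_fraction
    M[_IDX["ckd4"], _IDX["ckd5_nohd"]] = move * (1.0 - hd_fraction)
    M[_IDX["ckd4"], _IDX["death"]] = die

    for s in ("ckd5_nohd", "ckd5_hd"):
        M[_IDX[s], _IDX[s]] = 1.0 - m[s]
        M[_IDX[s], _IDX["death"]] = m[s]

    M[_IDX["death"], _IDX["death"]] = 1.0
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
    return M


@dataclass
class CohortTrace:
    """State occupancy per cycle boundary plus discounted accumulators."""

    occupancy: np.ndarray  # (horizon+1, 5)
    cycle_costs: np.ndarray  # discounted, weighted, per boundary
    cycle_qalys: np.ndarray
    total_cost: float
    total_qalys: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(len(df)))
        df["disc_cost"] = self.cycle_costs
        df["disc_qalys"] = self.cycle_qalys
        return df


def run_trace(
    matrix: np.ndarray,
    payoffs: Payoffs,
    config: ModelConfig = ModelConfig(),
    initial: Optional[Sequence[float]] = None,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted costs and QALYs.

    ``initial`` is the distribution over states at t=0 (default: everyone in
    CKD stage 3).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (5, 5):
        raise ConfigError("matrix must be 5x5 in the canonical state order")
    if initial is None:
        initial = np.eye(5)[0]
    initial = np.asarray(initial, dtype=float)
    if initial.min() < 0 or abs(initial.sum() - 1.0) > 1e-9:
        raise ConfigError("initial must be a distribution over states")

    T = config.horizon
    occ = np.empty((T + 1, 5))
    occ[0] = initial
    for t in range(T):
        occ[t + 1] = occ[t] @ matrix

    if config.half_cycle:
        weights = np.ones(T + 1)
        weights[0] = 0.5
        weights[-1] = 0.5
    else:
        weights = np.ones(T + 1)
        weights[0] = 0.0
    disc = (1.0 + config.discount_rate) ** -np.arange(T + 1)
    w = weights * disc

    cost_per_boundary = occ @ payoffs.cost_vector()
    qaly_per_boundary = occ @ payoffs.utility_vector() * config.cycle_years
    cycle_costs = w * cost_per_boundary
    cycle_qalys = w * qaly_per_boundary
    return CohortTrace(
        occupancy=occ,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
        total_cost=float(cycle_costs.sum()),
        total_qalys=float(cycle_qalys.sum()),
    )


@dataclass(frozen=True)
class Strategy:
    """A named arm bundling its transition matrix and payoffs."""

    name: str
    matrix: np.ndarray
    payoffs: Payoffs


def evaluate_strategy(
    strategy: Strategy,
    config: ModelConfig = ModelConfig(),
    initial: Optional[Sequence[float]] = None,
) -> CohortTrace:
    return run_trace(strategy.matrix, strategy.payoffs, config, initial)


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of two strategies at a WTP threshold."""

    cost_ref: float
    qaly_ref: float
    cost_comp: float
    qaly_comp: float
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    nmb: float
    wtp: float
    dominant: bool
    dominated: bool
    cost_effective: bool

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare(
    reference: tuple,
    comparator: tuple,
    wtp: float = 80_976.0,
) -> CEResult:
    """Incremental cost-effectiveness of ``comparator`` vs ``reference``.

    Each argument is a ``(total_cost, total_qalys)`` pair evaluated under an
    identical model configuration.  The ICER is reported at full precision
    when the QALY increment is non-zero; dominance flags cover the
    quadrants where an ICER is not meaningful.  The net monetary benefit
    NMB = wtp * dQALY - dCost is always reported.
    """
    cost_ref, qaly_ref = map(float, reference)
    cost_comp, qaly_comp = map(float, comparator)
    d_cost = cost_comp - cost_ref
    d_qaly = qaly_comp - qaly_ref
    icer = d_cost / d_qaly if d_qaly != 0.0 else None
    nmb = wtp * d_qaly - d_cost
    dominant = d_cost < 0 and d_qaly > 0
    dominated = d_cost > 0 and d_qaly < 0
    return CEResult(
        cost_ref=cost_ref,
        qaly_ref=qaly_ref,
        cost_comp=cost_comp,
        qaly_comp=qaly_comp,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        icer=None if (dominant or dominated) else icer,
        nmb=nmb,
        wtp=float(wtp),
        dominant=dominant,
        dominated=dominated,
        cost_effective=nmb > 0.0,
    )
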