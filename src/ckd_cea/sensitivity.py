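"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis perturbs each parameter to its low/high bound — the
reported 95% CI where available, otherwise +/-30% of the base case (with
probabilities and utilities clipped to [0, 1]) — holding the rest at base,
and ranks parameters by the width of the induced output range (tornado
order).

Probabilistic analysis draws each parameter from a distribution
parameterized by method of moments from (mean, sd): gamma for costs, beta
for probabilities/proportions/utilities, degenerate for fixed quantities.
Draws are independent across parameters; when only +/-30% bounds exist the
sd defaults to (high - low)/(2 * 1.96).  The cost-effectiveness
acceptability curve is the fraction of Monte Carlo draws with positive net
monetary benefit across a willingness-to-pay grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .markov import CEResult

__all__ = [
    "ParamSpec",
    "PsaDraws",
    "owsa_bounds",
    "one_way_sa",
    "moments_to_gamma",
    "moments_to_beta",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96

#: 0 to three times 2021 GDP per capita (CNY 242,928), 1,000-CNY steps
DEFAULT_WTP_GRID = np.arange(0.0, 242_928.0 + 1_000.0, 1_000.0)


@dataclass(frozen=True)
class ParamSpec:
    """One model parameter: base value, OWSA bounds and PSA distribution.

    ``low``/``high`` are explicit interval bounds (e.g. a reported 95% CI);
    when absent, +/-30% of base is used.  ``unit_interval`` marks
    probabilities/proportions/utilities, whose bounds are clipped to [0, 1]
    (implied when ``psa_family="beta"``).  ``psa_mean``/``psa_sd`` default
    to the base value and the implied OWSA half-width / 1.96.
    """

    name: str
    base: float
    low: Optional[float] = None
    high: Optional[float] = None
    psa_family: str = "degenerate"  # gamma | beta | degenerate
    psa_mean: Optional[float] = None
    psa_sd: Optional[float] = None
    unit_interval: bool = False

    def __post_init__(self) -> None:
        if self.psa_family not in ("gamma", "beta", "degenerate"):
            raise ConfigError(f"{self.name}: unknown PSA family {self.psa_family!r}")
        if self.psa_family == "beta":
            object.__setattr__(self, "unit_interval", True)
        if self.low is not None and self.high is not None:
            if not self.low <= self.base <= self.high:
                raise ConfigError(f"{self.name}: bounds must bracket base")
        mean = self.base if self.psa_mean is None else self.psa_mean
        if self.psa_family == "gamma" and mean <= 0:
            raise ConfigError(f"{self.name}: gamma mean must be > 0")
        if self.psa_family == "beta" and not (0.0 < mean < 1.0):
            raise ConfigError(f"{self.name}: beta mean must be in (0, 1)")
        if self.psa_sd is not None and self.psa_sd < 0:
            raise ConfigError(f"{self.name}: sd must be >= 0")

    @property
    def effective_mean(self) -> float:
        return self.base if self.psa_mean is None else self.psa_mean

    @property
    def effective_sd(self) -> float:
        if self.psa_sd is not None:
            return self.psa_sd
        low, high = owsa_bounds(self)
        return (high - low) / (2.0 * Z_95)


def owsa_bounds(spec: ParamSpec) -> tuple:
    """Low/high values for one-way sensitivity analysis.

    Stated bounds win; otherwise +/-30% of base.  Unit-interval quantities
    are clipped to [0, 1].
    """
    if spec.low is not None and spec.high is not None:
        low, high = float(spec.low), float(spec.high)
    else:
        low, high = 0.7 * spec.base, 1.3 * spec.base
        if spec.base < 0:
            low, high = high, low
    if spec.unit_interval:
        low, high = max(low, 0.0), min(high, 1.0)
    return low, high


def moments_to_gamma(mean: float, sd: float) -> tuple:
    """Method-of-moments gamma: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0 or sd <= 0:
        raise ConfigError("gamma requires mean > 0 and sd > 0")
    return mean**2 / sd**2, sd**2 / mean


def moments_to_beta(mean: float, sd: float) -> tuple:
    """Method-of-moments beta: requires sd^2 < mean(1-mean)."""
    if not (0.0 < mean < 1.0):
        raise ConfigError("beta requires mean in (0, 1)")
    var = sd**2
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ConfigError("beta requires 0 < sd^2 < mean(1-mean)")
    alpha = mean * (mean * (1.0 - mean) / var - 1.0)
    beta = alpha * (1.0 - mean) / mean
    return alpha, beta


def sample_param(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from the parameter's PSA distribution."""
    mean, sd = spec.effective_mean, spec.effective_sd
    if spec.psa_family == "degenerate" or sd == 0.0:
        return np.full(size, mean) if size is not None else mean
    if spec.psa_family == "gamma":
        shape, scale = moments_to_gamma(mean, sd)
        return rng.gamma(shape, scale, size=size)
    alpha, beta = moments_to_beta(mean, sd)
    return rng.beta(alpha, beta, size=size)


def one_way_sa(
    params: Sequence[ParamSpec],
    model: Callable[[Mapping[str, float]], CEResult],
    metric: str = "icer",
) -> pd.DataFrame:
    """Tornado table: the output at each parameter's bounds, others at base.

    ``model`` maps a {name: value} dict to a :class:`CEResult`.  ``metric``
    is "icer" or "nmb".  Rows come back sorted by descending output range;
    a bound at which the model fails is recorded as NaN with a warning.
    """
    if metric not in ("icer", "nmb"):
        raise ConfigError(f"unknown metric {metric!r}")
    base_values = {p.name: p.base for p in params}
    base_res = model(base_values)
    base_out = getattr(base_res, metric)

    def _eval(values: Mapping[str, float], which: str, name: str):
        try:
            res = model(values)
        except Exception as exc:  # model failure at a bound is data, not a crash
            warnings.warn(f"one_way_sa: model failed at {name} {which}: {exc}")
            return np.nan, np.nan
        return getattr(res, "icer"), getattr(res, "nmb")

    rows = []
    for p in params:
        low, high = owsa_bounds(p)
        icer_lo, nmb_lo = _eval({**base_values, p.name: low}, "low", p.name)
        icer_hi, nmb_hi = _eval({**base_values, p.name: high}, "high", p.name)
        out_lo = icer_lo if metric == "icer" else nmb_lo
        out_hi = icer_hi if metric == "icer" else nmb_hi
        vals = [v for v in (out_lo, out_hi) if v is not None and np.isfinite(v)]
        width = (max(vals) - min(vals)) if len(vals) == 2 else (
            np.nan if not vals else 0.0)
        rows.append({
            "parameter": p.name, "base": p.base, "low": low, "high": high,
            "icer_low": icer_lo, "icer_high": icer_hi,
            "nmb_low": nmb_lo, "nmb_high": nmb_hi,
            "range": width,
        })
    df = pd.DataFrame(rows)
    df["base_output"] = base_out
    df = df.sort_values("range", ascending=False, na_position="last",
                        kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class PsaDraws:
    """Monte Carlo parameter draws and the per-draw model outputs."""

    params: pd.DataFrame  # one column per parameter, one row per draw
    results: pd.DataFrame  # delta_cost, delta_qaly, costs/qalys per arm
    seed: int
    n_resampled: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.results)


def run_psa(
    params: Sequence[ParamSpec],
    model: Callable[[Mapping[str, float]], CEResult],
    n_draws: int = 1_000,
    seed: int = 0,
    max_retries: int = 100,
) -> PsaDraws:
    """Propagate parameter uncertainty through the model by Monte Carlo.

    Draws are independent across parameters and across iterations and fully
    reproducible under ``seed``.  A draw on which the model raises is
    resampled (up to ``max_retries`` per draw, counted and logged).
    """
    if n_draws < 1:
        raise ConfigError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    records, outputs = [], []
    n_resampled = 0
    for _ in range(n_draws):
        for attempt in range(max_retries + 1):
            values = {p.name: float(sample_param(p, rng)) for p in params}
            try:
                res = model(values)
                break
            except Exception:
                n_resampled += 1
                if attempt == max_retries:
                    raise
        records.append(values)
        outputs.append({
            "cost_ref": res.cost_ref, "qaly_ref": res.qaly_ref,
            "cost_comp": res.cost_comp, "qaly_comp": res.qaly_comp,
            "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
        })
    if n_resampled:
        logger.info("PSA resampled %d infeasible draws", n_resampled)
    return PsaDraws(
        params=pd.DataFrame(records),
        results=pd.DataFrame(outputs),
        seed=seed,
        n_resampled=n_resampled,
    )


def ceac(draws: PsaDraws, wtp_grid: Sequence[float] = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each threshold lambda, the probability of cost-effectiveness is the
    fraction of draws with lambda * dQALY - dCost > 0 (strict; ties count
    as not cost-effective).
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ConfigError("wtp_grid must be non-empty")
    if draws.n_draws < 1:
        raise ConfigError("need at least one PSA draw")
    dq = draws.results["delta_qaly"].to_numpy()
    dc = draws.results["delta_cost"].to_numpy()
    nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})
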