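"""Trial-level meta-analysis of mean differences in serum-creatinine change.

Per-study effects are unadjusted mean differences between arms (umol/L) with
the usual two-sample standard error.  Pooling is inverse-variance, either
fixed-effect or DerSimonian-Laird random-effects; heterogeneity is
quantified by Cochran's Q, I^2 and the DL moment estimator of the
between-study variance tau^2.  Model selection can be automatic, mirroring
common systematic-review practice: random effects whenever the Q-test
p-value is at or below 0.10 or I^2 is at or above 25%, fixed effect
otherwise (ties resolved conservatively toward random effects).

Meta-regression is univariable weighted least squares of study effects on
one covariate, with weights 1/(se^2 + tau^2) and a normal-approximation
p-value for the slope.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateDesignError,
    InsufficientStudiesError,
    InvalidTrialError,
)

__all__ = [
    "TrialRecord",
    "EffectEstimate",
    "PooledResult",
    "MetaRegressionResult",
    "HeterogeneityStats",
    "study_effect",
    "heterogeneity",
    "pool",
    "meta_regress",
    "EffectPooler",
    "read_trials_csv",
    "trials_to_frame",
    "forest_table",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal 95% CI multiplier

#: covariates the trial CSV carries for meta-regression
COVARIATE_NAMES = (
    "sample_size",
    "mean_age",
    "male_prop",
    "dis_duration",
    "trt_duration",
)

CSV_COLUMNS = (
    "study_id",
    "n_trt",
    "mean_trt",
    "sd_trt",
    "n_ctl",
    "mean_ctl",
    "sd_ctl",
) + COVARIATE_NAMES


@dataclass(frozen=True)
class TrialRecord:
    """Per-arm summaries of one randomized trial.

    Means and SDs are serum-creatinine change in umol/L; ``covariates``
    holds trial-level moderators (sample_size, mean_age in years,
    male_prop in [0,1], dis_duration in years, trt_duration in weeks).
    """

    study_id: str
    n_trt: int
    mean_trt: float
    sd_trt: float
    n_ctl: int
    mean_ctl: float
    sd_ctl: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trt < 2 or self.n_ctl < 2:
            raise InvalidTrialError(
                f"{self.study_id}: each arm needs n >= 2 "
                f"(got {self.n_trt}/{self.n_ctl})"
            )
        if not (self.sd_trt > 0 and self.sd_ctl > 0):
            raise InvalidTrialError(
                f"{self.study_id}: SDs must be strictly positive"
            )
        for v in (self.mean_trt, self.mean_ctl, self.sd_trt, self.sd_ctl):
            if not math.isfinite(v):
                raise InvalidTrialError(f"{self.study_id}: non-finite summary")
        for name, v in self.covariates.items():
            if v is not None and not math.isfinite(v):
                raise InvalidTrialError(
                    f"{self.study_id}: covariate {name!r} not finite"
                )


@dataclass(frozen=True)
class EffectEstimate:
    """A study-level mean difference (umol/L) with its 95% CI."""

    md: float
    se: float
    ci_low: float = None  # type: ignore[assignment]
    ci_high: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.se > 0 and math.isfinite(self.se)):
            raise InvalidTrialError(f"se must be > 0, got {self.se}")
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.md - Z_95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.md + Z_95 * self.se)
        if not (self.ci_low <= self.md <= self.ci_high):
            raise InvalidTrialError("CI must bracket the point estimate")

    @classmethod
    def from_ci(cls, md: float, ci_low: float, ci_high: float) -> "EffectEstimate":
        """Back-compute the SE from a reported 95% CI (normal approximation)."""
        se = (ci_high - ci_low) / (2.0 * Z_95)
        return cls(md=md, se=se, ci_low=ci_low, ci_high=ci_high)


@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class PooledResult:
    model: str  # "fixed" | "random"
    md: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float
    k: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class MetaRegressionResult:
    covariate: str
    slope: float
    se_slope: float
    p_value: float
    intercept: float
    k: int

    def to_dict(self) -> dict:
        return asdict(self)


def study_effect(trial: TrialRecord) -> EffectEstimate:
    """Mean difference (treatment minus control) and its standard error."""
    md = trial.mean_trt - trial.mean_ctl
    se = math.sqrt(
        trial.sd_trt**2 / trial.n_trt + trial.sd_ctl**2 / trial.n_ctl
    )
    return EffectEstimate(md=md, se=se)


def _fixed_weights(effects: Sequence[EffectEstimate]) -> np.ndarray:
    return np.array([1.0 / e.se**2 for e in effects])


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityStats:
    """Cochran's Q, I^2 and the DerSimonian-Laird tau^2.

    Q = sum w_i (md_i - md_fixed)^2 with w_i = 1/se_i^2;
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w));
    I^2 = max(0, (Q - df) / Q).
    """
    effects = list(effects)
    if len(effects) < 2:
        raise InsufficientStudiesError("heterogeneity requires >= 2 studies")
    w = _fixed_weights(effects)
    md = np.array([e.md for e in effects])
    pooled = float(np.sum(w * md) / np.sum(w))
    q = float(np.sum(w * (md - pooled) ** 2))
    df = len(effects) - 1
    p_q = float(stats.chi2.sf(q, df))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityStats(Q=q, df=df, p_Q=p_q, I2=i2, tau2=tau2)


def _select_model(het: HeterogeneityStats) -> str:
    # random effects if p <= 0.10 or I^2 >= 25% (boundary ties -> random)
    return "random" if (het.p_Q <= 0.10 or het.I2 >= 0.25) else "fixed"


def pool(
    effects: Sequence[EffectEstimate],
    rule: str = "auto",
) -> PooledResult:
    """Inverse-variance pooling with fixed/random/auto model selection.

    ``rule="auto"`` applies the heterogeneity-driven rule documented in the
    module docstring.  A single study is returned unchanged as a fixed-effect
    "pool".
    """
    effects = list(effects)
    if not effects:
        raise InsufficientStudiesError("pool requires >= 1 study")
    if rule not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(effects) == 1:
        e = effects[0]
        return PooledResult(
            model="fixed", md=e.md, se=e.se, ci_low=e.ci_low, ci_high=e.ci_high,
            Q=0.0, df=0, p_Q=1.0, I2=0.0, tau2=0.0, k=1,
        )
    het = heterogeneity(effects)
    model = _select_model(het) if rule == "auto" else rule
    if rule == "auto":
        logger.info(
            "model selection: %s (I2=%.3f, p_Q=%.4g, Q=%.3f, df=%d)",
            model, het.I2, het.p_Q, het.Q, het.df,
        )
    tau2 = het.tau2 if model == "random" else 0.0
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    md = np.array([e.md for e in effects])
    pooled = float(np.sum(w * md) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return PooledResult(
        model=model,
        md=pooled,
        se=se,
        ci_low=pooled - Z_95 * se,
        ci_high=pooled + Z_95 * se,
        Q=het.Q,
        df=het.df,
        p_Q=het.p_Q,
        I2=het.I2,
        tau2=het.tau2,
        k=len(effects),
    )


def meta_regress(
    trials: Sequence[TrialRecord],
    covariate: str,
) -> MetaRegressionResult:
    """Univariable random-effects meta-regression.

    Weighted least squares of study mean differences on one trial-level
    covariate with weights 1/(se^2 + tau^2_DL); the slope p-value uses the
    normal approximation.
    """
    trials = list(trials)
    if len(trials) < 3:
        raise InsufficientStudiesError("meta-regression requires >= 3 trials")
    x = []
    for t in trials:
        if covariate not in t.covariates or t.covariates[covariate] is None:
            raise DegenerateDesignError(
                f"covariate {covariate!r} missing in {t.study_id}"
            )
        x.append(float(t.covariates[covariate]))
    x = np.array(x)
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"covariate {covariate!r} is constant")
    effects = [study_effect(t) for t in trials]
    tau2 = heterogeneity(effects).tau2
    y = np.array([e.md for e in effects])
    w = np.array([1.0 / (e.se**2 + tau2) for e in effects])
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    slope = float(fit.params[1])
    se_slope = float(fit.bse[1])
    z = slope / se_slope
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaRegressionResult(
        covariate=covariate,
        slope=slope,
        se_slope=se_slope,
        p_value=p,
        intercept=float(fit.params[0]),
        k=len(trials),
    )


class EffectPooler(BaseEstimator):
    """Meta-analytic pooling as a fit-shaped estimator.

    Parameters
    ----------
    rule : {"auto", "fixed", "random"}
        Pooling-model selection rule (see :func:`pool`).

    Attributes (after ``fit``)
    --------------------------
    effects_ : list of EffectEstimate
    result_ : PooledResult
    md_, se_, tau2_, i2_, q_, p_q_ : floats
    model_ : str
    """

    def __init__(self, rule: str = "auto"):
        self.rule = rule

    def fit(self, trials: Iterable[TrialRecord], y=None) -> "EffectPooler":
        trials = list(trials)
        self.effects_ = [study_effect(t) for t in trials]
        self.result_ = pool(self.effects_, rule=self.rule)
        self.md_ = self.result_.md
        self.se_ = self.result_.se
        self.tau2_ = self.result_.tau2
        self.i2_ = self.result_.I2
        self.q_ = self.result_.Q
        self.p_q_ = self.result_.p_Q
        self.model_ = self.result_.model
        return self

    def regress(self, trials: Sequence[TrialRecord],
                covariates: Optional[Sequence[str]] = None) -> dict:
        """Univariable meta-regression for each named covariate."""
        names = covariates if covariates is not None else COVARIATE_NAMES
        return {c: meta_regress(trials, c) for c in names}


def read_trials_csv(path) -> list:
    """Load trial records from the canonical CSV layout.

    Expected header: ``study_id,n_trt,mean_trt,sd_trt,n_ctl,mean_ctl,sd_ctl,
    sample_size,mean_age,male_prop,dis_duration,trt_duration`` (UTF-8,
    "." decimal separator).
    """
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise InvalidTrialError(f"trial CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cov = {
            c: (float(row[c]) if c in df.columns and pd.notna(row[c]) else None)
            for c in COVARIATE_NAMES
        }
        records.append(
            TrialRecord(
                study_id=str(row["study_id"]),
                n_trt=int(row["n_trt"]),
                mean_trt=float(row["mean_trt"]),
                sd_trt=float(row["sd_trt"]),
                n_ctl=int(row["n_ctl"]),
                mean_ctl=float(row["mean_ctl"]),
                sd_ctl=float(row["sd_ctl"]),
                covariates=cov,
            )
        )
    return records


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        row = {
            "study_id": t.study_id,
            "n_trt": t.n_trt, "mean_trt": t.mean_trt, "sd_trt": t.sd_trt,
            "n_ctl": t.n_ctl, "mean_ctl": t.mean_ctl, "sd_ctl": t.sd_ctl,
        }
        for c in COVARIATE_NAMES:
            row[c] = t.covariates.get(c)
        rows.append(row)
    return pd.DataFrame(rows)


def forest_table(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-study effect table suitable for a forest plot (CSV export)."""
    rows = []
    for t in trials:
        e = study_effect(t)
        rows.append({
            "study_id": t.study_id, "md": e.md, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "n_total": t.n_trt + t.n_ctl,
        })
    return pd.DataFrame(rows)
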