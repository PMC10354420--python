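"""MDRD eGFR equation (Chinese-population variant), its inverse, and CKD staging.

The estimated glomerular filtration rate follows the Modification of Diet in
Renal Disease (MDRD) study equation,

    eGFR = 186 * Scr^-1.154 * age^-0.203 * 0.742[female] * 1.233[Chinese],

with serum creatinine (Scr) in mg/dL and eGFR in mL/min/1.73 m^2.  This
package stores creatinine in umol/L everywhere (the unit of the trial
outcomes) and converts by /88.4 inside the equation, so a single internal
unit prevents silent double conversion.

CKD stages follow the KDIGO eGFR bands: stage 3 is 30-59, stage 4 is 15-29
and stage 5 (end-stage renal disease) is < 15 mL/min/1.73 m^2.  Bands are
half-open with the lower bound inclusive.  eGFR >= 60 is above the modelled
disease range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import ConfigError

__all__ = [
    "UMOL_PER_MGDL",
    "PatientProfile",
    "StagingRule",
    "DEFAULT_STAGING",
    "mdrd_egfr",
    "invert_mdrd",
    "stage_of",
    "STAGE_ABOVE",
]

#: unit bridge between umol/L (internal) and mg/dL (equation's native unit)
UMOL_PER_MGDL = 88.4

_SCR_EXP = -1.154
_AGE_EXP = -0.203
_FEMALE_FACTOR = 0.742
_CHINESE_FACTOR = 1.233

ArrayLike = Union[float, np.ndarray]

#: label returned for eGFR at or above the top staging threshold
STAGE_ABOVE = "above_stage3"


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient.

    Parameters
    ----------
    age : float
        Years; the adult MDRD equation requires age >= 18.
    female : bool
        Sex indicator entering the 0.742 multiplier.
    scr : float
        Serum creatinine, umol/L, strictly positive.
    gfr_decline : float
        Annual loss of eGFR, mL/min/1.73 m^2 per year, non-negative.
    """

    age: float
    female: bool
    scr: float
    gfr_decline: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 18:
            raise ConfigError(f"age must be finite and >= 18, got {self.age}")
        if not np.isfinite(self.scr) or self.scr <= 0:
            raise ConfigError(f"scr must be finite and > 0, got {self.scr}")
        if not np.isfinite(self.gfr_decline) or self.gfr_decline < 0:
            raise ConfigError(
                f"gfr_decline must be finite and >= 0, got {self.gfr_decline}"
            )

    def egfr(self, chinese: bool = True) -> float:
        return float(mdrd_egfr(self.scr, self.age, self.female, chinese=chinese))


@dataclass(frozen=True)
class StagingRule:
    """Ordered eGFR thresholds delimiting CKD stages 3, 4 and 5.

    ``thresholds = (t3, t4, t5)`` means stage 3 is [t4, t3), stage 4 is
    [t5, t4) and stage 5 is [0, t5); eGFR >= t3 is above the model.
    """

    thresholds: tuple = field(default=(60.0, 30.0, 15.0))
    labels: tuple = field(default=("ckd3", "ckd4", "ckd5"))

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if len(t) != 3 or not (t[0] > t[1] > t[2] > 0):
            raise ConfigError(f"thresholds must be strictly decreasing > 0, got {t}")
        object.__setattr__(self, "thresholds", t)

    def stage_of(self, egfr: float) -> str:
        t3, t4, t5 = self.thresholds
        if egfr >= t3:
            return STAGE_ABOVE
        if egfr >= t4:
            return self.labels[0]
        if egfr >= t5:
            return self.labels[1]
        return self.labels[2]

    def to_dict(self) -> dict:
        return {"thresholds": list(self.thresholds), "labels": list(self.labels)}

    @classmethod
    def from_dict(cls, d: dict) -> "StagingRule":
        return cls(
            thresholds=tuple(d.get("thresholds", (60.0, 30.0, 15.0))),
            labels=tuple(d.get("labels", ("ckd3", "ckd4", "ckd5"))),
        )


DEFAULT_STAGING = StagingRule()


def mdrd_egfr(
    scr: ArrayLike,
    age: ArrayLike,
    female: ArrayLike,
    chinese: bool = True,
) -> ArrayLike:
    """Evaluate the MDRD equation.

    Parameters
    ----------
    scr : float or array
        Serum creatinine in umol/L (> 0); converted to mg/dL internally.
    age : float or array
        Years (> 0).
    female : bool or array
        Applies the 0.742 factor where true.
    chinese : bool
        Applies the 1.233 Chinese-population coefficient (default on).

    Returns
    -------
    eGFR in mL/min/1.73 m^2, same shape as the broadcast inputs.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ConfigError("scr and age must be strictly positive")
    scr_mgdl = scr / UMOL_PER_MGDL
    out = 186.0 * scr_mgdl**_SCR_EXP * age**_AGE_EXP
    out = np.where(np.asarray(female, dtype=bool), out * _FEMALE_FACTOR, out)
    if chinese:
        out = out * _CHINESE_FACTOR
    return out if out.ndim else float(out)


def invert_mdrd(
    egfr: ArrayLike,
    age: ArrayLike,
    female: ArrayLike,
    chinese: bool = True,
) -> ArrayLike:
    """Serum creatinine (umol/L) yielding a given eGFR.

    Algebraic inverse of :func:`mdrd_egfr`; round-trips to ~1e-9 relative.
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(egfr <= 0) or np.any(age <= 0):
        raise ConfigError("egfr and age must be strictly positive")
    coef = 186.0 * age**_AGE_EXP
    coef = np.where(np.asarray(female, dtype=bool), coef * _FEMALE_FACTOR, coef)
    if chinese:
        coef = coef * _CHINESE_FACTOR
    scr_mgdl = (egfr / coef) ** (1.0 / _SCR_EXP)
    out = scr_mgdl * UMOL_PER_MGDL
    return out if out.ndim else float(out)


def stage_of(egfr: float, rule: StagingRule = DEFAULT_STAGING) -> str:
    """Map a single eGFR value to its CKD stage label under ``rule``."""
    if egfr < 0:
        raise ConfigError(f"egfr must be >= 0, got {egfr}")
    return rule.stage_of(float(egfr))
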