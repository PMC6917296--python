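"""Pure and absolute interval risks for individual women.

A :class:`WomanRiskProfile` carries per-year cause-specific disease and
mortality hazards over a prediction horizon (typically 5 years from a
woman's enrollment age).  The disease hazard may come from any provenance —
a Cox linear predictor applied to a baseline table, or the family multiplier
f(p_hat) applied to the population hazard.

Pure risk ignores competing mortality (1 - exp(-sum h1)); absolute risk is
the cause-specific cumulative incidence, computed with the exact
piecewise-constant within-year algebra (Gail-style lifetable practice):
each year contributes S(t) * h1/(h1+h2) * (1 - exp(-(h1+h2))), never the
cruder h1 * S approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hazard import HazardTable, _cumulative_incidence

__all__ = [
    "WomanRiskProfile",
    "pure_interval_risk",
    "absolute_interval_risk",
    "profile_from_tables",
    "risks_to_frame",
]


class RiskError(ValueError):
    pass


@dataclass(frozen=True)
class WomanRiskProfile:
    """Per-year hazards for one woman over her prediction horizon.

    ``disease_hazard[k]`` and ``mortality_hazard[k]`` apply on year k of
    follow-up, i.e. ages [age_at_start + k, age_at_start + k + 1).
    """

    id: str
    age_at_start: float
    disease_hazard: np.ndarray
    mortality_hazard: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.disease_hazard, dtype=float)
        m = np.asarray(self.mortality_hazard, dtype=float)
        if d.shape != m.shape or d.ndim != 1:
            raise RiskError("hazard vectors must be 1-D and equal length")
        if np.any(~np.isfinite(d)) or np.any(~np.isfinite(m)):
            raise RiskError("non-finite hazard entries")
        if np.any(d < 0) or np.any(m < 0):
            raise RiskError("negative hazard entries")
        object.__setattr__(self, "disease_hazard", d)
        object.__setattr__(self, "mortality_hazard", m)

    @property
    def span(self) -> int:
        return self.disease_hazard.size


def _check_span(profile: WomanRiskProfile, years: float) -> None:
    if years < 0 or years > profile.span:
        raise RiskError(
            f"horizon {years} exceeds available span {profile.span}"
        )


def pure_interval_risk(profile: WomanRiskProfile, years: float) -> float:
    """Competing-risk-free risk over ``years``: 1 - exp(-integrated hazard)."""
    _check_span(profile, years)
    whole = int(np.floor(years))
    frac = years - whole
    lam = profile.disease_hazard[:whole].sum()
    if frac > 0:
        lam += frac * profile.disease_hazard[whole]
    return float(-np.expm1(-lam))


def absolute_interval_risk(profile: WomanRiskProfile, years: float) -> float:
    """Cumulative incidence over ``years`` under competing mortality.

    Equals the pure risk when mortality is zero and never exceeds it.
    """
    _check_span(profile, years)
    return _cumulative_incidence(
        profile.disease_hazard, profile.mortality_hazard, float(years)
    )


def profile_from_tables(
    id: str,
    age_at_start: float,
    disease: HazardTable,
    mortality: HazardTable,
    years: int,
    log_hazard_ratio: float = 0.0,
) -> WomanRiskProfile:
    """Build a profile from baseline tables and a log hazard ratio.

    The disease hazard over the horizon is the baseline rate at each attained
    age multiplied by exp(log_hazard_ratio); ages are truncated to integer
    years (table resolution).
    """
    a0 = int(np.floor(age_at_start))
    if a0 + years > disease.span or a0 + years > mortality.span:
        raise RiskError(
            f"age {age_at_start} + horizon {years} exceeds table span"
        )
    hr = float(np.exp(log_hazard_ratio))
    return WomanRiskProfile(
        id=id,
        age_at_start=age_at_start,
        disease_hazard=disease.rates[a0 : a0 + years] * hr,
        mortality_hazard=mortality.rates[a0 : a0 + years].copy(),
    )


def risks_to_frame(profiles, years: float) -> pd.DataFrame:
    """Tabulate ``id,pure_risk,absolute_risk`` over a common horizon."""
    rows = [
        {
            "id": p.id,
            "pure_risk": pure_interval_risk(p, years),
            "absolute_risk": absolute_interval_risk(p, years),
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["id", "pure_risk", "absolute_risk"])
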