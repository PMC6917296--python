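"""Age-specific one-year hazard tables.

A :class:`HazardTable` holds per-year rates lambda(t) on consecutive integer
ages 0..A_max, treated as piecewise-constant over [age, age+1).  It supports
cumulative hazard, lifetime *pure* risk (the competing-risk-free risk
1 - exp(-Lambda)), lifetime *absolute* risk (cumulative incidence under a
competing mortality table), and LOESS smoothing of noisy raw rates.

Tables are read from/written to delimited text with header ``age,rate``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "HazardTable",
    "read_hazard_table",
    "constant_hazard_table",
    "toy_disease_hazard",
    "toy_mortality_hazard",
    "loess_smooth",
]

#: Default lifetime horizon in years (conventional SEER-style lifetime bound).
DEFAULT_HORIZON = 90

#: Population lifetime pure risk of breast cancer (invasive + in situ) used to
#: calibrate the bundled toy tables and as the default prior mean anchor.
DEFAULT_P0 = 0.197


class HazardTableError(ValueError):
    """Raised for malformed hazard tables or out-of-span evaluation."""


@dataclass(frozen=True)
class HazardTable:
    """One-year hazard rates on consecutive integer ages starting at 0.

    Parameters
    ----------
    ages
        Consecutive integers 0..A_max.
    rates
        Non-negative per-year hazards, one per age; the rate at age ``a``
        applies on the half-open interval [a, a+1).
    kind
        Cause label, e.g. ``"disease"`` or ``"mortality"``.
    """

    ages: np.ndarray
    rates: np.ndarray
    kind: str = "disease"
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.ndim != 1 or rates.shape != ages.shape:
            raise HazardTableError("ages and rates must be 1-D and equal length")
        if ages.size == 0:
            raise HazardTableError("empty hazard table")
        if not np.array_equal(ages, np.arange(ages.size)):
            raise HazardTableError("non-consecutive ages: expected 0..A_max")
        if not np.all(np.isfinite(rates)):
            raise HazardTableError("non-finite rate entries")
        if np.any(rates < 0):
            bad = int(np.argmax(rates < 0))
            raise HazardTableError(f"negative rate at age {bad}")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        # cum[a] = Lambda(a) at integer ages 0..A_max+1
        object.__setattr__(
            self, "_cum", np.concatenate([[0.0], np.cumsum(rates)])
        )

    @property
    def a_max(self) -> int:
        return int(self.ages[-1])

    @property
    def span(self) -> float:
        """Largest age at which the table can be evaluated (A_max + 1)."""
        return float(self.a_max + 1)

    def cumulative_hazard(self, x: float) -> float:
        """Integrated hazard Lambda(x) = int_0^x lambda(t) dt.

        ``x`` may be fractional; rates are piecewise-constant per year.
        Raises for x outside [0, A_max+1] — no extrapolation, because hazard
        tails dominate lifetime risk and silent continuation would hide that.
        """
        x = float(x)
        if not 0.0 <= x <= self.span:
            raise HazardTableError(
                f"age {x} outside table span [0, {self.span}]"
            )
        whole = int(np.floor(x))
        frac = x - whole
        if whole == self.span:  # x == A_max + 1 exactly
            return float(self._cum[-1])
        return float(self._cum[whole] + frac * self.rates[whole])

    def cumulative_hazard_grid(self) -> np.ndarray:
        """Lambda at integer ages 0..A_max+1 (read-only view)."""
        return self._cum

    def lifetime_pure_risk(self, horizon: float = DEFAULT_HORIZON) -> float:
        """Pure (competing-risk-free) risk by ``horizon``: 1 - exp(-Lambda)."""
        return float(-np.expm1(-self.cumulative_hazard(horizon)))

    def lifetime_absolute_risk(
        self, mortality: "HazardTable", horizon: float = DEFAULT_HORIZON
    ) -> float:
        """Cumulative incidence by ``horizon`` under competing mortality.

        Exact under piecewise-constant hazards: each year t contributes
        S(t) * h1/(h1+h2) * (1 - exp(-(h1+h2))) with S the all-cause survivor
        to the start of the year.  Always <= the pure risk, with equality iff
        mortality is zero before the horizon.
        """
        if mortality.a_max != self.a_max:
            raise HazardTableError(
                "disease and mortality tables must share the age grid"
            )
        horizon = float(horizon)
        if not 0.0 <= horizon <= self.span:
            raise HazardTableError(
                f"horizon {horizon} outside table span [0, {self.span}]"
            )
        return _cumulative_incidence(self.rates, mortality.rates, horizon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "rate": self.rates})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cumulative_incidence(
    h1: np.ndarray, h2: np.ndarray, horizon: float
) -> float:
    """Discrete-year cause-1 cumulative incidence, fractional final year."""
    whole = int(np.floor(horizon))
    frac = horizon - whole
    total = 0.0
    log_surv = 0.0
    for t in range(whole + (1 if frac > 0 else 0)):
        width = frac if (t == whole) else 1.0
        a, b = h1[t], h2[t]
        tot = a + b
        if tot > 0:
            total += np.exp(log_surv) * (a / tot) * -np.expm1(-tot * width)
        log_surv -= tot * width
    return float(total)


def read_hazard_table(path, kind: str = "disease", fill_gaps: bool = False) -> HazardTable:
    """Read a delimited-text table with columns ``age`` and ``rate``.

    Rows are normalised by age.  Leading or internal missing ages are filled
    with rate 0 only when ``fill_gaps`` is set; otherwise non-consecutive ages
    are an error.  Duplicate ages, negative rates and non-numeric entries
    raise :class:`HazardTableError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = {"age", "rate"} - set(df.columns)
    if missing:
        raise HazardTableError(f"missing required columns: {sorted(missing)}")
    for col in ("age", "rate"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise HazardTableError(f"non-numeric {col!r} entry at row {row}")
        df[col] = coerced
    ages_f = df["age"].to_numpy(dtype=float)
    if np.any(ages_f != np.round(ages_f)):
        row = int(np.argmax(ages_f != np.round(ages_f)))
        raise HazardTableError(f"non-integer age at row {row}")
    df = df.assign(age=df["age"].astype(int)).sort_values("age")
    ages = df["age"].to_numpy()
    rates = df["rate"].to_numpy(dtype=float)
    dup = pd.Index(ages).duplicated()
    if dup.any():
        raise HazardTableError(f"duplicate age {ages[dup][0]}")
    neg = rates < 0
    if neg.any():
        raise HazardTableError(f"negative rate at age {ages[neg][0]}")
    if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)) or ages.min() != 0:
        if not fill_gaps:
            raise HazardTableError(
                "non-consecutive ages (set fill_gaps=True to pad with 0)"
            )
        full = np.zeros(int(ages.max()) + 1)
        full[ages] = rates
        ages, rates = np.arange(full.size), full
    return HazardTable(ages=ages, rates=rates, kind=kind)


def constant_hazard_table(
    rate: float, a_max: int = DEFAULT_HORIZON - 1, kind: str = "disease"
) -> HazardTable:
    """Table with the same per-year rate at every age 0..a_max."""
    return HazardTable(
        ages=np.arange(a_max + 1), rates=np.full(a_max + 1, float(rate)), kind=kind
    )


def toy_disease_hazard(
    p0: float = DEFAULT_P0, horizon: int = DEFAULT_HORIZON
) -> HazardTable:
    """Synthetic SEER-like breast-cancer hazard table (a built fixture, not
    registry data): zero hazard before age 20, then linearly increasing rates
    scaled so that the lifetime pure risk at ``horizon`` equals ``p0``.
    """
    ages = np.arange(horizon)
    shape = np.where(ages >= 20, ages - 19, 0).astype(float)
    target = -np.log1p(-p0)  # Lambda(horizon) giving pure risk p0
    rates = shape * (target / shape.sum())
    return HazardTable(ages=ages, rates=rates, kind="disease")


def toy_mortality_hazard(horizon: int = DEFAULT_HORIZON) -> HazardTable:
    """Synthetic Gompertz-like all-cause female mortality table (fixture):
    exponentially increasing rates, roughly 3e-4/yr at age 30 and 5%/yr at 85.
    """
    ages = np.arange(horizon)
    rates = 2.0e-5 * np.exp(0.088 * ages)
    return HazardTable(ages=ages, rates=rates, kind="mortality")


def loess_smooth(
    raw_rates, span: float = 0.5, kind: str = "disease"
) -> HazardTable:
    """LOESS-smooth noisy age-indexed rates into a valid hazard table.

    Degree-1 local regression with tricube weights, no robustness iterations
    (the common defaults).  Negative fitted values are clamped to 0.

    ``raw_rates`` is a sequence of per-year rates indexed by age 0..A_max,
    or a mapping/Series with an integer age index.
    """
    if isinstance(raw_rates, (pd.Series, dict)):
        s = pd.Series(raw_rates).sort_index()
        ages = s.index.to_numpy(dtype=int)
        vals = s.to_numpy(dtype=float)
        if not np.array_equal(ages, np.arange(ages.size)):
            raise HazardTableError("raw rates must cover consecutive ages from 0")
    else:
        vals = np.asarray(raw_rates, dtype=float)
        ages = np.arange(vals.size)
    if vals.size < 5:
        raise HazardTableError("need at least 5 points for LOESS smoothing")
    if not 0 < span <= 1:
        raise HazardTableError("span must be in (0, 1]")
    fitted = lowess(
        vals, ages.astype(float), frac=span, it=0, return_sorted=False
    )
    return HazardTable(ages=ages, rates=np.clip(fitted, 0.0, None), kind=kind)
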