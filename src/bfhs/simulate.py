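"""Synthetic family-cohort generator under the score's own model.

Each family draws its lifetime pure risk p from the Beta prior; relatives'
breast-cancer onset ages then follow the family hazard
lambda_p(t) = f(p) lambda_0(t) by inverse-transform sampling of the
piecewise-constant cumulative hazard, with independent competing death from
a mortality table and censoring at the relative's attained age.  Index women
enrol cancer-free at ages 35-74 and are followed for 5-year outcomes.

The cohort emulates the shape of a Sister-Study-like population — families
with 0-16 first-degree female relatives (mean about 3.9), multi-year
follow-up, a small loss-to-follow-up fraction — but every structural
distribution (family size, relatives' attained ages, the mother's age
offset) is a stand-in: the real joint distribution of family structure is
unknown.  What the simulator guarantees is internal model consistency, which
is what makes posterior-mean calibration (E[p | data] = BFHS) testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hazard import HazardTable, toy_disease_hazard, toy_mortality_hazard
from .prior import BetaPrior, PRINTED_ALPHA, PRINTED_BETA
from .score import (
    Family,
    RelativeRecord,
    bfhs,
    family_hazard_multiplier,
    three_level_score,
)
from .absolute_risk import WomanRiskProfile, absolute_interval_risk

__all__ = ["SimConfig", "SimulatedFamily", "draw_family", "simulate_cohort"]

FAMILY_SIZE_MAX = 16
FAMILY_SIZE_MEAN = 3.9
OUTCOME_HORIZON = 5.0


def _family_size_probs(mean: float = FAMILY_SIZE_MEAN) -> np.ndarray:
    """Poisson(mean) truncated to 0..16 and renormalised; keeps the mean at
    about 3.9 with range 0-16."""
    k = np.arange(FAMILY_SIZE_MAX + 1)
    probs = stats.poisson.pmf(k, mean)
    return probs / probs.sum()


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults: Beta(1.184, 4.828) prior anchored at p0 = 0.197, the bundled
    synthetic SEER-like disease hazard and Gompertz-like mortality, family
    sizes 0-16 with mean about 3.9, relatives' attained ages uniform on
    30-85 (the mother, when present, attains index age + 25), enrollment
    ages uniform on 35-74, administrative follow-up uniform on 5-10 years
    with a 2.3% loss-to-follow-up fraction censored uniformly within the
    5-year outcome window.
    """

    n_families: int = 1000
    prior: BetaPrior = field(default_factory=lambda: BetaPrior(PRINTED_ALPHA, PRINTED_BETA))
    p0: float = 0.197
    disease_hazard: HazardTable = field(default_factory=toy_disease_hazard)
    mortality: HazardTable = field(default_factory=toy_mortality_hazard)
    family_size_probs: np.ndarray = field(default_factory=_family_size_probs)
    relative_age_range: tuple[float, float] = (30.0, 85.0)
    index_age_range: tuple[float, float] = (35.0, 74.0)
    followup_range: tuple[float, float] = (5.0, 10.0)
    ltfu_rate: float = 0.023
    mother_offset: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.family_size_probs, dtype=float)
        if probs.size != FAMILY_SIZE_MAX + 1 or np.any(probs < 0):
            raise ValueError("family_size_probs must be 17 non-negative values")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("family_size_probs must sum to 1")
        object.__setattr__(self, "family_size_probs", probs)
        if not 0 <= self.ltfu_rate < 1:
            raise ValueError("ltfu_rate must lie in [0, 1)")
        if self.n_families < 0:
            raise ValueError("n_families must be non-negative")


@dataclass(frozen=True)
class SimulatedFamily:
    """One simulated family: latent truth plus observable records."""

    id: str
    true_p: float
    relatives: tuple[RelativeRecord, ...]
    index_age: float
    index_event5: int
    index_died5: int
    index_followup: float
    index_weight: float

    @property
    def family(self) -> Family:
        return Family(id=self.id, relatives=self.relatives)


def _invert_cumhaz(table: HazardTable, target: float) -> float:
    """Smallest age T with Lambda(T) = target; inf if beyond the table."""
    cum = table.cumulative_hazard_grid()
    if target >= cum[-1]:
        return np.inf
    t = int(np.searchsorted(cum, target, side="right")) - 1
    rate = table.rates[t]
    return t + ((target - cum[t]) / rate if rate > 0 else 0.0)


def _onset_age(
    table: HazardTable, multiplier: float, rng, from_age: float = 0.0
) -> float:
    """Inverse-transform onset age under multiplier * lambda_0, conditional
    on being event-free at ``from_age``."""
    u = rng.random()
    target = table.cumulative_hazard(from_age) - np.log(u) / multiplier
    return _invert_cumhaz(table, target)


def draw_family(config: SimConfig, rng: np.random.Generator, id: str = "f0") -> SimulatedFamily:
    """Draw one family: p from the prior, relatives' (X_i, d_i) from
    lambda_p with death and attained-age censoring independent of p, and the
    index woman's cancer-free enrollment and 5-year outcome.
    """
    p = float(rng.beta(config.prior.alpha, config.prior.beta))
    # guard against degenerate draws at the floating-point boundary
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    f = family_hazard_multiplier(p, config.p0)

    index_age = float(rng.uniform(*config.index_age_range))
    n_rel = int(rng.choice(FAMILY_SIZE_MAX + 1, p=config.family_size_probs))
    span = config.disease_hazard.span

    relatives = []
    for i in range(n_rel):
        if i == 0:  # the mother, offset from the index woman
            attained = min(index_age + config.mother_offset, span)
            relation = "mother"
        else:
            attained = float(rng.uniform(*config.relative_age_range))
            relation = "sister"
        onset = _onset_age(config.disease_hazard, f, rng)
        death = _onset_age(config.mortality, 1.0, rng)
        x = min(onset, death, attained)
        d = int(onset <= min(death, attained))
        relatives.append(RelativeRecord(x=min(x, span), d=d, relation=relation))

    # index woman: cancer-free and alive at enrollment by construction
    t_event = _onset_age(config.disease_hazard, f, rng, from_age=index_age) - index_age
    t_death = _onset_age(config.mortality, 1.0, rng, from_age=index_age) - index_age
    if rng.random() < config.ltfu_rate:
        censor = float(rng.uniform(0.0, OUTCOME_HORIZON))
    else:
        censor = float(rng.uniform(*config.followup_range))
    first = min(t_event, t_death, censor, OUTCOME_HORIZON)
    event5 = int(t_event == first)
    died5 = int(not event5 and t_death == first)
    followup = float(first)

    if event5 or died5 or followup >= OUTCOME_HORIZON:
        weight = 1.0
    else:
        weight = _index_weight(config, index_age, f, followup)

    return SimulatedFamily(
        id=id,
        true_p=p,
        relatives=tuple(relatives),
        index_age=index_age,
        index_event5=event5,
        index_died5=died5,
        index_followup=followup,
        index_weight=weight,
    )


def _index_profile(
    config: SimConfig, index_age: float, multiplier: float
) -> WomanRiskProfile:
    a0 = int(np.floor(index_age))
    years = int(OUTCOME_HORIZON)
    return WomanRiskProfile(
        id="index",
        age_at_start=index_age,
        disease_hazard=config.disease_hazard.rates[a0 : a0 + years] * multiplier,
        mortality_hazard=config.mortality.rates[a0 : a0 + years],
    )


def _index_weight(
    config: SimConfig, index_age: float, multiplier: float, followup: float
) -> float:
    profile = _index_profile(config, index_age, multiplier)
    full = absolute_interval_risk(profile, OUTCOME_HORIZON)
    if full <= 0:
        return 1.0
    return max(absolute_interval_risk(profile, followup) / full, 1e-12)


def simulate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[SimulatedFamily], pd.DataFrame, pd.DataFrame]:
    """Simulate a reproducible cohort and optionally write it to disk.

    Returns (families, outcomes, truth).  ``outcomes`` carries the index
    women's observed 5-year outcomes together with two predicted 5-year
    absolute risks: ``risk5_true`` from the family's latent p (the oracle
    predictor, exactly calibrated by construction) and ``risk5_bfhs`` from
    the computed score via f(p_hat).  ``truth`` records the latent p, the
    computed BFHS and the three-level comparator per family.

    When ``out_dir`` is given, writes ``families.csv`` (the relative-level
    table in the format ``read_families`` consumes), ``outcomes.csv`` and
    ``truth.csv``.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(max(config.n_families, 1))
    sims: list[SimulatedFamily] = []
    for i in range(config.n_families):
        rng = np.random.default_rng(streams[i])
        sims.append(draw_family(config, rng, id=f"fam{i:06d}"))

    truth_rows, outcome_rows, family_rows = [], [], []
    for sim in sims:
        fam = sim.family
        res = bfhs(fam, config.disease_hazard, config.prior, config.p0)
        f_true = family_hazard_multiplier(sim.true_p, config.p0)
        f_hat = family_hazard_multiplier(res.p_hat, config.p0)
        prof_true = _index_profile(config, sim.index_age, f_true)
        prof_hat = _index_profile(config, sim.index_age, f_hat)
        truth_rows.append(
            {
                "family_id": sim.id,
                "true_p": sim.true_p,
                "bfhs": res.p_hat,
                "c": res.c,
                "m": res.m,
                "n_relatives": fam.n,
                "three_level": three_level_score(fam),
            }
        )
        outcome_rows.append(
            {
                "id": sim.id,
                "age": sim.index_age,
                "event5": sim.index_event5,
                "died5": sim.index_died5,
                "followup_years": sim.index_followup,
                "weight": sim.index_weight,
                "risk5_true": absolute_interval_risk(prof_true, OUTCOME_HORIZON),
                "risk5_bfhs": absolute_interval_risk(prof_hat, OUTCOME_HORIZON),
            }
        )
        for j, r in enumerate(fam.relatives):
            family_rows.append(
                {
                    "family_id": sim.id,
                    "relative_id": f"{sim.id}r{j}",
                    "relation": r.relation,
                    "age": r.x,
                    "event": r.d,
                }
            )

    outcomes = pd.DataFrame(
        outcome_rows,
        columns=[
            "id", "age", "event5", "died5", "followup_years", "weight",
            "risk5_true", "risk5_bfhs",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["family_id", "true_p", "bfhs", "c", "m", "n_relatives", "three_level"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            family_rows,
            columns=["family_id", "relative_id", "relation", "age", "event"],
        ).to_csv(out / "families.csv", index=False)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return sims, outcomes, truth
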