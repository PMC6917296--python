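"""Calibration and discrimination machinery for 5-year risk predictions.

Women are binned into 1% predicted-risk categories (1%-or-lower .. 10%-or-
higher).  Observed case counts per bin are compared with the expected counts
(k/100) * n_k through a chi-square statistic on 9 degrees of freedom, with
women lost to follow-up before 5 years contributing fractionally to the
denominator (the ratio of the absolute risk they experienced during follow-up
to their 5-year absolute risk).  Exact (Clopper-Pearson) binomial intervals
accompany each bin.  Discrimination is summarised by AUC, the unnormalised
partial AUC on the 90-100% specificity band, and sensitivity at 90%
specificity.  Ten-fold cross-validation index partitions and nested-model
likelihood-ratio tests round out the comparison harness; Cox fitting itself
is delegated to standard survival routines, this module only consumes
predicted risks and log-likelihoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .absolute_risk import WomanRiskProfile, absolute_interval_risk

__all__ = [
    "OutcomeRecord",
    "RiskBinTable",
    "assign_bin",
    "ltfu_weight",
    "gof_chi2",
    "exact_binomial_ci",
    "roc_summary",
    "kfold_indices",
    "likelihood_ratio_test",
    "MODEL_GRID",
]

logger = logging.getLogger(__name__)

N_BINS = 10
GOF_DF = 9  # fixed at bins - 1 even when bins are empty
FOLLOWUP_HORIZON = 5.0


class EvaluationError(ValueError):
    pass


#: Covariate sets of the standard model-comparison grid.  The three-level
#: 0/1/>1 family-history score appears in every model; the BFHS is added only
#: in the b-variants.  Models 2* add Gail-style covariates and interactions;
#: models 3* additionally adjust for BMI category and baseline menopause
#: status (with nulliparous women split from the 25-29 first-birth category).
_GAIL_COVARIATES = (
    "age_menarche_cat",
    "biopsies_cat",
    "age_first_birth_cat",
    "age_ge_50",
    "age_ge_50:biopsies_cat",
    "fh3:age_first_birth_cat",
)
MODEL_GRID: dict[str, tuple[str, ...]] = {
    "1a": ("fh3",),
    "1b": ("fh3", "bfhs"),
    "2a": ("fh3", *_GAIL_COVARIATES),
    "2b": ("fh3", "bfhs", *_GAIL_COVARIATES),
    "3a": ("fh3", *_GAIL_COVARIATES, "bmi_cat", "menopause"),
    "3b": ("fh3", "bfhs", *_GAIL_COVARIATES, "bmi_cat", "menopause"),
}


@dataclass(frozen=True)
class OutcomeRecord:
    """One woman's predicted 5-year absolute risk and observed outcome.

    weight is the denominator contribution: 1 for women followed the full 5
    years or observed to have the event or die, in (0, 1) for women lost to
    follow-up earlier.
    """

    id: str
    risk5: float
    event5: int
    followup_years: float = FOLLOWUP_HORIZON
    died5: int = 0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.risk5 < 1:
            raise EvaluationError(f"risk5 must lie in (0, 1), got {self.risk5}")
        if self.event5 not in (0, 1) or self.died5 not in (0, 1):
            raise EvaluationError("event5 and died5 must be 0/1")
        if not 0 < self.weight <= 1:
            raise EvaluationError("weight must lie in (0, 1]")
        if not 0 <= self.followup_years <= FOLLOWUP_HORIZON:
            raise EvaluationError("followup_years must lie in [0, 5]")


@dataclass(frozen=True)
class RiskBinTable:
    """Per-bin calibration table plus the overall chi-square statistic."""

    table: pd.DataFrame  # columns: bin, n, observed, expected, ci_low, ci_high
    chi2: float
    pvalue: float
    df: int = GOF_DF


def assign_bin(risk5: float) -> int:
    """1% risk bin in 1..10: bin 1 is '1% or lower', bin 10 '10% or higher',
    interior bins half-open on the left, k = ceil(100 * risk).
    """
    if not 0 < risk5 < 1:
        raise EvaluationError(f"risk5 must lie in (0, 1), got {risk5}")
    if risk5 <= 0.01:
        return 1
    if risk5 > 0.09:
        return N_BINS
    return int(math.ceil(100.0 * risk5))


def ltfu_weight(profile: WomanRiskProfile, followup_years: float) -> float:
    """Fractional denominator weight for a woman lost before 5 years:
    absolute risk experienced during follow-up over her 5-year absolute risk.
    """
    if not 0 < followup_years <= FOLLOWUP_HORIZON:
        raise EvaluationError("followup_years must lie in (0, 5]")
    full = absolute_interval_risk(profile, FOLLOWUP_HORIZON)
    if full <= 0:
        raise EvaluationError(
            "zero 5-year absolute risk: LTFU weight undefined"
        )
    if followup_years == FOLLOWUP_HORIZON:
        return 1.0
    return absolute_interval_risk(profile, followup_years) / full


def gof_chi2(records) -> RiskBinTable:
    """Observed/expected calibration table and the 9-df chi-square statistic.

    n_k sums the (possibly fractional) weights in bin k, O_k counts observed
    events, E_k = (k/100) n_k — using k% even for the open-ended first and
    last bins, a deliberate slight approximation.  Empty bins contribute 0.
    Intervals are Clopper-Pearson on (O_k, round(n_k)).
    """
    records = list(records)
    if not records:
        raise EvaluationError("no outcome records")
    n = np.zeros(N_BINS)
    obs = np.zeros(N_BINS)
    for r in records:
        k = assign_bin(r.risk5) - 1
        n[k] += r.weight
        obs[k] += r.event5
    rows = []
    chi2 = 0.0
    for k in range(N_BINS):
        expected = (k + 1) / 100.0 * n[k]
        if n[k] > 0:
            chi2 += (obs[k] - expected) ** 2 / expected
            trials = max(int(round(n[k])), 1)
            lo, hi = exact_binomial_ci(int(obs[k]), trials)
        else:
            logger.info("risk bin %d is empty; contributes 0 to chi-square", k + 1)
            lo = hi = np.nan
        rows.append(
            {
                "bin": k + 1,
                "n": n[k],
                "observed": obs[k],
                "expected": expected,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    pvalue = float(stats.chi2.sf(chi2, GOF_DF))
    return RiskBinTable(table=pd.DataFrame(rows), chi2=float(chi2), pvalue=pvalue)


def exact_binomial_ci(
    events: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval from Beta quantiles."""
    if trials < 1 or not 0 <= events <= trials:
        raise EvaluationError("need 0 <= events <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if events == 0 else float(stats.beta.ppf(alpha / 2, events, trials - events + 1))
    hi = 1.0 if events == trials else float(
        stats.beta.ppf(1 - alpha / 2, events + 1, trials - events)
    )
    return lo, hi


def roc_summary(risks, outcomes) -> dict[str, float]:
    """Empirical ROC summaries: AUC, unnormalised pAUC over specificity
    0.90-1.00 (maximum 0.1) and sensitivity at >= 90% specificity.

    Ties are handled by the midpoint (trapezoidal) convention, so identical
    scores for everyone give AUC 0.5.  Women censored before 5 years without
    an event are expected to have been excluded upstream.
    """
    y = np.asarray(outcomes, dtype=int)
    s = np.asarray(risks, dtype=float)
    if y.size != s.size or y.size == 0:
        raise EvaluationError("risks and outcomes must be equal-length, nonempty")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both outcome classes must be present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # clip the curve at fpr = 0.1 (specificity 0.90), interpolating the edge
    band = 0.1
    tpr_at_band = float(np.interp(band, fpr, tpr))
    mask = fpr <= band
    fpr_c = np.append(fpr[mask], band)
    tpr_c = np.append(tpr[mask], tpr_at_band)
    pauc = float(np.trapezoid(tpr_c, fpr_c))
    # sensitivity at the operating point: best TPR among thresholds with
    # specificity >= 0.90 (no interpolation — an achievable threshold)
    sens = float(tpr[mask].max()) if mask.any() else 0.0
    return {"auc": auc, "pauc": pauc, "sensitivity_at_90_specificity": sens}


def kfold_indices(n: int, folds: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded near-equal partition of range(n) into ``folds`` disjoint test
    sets; identical seed gives the identical partition, so competing model
    variants can share training/testing splits.
    """
    if n < folds:
        raise EvaluationError(f"need n >= folds, got n={n}, folds={folds}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, folds)]


def likelihood_ratio_test(
    loglik_null: float, loglik_full: float, df_diff: int, slack: float = 1e-8
) -> float:
    """p-value of the nested-model likelihood-ratio test:
    upper chi-square tail of 2 (l_full - l_null) on df_diff degrees of freedom.
    """
    if df_diff < 1:
        raise EvaluationError("df_diff must be >= 1")
    statistic = 2.0 * (loglik_full - loglik_null)
    if statistic < -slack:
        raise EvaluationError(
            f"full model log-likelihood below null ({statistic / 2:+.3g}): "
            "model nesting violated"
        )
    return float(stats.chi2.sf(max(statistic, 0.0), df_diff))
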