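"""Beta prior on family-specific lifetime pure risk.

The score assumes the lifetime pure risk p of a family follows a
Beta(alpha, beta) prior anchored at the population lifetime pure risk
p0 = alpha / (alpha + beta), with the familial-aggregation constraint that
risk given one affected first-degree relative is roughly double the baseline.

The constants alpha = 1.184, beta = 4.828 are the published calibration for
p0 = 0.197 and are the default (``printed_constants``).  The exact form of the
doubling equation behind them is not reconstructible from the available
derivation, so three plausible operationalisations of "risk doubles given an
affected relative" are provided as solving variants for sensitivity analysis;
none reproduces 1.184 exactly.  Each solver keeps the mean pinned at p0 by
setting beta = alpha (1 - p0) / p0 and root-finds its own equation in alpha:

``conjugate_event_ratio``
    Ratio of posterior means under a likelihood proportional to p (one
    affected relative, full observation) vs proportional to (1 - p):
    E[p | affected] / E[p | unaffected] = (alpha + 1) / alpha = rr.
``posterior_mean_ratio``
    Ratio of posterior means under the score's own likelihood with one
    relative observed over a full lifetime (exposure c = -1): affected
    (m = 1) vs cancer-free (m = 0), evaluated in closed form via digamma.
``joint_event_ratio``
    Joint-event identity E[p^2]/E[p] = rr * E[p(1-p)] / (1 - p0).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import digamma

__all__ = ["BetaPrior", "CalibrationSpec", "calibrate_prior", "prior_mean"]

#: Published calibration at p0 = 0.197 with the doubling assumption.
PRINTED_ALPHA = 1.184
PRINTED_BETA = 4.828

VARIANTS = (
    "printed_constants",
    "conjugate_event_ratio",
    "posterior_mean_ratio",
    "joint_event_ratio",
)

_BRACKET = (1e-6, 1e3)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on the family lifetime pure risk p."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise CalibrationError("Beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class CalibrationSpec:
    """Inputs to prior calibration.

    p0 : population lifetime pure risk in (0, 1).
    familial_rr : target relative risk given an affected first-degree
        relative (> 1; the standard epidemiological value is 2).
    variant : one of ``printed_constants`` (default), ``conjugate_event_ratio``,
        ``posterior_mean_ratio``, ``joint_event_ratio``.
    """

    p0: float = 0.197
    familial_rr: float = 2.0
    variant: str = "printed_constants"

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise CalibrationError("p0 must lie in (0, 1)")
        if not self.familial_rr > 1:
            raise CalibrationError("familial_rr must exceed 1")
        if self.variant not in VARIANTS:
            raise CalibrationError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}"
            )


def prior_mean(prior: BetaPrior) -> float:
    """Mean alpha / (alpha + beta) of the prior."""
    return prior.mean


def _beta_for(alpha: float, p0: float) -> float:
    return alpha * (1.0 - p0) / p0


def _residual(alpha: float, spec: CalibrationSpec) -> float:
    """Variant equation residual at mean-pinned (alpha, beta)."""
    p0, rr = spec.p0, spec.familial_rr
    beta = _beta_for(alpha, p0)
    s = alpha + beta
    if spec.variant == "conjugate_event_ratio":
        return (alpha + 1.0) / alpha - rr
    if spec.variant == "posterior_mean_ratio":
        # one relative, full lifetime: c = -1 so the posterior's second
        # shape is b = beta + 1.  Affected (m=1) mean over cancer-free (m=0).
        b = beta + 1.0
        affected = (
            (alpha / (alpha + b))
            * (digamma(alpha + b + 1.0) - digamma(b))
            / (digamma(alpha + b) - digamma(b))
        )
        return affected / (alpha / (alpha + b)) - rr
    if spec.variant == "joint_event_ratio":
        ep = alpha / s
        ep2 = alpha * (alpha + 1.0) / (s * (s + 1.0))
        epq = alpha * beta / (s * (s + 1.0))
        return ep2 / ep - rr * epq / (1.0 - p0)
    raise CalibrationError(f"no equation for variant {spec.variant!r}")


def calibrate_prior(spec: CalibrationSpec) -> BetaPrior:
    """Solve for the Beta prior satisfying the spec's two constraints.

    ``printed_constants`` returns the published (1.184, 4.828) verbatim;
    solving variants root-find alpha on (1e-6, 1e3) with
    beta = alpha (1 - p0) / p0, so the mean constraint holds by construction.
    """
    if spec.variant == "printed_constants":
        return BetaPrior(PRINTED_ALPHA, PRINTED_BETA)
    lo, hi = _BRACKET
    f_lo, f_hi = _residual(lo, spec), _residual(hi, spec)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"no root for {spec.variant} in ({lo}, {hi}): "
            f"residuals ({f_lo:.4g}, {f_hi:.4g})"
        )
    alpha = brentq(_residual, lo, hi, args=(spec,), xtol=1e-12, rtol=1e-14)
    return BetaPrior(alpha, _beta_for(alpha, spec.p0))
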