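"""Scale harmonization and Bland-Altman agreement analysis.

The CAT total runs 0-40 and the SGRQ 0-100, so CAT scores are multiplied by
2.5 ("adjCAT") before the two instruments are compared.  Agreement is then
summarised the Bland-Altman way: per-person differences (SGRQ - adjCAT)
plotted against per-person means, with the mean difference (bias), limits
of agreement, the difference-vs-mean correlation, and the proportion of
differences below chosen thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedScores",
    "AgreementResult",
    "EndpointEstimate",
    "cat_to_adjcat",
    "adjcat_to_cat",
    "bland_altman",
    "agreement_endpoints",
]

#: Multiplier putting the 0-40 CAT total on the SGRQ's 0-100 range.
ADJCAT_FACTOR = 2.5


def cat_to_adjcat(cat_score: float) -> float:
    """Rescale a CAT total (0-40) onto the SGRQ's 0-100 range."""
    if not 0 <= cat_score <= 40:
        raise ValueError(f"CAT score {cat_score} outside [0, 40]")
    return ADJCAT_FACTOR * cat_score


def adjcat_to_cat(adjcat: float) -> float:
    """Exact inverse of :func:`cat_to_adjcat` (0-100 back to CAT units)."""
    if not 0 <= adjcat <= 100:
        raise ValueError(f"adjCAT score {adjcat} outside [0, 100]")
    return adjcat / ADJCAT_FACTOR


@dataclass(frozen=True)
class PairedScores:
    """One person's totals on both 0-100 scales (a: SGRQ-like, b: adjCAT-like)."""

    person_id: str
    score_a: float
    score_b: float

    def __post_init__(self) -> None:
        for name, v in (("score_a", self.score_a), ("score_b", self.score_b)):
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary of paired differences d = a - b.

    ``r_diff_vs_mean`` / ``p_value`` are NaN with ``r_defined`` False when
    fewer than 3 pairs are available or either the differences or the means
    have zero variance.
    """

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    r_diff_vs_mean: float
    p_value: float
    r_defined: bool
    prop_below: dict[float, float]


def bland_altman(
    pairs: Sequence[PairedScores],
    thresholds: Sequence[float] = (5.0, 10.0, 20.0),
) -> AgreementResult:
    """Bland-Altman analysis of paired scores.

    The difference direction is fixed as ``score_a - score_b`` (SGRQ minus
    adjCAT).  For each threshold t, ``prop_below[t]`` is the proportion of
    pairs with ``|difference| < t`` (strict).  Limits of agreement are
    bias +/- 1.96 sd.
    """
    if not pairs:
        raise ValueError("no pairs given")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    a = np.array([p.score_a for p in pairs])
    b = np.array([p.score_b for p in pairs])
    d = a - b
    mean_ab = (a + b) / 2.0
    n = len(pairs)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    r = p_val = float("nan")
    r_defined = False
    if n >= 3 and np.ptp(d) > 0 and np.ptp(mean_ab) > 0:
        r, p_val = stats.pearsonr(mean_ab, d)
        r, p_val = float(r), float(p_val)
        r_defined = True
    prop = {float(t): float(np.mean(np.abs(d) < t)) for t in thresholds}
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        r_diff_vs_mean=r,
        p_value=p_val,
        r_defined=r_defined,
        prop_below=prop,
    )


@dataclass(frozen=True)
class EndpointEstimate:
    """OLS-predicted score_b at the two ends of the score_a scale, clamped
    to [0, 100], with CAT-unit equivalents."""

    at_a0: float
    at_a100: float
    slope: float
    intercept: float

    @property
    def at_a0_cat_units(self) -> float:
        return adjcat_to_cat(self.at_a0)

    @property
    def at_a100_cat_units(self) -> float:
        return adjcat_to_cat(self.at_a100)


def agreement_endpoints(pairs: Sequence[PairedScores]) -> EndpointEstimate:
    """Where does one scale sit when the other reads 0 or 100?

    Fits the ordinary least-squares line of score_b on score_a and evaluates
    it at score_a = 0 and 100, clamping predictions to the scale range.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    a = np.array([p.score_a for p in pairs])
    b = np.array([p.score_b for p in pairs])
    if np.ptp(a) == 0:
        raise ValueError("score_a values are all equal: regression is degenerate")
    fit = stats.linregress(a, b)
    clamp = lambda v: float(min(100.0, max(0.0, v)))
    return EndpointEstimate(
        at_a0=clamp(fit.intercept),
        at_a100=clamp(fit.intercept + 100.0 * fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
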