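"""Rasch / partial-credit measurement model.

Items and persons live on one logit scale: an item's severity is the latent
trait value at which a patient affirms it half the time.  Polytomous items
follow the partial credit model (PCM),

    P(X = k | theta) ∝ exp( sum_{j=1..k} (theta - delta_j) ),   k = 0..m,

with the empty sum for k = 0, so a dichotomous item (m = 1) reduces to the
one-parameter logistic Rasch model.  The expected simple-sum score over an
item bank is the test characteristic curve (TCC); it is strictly increasing
in theta, which is what makes the raw-score-to-logit conversion table well
defined.

Estimation is joint (unconditional) maximum likelihood: person locations and
item thresholds are updated in alternation under the conventional zero-mean
constraint on the item thresholds.  Persons and items whose responses are
all-extreme carry infinite ML estimates and are excluded up front; a fully
deterministic (Guttman) matrix has no finite ML solution at all and is
reported as an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .crosswalk import ConversionTable

__all__ = [
    "ItemDefinition",
    "ItemBank",
    "PersonAbility",
    "ResponseMatrix",
    "FitResult",
    "EstimationError",
    "SeparationError",
    "response_probability",
    "expected_total_score",
    "score_variance",
    "fit_item_bank",
    "person_estimate_for_score",
    "build_conversion_table",
]

# ML estimates diverging past this magnitude indicate (quasi-)perfect
# separation: the likelihood has no finite maximiser.
_SEPARATION_BOUND = 15.0
_THETA_BRACKET = 60.0


class EstimationError(RuntimeError):
    """Estimation cannot proceed (degenerate or empty data)."""


class SeparationError(EstimationError):
    """The ML estimate does not exist (perfect Guttman separation)."""


@dataclass(frozen=True)
class ItemDefinition:
    """One item with ordered response categories 0..m and m step thresholds
    (in logits). m = 1 for a dichotomous item."""

    item_id: str
    instrument_id: str
    label: str
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError(f"item {self.item_id!r}: thresholds must be non-empty")
        if not all(math.isfinite(t) for t in self.thresholds):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))

    @property
    def max_score(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ItemBank:
    """An instrument: ordered items sharing one logit metric.  When
    ``centred``, the mean of all thresholds across items is fixed at zero."""

    instrument_id: str
    items: tuple[ItemDefinition, ...]
    centred: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique within a bank")
        if self.centred and self.items:
            mean = float(np.mean(self.all_thresholds()))
            if abs(mean) > 1e-9:
                raise ValueError(
                    f"bank flagged centred but mean threshold is {mean:.3g}"
                )

    def __len__(self) -> int:
        return len(self.items)

    def all_thresholds(self) -> np.ndarray:
        return np.concatenate([np.asarray(it.thresholds) for it in self.items])

    @property
    def max_score(self) -> int:
        return sum(it.max_score for it in self.items)

    def centre(self) -> "ItemBank":
        """Return a copy shifted so the mean threshold is exactly zero."""
        mean = float(np.mean(self.all_thresholds()))
        items = tuple(
            ItemDefinition(
                it.item_id,
                it.instrument_id,
                it.label,
                tuple(t - mean for t in it.thresholds),
            )
            for it in self.items
        )
        return ItemBank(self.instrument_id, items, centred=True)


@dataclass(frozen=True)
class PersonAbility:
    person_id: str
    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError(f"person {self.person_id!r}: theta must be finite")


@dataclass
class ResponseMatrix:
    """Persons x items grid of integer category codes; NaN marks missing."""

    person_ids: list[str]
    item_ids: list[str]
    responses: np.ndarray  # float array, shape (n_persons, n_items), NaN = missing

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError("response grid shape does not match id lists")
        obs = self.responses[~np.isnan(self.responses)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValueError("responses must be non-negative integer category codes")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def validate_against(self, bank: ItemBank) -> None:
        """Check every non-missing response lies in 0..m for its item."""
        by_id = {it.item_id: it for it in bank.items}
        for j, iid in enumerate(self.item_ids):
            item = by_id[iid]
            col = self.responses[:, j]
            obs = col[~np.isnan(col)]
            if obs.size and np.any(obs > item.max_score):
                raise ValueError(f"item {iid!r}: response above category range")


# ---------------------------------------------------------------------------
# model probabilities and the test characteristic curve


def _category_log_weights(thetas: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """PCM category log-weights, shape (n_persons, m+1)."""
    cum = np.concatenate([[0.0], np.cumsum(thresholds)])
    k = np.arange(len(thresholds) + 1)
    return np.outer(thetas, k) - cum[None, :]


def _category_probs(thetas: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    z = _category_log_weights(thetas, thresholds)
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)


def response_probability(theta: float, item: ItemDefinition) -> np.ndarray:
    """Probability vector over categories 0..m at latent severity *theta*.

    For a dichotomous item this is the Rasch logistic pair
    (1-p, p) with p = 1/(1+exp(-(theta-delta))); in general the PCM
    category distribution.  Entries sum to one.
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    return _category_probs(np.array([theta]), np.asarray(item.thresholds))[0]


def _expected_scores(thetas: np.ndarray, bank: ItemBank) -> np.ndarray:
    """TCC evaluated at each theta (vectorised over persons)."""
    total = np.zeros(len(thetas))
    for it in bank.items:
        p = _category_probs(thetas, np.asarray(it.thresholds))
        total += p @ np.arange(it.n_categories)
    return total


def expected_total_score(theta: float, bank: ItemBank) -> float:
    """Expected simple-sum score at *theta* — the test characteristic curve."""
    if not bank.items:
        raise ValueError("bank is empty")
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    return float(_expected_scores(np.array([theta]), bank)[0])


def score_variance(theta: float, bank: ItemBank) -> float:
    """Variance of the simple-sum score at *theta* (the test information
    with respect to the score metric)."""
    var = 0.0
    for it in bank.items:
        p = _category_probs(np.array([theta]), np.asarray(it.thresholds))[0]
        k = np.arange(it.n_categories)
        mu = float(p @ k)
        var += float(p @ (k - mu) ** 2)
    return var


def person_estimate_for_score(
    raw_score: float, bank: ItemBank, extreme_adjustment: float = 0.3
) -> float:
    """Invert the TCC: the theta whose expected total score equals the raw
    score.

    Extreme scores 0 and max have no finite ML estimate, so they are
    replaced by ``0 + extreme_adjustment`` and ``max - extreme_adjustment``
    before inversion — the standard fractional-score correction that keeps
    the endpoints of a conversion table finite.
    """
    max_score = bank.max_score
    if not 0 <= raw_score <= max_score:
        raise ValueError(f"raw_score {raw_score} outside [0, {max_score}]")
    if not 0 < extreme_adjustment < 1:
        raise ValueError("extreme_adjustment must lie in (0, 1)")
    target = float(raw_score)
    if target == 0:
        target = extreme_adjustment
    elif target == max_score:
        target = max_score - extreme_adjustment
    f = lambda th: expected_total_score(th, bank) - target
    return float(optimize.brentq(f, -_THETA_BRACKET, _THETA_BRACKET, xtol=1e-12))


def build_conversion_table(
    bank: ItemBank, extreme_adjustment: float = 0.3
) -> ConversionTable:
    """Tabulate the score-to-logit mapping for every integer raw score.

    The result has ``max_score + 1`` strictly increasing rows: steep near
    the extremes, near-linear in the middle, finite at both ends thanks to
    the extreme-score adjustment.
    """
    if not bank.centred:
        raise ValueError("bank must be centred before tabulation")
    rows = tuple(
        (r, person_estimate_for_score(r, bank, extreme_adjustment))
        for r in range(bank.max_score + 1)
    )
    return ConversionTable(rows)


# ---------------------------------------------------------------------------
# joint maximum likelihood estimation


@dataclass
class FitResult:
    """Outcome of :func:`fit_item_bank`.

    Unpacks as ``bank, abilities = fit_item_bank(...)`` for convenience.
    ``converged`` is False when the iteration cap was reached before the
    parameter-change tolerance (a warning is also emitted).
    """

    bank: ItemBank
    abilities: list[PersonAbility]
    converged: bool
    n_iter: int
    excluded_person_ids: list[str] = field(default_factory=list)
    excluded_item_ids: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter((self.bank, self.abilities))


def _item_nll_and_grad(deltas, thetas, x, m):
    """Negative log-likelihood of one item's thresholds and its gradient.

    d(nll)/d(delta_j) = sum_p [ 1(x_p >= j) - P_p(X >= j) ].
    """
    z = _category_log_weights(thetas, deltas)
    logZ = logsumexp(z, axis=1)
    idx = x.astype(int)
    nll = float(np.sum(logZ - z[np.arange(len(x)), idx]))
    zs = z - z.max(axis=1, keepdims=True)
    p = np.exp(zs)
    p /= p.sum(axis=1, keepdims=True)
    # P(X >= j) for j = 1..m via reverse cumulative sum over categories
    p_ge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
    ind_ge = idx[:, None] >= np.arange(1, m + 1)[None, :]
    grad = np.sum(ind_ge - p_ge, axis=0)
    return nll, grad


def _solve_thetas(thetas, scores, item_thresholds, obs_mask):
    """Per-person ML: solve expected-score = observed-score by damped
    Newton, vectorised over persons.  Missing responses drop item-wise."""
    thetas = thetas.copy()
    for _ in range(200):
        expected = np.zeros_like(thetas)
        variance = np.zeros_like(thetas)
        for j, thr in enumerate(item_thresholds):
            p = _category_probs(thetas, thr)
            k = np.arange(len(thr) + 1)
            mu = p @ k
            v = p @ (k**2) - mu**2
            m_j = obs_mask[:, j]
            expected += np.where(m_j, mu, 0.0)
            variance += np.where(m_j, v, 0.0)
        step = (scores - expected) / np.maximum(variance, 1e-10)
        step = np.clip(step, -1.0, 1.0)
        thetas += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return thetas


def fit_item_bank(
    responses: ResponseMatrix,
    tol: float = 1e-6,
    max_iter: int = 200,
    bias_correction: bool = False,
    instrument_id: str = "fitted",
) -> FitResult:
    """Joint ML estimation of PCM thresholds and person severities.

    Alternates a vectorised Newton solve for person locations with a
    quasi-Newton maximisation of each item's threshold likelihood, recentring
    the thresholds to mean zero after every cycle.  Category counts per item
    are inferred from the largest observed code.

    Persons with all-minimum or all-maximum observed responses, and items
    with a single observed category, are excluded before estimation (their
    ML estimates are infinite) and reported in the result.  A response
    matrix that remains deterministic after exclusion (a perfect Guttman
    pattern) drives the estimates to infinity; this is detected and raised
    as :class:`SeparationError`.

    ``bias_correction`` applies the (K-1)/K shrinkage (K = number of items)
    to the final thresholds, countering the outward bias of joint ML.
    """
    X = responses.responses.copy()
    person_ids = list(responses.person_ids)
    item_ids = list(responses.item_ids)
    if len(item_ids) < 2 or len(person_ids) < 2:
        raise EstimationError("need at least 2 persons and 2 items")

    m_by_item = {}
    for j, iid in enumerate(item_ids):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            m_by_item[iid] = 0
        else:
            m_by_item[iid] = int(obs.max())

    # iterate exclusions: all-extreme persons <-> single-category items
    keep_p = np.ones(len(person_ids), dtype=bool)
    keep_i = np.ones(len(item_ids), dtype=bool)
    changed = True
    while changed:
        changed = False
        for j in np.where(keep_i)[0]:
            col = X[keep_p, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0 or obs.min() == obs.max():
                keep_i[j] = False
                changed = True
        for i in np.where(keep_p)[0]:
            row = X[i, keep_i]
            obs_mask = ~np.isnan(row)
            if not obs_mask.any():
                keep_p[i] = False
                changed = True
                continue
            maxima = np.array(
                [m_by_item[iid] for iid, k in zip(item_ids, keep_i) if k]
            )[obs_mask]
            vals = row[obs_mask]
            if np.all(vals == 0) or np.all(vals == maxima):
                keep_p[i] = False
                changed = True

    excluded_p = [pid for pid, k in zip(person_ids, keep_p) if not k]
    excluded_i = [iid for iid, k in zip(item_ids, keep_i) if not k]
    Xf = X[np.ix_(keep_p, keep_i)]
    kept_pids = [pid for pid, k in zip(person_ids, keep_p) if k]
    kept_iids = [iid for iid, k in zip(item_ids, keep_i) if k]
    if len(kept_iids) < 2 or len(kept_pids) < 2:
        raise EstimationError("fewer than 2 persons or items remain after "
                              "excluding extreme response vectors")

    ms = np.array([m_by_item[iid] for iid in kept_iids])
    obs_mask = ~np.isnan(Xf)
    scores = np.nansum(Xf, axis=1)
    max_scores = obs_mask @ ms

    # initial values: logit of the relative score / zero thresholds
    frac = (scores + 0.5) / (max_scores + 1.0)
    thetas = np.log(frac / (1 - frac))
    thresholds = [np.zeros(m) for m in ms]

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        thetas = _solve_thetas(thetas, scores, thresholds, obs_mask)
        new_thresholds = []
        for j, thr in enumerate(thresholds):
            rows = obs_mask[:, j]
            x_j = Xf[rows, j]
            th_j = thetas[rows]
            res = optimize.minimize(
                _item_nll_and_grad,
                thr,
                args=(th_j, x_j, ms[j]),
                jac=True,
                method="BFGS",
                options={"gtol": tol * 1e-2, "maxiter": 200},
            )
            new_thresholds.append(res.x)
        # zero-mean constraint: shift items and persons together
        mean = float(np.mean(np.concatenate(new_thresholds)))
        new_thresholds = [t - mean for t in new_thresholds]
        thetas = thetas - mean
        delta = max(
            float(np.max(np.abs(a - b))) for a, b in zip(new_thresholds, thresholds)
        )
        thresholds = new_thresholds
        mags = np.concatenate(thresholds + [thetas])
        if np.max(np.abs(mags)) > _SEPARATION_BOUND:
            raise SeparationError(
                "parameter estimates diverged: the data are (quasi-)perfectly "
                "separated and no finite maximum-likelihood solution exists"
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"joint ML did not reach tol={tol} within {max_iter} iterations",
            RuntimeWarning,
        )

    if bias_correction:
        k_items = len(kept_iids)
        thresholds = [t * (k_items - 1) / k_items for t in thresholds]
        mean = float(np.mean(np.concatenate(thresholds)))
        thresholds = [t - mean for t in thresholds]

    thetas = _solve_thetas(thetas, scores, thresholds, obs_mask)

    items = tuple(
        ItemDefinition(iid, instrument_id, iid, tuple(thr))
        for iid, thr in zip(kept_iids, thresholds)
    )
    bank = ItemBank(instrument_id, items).centre()
    abilities = [
        PersonAbility(pid, float(th)) for pid, th in zip(kept_pids, thetas)
    ]
    return FitResult(
        bank=bank,
        abilities=abilities,
        converged=converged,
        n_iter=n_iter,
        excluded_person_ids=excluded_p,
        excluded_item_ids=excluded_i,
    )
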