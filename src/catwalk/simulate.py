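"""Synthetic respondents for paired patient-reported-outcome instruments.

Two instruments measuring one latent trait: a CAT-like questionnaire
(8 items, 6 ordered categories, simple-sum total 0-40) and an SGRQ-C-like
one (mostly dichotomous items with about 15% polytomous, totalled as
percent-of-maximum on 0-100).  Respondent severities are drawn from a
normal latent-trait distribution and responses sampled from the
partial-credit category distributions, which is what powers parameter
recovery, agreement and end-to-end rehearsals without patient data.

The SGRQ's empirically derived item weights are deliberately not emulated:
the agreement machinery only needs two 0-100 scales estimating the same
construct, and percent-of-maximum keeps the synthetic score transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agreement import ADJCAT_FACTOR, PairedScores
from .rasch import ItemBank, ItemDefinition, PersonAbility, ResponseMatrix, _category_probs

__all__ = [
    "SimulationConfig",
    "PairedInstruments",
    "sample_thetas",
    "simulate_responses",
    "random_bank",
    "make_paired_instruments",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a paired-instrument simulation.

    Defaults: 1000 respondents with theta ~ Normal(0, 1); a CAT-like bank of
    8 five-threshold items drawn in [-2, 2]; an SGRQ-C-like bank of 34
    dichotomous plus 6 three-category items drawn in [-3, 3] (≈15%
    polytomous).  All banks are centred after drawing.
    """

    n_persons: int = 1000
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    n_cat_items: int = 8
    n_cat_thresholds: int = 5
    cat_threshold_range: tuple[float, float] = (-2.0, 2.0)
    n_sgrq_dichotomous: int = 34
    n_sgrq_polytomous: int = 6
    n_sgrq_poly_thresholds: int = 2
    sgrq_threshold_range: tuple[float, float] = (-3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not self.theta_sd > 0:
            raise ValueError("theta_sd must be > 0")
        for rng in (self.cat_threshold_range, self.sgrq_threshold_range):
            if not (np.isfinite(rng[0]) and np.isfinite(rng[1]) and rng[0] < rng[1]):
                raise ValueError("threshold ranges must be finite and increasing")


@dataclass(frozen=True)
class PairedInstruments:
    """Everything one simulated study produces: both banks, the shared
    person severities, both response matrices and the paired 0-100 totals."""

    cat_bank: ItemBank
    sgrq_bank: ItemBank
    thetas: list[PersonAbility]
    cat_responses: ResponseMatrix
    sgrq_responses: ResponseMatrix
    paired_scores: list[PairedScores]


def _substreams(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


def sample_thetas(
    n: int, mean: float = 0.0, sd: float = 1.0, seed: int = 0
) -> list[PersonAbility]:
    """Draw n person severities from Normal(mean, sd), reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sd > 0:
        raise ValueError("sd must be > 0")
    if not (np.isfinite(mean) and np.isfinite(sd)):
        raise ValueError("mean and sd must be finite")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=n)
    width = len(str(n))
    return [
        PersonAbility(f"p{i + 1:0{width}d}", float(t)) for i, t in enumerate(draws)
    ]


def random_bank(
    instrument_id: str,
    n_items: int,
    n_thresholds: int | Sequence[int],
    threshold_range: tuple[float, float],
    seed: int,
) -> ItemBank:
    """A centred bank with thresholds drawn uniformly in *threshold_range*
    and sorted ascending within each item."""
    rng = np.random.default_rng(seed)
    if isinstance(n_thresholds, int):
        n_thresholds = [n_thresholds] * n_items
    items = []
    for i, m in enumerate(n_thresholds):
        thr = np.sort(rng.uniform(*threshold_range, size=m))
        items.append(
            ItemDefinition(
                f"{instrument_id}_{i + 1:02d}", instrument_id,
                f"{instrument_id} item {i + 1}", tuple(thr),
            )
        )
    return ItemBank(instrument_id, tuple(items)).centre()


def simulate_responses(
    bank: ItemBank, thetas: Sequence[PersonAbility], seed: int = 0
) -> ResponseMatrix:
    """Sample one response per person x item from the PCM category
    distribution at that person's severity."""
    rng = np.random.default_rng(seed)
    th = np.array([p.theta for p in thetas])
    cols = []
    for item in bank.items:
        probs = _category_probs(th, np.asarray(item.thresholds))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(len(th))
        cols.append(np.sum(u[:, None] > cum[:, :-1], axis=1).astype(float))
    return ResponseMatrix(
        person_ids=[p.person_id for p in thetas],
        item_ids=[it.item_id for it in bank.items],
        responses=np.column_stack(cols),
    )


def make_paired_instruments(config: SimulationConfig) -> PairedInstruments:
    """Simulate one cohort answering both instruments.

    Both response sets are generated from the SAME latent severities; the
    CAT-like total is the simple sum rescaled by 2.5 (adjCAT) and the
    SGRQ-like total is percent of its maximum simple sum, so both paired
    scores live on 0-100.  One master seed feeds four independent
    substreams (two bank draws, the trait draw, and response sampling).
    """
    s_cat_bank, s_sgrq_bank, s_theta, s_resp = _substreams(config.seed, 4)
    cat_bank = random_bank(
        "cat", config.n_cat_items, config.n_cat_thresholds,
        config.cat_threshold_range, s_cat_bank,
    )
    sizes = [1] * config.n_sgrq_dichotomous + (
        [config.n_sgrq_poly_thresholds] * config.n_sgrq_polytomous
    )
    sgrq_bank = random_bank(
        "sgrq", len(sizes), sizes, config.sgrq_threshold_range, s_sgrq_bank,
    )
    thetas = sample_thetas(
        config.n_persons, config.theta_mean, config.theta_sd, s_theta
    )
    s_resp_cat, s_resp_sgrq = _substreams(s_resp, 2)
    cat_resp = simulate_responses(cat_bank, thetas, s_resp_cat)
    sgrq_resp = simulate_responses(sgrq_bank, thetas, s_resp_sgrq)

    cat_totals = cat_resp.responses.sum(axis=1)
    sgrq_totals = sgrq_resp.responses.sum(axis=1)
    paired = [
        PairedScores(
            person_id=p.person_id,
            score_a=float(100.0 * s_tot / sgrq_bank.max_score),
            score_b=float(ADJCAT_FACTOR * c_tot),
        )
        for p, c_tot, s_tot in zip(thetas, cat_totals, sgrq_totals)
    ]
    return PairedInstruments(
        cat_bank=cat_bank,
        sgrq_bank=sgrq_bank,
        thetas=thetas,
        cat_responses=cat_resp,
        sgrq_responses=sgrq_resp,
        paired_scores=paired,
    )
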