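"""Partial-credit model probabilities, the TCC, its inversion, and joint ML."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catwalk.rasch import (
    EstimationError,
    ItemBank,
    ItemDefinition,
    ResponseMatrix,
    build_conversion_table,
    expected_total_score,
    fit_item_bank,
    person_estimate_for_score,
    response_probability,
)
from catwalk.simulate import random_bank, sample_thetas, simulate_responses


class TestResponseProbability:
    def test_dichotomous_half_probability_at_item_severity(self, dichotomous_bank):
        """At theta equal to the item severity, a patient affirms the item
        half the time — the defining property of the logit metric."""
        p = response_probability(0.0, dichotomous_bank.items[0])
        assert p[1] == pytest.approx(0.5, abs=1e-12)

    def test_dichotomous_logistic_limit(self):
        item = ItemDefinition("d", "t", "d", (0.0,))
        p = response_probability(10.0, item)
        assert p[1] == pytest.approx(1.0 / (1.0 + math.exp(-10.0)), rel=1e-12)

    def test_polytomous_hand_normalised_weights(self, symmetric_poly_bank):
        """Thresholds (-1, +1) at theta 0: weights (1, e, 1) normalised."""
        p = response_probability(0.0, symmetric_poly_bank.items[0])
        e = math.e
        expected = np.array([1.0, e, 1.0]) / (2.0 + e)
        assert p == pytest.approx(expected, abs=1e-10)

    @given(
        theta=st.floats(-8, 8),
        thresholds=st.lists(st.floats(-4, 4), min_size=1, max_size=6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_normalises_and_stays_positive(self, theta, thresholds):
        p = response_probability(theta, ItemDefinition("i", "t", "i", tuple(thresholds)))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_rejects_non_finite_theta(self, dichotomous_bank):
        with pytest.raises(ValueError):
            response_probability(float("nan"), dichotomous_bank.items[0])


class TestExpectedTotalScore:
    def test_floor_at_very_low_severity(self, symmetric_poly_bank):
        assert expected_total_score(-50.0, symmetric_poly_bank) == pytest.approx(0.0, abs=1e-9)

    def test_bernoulli_expectation_at_item_severity(self, dichotomous_bank):
        assert expected_total_score(0.0, dichotomous_bank) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_thresholds_give_half_range(self, symmetric_poly_bank):
        """Symmetric thresholds force the TCC through m/2 at theta 0."""
        assert expected_total_score(0.0, symmetric_poly_bank) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_strictly_increasing_in_theta(self, seed):
        bank = random_bank("b", 5, 3, (-2, 2), seed)
        grid = np.linspace(-6, 6, 100)
        values = [expected_total_score(t, bank) for t in grid]
        assert np.all(np.diff(values) > 0)


class TestScoreInversion:
    def test_midpoint_score_maps_to_zero_for_symmetric_bank(self, symmetric_poly_bank):
        assert person_estimate_for_score(1, symmetric_poly_bank) == pytest.approx(0.0, abs=1e-8)

    def test_extreme_adjustment_closed_form(self, dichotomous_bank):
        """Raw score 0 replaced by 0.3: theta = log(0.3/0.7) for one
        dichotomous item at severity zero."""
        theta = person_estimate_for_score(0, dichotomous_bank, extreme_adjustment=0.3)
        assert theta == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_monotone_in_raw_score(self):
        bank = random_bank("b", 4, 4, (-2, 2), 7)
        thetas = [person_estimate_for_score(r, bank) for r in range(bank.max_score + 1)]
        assert np.all(np.diff(thetas) > 0)

    def test_out_of_range_score_rejected(self, dichotomous_bank):
        with pytest.raises(ValueError):
            person_estimate_for_score(2, dichotomous_bank)


class TestConversionTableConstruction:
    def test_cat_like_bank_yields_41_strictly_increasing_rows(self):
        bank = random_bank("cat", 8, 5, (-2, 2), 11)
        table = build_conversion_table(bank)
        assert len(table.rows) == 41
        logits = np.array(table.logits)
        assert np.all(np.diff(logits) > 0)
        assert np.all(np.isfinite(logits))

    def test_symmetric_bank_gives_antisymmetric_table(self):
        """Mirroring all thresholds about zero mirrors the table about the
        midpoint score."""
        thr = (-1.5, -0.5, 0.5, 1.5)
        items = tuple(
            ItemDefinition(f"i{k}{s}", "t", "i", tuple(s * t for t in thr))
            for k in range(2) for s in (1, -1)
        )
        bank = ItemBank("t", items, centred=True)
        table = build_conversion_table(bank)
        logits = np.array(table.logits)
        assert logits == pytest.approx(-logits[::-1], abs=1e-6)

    def test_round_trips_through_the_tcc(self):
        bank = random_bank("b", 6, 4, (-2, 2), 3)
        table = build_conversion_table(bank)
        for score, logit in table.rows[1:-1]:
            assert expected_total_score(logit, bank) == pytest.approx(score, abs=1e-6)

    def test_requires_centred_bank(self):
        item = ItemDefinition("i", "t", "i", (1.0,))
        with pytest.raises(ValueError):
            build_conversion_table(ItemBank("t", (item,)))


class TestJointMaximumLikelihood:
    def test_recovers_generating_thresholds(self):
        """Simulated cohort from known centred thresholds: the fitted bank
        (with the joint-ML shrinkage correction) recovers them closely."""
        bank = random_bank("cat", 8, 5, (-2, 2), 42)
        thetas = sample_thetas(1000, 0.0, 1.0, 43)
        responses = simulate_responses(bank, thetas, 44)
        result = fit_item_bank(responses, bias_correction=True)
        assert result.converged
        true_by_id = {it.item_id: np.asarray(it.thresholds) for it in bank.items}
        err = np.concatenate(
            [np.asarray(it.thresholds) - true_by_id[it.item_id]
             for it in result.bank.items]
        )
        assert np.sqrt(np.mean(err**2)) <= 0.2

    def test_fitted_bank_is_centred(self):
        bank = random_bank("b", 4, 2, (-1.5, 1.5), 5)
        responses = simulate_responses(bank, sample_thetas(300, 0, 1, 6), 7)
        fitted, abilities = fit_item_bank(responses)
        assert fitted.centred
        assert abs(np.mean(fitted.all_thresholds())) < 1e-9
        assert len(abilities) <= 300

    def test_identical_item_columns_get_equal_estimates(self):
        rng = np.random.default_rng(0)
        col = (rng.random(300) < 0.5).astype(float)
        other = np.column_stack(
            [(rng.random(300) < p).astype(float) for p in (0.4, 0.6)]
        )
        matrix = ResponseMatrix(
            [f"p{i}" for i in range(300)],
            ["a", "a_copy", "c", "d"],
            np.column_stack([col, col, other]),
        )
        result = fit_item_bank(matrix)
        thr = {it.item_id: it.thresholds[0] for it in result.bank.items}
        assert thr["a"] == pytest.approx(thr["a_copy"], abs=1e-5)

    def test_guttman_matrix_has_no_finite_estimate(self):
        """A deterministic Guttman pattern collapses entirely under
        extreme-vector exclusion: no finite ML solution exists."""
        rows = [[1] * s + [0] * (4 - s) for s in [1, 2, 3] * 10]
        matrix = ResponseMatrix(
            [f"p{i}" for i in range(30)],
            [f"i{j}" for j in range(4)],
            np.array(rows, dtype=float),
        )
        with pytest.raises(EstimationError):
            fit_item_bank(matrix)

    def test_extreme_persons_are_excluded_and_reported(self):
        bank = random_bank("b", 3, 1, (-1, 1), 9)
        thetas = sample_thetas(100, 0, 1, 10)
        responses = simulate_responses(bank, thetas, 11)
        responses.responses[0, :] = 0.0  # force one all-minimum person
        result = fit_item_bank(responses)
        assert responses.person_ids[0] in result.excluded_person_ids
        fitted_ids = {a.person_id for a in result.abilities}
        assert responses.person_ids[0] not in fitted_ids
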