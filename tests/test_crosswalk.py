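"""Score-to-logit conversion, band windows, and item-to-band assignment."""

import pytest

from catwalk.crosswalk import (
    ABOVE_RANGE,
    BELOW_RANGE,
    DEFAULT_BANDS,
    BandWindow,
    CategoryBand,
    ConversionTable,
    ItemSeverityRecord,
    assign_items,
    band_windows,
    score_to_logit,
    validate_assignment,
)


class TestScoreToLogit:
    @pytest.mark.parametrize("score,logit", [(0, -4.31), (20, 0.07), (40, 4.01)])
    def test_tabulated_scores_return_exact_values(self, table1, score, logit):
        assert score_to_logit(table1, score) == logit

    def test_linear_interpolation_between_rows(self, table1):
        """Score 22 sits 2/5 of the way from the row at 20 to the row at 25."""
        expected = 0.07 + (2 / 5) * (0.55 - 0.07)
        assert score_to_logit(table1, 22) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_over_all_integer_scores(self, table1):
        vals = [score_to_logit(table1, s) for s in range(0, 41)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_and_interpolation_off(self, table1):
        with pytest.raises(ValueError):
            score_to_logit(table1, 41)
        with pytest.raises(ValueError):
            score_to_logit(table1, 22, interpolate=False)

    def test_table_validation_rejects_non_monotone_rows(self):
        with pytest.raises(ValueError):
            ConversionTable(((0, 1.0), (5, 0.5)))


class TestBandWindows:
    def test_published_band_boundaries(self, table1):
        windows = band_windows(DEFAULT_BANDS, table1)
        by_name = {w.name: w for w in windows}
        assert by_name["Low Impact"].logit_lo == -4.31
        assert by_name["Low Impact"].logit_hi == -1.03
        assert by_name["Very High Impact"].logit_lo == 1.07
        assert by_name["Very High Impact"].logit_hi == 4.01

    def test_windows_tile_without_gaps(self, table1):
        windows = band_windows(DEFAULT_BANDS, table1)
        ordered = sorted(windows, key=lambda w: w.logit_lo)
        for a, b in zip(ordered, ordered[1:]):
            assert a.logit_hi == b.logit_lo
        assert ordered[0].logit_lo == score_to_logit(table1, 0)
        assert ordered[-1].logit_hi == score_to_logit(table1, 40)

    def test_non_contiguous_bands_rejected(self, table1):
        bands = [CategoryBand("a", 1, 10), CategoryBand("b", 12, 20)]
        with pytest.raises(ValueError):
            band_windows(bands, table1)


def _brute_force_assign(records, windows):
    out = {}
    lo = min(w.logit_lo for w in windows)
    hi = max(w.logit_hi for w in windows)
    for rec in records:
        if rec.logit <= lo:
            out[rec] = BELOW_RANGE
        elif rec.logit > hi:
            out[rec] = ABOVE_RANGE
        else:
            matches = [w.name for w in windows if w.logit_lo < rec.logit <= w.logit_hi]
            assert len(matches) == 1
            out[rec] = matches[0]
    return out


class TestAssignment:
    @pytest.mark.parametrize(
        "label,logit,band",
        [
            ("Cough causes tiredness", 1.13, "Very High Impact"),
            ("Usually cannot play sports or games", -1.05, "Low Impact"),
            ("Chest causes lot of problems or most important problem", 0.15,
             "High Impact"),
        ],
    )
    def test_published_single_item_assignments(self, default_windows, label,
                                               logit, band):
        rec = ItemSeverityRecord(label, logit)
        assert assign_items([rec], default_windows)[rec] == band

    def test_out_of_range_items_are_marked_not_dropped(self, default_windows):
        below = ItemSeverityRecord("too mild", -4.50)
        above = ItemSeverityRecord("too severe", 4.50)
        result = assign_items([below, above], default_windows)
        assert result[below] == BELOW_RANGE
        assert result[above] == ABOVE_RANGE

    def test_boundary_logit_goes_to_lower_severity_band(self, default_windows):
        rec = ItemSeverityRecord("exactly on boundary", -1.03)
        assert assign_items([rec], default_windows)[rec] == "Low Impact"

    def test_matches_brute_force_scan(self, table2_records, default_windows):
        fast = assign_items(table2_records, default_windows)
        slow = _brute_force_assign(table2_records, default_windows)
        assert fast == slow

    def test_invariant_to_record_and_window_order(self, table2_records,
                                                  default_windows):
        base = assign_items(table2_records, default_windows)
        shuffled = assign_items(table2_records[::-1], default_windows[::-1])
        assert dict(base) == dict(shuffled)


class TestValidation:
    def test_published_grouping_reproduced_exactly(self, table2_records,
                                                   default_windows):
        """All 55 printed band memberships fall out of the window rule."""
        computed = assign_items(table2_records, default_windows)
        report = validate_assignment(computed, table2_records)
        assert report.n_checked == 55
        assert report.n_mismatches == 0
        assert report.ok

    def test_perturbed_reference_is_caught_by_name(self, table2_records,
                                                   default_windows):
        computed = assign_items(table2_records, default_windows)
        perturbed = list(table2_records)
        victim = perturbed[0]
        perturbed[0] = ItemSeverityRecord(victim.label, victim.logit,
                                          "Very High Impact")
        report = validate_assignment(computed, perturbed)
        assert report.n_mismatches == 1
        assert report.mismatches[0][0] == victim.label

    def test_empty_reference_gives_empty_report(self, table2_records,
                                                default_windows):
        computed = assign_items(table2_records, default_windows)
        report = validate_assignment(computed, [])
        assert report.n_checked == 0 and report.ok

    def test_unknown_reference_band_rejected(self, table2_records,
                                             default_windows):
        computed = assign_items(table2_records, default_windows)
        bogus = [ItemSeverityRecord("x", 0.0, "No Such Band")]
        with pytest.raises(ValueError):
            validate_assignment(computed, bogus)
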