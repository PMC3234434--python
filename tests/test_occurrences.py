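import math

import pytest

from geocat import (Occurrence, OccurrenceSet, edit_point, filter_bbox,
                    filter_precision, validate_occurrences)


def make_set(coords, **kwargs):
    occs = [Occurrence(id=f"o{i}", lat=la, lon=lo) for i, (la, lo) in enumerate(coords)]
    return OccurrenceSet(taxon_name="t", occurrences=occs, **kwargs)


class TestValidation:
    def test_lat_beyond_90_flagged_as_swap_and_hidden(self):
        s = make_set([(120.0, 10.0), (5.0, 5.0)])
        report = validate_occurrences(s)
        assert report.n_suspected_swaps == 1
        assert "possible lat/lon swap" in report.flags["o0"]
        assert not s.get("o0").visible and s.get("o1").visible

    def test_duplicate_coordinates_counted_as_pairs_and_stay_visible(self):
        s = make_set([(1.0, 2.0), (1.0, 2.0), (3.0, 4.0)])
        report = validate_occurrences(s)
        assert report.n_duplicate_pairs == 1
        assert all(o.visible for o in s.occurrences)

    def test_three_identical_records_make_three_pairs(self):
        s = make_set([(1.0, 2.0)] * 3)
        assert validate_occurrences(s).n_duplicate_pairs == 3

    def test_all_valid_set_reports_zero_counts(self):
        s = make_set([(i * 1.0, i * 2.0) for i in range(10)])
        report = validate_occurrences(s)
        assert (report.n_out_of_range, report.n_missing,
                report.n_duplicate_pairs, report.n_suspected_swaps) == (0, 0, 0, 0)
        assert report.clean

    def test_missing_coordinates_hidden_and_counted(self):
        s = make_set([(math.nan, math.nan), (1.0, 1.0)])
        report = validate_occurrences(s)
        assert report.n_missing == 1
        assert not s.get("o0").visible

    def test_out_of_range_longitude_hidden(self):
        s = make_set([(10.0, 190.0), (1.0, 1.0)])
        report = validate_occurrences(s)
        assert report.n_out_of_range == 1
        assert not s.get("o0").visible

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="no occurrences"):
            validate_occurrences(OccurrenceSet(taxon_name="t"))


class TestBboxFilter:
    def test_hide_inside_hides_only_contained_points(self):
        s = make_set([(0.0, 0.0), (10.0, 0.0)])
        filter_bbox(s, 5, -180, 15, 180, "hide_inside")
        assert s.get("o0").visible and not s.get("o1").visible

    def test_global_bbox_hide_outside_is_identity(self):
        s = make_set([(0.0, 0.0), (45.0, 90.0), (-60.0, -120.0)])
        filter_bbox(s, -90, -180, 90, 180, "hide_outside")
        assert all(o.visible for o in s.occurrences)

    def test_point_on_edge_counts_as_inside(self):
        s = make_set([(5.0, 0.0)])
        filter_bbox(s, 5, -10, 15, 10, "hide_inside")
        assert not s.get("o0").visible

    def test_delete_inside_removes_records(self):
        s = make_set([(0.0, 0.0), (10.0, 0.0)])
        filter_bbox(s, 5, -180, 15, 180, "delete_inside")
        assert [o.id for o in s.occurrences] == ["o0"]

    def test_inverted_bbox_raises(self):
        s = make_set([(0.0, 0.0)])
        with pytest.raises(ValueError, match="inverted"):
            filter_bbox(s, 10, 0, 5, 10, "hide_inside")

    def test_inside_outside_partition_hides_everything(self):
        coords = [(la, lo) for la in (-10.0, 0.0, 5.0, 10.0) for lo in (-5.0, 5.0, 20.0)]
        s1 = make_set(coords)
        s2 = make_set(coords)
        filter_bbox(s1, 0, 0, 5, 10, "hide_inside")
        filter_bbox(s2, 0, 0, 5, 10, "hide_outside")
        hidden = {o.id for o in s1.occurrences if not o.visible} | \
                 {o.id for o in s2.occurrences if not o.visible}
        assert hidden == {o.id for o in s1.occurrences}

    def test_filters_never_change_coordinates(self):
        coords = [(0.0, 0.0), (10.0, 20.0)]
        s = make_set(coords)
        filter_bbox(s, -5, -5, 5, 5, "hide_inside")
        filter_precision(s, 100)
        assert [(o.lat, o.lon) for o in s.occurrences] == coords
        assert not any(o.edited for o in s.occurrences)


class TestPrecisionFilter:
    def test_hides_only_records_exceeding_threshold(self):
        occs = [
            Occurrence(id="a", lat=0, lon=0, coordinate_uncertainty_m=100),
            Occurrence(id="b", lat=1, lon=1, coordinate_uncertainty_m=5000),
            Occurrence(id="c", lat=2, lon=2),
        ]
        s = OccurrenceSet(taxon_name="t", occurrences=occs)
        filter_precision(s, 1000)
        assert s.get("a").visible and not s.get("b").visible and s.get("c").visible

    def test_huge_threshold_is_identity(self):
        occs = [Occurrence(id="a", lat=0, lon=0, coordinate_uncertainty_m=5000)]
        s = OccurrenceSet(taxon_name="t", occurrences=occs)
        filter_precision(s, 1e9)
        assert s.get("a").visible

    def test_all_records_lacking_uncertainty_warns_and_passes(self, caplog):
        s = make_set([(0.0, 0.0), (1.0, 1.0)])
        with caplog.at_level("WARNING", logger="geocat"):
            filter_precision(s, 1000)
        assert all(o.visible for o in s.occurrences)
        assert any("coordinate_uncertainty_m" in r.message for r in caplog.records)

    def test_non_positive_threshold_raises(self):
        s = make_set([(0.0, 0.0)])
        with pytest.raises(ValueError):
            filter_precision(s, 0)


class TestEditPoint:
    def test_move_updates_coords_and_sets_edited(self):
        s = make_set([(0.0, 0.0)])
        edit_point(s, "o0", "move", (1.0, 2.0))
        o = s.get("o0")
        assert (o.lat, o.lon) == (1.0, 2.0) and o.edited

    def test_hide_then_show_restores_visibility(self):
        s = make_set([(0.0, 0.0)])
        edit_point(s, "o0", "hide")
        assert not s.get("o0").visible
        edit_point(s, "o0", "show")
        assert s.get("o0").visible

    def test_delete_removes_record(self):
        s = make_set([(0.0, 0.0), (1.0, 1.0)])
        edit_point(s, "o1", "delete")
        assert len(s) == 1

    def test_unknown_id_raises(self):
        s = make_set([(0.0, 0.0)])
        with pytest.raises(KeyError, match="zzz"):
            edit_point(s, "zzz", "delete")

    def test_move_out_of_range_raises(self):
        s = make_set([(0.0, 0.0)])
        with pytest.raises(ValueError, match="out of range"):
            edit_point(s, "o0", "move", (95.0, 0.0))

    def test_audit_trail_length_equals_number_of_edits(self):
        s = make_set([(0.0, 0.0), (1.0, 1.0)])
        edit_point(s, "o0", "move", (2.0, 2.0))
        edit_point(s, "o0", "hide")
        edit_point(s, "o1", "delete")
        assert len(s.audit) == 3

    def test_duplicate_ids_rejected(self):
        occs = [Occurrence(id="a", lat=0, lon=0), Occurrence(id="a", lat=1, lon=1)]
        with pytest.raises(ValueError, match="unique"):
            OccurrenceSet(taxon_name="t", occurrences=occs)
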