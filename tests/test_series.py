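"""Core data model: series invariants, selection, radial means, validation."""

import numpy as np
import pytest

from shrubring import (
    RingWidthSeries,
    SeriesCollection,
    combine_radii,
    validate_collection,
)
from shrubring.errors import AlignmentError, IntervalError

from conftest import make_series


class TestRingWidthSeries:
    def test_year_bookkeeping(self):
        s = make_series([100, 200, 300], first_year=1999)
        assert len(s) == 3
        assert s.last_year == 2001
        assert list(s.years) == [1999, 2000, 2001]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_series([100])

    def test_widths_read_only(self):
        s = make_series([100, 200])
        with pytest.raises(ValueError):
            s.widths[0] = 5

    def test_crop(self):
        s = make_series([1, 2, 3, 4, 5], first_year=2000)
        c = s.crop(2001, 2003)
        assert c.first_year == 2001
        assert list(c.widths) == [2, 3, 4]
        with pytest.raises(IntervalError):
            s.crop(1990, 2001)


class TestSeriesCollection:
    def test_unique_ids_enforced(self):
        s = make_series([1, 2])
        with pytest.raises(ValueError):
            SeriesCollection([s, make_series([3, 4])])

    def test_one_series_per_hierarchy_cell(self):
        a = make_series([1, 2], series_id="X1")
        b = make_series([3, 4], series_id="X2")  # same (site,stock,shoot,radius)
        with pytest.raises(ValueError):
            SeriesCollection([a, b])

    def test_selection_is_a_partition(self, small_stand):
        """Every series lands in exactly one (stock, shoot, radius) cell."""
        seen = []
        for stock in small_stand.stocks():
            for shoot in small_stand.shoots(stock):
                for radius in small_stand.radius_labels():
                    cell = small_stand.select(stock=stock, shoot=shoot, radius=radius)
                    seen.extend(s.series_id for s in cell)
        assert sorted(seen) == small_stand.ids

    def test_common_interval(self):
        coll = SeriesCollection(
            [
                make_series([1, 2, 3, 4], first_year=2000, series_id="A", shoot="01"),
                make_series([1, 2, 3], first_year=2002, series_id="B", shoot="02"),
            ]
        )
        assert coll.common_interval() == (2002, 2003)


class TestCombineRadii:
    def test_mean_of_identical_is_identity(self):
        a = make_series([100, 200, 300], radius="a", series_id="WE101a")
        b = a.with_values(a.widths, series_id="WE101b", radius_label="b")
        ab = combine_radii({"a": a, "b": b}, "ab")
        assert np.array_equal(ab.widths, a.widths)
        assert ab.radius_label == "ab"
        assert ab.series_id == "WE101ab"

    def test_arithmetic_mean(self):
        a = make_series([100, 200], radius="a")
        b = make_series([300, 400], radius="b", series_id="WE101b")
        ab = combine_radii({"a": a, "b": b}, "ab")
        assert list(ab.widths) == [200, 300]

    def test_four_radius_mean(self):
        radii = {
            r: make_series([v, v], radius=r, series_id=f"WE101{r}")
            for r, v in zip("abcd", [100, 100, 400, 400])
        }
        abcd = combine_radii(radii, "abcd")
        assert list(abcd.widths) == [250, 250]

    def test_abcd_equals_mean_of_ab_and_cd(self, small_stand):
        """Mean of means holds because ab and cd have equal cardinality."""
        shoot = small_stand.by_shoot(small_stand.stocks()[0])["01"]
        ab = combine_radii(shoot, "ab")
        cd = combine_radii(shoot, "cd")
        abcd = combine_radii(shoot, "abcd")
        np.testing.assert_allclose(abcd.widths, (ab.widths + cd.widths) / 2)

    def test_misaligned_years_rejected(self):
        a = make_series([1, 2, 3], first_year=2000, radius="a")
        b = make_series([1, 2, 3], first_year=2001, radius="b", series_id="WE101b")
        with pytest.raises(AlignmentError):
            combine_radii({"a": a, "b": b}, "ab")

    def test_missing_radius_rejected(self):
        a = make_series([1, 2], radius="a")
        with pytest.raises(ValueError):
            combine_radii({"a": a}, "ab")


class TestValidateCollection:
    def test_valid_stand_has_no_findings(self, small_stand):
        assert validate_collection(small_stand) == []

    def test_negative_width_flagged(self):
        s = make_series([100, -1, 50])
        peer = make_series([1, 2], series_id="WE101b", radius="b")
        kinds = [f.kind for f in validate_collection([s, peer])]
        assert kinds == ["negative_width"]

    def test_duplicate_id_flagged(self):
        a = make_series([1, 2])
        b = make_series([3, 4], shoot="02")
        b = RingWidthSeries(
            series_id=a.series_id, site=b.site, stock=b.stock, shoot=b.shoot,
            radius_label=b.radius_label, first_year=b.first_year, widths=b.widths,
        )
        kinds = {f.kind for f in validate_collection([a, b])}
        assert "duplicate_id" in kinds

    def test_singleton_shoot_flagged(self):
        a = make_series([1, 2], shoot="01")
        b = make_series([1, 2], shoot="02", series_id="WE102a")
        kinds = [f.kind for f in validate_collection([a, b])]
        assert kinds == ["singleton_shoot", "singleton_shoot"]
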