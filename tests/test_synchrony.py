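"""Gleichläufigkeit, overlap-adjusted t, BP t-scores, matrices, screen."""

import dataclasses
import math

import numpy as np
import pytest

from shrubring import (
    RingWidthSeries,
    crossdate_screen,
    generate_stand,
    glk,
    glk_threshold,
    pairwise_matrix,
    default_scenario,
    t_from_r,
    tbp,
)
from shrubring.errors import OverlapError

from conftest import make_series


def glk_oracle(x, y):
    """Brute-force sign-count Gleichläufigkeit (independent of the library)."""
    score = 0.0
    n = len(x)
    for t in range(1, n):
        dx = x[t] - x[t - 1]
        dy = y[t] - y[t - 1]
        if dx == 0 or dy == 0:
            score += 0.5
        elif (dx > 0) == (dy > 0):
            score += 1.0
    return 100.0 * score / (n - 1)


class TestGlk:
    def test_identical_sign_pattern_is_100(self):
        percent, p, n = glk([1, 3, 2, 4], [2, 4, 3, 5])
        assert percent == 100.0
        assert n == 4
        assert p < 0.1  # only 3 intervals: strong but short evidence

    def test_half_agreement(self):
        percent, _, _ = glk([1, 3, 2, 4, 5], [2, 1, 3, 4, 6])
        assert percent == 50.0

    def test_perfect_opposition_is_0(self):
        percent, p, _ = glk([1, 2, 3], [3, 2, 1])
        assert percent == 0.0
        assert p > 0.9

    def test_tie_scores_half(self):
        percent, _, _ = glk([1, 1, 2], [1, 2, 3])
        assert percent == 75.0  # one tie (0.5) + one agreement (1) over 2

    def test_calendar_alignment_of_series_inputs(self):
        x = make_series([1, 3, 2, 4, 6], first_year=2000)
        y = make_series([9, 2, 4, 3, 5], first_year=1999, series_id="WE101b",
                        radius="b")
        percent, _, n = glk(x, y)
        assert n == 4  # shared years 2000-2003
        assert percent == 100.0

    def test_short_overlap_rejected(self):
        with pytest.raises(OverlapError):
            glk([1, 2], [2, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = rng.integers(0, 6, n)  # small ints provoke ties
            y = rng.integers(0, 6, n)
            assert glk(x, y)[0] == pytest.approx(glk_oracle(x, y), abs=1e-12)

    def test_threshold_inverts_pvalue(self):
        for n in (10, 22, 35):
            for alpha in (0.05, 0.001):
                g = glk_threshold(n, alpha)
                # a pair exactly at the threshold has p == alpha
                from shrubring.synchrony import glk_pvalue

                assert glk_pvalue(g, n) == pytest.approx(alpha, rel=1e-9)


class TestTFromR:
    def test_zero_correlation_gives_zero(self):
        assert t_from_r(0.0, 30) == 0.0

    def test_reference_value(self):
        assert t_from_r(0.8, 23) == pytest.approx(6.11, abs=0.01)

    def test_perfect_correlation_is_infinite_not_fatal(self):
        assert math.isinf(t_from_r(1.0, 10))
        assert t_from_r(-1.0, 10) == -math.inf

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(-0.95, 0.95, 21)
        ts = [t_from_r(r, 20) for r in rs]
        assert all(a < b for a, b in zip(ts, ts[1:]))
        ns = [5, 10, 20, 50]
        ts = [t_from_r(0.6, n) for n in ns]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(OverlapError):
            t_from_r(0.5, 2)


class TestTbp:
    def test_self_comparison_flags_infinite_t(self):
        rng = np.random.default_rng(1)
        x = make_series(np.exp(rng.normal(6, 0.3, 21)))
        res = tbp(x, x.with_values(x.widths, series_id="WE101b", radius_label="b"))
        assert res.t_infinite
        assert res.glk_percent == 100.0
        assert res.r == 1.0

    def test_time_reversed_series_does_not_cross_date(self):
        rng = np.random.default_rng(8)
        w = np.exp(rng.normal(6, 0.4, 21))
        x = make_series(w)
        y = make_series(w[::-1], series_id="WE102a", shoot="02")
        assert tbp(x, y).t_bp < 3.5

    def test_white_noise_null_distribution(self):
        """Independent pairs: t_BP centred at 0, rarely above 3.5."""
        rng = np.random.default_rng(42)
        ts = []
        for _ in range(400):
            x = make_series(np.exp(rng.normal(6, 0.3, 21)))
            y = make_series(
                np.exp(rng.normal(6, 0.3, 21)), series_id="WE102a", shoot="02"
            )
            ts.append(tbp(x, y).t_bp)
        ts = np.asarray(ts)
        assert abs(ts.mean()) < 0.2
        assert np.mean(ts >= 3.5) < 0.02

    def test_short_overlap_rejected(self):
        x = make_series([1, 2, 3, 4, 5, 6])
        y = make_series([1, 2, 3, 4, 5, 6], series_id="WE102a", shoot="02")
        with pytest.raises(OverlapError):
            tbp(x, y)


class TestPairwiseMatrix:
    def test_identical_pair_glk(self):
        rng = np.random.default_rng(2)
        w = np.exp(rng.normal(6, 0.3, 15))
        group = [
            make_series(w, series_id="WE101a", shoot="01"),
            make_series(w, series_id="WE102a", shoot="02"),
        ]
        res = pairwise_matrix(group, metric="glk")
        assert res.matrix.iloc[0, 1] == 100.0
        assert res.mean == 100.0

    def test_hand_computed_mean(self):
        # pairwise Glk: (x,y)=100, (x,z)=50, (y,z)=50 -> mean 66.7
        x = make_series([1, 3, 2, 4, 5], series_id="S1", shoot="01")
        y = make_series([2, 4, 3, 5, 7], series_id="S2", shoot="02")
        z = make_series([2, 1, 3, 4, 6], series_id="S3", shoot="03")
        assert glk(x, y)[0] == 100.0
        assert glk(x, z)[0] == 50.0
        assert glk(y, z)[0] == 50.0
        res = pairwise_matrix([x, y, z], metric="glk")
        assert res.mean == pytest.approx(200.0 / 3, abs=1e-9)

    def test_matrix_symmetric_on_stand(self, small_stand):
        group = list(small_stand.select(radius="a"))
        res = pairwise_matrix(group, metric="tbp")
        m = res.matrix.to_numpy()
        np.testing.assert_array_equal(m, m.T)

    def test_infinite_t_excluded_from_mean(self):
        rng = np.random.default_rng(4)
        w = np.exp(rng.normal(6, 0.3, 21))
        group = [
            make_series(w, series_id="S1", shoot="01"),
            make_series(w, series_id="S2", shoot="02"),
            make_series(np.exp(rng.normal(6, 0.3, 21)), series_id="S3", shoot="03"),
        ]
        res = pairwise_matrix(group, metric="tbp")
        assert res.n_infinite == 1
        assert math.isfinite(res.mean)


class TestCrossdateScreen:
    def _group(self, seed=0, n=8):
        params = dataclasses.replace(
            default_scenario(seed=seed),
            n_stocks=1,
            shoots_per_stock=n,
            radii_labels=("a",),
            age_range=(30, 34),
        )
        return list(generate_stand(params).select(radius="a"))

    def test_well_dated_group_not_flagged(self):
        records = crossdate_screen(self._group(seed=3))
        assert all(not r.flagged for r in records)

    def test_shifted_series_flagged_at_minus_one(self):
        group = self._group(seed=5)
        s = group[0]
        shifted = RingWidthSeries(
            series_id=s.series_id, site=s.site, stock=s.stock, shoot=s.shoot,
            radius_label=s.radius_label, first_year=s.first_year + 1,
            widths=s.widths,
        )
        records = crossdate_screen([shifted] + group[1:])
        rec = {r.series_id: r for r in records}[s.series_id]
        assert rec.flagged
        assert rec.best_lag == -1

    def test_deleted_ring_flags_the_shoot(self):
        group = self._group(seed=6)
        s = group[0]
        # deleting an early ring shifts most of the series one year back
        mangled = s.with_values(np.delete(s.widths, 5))
        records = crossdate_screen([mangled] + group[1:])
        rec = {r.series_id: r for r in records}[s.series_id]
        assert rec.flagged
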