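"""MS, AC, Rbar, S/N, EPS, EV, chronology bands and sample-size design."""

import dataclasses
import math

import numpy as np
import pytest

from shrubring import (
    CommonInterval,
    ac1,
    build_chronology,
    eps,
    eps_from_snr,
    ev_first,
    generate_stand,
    group_stats,
    mean_sensitivity,
    rbar,
    recommend_n,
    default_scenario,
    snr,
)
from shrubring.errors import LengthError

from conftest import make_series


def _exact_corr_group(correlations, n=20, seed=0):
    """Series with exact pairwise sample correlations via an orthonormal
    centred basis (Gram–Schmidt on random vectors)."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, 3))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    z1, z2, z3 = q.T
    r12, r13, r23 = correlations
    x1 = z1
    x2 = r12 * z1 + math.sqrt(1 - r12**2) * z2
    a = (r23 - r12 * r13) / math.sqrt(1 - r12**2)
    x3 = r13 * z1 + a * z2 + math.sqrt(max(1 - r13**2 - a**2, 0.0)) * z3
    out = []
    for i, x in enumerate([x1, x2, x3]):
        out.append(
            make_series(x + 10.0, series_id=f"S{i}", shoot=f"{i:02d}")
        )
    return out


class TestMeanSensitivity:
    def test_constant_is_zero(self):
        assert mean_sensitivity(np.full(10, 450.0)) == 0.0

    def test_hand_value(self):
        assert mean_sensitivity([100, 200]) == pytest.approx(200.0 / 3, abs=1e-12)

    def test_missing_ring_attains_maximum(self):
        assert mean_sensitivity([400, 0]) == 200.0

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = np.abs(rng.normal(500, 300, 30))
            assert 0.0 <= mean_sensitivity(x) <= 200.0

    def test_too_short(self):
        with pytest.raises(LengthError):
            mean_sensitivity([5.0])


class TestAc1:
    def test_linear_series_is_one(self):
        assert ac1([1, 2, 3, 4, 5]) == pytest.approx(1.0, abs=1e-12)

    def test_alternating_is_minus_one(self):
        assert ac1([1, 2, 1, 2, 1, 2]) == pytest.approx(-1.0, abs=1e-12)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(1)
        assert abs(ac1(rng.normal(0, 1, 1000))) < 0.1

    def test_zero_variance_undefined(self):
        assert math.isnan(ac1([3.0, 3.0, 3.0, 3.0]))


class TestRbar:
    def test_identical_series(self):
        rng = np.random.default_rng(2)
        w = np.exp(rng.normal(6, 0.3, 15))
        group = [
            make_series(w, series_id=f"S{i}", shoot=f"{i:02d}") for i in range(3)
        ]
        assert rbar(group) == pytest.approx(1.0, abs=1e-12)

    def test_constructed_pairwise_values_average_to_zero(self):
        group = _exact_corr_group((0.5, -0.5, 0.0))
        assert rbar(group) == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance(self):
        group = _exact_corr_group((0.4, 0.2, 0.1), seed=5)
        r0 = rbar(group)
        scaled = [
            s.with_values(3.0 * s.widths + 40.0 * (i + 1))
            for i, s in enumerate(group)
        ]
        assert rbar(scaled) == pytest.approx(r0, abs=1e-9)


class TestSnrEps:
    def test_zero_correlation(self):
        assert snr(10, 0.0) == 0.0
        assert eps_from_snr(0.0) == 0.0

    def test_hand_values(self):
        assert snr(10, 0.5) == pytest.approx(10.0)
        assert snr(15, 0.657) == pytest.approx(28.7, abs=0.05)

    def test_perfect_correlation_infinite(self):
        assert math.isinf(snr(5, 1.0))
        assert eps_from_snr(math.inf) == 1.0

    def test_identity_eps_equals_snr_over_one_plus_snr(self):
        for n in (2, 5, 15, 40):
            for r in (0.05, 0.3, 0.657, 0.9):
                s = snr(n, r)
                assert eps(n, r) == pytest.approx(s / (1 + s), abs=1e-12)


class TestEvFirst:
    def test_identical_series_100_percent(self):
        rng = np.random.default_rng(3)
        w = np.exp(rng.normal(6, 0.3, 15))
        group = [
            make_series(w, series_id=f"S{i}", shoot=f"{i:02d}") for i in range(3)
        ]
        iv = CommonInterval(2000, 2014)
        assert ev_first(group, iv) == pytest.approx(100.0, abs=1e-9)

    def test_two_series_with_r_half(self):
        group = _exact_corr_group((0.5, 0.0, 0.0))[:2]
        iv = CommonInterval(2000, 2019)
        # eigenvalues of [[1, .5], [.5, 1]] are 1.5 and 0.5 -> 75 %
        assert ev_first(group, iv) == pytest.approx(75.0, abs=1e-9)

    def test_two_uncorrelated_series(self):
        group = _exact_corr_group((0.0, 0.0, 0.0))[:2]
        iv = CommonInterval(2000, 2019)
        assert ev_first(group, iv) == pytest.approx(50.0, abs=1e-9)

    def test_first_component_at_least_average(self):
        group = _exact_corr_group((0.3, 0.1, -0.2), seed=9)
        assert ev_first(group, CommonInterval(2000, 2019)) >= 100.0 / 3


class TestBuildChronology:
    def test_single_series(self):
        s = make_series([100, 200, 300])
        chron = build_chronology([s])
        assert list(chron.mean) == [100, 200, 300]
        assert list(chron.table["median"]) == [100, 200, 300]
        assert list(chron.table["depth"]) == [1, 1, 1]

    def test_two_series_mean_and_depth(self):
        a = make_series([100, 200], series_id="A", shoot="01")
        b = make_series([300, 400], series_id="B", shoot="02")
        chron = build_chronology([a, b])
        assert list(chron.mean) == [200, 300]
        assert list(chron.table["depth"]) == [2, 2]

    def test_bands_nested_on_random_groups(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            group = [
                make_series(
                    rng.lognormal(6, 0.5, int(rng.integers(5, 20))),
                    first_year=int(rng.integers(1995, 2005)),
                    series_id=f"S{i}",
                    shoot=f"{i:02d}",
                )
                for i in range(int(rng.integers(1, 8)))
            ]
            t = build_chronology(group).table
            assert (t["p5"] <= t["q25"]).all()
            assert (t["q25"] <= t["median"]).all()
            assert (t["median"] <= t["q75"]).all()
            assert (t["q75"] <= t["p95"]).all()


class TestGroupStats:
    def test_identical_series(self):
        rng = np.random.default_rng(6)
        w = np.exp(rng.normal(6, 0.3, 21))
        group = [
            make_series(w, series_id=f"S{i}", shoot=f"{i:02d}") for i in range(5)
        ]
        st = group_stats(group)
        assert st.rbar == pytest.approx(1.0, abs=1e-12)
        assert st.eps == 1.0
        assert st.ev_percent == pytest.approx(100.0, abs=1e-9)
        from shrubring import fit_conservative

        single = mean_sensitivity(fit_conservative(group[0]).indices)
        assert st.ms_percent == pytest.approx(single, abs=1e-9)

    def test_strong_common_signal_gives_high_eps(self):
        params = dataclasses.replace(
            default_scenario(seed=11),
            n_stocks=1,
            shoots_per_stock=10,
            radii_labels=("a",),
            sigma_climate=0.4,
            sigma_noise=0.1,
            disturbance=(0.0, 0.5, 2),
        )
        group = list(generate_stand(params).select(radius="a"))
        assert group_stats(group).eps > 0.9

    def test_no_common_signal_gives_low_eps(self):
        epss = []
        for seed in range(20):
            params = dataclasses.replace(
                default_scenario(seed=300 + seed),
                n_stocks=1,
                shoots_per_stock=15,
                radii_labels=("a",),
                sigma_climate=0.0,
                sigma_noise=0.3,
                disturbance=(0.0, 0.5, 2),
            )
            group = list(generate_stand(params).select(radius="a"))
            epss.append(group_stats(group).eps)
        assert np.median(epss) < 0.5


class TestRecommendN:
    def test_inverts_eps_formula(self):
        assert recommend_n(0.5, 0.85) == 6
        assert recommend_n(0.9, 0.85) == 1
        assert recommend_n(0.5, 1e-9) == 1

    def test_matches_brute_force_search(self):
        for r in (0.05, 0.2, 0.35, 0.657, 0.95):
            for target in (0.5, 0.85, 0.99):
                n = 1
                while eps(n, r) < target:
                    n += 1
                assert recommend_n(r, target) == n

    def test_monotone(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ns = [recommend_n(r, 0.85) for r in rs]
        assert all(a >= b for a, b in zip(ns, ns[1:]))
        targets = [0.5, 0.7, 0.85, 0.95]
        ns = [recommend_n(0.4, t) for t in targets]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_unattainable(self):
        with pytest.raises(ValueError):
            recommend_n(-0.1)
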