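"""Circular KDE, the overlap coefficient estimators, and diel tagging."""

import warnings
from datetime import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import vonmises

from civetniche.core_io import DataError
from civetniche.synthetic_data import ActivityModel, true_temporal_overlap
from civetniche.temporal_overlap import (
    CircularSample,
    assign_diel_period,
    circular_kde,
    classify_overlap,
    fit_concentration,
    mean_resultant_length,
    overlap_delta1,
    overlap_delta4,
    times_to_radians,
)

from conftest import make_events

TWO_PI = 2 * np.pi


def vm_sample(rng, mu, kappa, n, species=""):
    return CircularSample(np.mod(rng.vonmises(mu, kappa, n), TWO_PI), species=species)


@pytest.mark.parametrize(
    "clock, angle",
    [("00:00", 0.0), ("12:00", np.pi), ("18:00", 1.5 * np.pi), ("06:00", 0.5 * np.pi)],
)
def test_times_to_radians_maps_the_clock_onto_the_circle(clock, angle):
    s = times_to_radians([clock])
    assert s.angles[0] == pytest.approx(angle)


def test_times_to_radians_accepts_time_objects_and_fractions():
    s = times_to_radians([time(6, 0), 0.75])
    assert s.angles == pytest.approx([np.pi / 2, 1.5 * np.pi])
    with pytest.raises(DataError):
        times_to_radians([1.5])


class TestConcentrationFit:
    def test_inversion_matches_bessel_ratio_to_1e9(self, rng):
        """kappa-hat solves A(kappa) = Rbar; at Rbar = 0.8, kappa ~ 2.87."""
        from civetniche.temporal_overlap import _bessel_ratio

        # construct a sample, then check the defining equation directly
        s = vm_sample(rng, 1.0, 3.0, 500)
        kappa = fit_concentration(s)
        rbar = mean_resultant_length(s.angles)
        assert abs(_bessel_ratio(kappa) - rbar) < 1e-9
        # frozen inversion value for Rbar = 0.8 (independent numeric root)
        from scipy.optimize import brentq
        from scipy.special import i0, i1

        k_star = brentq(lambda k: i1(k) / i0(k) - 0.8, 1e-8, 50)
        assert k_star == pytest.approx(2.8713, abs=1e-3)
        assert abs(_bessel_ratio(k_star) - 0.8) < 1e-9

    def test_near_uniform_sample_gives_small_kappa(self, rng):
        s = CircularSample(rng.uniform(0, TWO_PI, 20_000))
        assert fit_concentration(s) < 0.1

    def test_simulation_consistency(self, rng):
        s = vm_sample(rng, 1.0, 2.0, 10_000)
        assert fit_concentration(s) == pytest.approx(2.0, abs=0.1)

    def test_degenerate_point_mass_errors(self):
        with pytest.raises(DataError, match="jitter"):
            fit_concentration(CircularSample(np.full(5, 1.0)))
        with pytest.raises(DataError):
            fit_concentration(CircularSample(np.array([1.0])))


class TestCircularKDE:
    @given(
        mu=st.floats(0, TWO_PI - 1e-9),
        kappa=st.floats(0.5, 8),
        n=st.integers(10, 200),
    )
    @settings(max_examples=30, deadline=None)
    def test_is_a_proper_circular_density(self, mu, kappa, n):
        rng = np.random.default_rng(abs(hash((mu, kappa, n))) % 2**31)
        kde = circular_kde(vm_sample(rng, mu, kappa, n))
        assert (kde.values >= 0).all()
        assert kde.integral() == pytest.approx(1.0, abs=1e-6)
        assert kde(np.array([0.0]))[0] == pytest.approx(kde(np.array([TWO_PI]))[0])

    def test_converges_to_true_density(self, rng):
        kde = circular_kde(vm_sample(rng, 0.0, 4.0, 10_000))
        true = vonmises.pdf(kde.grid, 4.0, loc=0.0)
        assert np.abs(kde.values - true).max() < 0.05


class TestOverlapEstimators:
    def test_delta4_of_a_sample_with_itself_is_exactly_one(self, rng):
        s = vm_sample(rng, 1.0, 2.0, 100)
        res = overlap_delta4(s, s)
        assert res.value == 1.0
        assert res.classification == "high"

    def test_delta1_of_a_sample_with_itself_is_one_up_to_quadrature(self, rng):
        s = vm_sample(rng, 1.0, 2.0, 100)
        assert overlap_delta1(s, s).value == pytest.approx(1.0, abs=1e-6)

    def test_opposite_phase_concentrated_samples_barely_overlap(self, rng):
        s1 = vm_sample(rng, 0.0, 50.0, 300)
        s2 = vm_sample(rng, np.pi, 50.0, 300)
        assert overlap_delta1(s1, s2).value < 0.05
        assert overlap_delta4(s1, s2).value < 0.05

    def test_both_estimators_recover_the_quadrature_oracle(self, rng):
        m1 = ActivityModel((0.0,), (2.0,))
        m2 = ActivityModel((np.pi / 2,), (2.0,))
        truth = true_temporal_overlap(m1, m2)
        s1 = CircularSample(m1.sample(1000, rng))
        s2 = CircularSample(m2.sample(1000, rng))
        assert overlap_delta1(s1, s2).value == pytest.approx(truth, abs=0.05)
        assert overlap_delta4(s1, s2).value == pytest.approx(truth, abs=0.05)

    def test_symmetry_and_rotation_invariance(self, rng):
        s1 = vm_sample(rng, 0.5, 2.0, 150)
        s2 = vm_sample(rng, 2.5, 3.0, 150)
        d12 = overlap_delta4(s1, s2).value
        d21 = overlap_delta4(s2, s1).value
        assert d12 == pytest.approx(d21, abs=1e-12)
        rot = 1.234
        r1 = CircularSample(np.mod(s1.angles + rot, TWO_PI))
        r2 = CircularSample(np.mod(s2.angles + rot, TWO_PI))
        assert overlap_delta4(r1, r2).value == pytest.approx(d12, abs=1e-9)
        assert overlap_delta1(r1, r2).value == pytest.approx(
            overlap_delta1(s1, s2).value, abs=1e-3
        )

    def test_delta4_warns_for_small_samples(self, rng):
        s1 = vm_sample(rng, 0.0, 2.0, 40)
        s2 = vm_sample(rng, 1.0, 2.0, 40)
        with pytest.warns(UserWarning, match="recommended"):
            overlap_delta4(s1, s2)


@pytest.mark.parametrize(
    "delta, expected",
    [
        (0.39, "low"),
        (0.50, "low"),
        (0.51, "moderate"),
        (0.75, "moderate"),
        (0.76, "high"),
        (1.0, "high"),
        (0.0, "low"),
    ],
)
def test_overlap_classification_thresholds(delta, expected):
    assert classify_overlap(delta) == expected


def test_classification_rejects_out_of_range():
    with pytest.raises(DataError):
        classify_overlap(1.2)


class TestDielPeriods:
    @pytest.mark.parametrize(
        "clock, period",
        [
            ("12:00", "day"),
            ("06:00", "day"),
            ("18:29", "day"),
            ("18:30", "dusk"),
            ("19:00", "dusk"),
            ("20:30", "night"),
            ("21:00", "night"),
            ("03:59", "night"),
            ("04:00", "dawn"),
            ("05:00", "dawn"),
            ("05:59", "dawn"),
        ],
    )
    def test_boundary_assignments(self, clock, period):
        assert assign_diel_period(clock) == period

    def test_partition_covers_every_minute_exactly_once(self):
        tally = {"day": 0, "night": 0, "dawn": 0, "dusk": 0}
        for minute in range(1440):
            tally[assign_diel_period(minute)] += 1
        assert sum(tally.values()) == 1440
        assert tally == {"day": 750, "dusk": 120, "night": 450, "dawn": 120}


class TestActivityProfile:
    def test_point_mass_yields_single_peak_bin(self):
        from civetniche.temporal_overlap import activity_profile

        t = make_events([3 * 60] * 20)  # all detections at 03:00
        result = activity_profile(t, "sp", bin_hours=1.0)
        assert result["peaks"] == [(3.0, 4.0)]

    def test_uniform_times_flag_no_peak(self, rng):
        minutes = rng.integers(0, 1440, size=2000)
        t = make_events(list(minutes))
        from civetniche.temporal_overlap import activity_profile

        result = activity_profile(t, "sp", bin_hours=1.0)
        assert result["peaks"] == "no peak"

    def test_von_mises_night_activity_peaks_in_the_right_window(self, rng):
        # mean at 03:30 with moderate concentration
        mu = 3.5 / 24 * TWO_PI
        angles = np.mod(rng.vonmises(mu, 3.0, 1000), TWO_PI)
        minutes = angles / TWO_PI * 1440
        t = make_events(list(minutes))
        from civetniche.temporal_overlap import activity_profile

        result = activity_profile(t, "sp", bin_hours=1.0)
        counts = result["counts"]
        modal_bin = int(np.argmax(counts))
        assert 2 <= modal_bin <= 5
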