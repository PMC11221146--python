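"""Circular-statistics kernel: means, wrapped differences, von Mises, Watson U2."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ciliapol.circular import (
    AngularSample,
    circular_mean_resultant,
    kappa_for_mean_abs_deviation,
    vonmises_abs_deviation_expectation,
    vonmises_fit,
    vonmises_prob_within,
    watson_u2,
    wrap_difference,
)
from ciliapol.errors import InvalidParameterError


def brute_force_u2(a, b):
    """Independent double-loop CDF-difference implementation of Watson U2.

    Walks the combined sorted sample one point at a time, tracks the two
    empirical CDFs explicitly, and averages d within tie groups.
    """
    combined = sorted([(v, 0) for v in a] + [(v, 1) for v in b])
    n1, n2, n = len(a), len(b), len(a) + len(b)
    d = []
    c1 = c2 = 0
    for v, which in combined:
        if which == 0:
            c1 += 1
        else:
            c2 += 1
        d.append(c1 / n1 - c2 / n2)
    # mid-rank tie handling: every tied point shares its group's mean d
    d_tied = []
    i = 0
    while i < n:
        j = i
        while j < n and combined[j][0] == combined[i][0]:
            j += 1
        group_mean = sum(d[i:j]) / (j - i)
        d_tied.extend([group_mean] * (j - i))
        i = j
    dbar = sum(d_tied) / n
    return (n1 * n2) / n**2 * sum((x - dbar) ** 2 for x in d_tied)


class TestMeanResultant:
    def test_two_orthogonal_angles(self):
        mean, r = circular_mean_resultant(AngularSample([0.0, 90.0]))
        assert mean == pytest.approx(45.0)
        assert r == pytest.approx(math.cos(math.radians(45.0)))

    def test_symmetric_pair_about_zero(self):
        mean, _ = circular_mean_resultant(AngularSample([10.0, 350.0]))
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_balanced_sample_mean_undefined(self):
        mean, r = circular_mean_resultant(AngularSample([0.0, 120.0, 240.0]))
        assert r == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(mean)

    def test_axial_sample_uses_angle_doubling(self):
        # axes at 10 and 170 are 20 degrees apart through 0/180, mean axis 0
        mean, _ = circular_mean_resultant(AngularSample([10.0, 170.0], "axial_180"))
        assert mean == pytest.approx(0.0, abs=1e-9) or mean == pytest.approx(180.0)

    @given(
        st.lists(st.floats(0.0, 359.99), min_size=2, max_size=30),
        st.floats(-720.0, 720.0),
    )
    def test_mean_commutes_with_rotation(self, angles, offset):
        base = AngularSample(np.array(angles))
        m0, r0 = circular_mean_resultant(base)
        m1, r1 = circular_mean_resultant(base.rotated(offset))
        assert r1 == pytest.approx(r0, abs=1e-9)
        if not math.isnan(m0) and r0 > 1e-6:
            assert abs(wrap_difference(m1, m0 + offset)) < 1e-6


class TestWrapDifference:
    @pytest.mark.parametrize(
        "a,b,periodicity,expected",
        [
            (350.0, 10.0, "directional_360", -20.0),
            (10.0, 10.0, "directional_360", 0.0),
            (179.0, 1.0, "axial_180", -2.0),
            (0.0, 180.0, "directional_360", 180.0),  # half-period maps to +period/2
        ],
    )
    def test_hand_computed_cases(self, a, b, periodicity, expected):
        assert wrap_difference(a, b, periodicity) == pytest.approx(expected)

    @given(st.floats(-1000.0, 1000.0), st.floats(-1000.0, 1000.0))
    def test_antisymmetric_up_to_wrap(self, a, b):
        d1 = wrap_difference(a, b)
        d2 = wrap_difference(b, a)
        assert abs(d1) <= 180.0 and abs(d2) <= 180.0
        assert abs((d1 + d2) % 360.0) < 1e-6


class TestWatsonU2:
    def test_matches_brute_force_on_small_samples(self, rng):
        for trial in range(30):
            n1 = int(rng.integers(4, 11))
            n2 = int(rng.integers(4, 11))
            a = np.round(rng.uniform(0, 360, n1), 1)  # rounding induces ties
            b = np.round(rng.uniform(0, 360, n2), 1)
            res = watson_u2(AngularSample(a), AngularSample(b), n_permutations=5, seed=trial)
            assert res.u2 == pytest.approx(brute_force_u2(list(a), list(b)), abs=1e-12)

    def test_identical_samples_give_p_one(self, rng):
        angles = rng.uniform(0, 360, 25)
        res = watson_u2(
            AngularSample(angles), AngularSample(angles.copy()),
            n_permutations=99, seed=0,
        )
        assert res.p_permutation == 1.0
        assert res.u2 == pytest.approx(0.0, abs=1e-20)

    def test_invariant_under_common_rotation(self, rng):
        a = rng.uniform(0, 360, 20)
        b = rng.uniform(0, 360, 25)
        base = watson_u2(AngularSample(a), AngularSample(b), 5, seed=0).u2
        for offset in (13.7, 90.0, 301.2):
            rotated = watson_u2(
                AngularSample(a + offset), AngularSample(b + offset), 5, seed=0
            ).u2
            assert rotated == pytest.approx(base, abs=1e-10)

    def test_invariant_under_sample_exchange(self, rng):
        a = rng.uniform(0, 360, 12)
        b = rng.uniform(0, 360, 18)
        r1 = watson_u2(AngularSample(a), AngularSample(b), 5, seed=0)
        r2 = watson_u2(AngularSample(b), AngularSample(a), 5, seed=0)
        assert r1.u2 == pytest.approx(r2.u2, abs=1e-14)

    def test_power_against_shifted_von_mises(self):
        """mu 0 vs 90 at kappa=4, n=50: p < 0.001 in >= 99% of 200 replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            a = np.degrees(stats.vonmises.rvs(4.0, loc=0.0, size=50, random_state=rng))
            b = np.degrees(stats.vonmises.rvs(4.0, loc=np.pi / 2, size=50, random_state=rng))
            res = watson_u2(
                AngularSample(a % 360), AngularSample(b % 360),
                n_permutations=1999, seed=i,
            )
            hits += res.p_permutation < 0.001
        assert hits / n_rep >= 0.99

    def test_mismatched_periodicity_rejected(self):
        a = AngularSample([0.0, 10.0, 20.0, 30.0])
        b = AngularSample([0.0, 10.0, 20.0, 30.0], "axial_180")
        with pytest.raises(InvalidParameterError):
            watson_u2(a, b, 9, seed=0)

    def test_too_small_samples_rejected(self):
        with pytest.raises(InvalidParameterError):
            watson_u2(AngularSample([1.0, 2.0, 3.0]), AngularSample([1.0, 2.0, 3.0, 4.0]), 9, 0)

    def test_ties_reported_in_metadata(self):
        a = AngularSample([10.0, 10.0, 20.0, 30.0])
        b = AngularSample([10.0, 40.0, 50.0, 60.0])
        res = watson_u2(a, b, 9, seed=0)
        assert res.tie_fraction > 0.0


class TestVonMisesFit:
    def test_recovers_kappa_two(self, rng):
        angles = np.degrees(rng.vonmises(0.5, 2.0, size=1000)) % 360
        fit = vonmises_fit(AngularSample(angles))
        assert fit.kappa == pytest.approx(2.0, rel=0.10)
        assert abs(wrap_difference(fit.mu_deg, math.degrees(0.5))) < 10.0

    def test_agrees_with_scipy_mle(self, rng):
        theta = rng.vonmises(1.0, 3.0, size=500)
        kappa_scipy, _, _ = stats.vonmises.fit(theta, fscale=1)
        fit = vonmises_fit(AngularSample(np.degrees(theta) % 360))
        assert fit.kappa == pytest.approx(kappa_scipy, rel=0.02)

    def test_degenerate_concentration_capped(self, rng):
        angles = 30.0 + 1e-7 * rng.standard_normal(50)
        fit = vonmises_fit(AngularSample(angles))
        assert fit.capped and fit.kappa >= 1e6

    def test_uniform_sample_kappa_near_zero(self, rng):
        angles = rng.uniform(0, 360, 2000)
        fit = vonmises_fit(AngularSample(angles))
        assert fit.kappa < 0.1


class TestVonMisesIntegrals:
    def test_uniform_limits(self):
        assert vonmises_abs_deviation_expectation(0.0) == pytest.approx(90.0)
        assert vonmises_prob_within(0.0, 45.0) == pytest.approx(0.25)

    def test_prob_within_matches_scipy_cdf(self):
        for kappa in (0.5, 2.0, 8.0):
            b = math.radians(45.0)
            expected = stats.vonmises.cdf(b, kappa) - stats.vonmises.cdf(-b, kappa)
            assert vonmises_prob_within(kappa, 45.0) == pytest.approx(expected, abs=1e-9)

    def test_abs_deviation_matches_monte_carlo(self, rng):
        kappa = 5.0
        sample = np.abs(rng.vonmises(0.0, kappa, size=200_000))
        assert vonmises_abs_deviation_expectation(kappa) == pytest.approx(
            np.degrees(sample.mean()), rel=0.01
        )

    def test_mean_abs_deviation_inversion_round_trips(self):
        for target in (5.0, 10.0, 30.0):
            kappa = kappa_for_mean_abs_deviation(target)
            assert vonmises_abs_deviation_expectation(kappa) == pytest.approx(target, abs=1e-6)
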