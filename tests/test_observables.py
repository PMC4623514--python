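"""Correlation/structure profiles, lengths, scaling collapse, and fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrising import (
    CorrelationProfile,
    GrowthSeries,
    StructureProfile,
    correlation_field_2d,
    correlation_function,
    domain_length,
    growth_exponent,
    magnetization_curve,
    make_fixture,
    ojk_correlation,
    porod_tail_slope,
    scaling_collapse,
    structure_factor,
    structure_factor_2d,
)
from lrising.observables import OJK_HALF_X

from conftest import brute_force_pair_correlation


def ojk_profile(scale: float, r_max: int = 40) -> CorrelationProfile:
    r = np.arange(r_max + 1, dtype=float)
    return CorrelationProfile(
        r=r, C=ojk_correlation(r / scale), counts=np.ones_like(r, dtype=int)
    )


class TestCorrelation:
    def test_checkerboard_exact_shells(self):
        # alternating pattern: C = -1 at r = 1 and +1 at r = sqrt(2)
        prof = correlation_function([make_fixture("checkerboard", 4)], bins="exact")
        by_r = dict(zip(np.round(prof.r, 6), prof.C))
        assert by_r[0.0] == pytest.approx(1.0)
        assert by_r[1.0] == pytest.approx(-1.0)
        assert by_r[round(math.sqrt(2), 6)] == pytest.approx(1.0)

    def test_normalized_at_origin(self):
        prof = correlation_function([make_fixture("balanced_random", 64, seed=1)])
        assert prof.r[0] == 0.0
        assert prof.C[0] == 1.0

    def test_uncorrelated_spins_decay_immediately(self):
        prof = correlation_function([make_fixture("balanced_random", 128, seed=2)])
        assert np.all(np.abs(prof.C[prof.r >= 1]) < 0.05)

    def test_uniform_ensemble_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation_function([make_fixture("uniform_up", 16)])

    def test_matches_direct_pair_enumeration(self):
        """FFT autocorrelation against the O(N^2) pair sum on 8x8 lattices."""
        arrays = [
            make_fixture("balanced_random", 8, seed=s).spins.astype(float)
            for s in (0, 1, 2)
        ]
        direct = brute_force_pair_correlation(arrays)
        m = np.mean([a.mean() for a in arrays])
        expected = (direct - m * m) / (direct[0, 0] - m * m)
        np.testing.assert_allclose(correlation_field_2d(arrays), expected, atol=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            correlation_function(
                [make_fixture("balanced_random", 8, 0), make_fixture("balanced_random", 16, 0)]
            )


class TestStructureFactor:
    @pytest.mark.parametrize("kind,seed", [("balanced_random", 3), ("slab", 0)])
    def test_parseval_identity(self, kind, seed):
        snaps = [make_fixture(kind, 32, seed)]
        s2d = structure_factor_2d(snaps)
        prof = structure_factor(snaps)
        assert s2d.sum() == pytest.approx(32 * 32, abs=1e-9)
        assert prof.parseval_sum == pytest.approx(32 * 32, abs=1e-9)

    def test_checkerboard_peaks_at_zone_corner(self):
        s2d = structure_factor_2d([make_fixture("checkerboard", 8)])
        assert np.unravel_index(np.argmax(s2d), s2d.shape) == (4, 4)  # (pi, pi)

    def test_white_noise_is_flat(self):
        snaps = [make_fixture("balanced_random", 64, seed=s) for s in range(20)]
        prof = structure_factor(snaps)
        interior = prof.S[prof.k > 0]
        assert np.all(np.abs(interior - 1.0) < 0.35)


class TestDomainLength:
    def test_exponential_profile(self):
        r = np.arange(31, dtype=float)
        prof = CorrelationProfile(r=r, C=np.exp(-r / 5.0), counts=np.ones_like(r, int))
        assert domain_length(prof) == pytest.approx(5 * math.log(2), abs=0.05)

    def test_ojk_profile_half_height(self):
        # OJK(r/10) = 1/2 at r = 10 * sqrt(ln(2)/2) = 5.887
        assert domain_length(ojk_profile(10.0)) == pytest.approx(5.887, abs=0.06)

    def test_no_crossing_raises(self):
        r = np.arange(10, dtype=float)
        prof = CorrelationProfile(r=r, C=np.ones_like(r), counts=np.ones_like(r, int))
        with pytest.raises(ValueError, match="never drops"):
            domain_length(prof)

    def test_monotone_in_level(self):
        prof = ojk_profile(12.0)
        lengths = [domain_length(prof, level) for level in (0.2, 0.4, 0.6, 0.8)]
        assert np.all(np.diff(lengths) < 0)

    @given(scale=st.floats(min_value=1.5, max_value=8.0))
    def test_invariant_under_consistent_axis_rescaling(self, scale):
        prof = ojk_profile(10.0, r_max=60)
        stretched = CorrelationProfile(
            r=prof.r * scale, C=prof.C, counts=prof.counts
        )
        assert domain_length(stretched) == pytest.approx(
            scale * domain_length(prof), rel=1e-9
        )


class TestOJK:
    def test_limits(self):
        assert ojk_correlation(0.0) == pytest.approx(1.0)
        assert ojk_correlation(8.0) < 1e-10

    def test_reference_value(self):
        assert ojk_correlation(1.0) == pytest.approx(0.2398, abs=2e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ojk_correlation(-0.1)

    def test_half_height_constant(self):
        assert ojk_correlation(OJK_HALF_X) == pytest.approx(0.5, rel=1e-12)


class TestGrowthExponent:
    @pytest.mark.parametrize("prefactor,phi", [(3.0, 0.5), (2.0, 1.0)])
    def test_exact_power_law(self, prefactor, phi):
        t = np.array([10.0, 20.0, 50.0, 100.0, 400.0])
        series = GrowthSeries(times=t, lengths=prefactor * t**phi)
        fitted, stderr = growth_exponent(series)
        assert fitted == pytest.approx(phi, abs=1e-12)
        assert stderr == pytest.approx(0.0, abs=1e-10)
        assert series.prefactor == pytest.approx(prefactor)

    def test_fit_window_selects_points(self):
        t = np.arange(1.0, 21.0)
        L = 2.0 * np.sqrt(t)
        L[:5] = 1.0  # corrupted early transient excluded by the window
        series = GrowthSeries(times=t, lengths=L)
        phi, _ = growth_exponent(series, fit_window=(6.0, 20.0))
        assert phi == pytest.approx(0.5, abs=1e-9)

    def test_too_few_points(self):
        series = GrowthSeries(times=np.array([1.0, 2.0, 3.0]), lengths=np.ones(3))
        with pytest.raises(ValueError, match=">= 4"):
            growth_exponent(series)

    def test_nonpositive_rejected(self):
        series = GrowthSeries(
            times=np.array([1.0, 2.0, 3.0, 4.0]), lengths=np.array([1.0, 2.0, -1.0, 3.0])
        )
        with pytest.raises(ValueError):
            growth_exponent(series)


class TestScalingCollapse:
    def test_exact_self_similar_profiles_collapse(self):
        profiles = [ojk_profile(scale, r_max=60) for scale in (5.0, 10.0, 20.0)]
        report = scaling_collapse(profiles)
        assert report.rms_pairwise_dev < 0.01
        assert report.max_pairwise_dev < 0.03
        assert report.rms_vs_ojk < 0.01

    def test_needs_two_profiles(self):
        with pytest.raises(ValueError):
            scaling_collapse([ojk_profile(5.0)])

    def test_structure_collapse_requires_lengths(self):
        k = np.linspace(0.01, 3.0, 600)
        profs = [
            StructureProfile(k=k, S=L**2 / (1 + (k * L) ** 3), counts=np.ones_like(k, int))
            for L in (5.0, 10.0)
        ]
        with pytest.raises(ValueError, match="lengths"):
            scaling_collapse(profs, kind="structure")
        report = scaling_collapse(profs, lengths=[5.0, 10.0], kind="structure")
        # exact scaling form by construction; deviation is interpolation error
        assert report.rms_pairwise_dev < 0.01
        assert report.rms_vs_ojk is None


class TestPorod:
    def test_exact_power_tail(self):
        k = np.linspace(0.2, 2.0, 30)
        prof = StructureProfile(k=k, S=k**-3.0, counts=np.ones_like(k, int))
        slope, stderr = porod_tail_slope(prof, (0.2, 2.0))
        assert slope == pytest.approx(-3.0, abs=1e-12)

    def test_noisy_power_tail(self):
        rng = np.random.default_rng(6)
        k = np.linspace(0.2, 2.0, 30)
        S = k**-3.0 * (1.0 + 0.01 * rng.standard_normal(k.size))
        prof = StructureProfile(k=k, S=S, counts=np.ones_like(k, int))
        slope, _ = porod_tail_slope(prof, (0.2, 2.0))
        assert slope == pytest.approx(-3.0, abs=0.05)

    def test_window_too_small(self):
        k = np.linspace(0.2, 2.0, 30)
        prof = StructureProfile(k=k, S=k**-3.0, counts=np.ones_like(k, int))
        with pytest.raises(ValueError):
            porod_tail_slope(prof, (0.2, 0.25))


class TestMagnetizationCurve:
    def test_sigmoid_drop_and_susceptibility_peak(self):
        rng = np.random.default_rng(11)
        temps = np.array([1.0, 2.0, 3.0, 4.0])
        # ordered, critical (large fluctuations), disordered, disordered
        blocks = [
            0.95 + 0.01 * rng.standard_normal(50),
            0.5 + 0.3 * rng.standard_normal(50),
            0.05 * rng.standard_normal(50),
            0.03 * rng.standard_normal(50),
        ]
        T, mean_abs, chi, t_c = magnetization_curve(temps, blocks, n_sites=1024)
        assert mean_abs[0] > 0.9 > mean_abs[2]
        assert t_c == 2.0  # fluctuation-dominated block

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            magnetization_curve([2.0, 1.0], [np.ones(3), np.ones(3)], 16)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            magnetization_curve([1.0, 2.0], [np.ones(3), np.array([])], 16)
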