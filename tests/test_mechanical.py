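"""Mechanical moduli: K_A, Boltzmann inversion, tilt and splay fits, KC_eff."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_h

from ipabilayer import IPAComposition, SyntheticSpec, generate_trajectory
from ipabilayer import mechanical as mech
from ipabilayer import structural as st
from ipabilayer import synthetic as syn
from ipabilayer.constants import area_variance_for_ka, rt


class TestAreaExpansionModulus:
    def test_closed_form_unit_conversion(self):
        # <A>=28.8 nm^2, N=64, var=2.65e-3 nm^4, T=298 K -> 698.7 mN/m
        series = st.AreaSeries(np.array([28.8 - math.sqrt(2.65e-3),
                                         28.8 + math.sqrt(2.65e-3)]), 64)
        assert series.variance == pytest.approx(2.65e-3)
        assert mech.area_expansion_modulus(series, 298.0) == pytest.approx(
            698.66, abs=0.5
        )

    def test_inverse_proportional_to_variance(self):
        base = np.array([28.0, 28.4, 29.2, 28.8])
        s1 = st.AreaSeries(base, 64)
        scaled = 28.85 + (base - base.mean()) * math.sqrt(2.0)
        s2 = st.AreaSeries(scaled - scaled.mean() + base.mean(), 64)
        k1 = mech.area_expansion_modulus(s1)
        k2 = mech.area_expansion_modulus(s2)
        assert k2 == pytest.approx(k1 / 2.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroDivisionError, match="infinite"):
            mech.area_expansion_modulus(st.AreaSeries(np.full(5, 28.8), 64))

    @pytest.mark.parametrize("ka_target", [300.0, 1500.0])
    def test_generator_recovery(self, ka_target):
        spec = SyntheticSpec(
            composition=IPAComposition(10, 10), n_per_leaflet=64,
            n_frames=20_000, mean_area=28.8,
            area_variance=area_variance_for_ka(ka_target, 28.8, 64), seed=31,
        )
        areas = syn.sample_area_series(spec, np.random.default_rng(spec.seed))
        est = mech.area_expansion_modulus(st.AreaSeries(areas, 64))
        assert est == pytest.approx(ka_target, rel=0.05)


class TestBoltzmannInversion:
    def test_sin_distribution_inverts_to_flat(self):
        centers = np.arange(0.5, 90.0, 1.0)
        p = np.sin(np.radians(centers))
        dist = st.TiltDistribution(centers, p / p.sum(), 1.0)
        pmf = mech.boltzmann_invert(dist)
        assert pmf.free_energy.max() < 1e-9 * rt()

    def test_single_occupied_bin(self):
        centers = np.arange(0.5, 90.0, 1.0)
        p = np.zeros_like(centers)
        p[30] = 1.0
        pmf = mech.boltzmann_invert(st.TiltDistribution(centers, p, 1.0))
        assert pmf.bin_centers.tolist() == [centers[30]]
        assert pmf.free_energy[0] == 0.0

    def test_round_trip_recovers_histogram(self):
        rng = np.random.default_rng(5)
        centers = np.arange(0.5, 90.0, 1.0)
        p = np.sin(np.radians(centers)) * rng.uniform(0.5, 1.5, centers.size)
        p /= p.sum()
        dist = st.TiltDistribution(centers, p, 1.0)
        pmf = mech.boltzmann_invert(dist)
        # exp/log inverse: rebuilding P from F recovers occupied bins to round-off
        rebuilt = mech.reconstruct_distribution(pmf)
        assert np.allclose(rebuilt, p, rtol=1e-12)

    def test_analytic_quadratic_oracle(self):
        # P ~ sin(theta) exp(-c (theta-theta0)^2 / 2RT) inverts to the parabola
        centers = np.arange(0.5, 90.0, 1.0)
        c, theta0 = 50.0, 30.0
        p = syn.tilt_density(centers, theta0, c)
        p /= p.sum()
        pmf = mech.boltzmann_invert(st.TiltDistribution(centers, p, 1.0))
        expected = 0.5 * c * (pmf.bin_centers - theta0) ** 2
        expected -= expected.min()
        assert np.allclose(pmf.free_energy, expected, atol=1e-6)

    def test_empty_histogram_errors(self):
        dist = st.TiltDistribution(np.arange(0.5, 90.0, 1.0),
                                   np.zeros(90), 1.0)
        with pytest.raises(ValueError):
            mech.boltzmann_invert(dist)

    def test_multiply_convention_available(self):
        centers = np.arange(10.5, 80.0, 1.0)
        p = np.full(centers.size, 1.0 / centers.size)
        dist = st.TiltDistribution(centers, p, 1.0)
        f_div = mech.boltzmann_invert(dist, jacobian="divide")
        f_mul = mech.boltzmann_invert(dist, jacobian="multiply")
        assert not np.allclose(f_div.free_energy, f_mul.free_energy)


class TestTiltModulus:
    def test_exact_parabola(self):
        theta = np.arange(5.0, 60.0, 1.0)
        F = 0.5 * 50.0 * (theta - 30.0) ** 2
        fit = mech.tilt_modulus(mech.PMFProfile(theta, F, 1.0))
        assert fit.chi == pytest.approx(50.0, rel=1e-9)
        assert fit.theta0 == pytest.approx(30.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_profile_gives_zero(self):
        theta = np.arange(5.0, 60.0, 1.0)
        fit = mech.tilt_modulus(mech.PMFProfile(theta, np.zeros_like(theta), 1.0))
        assert fit.chi == pytest.approx(0.0, abs=1e-9)

    def test_window_restricted_to_2RT(self):
        theta = np.arange(0.5, 90.0, 1.0)
        F = 0.5 * 50.0 * (theta - 30.0) ** 2
        fit = mech.tilt_modulus(mech.PMFProfile(theta, F, 1.0))
        lo, hi = fit.window
        assert 0.5 * 50.0 * (lo - 1 - 30.0) ** 2 > 2 * rt()
        assert 0.5 * 50.0 * (hi + 1 - 30.0) ** 2 > 2 * rt()

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            mech.tilt_modulus(
                mech.PMFProfile(np.array([1.0, 2.0]), np.array([0.0, 1.0]), 1.0)
            )

    def test_sampled_recovery_moderate_size(self, rng):
        th = syn.sample_tilt_angles(100_000, 20.0, 40.0, rng)
        fit = mech.tilt_modulus_from_samples(th)
        assert fit.chi == pytest.approx(40.0, rel=0.1)
        assert fit.theta0 == pytest.approx(20.0, abs=1.0)


@pytest.fixture(scope="module")
def stiff_traj():
    spec = SyntheticSpec(
        composition=IPAComposition(10, 10), n_per_leaflet=16, n_frames=10,
        tilt_theta0=0.0, tilt_chi=1e6, p_gauche=0.0, seed=6,
        mean_area=0.45 * 16, area_variance=1e-6,
    )
    return generate_trajectory(spec)[0]


class TestSplay:
    def test_parallel_and_antiparallel_directors(self):
        v = np.array([[0.0, 0.0, 1.0]])
        cos_par = np.clip(np.dot(v[0], v[0]), -1, 1)
        assert math.degrees(math.acos(cos_par)) == pytest.approx(0.0)
        cos_anti = np.clip(np.dot(v[0], -v[0]), -1, 1)
        assert math.degrees(math.acos(cos_anti)) == pytest.approx(180.0)

    def test_stiff_limit_all_small_angles(self, stiff_traj):
        samples = mech.splay_angles(stiff_traj, cutoff=1.0)
        pooled = np.concatenate([v for v in samples.samples.values() if v.size])
        assert pooled.size > 0
        assert pooled.max() < 2.0

    def test_pair_types_present_and_counted(self, stiff_traj):
        samples = mech.splay_angles(stiff_traj, cutoff=1.5)
        assert set(samples.samples) == {"++", "--", "+-"}
        assert all(n > 0 for n in samples.phi.values())

    def test_identical_distributions_give_equal_moduli(self, rng):
        ang = syn.sample_tilt_angles(50_000, 10.0, 100.0, rng)
        samples = mech.SplaySamples({pt: ang for pt in mech.PAIR_TYPES})
        result = mech.splay_modulus(samples)
        vals = list(result.chi.values())
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_analytic_curvature_oracle(self):
        # analytic binned distribution with curvature c, inverted and fit,
        # then converted to kBT/rad^2
        from ipabilayer.constants import molar_deg2_to_kbt_rad2

        centers = np.arange(0.5, 180.0, 1.0)
        c = 30.0
        p = np.sin(np.radians(centers)) * np.exp(
            -c * (centers - 20.0) ** 2 / (2 * rt())
        )
        counts = np.round(p / p.sum() * 1e9).astype(int)
        # fake samples via direct histogram injection
        dist = st.TiltDistribution(centers, counts / counts.sum(), 1.0)
        pmf = mech.boltzmann_invert(dist)
        fit = mech.tilt_modulus(pmf)
        assert molar_deg2_to_kbt_rad2(fit.chi) == pytest.approx(
            molar_deg2_to_kbt_rad2(c), rel=0.01
        )

    def test_delta_distribution_flagged_stiff(self):
        samples = mech.SplaySamples(
            {"++": np.full(100, 5.2), "--": np.empty(0), "+-": np.empty(0)}
        )
        with pytest.warns(UserWarning):
            result = mech.splay_modulus(samples)
        assert math.isinf(result.chi["++"])


class TestEffectiveBendingRigidity:
    def test_constant_moduli(self):
        chi = {"++": 25.0, "--": 25.0, "+-": 25.0}
        phi = {"++": 10, "--": 3, "+-": 7}
        assert mech.effective_bending_rigidity(chi, phi) == pytest.approx(25.0)

    def test_equal_weights_harmonic_mean(self):
        assert mech.effective_bending_rigidity(
            {"++": 20.0, "--": 60.0}, {"++": 1, "--": 1}
        ) == pytest.approx(30.0)

    def test_weighted_harmonic_mean(self):
        assert mech.effective_bending_rigidity(
            {"++": 20.0, "--": 60.0}, {"++": 3, "--": 1}
        ) == pytest.approx(24.0)

    @given(
        st_h.lists(st_h.floats(1.0, 200.0), min_size=2, max_size=3),
        st_h.lists(st_h.integers(1, 1000), min_size=3, max_size=3),
    )
    def test_bounded_and_permutation_invariant(self, chis, phis):
        chis = (chis + chis)[:3]
        chi = dict(zip(mech.PAIR_TYPES, chis))
        phi = dict(zip(mech.PAIR_TYPES, phis))
        kc = mech.effective_bending_rigidity(chi, phi)
        assert min(chis) - 1e-9 <= kc <= max(chis) + 1e-9
        # permute labels jointly: result unchanged
        perm = {"++": "--", "--": "+-", "+-": "++"}
        chi_p = {perm[k]: v for k, v in chi.items()}
        phi_p = {perm[k]: v for k, v in phi.items()}
        assert mech.effective_bending_rigidity(chi_p, phi_p) == pytest.approx(kc)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mech.effective_bending_rigidity({"++": -1.0}, {"++": 5})
        with pytest.raises(ValueError):
            mech.effective_bending_rigidity({"++": 10.0}, {"++": 0})
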