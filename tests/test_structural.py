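"""Structural observables: areas, density profiles, tilt, S_CD, gauche."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_h

from ipabilayer import IPAComposition, SyntheticSpec, generate_trajectory
from ipabilayer import structural as st
from ipabilayer import synthetic as syn


class TestAreaPerIPA:
    def test_direct_division(self):
        series = st.AreaSeries(np.full(10, 28.8), 64)
        assert st.area_per_ipa(series) == pytest.approx(0.45)

    def test_reference_value(self):
        series = st.AreaSeries(np.full(5, 27.2), 64)
        assert st.area_per_ipa(series) == pytest.approx(0.425)

    def test_alternating_series(self):
        series = st.AreaSeries(np.array([28.0, 30.0] * 8), 64)
        assert st.area_per_ipa(series) == pytest.approx(29.0 / 64.0)

    @given(st_h.floats(0.5, 4.0))
    def test_linear_scaling(self, factor):
        base = np.array([27.0, 28.0, 29.0])
        a1 = st.area_per_ipa(st.AreaSeries(base, 64))
        a2 = st.area_per_ipa(st.AreaSeries(base * factor, 64))
        assert a2 == pytest.approx(factor * a1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.area_per_ipa(st.AreaSeries(np.array([28.0]), 0))
        with pytest.raises(ValueError):
            st.AreaSeries(np.array([-1.0]), 64)


@pytest.fixture(scope="module")
def offset_traj():
    spec = SyntheticSpec(
        composition=IPAComposition(10, 10), n_per_leaflet=16, n_frames=30,
        head_plane_offset=0.3, head_plane_z=2.0, seed=8,
        mean_area=0.45 * 16, area_variance=1e-4,
    )
    return generate_trajectory(spec)[0]


class TestDensityProfile:
    def test_peaks_at_head_planes(self, offset_traj):
        prof = st.density_profile(offset_traj, ("N",), 0.05)
        up = prof.peak_position("N", "upper")
        lo = prof.peak_position("N", "lower")
        assert up == pytest.approx(2.0, abs=0.1)
        assert lo == pytest.approx(-2.0, abs=0.1)

    def test_integrates_to_atom_count(self, offset_traj):
        prof = st.density_profile(offset_traj, ("N", "S"), 0.05)
        for sp in ("N", "S"):
            total = prof.densities[sp].sum() * prof.bin_width
            assert total == pytest.approx(offset_traj.n_molecules)

    def test_head_alignment_offset_recovers_ground_truth(self, offset_traj):
        prof = st.density_profile(offset_traj, ("N", "S"), 0.05)
        offset, unc = st.head_alignment_offset(prof)
        assert unc == 0.05
        assert offset == pytest.approx(0.3, abs=0.05)

    def test_coincident_planes_give_zero_offset(self, small_trajectory):
        traj, _ = small_trajectory
        prof = st.density_profile(traj, ("N", "S"), 0.05)
        offset, _ = st.head_alignment_offset(prof)
        assert abs(offset) <= 0.05 + 1e-12

    def test_translation_invariance(self, offset_traj):
        shifted_coords = offset_traj.coordinates + np.array([0.0, 0.0, 3.0])
        from ipabilayer.model import Trajectory

        shifted = Trajectory(
            shifted_coords, offset_traj.boxes, offset_traj.times,
            offset_traj.molecules, offset_traj.composition,
            offset_traj.n_per_leaflet,
        )
        p1 = st.density_profile(offset_traj, ("N",), 0.05)
        p2 = st.density_profile(shifted, ("N",), 0.05)
        assert np.allclose(p1.densities["N"], p2.densities["N"])

    def test_bad_inputs(self, offset_traj):
        with pytest.raises(ValueError):
            st.density_profile(offset_traj, ("N",), -0.1)
        prof = st.density_profile(offset_traj, ("N",), 0.05)
        with pytest.raises(ValueError):
            st.head_alignment_offset(prof)  # missing S


class TestTiltAngles:
    def test_vertical_chains_measure_zero_both_leaflets(self):
        # all-trans chains oriented along the normal in both leaflets
        chains = syn.chains_from_dihedrals(np.full((4, 9), 180.0))
        for sign in (1.0, -1.0):
            oriented, _ = syn._orient_chains(
                chains, np.zeros(4), np.zeros(4), np.zeros(4), sign
            )
            tilt = st.fold_tilt(oriented[:, -2] - oriented[:, 0])
            assert np.allclose(tilt, 0.0, atol=1e-6)

    def test_stiff_generator_recovers_theta0(self):
        spec = SyntheticSpec(
            composition=IPAComposition(10, 10), n_per_leaflet=16, n_frames=50,
            tilt_theta0=30.0, tilt_chi=5000.0, p_gauche=0.0, seed=4,
            mean_area=0.45 * 16, area_variance=1e-4,
        )
        traj, _ = generate_trajectory(spec)
        samples = st.tilt_angles(traj)
        assert samples.pooled().mean() == pytest.approx(30.0, abs=1.0)

    def test_distribution_normalized_and_single_bin_delta(self):
        dist = st.tilt_distribution(np.full(100, 33.3), bin_width=1.0)
        assert dist.probabilities.sum() == pytest.approx(1.0)
        assert dist.probabilities.max() == pytest.approx(1.0)

    def test_uniform_directors_give_sin_shape(self, rng):
        # isotropic directors folded to [0, 90]: P(theta) ~ sin(theta)
        v = rng.normal(size=(200_000, 3))
        tilt = st.fold_tilt(v)
        dist = st.tilt_distribution(tilt, bin_width=2.0)
        expected = np.sin(np.radians(dist.bin_centers))
        expected = expected / expected.sum()
        mask = dist.bin_centers > 10.0
        ratio = dist.probabilities[mask] / expected[mask]
        assert np.abs(ratio - 1.0).max() < 0.1

    def test_xy_rotation_invariance(self, small_trajectory):
        traj, _ = small_trajectory
        c, s = math.cos(0.7), math.sin(0.7)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        from ipabilayer.model import Trajectory

        rotated = Trajectory(
            traj.coordinates @ rot.T, traj.boxes, traj.times,
            traj.molecules, traj.composition, traj.n_per_leaflet,
        )
        t1 = st.tilt_angles(traj, "cation")["cation"]
        t2 = st.tilt_angles(rotated, "cation")["cation"]
        assert np.allclose(t1, t2, atol=1e-8)


class TestScd:
    def test_all_trans_vertical_is_exactly_minus_half(self):
        chains = syn.chains_from_dihedrals(np.full((2, 13), 180.0))
        oriented, _ = syn._orient_chains(
            chains, np.zeros(2), np.zeros(2), np.array([0.0, 1.3]), 1.0
        )
        prof = st.scd_from_chain_coords(oriented)
        assert np.allclose(prof.values, -0.5, atol=1e-12)
        assert list(prof.carbons) == list(range(2, 16))

    def test_tilted_all_trans_matches_azimuthal_oracle(self):
        # numeric oracle: average S_CD over a uniform spin grid equals
        # -1/2 * P2(cos(theta)) by the spherical-harmonic addition theorem
        theta = 30.0
        n_spin = 360
        chains = syn.chains_from_dihedrals(np.full((n_spin, 13), 180.0))
        spins = np.linspace(0.0, 2 * math.pi, n_spin, endpoint=False)
        oriented, _ = syn._orient_chains(
            chains, np.full(n_spin, theta), np.zeros(n_spin), spins, 1.0
        )
        prof = st.scd_from_chain_coords(oriented)
        analytic = -0.5 * 0.5 * (3 * math.cos(math.radians(theta)) ** 2 - 1)
        assert np.allclose(prof.values, analytic, atol=1e-3)

    def test_isotropic_chains_average_to_zero(self, rng):
        from scipy.spatial.transform import Rotation

        chain = syn.chains_from_dihedrals(np.full((1, 9), 180.0))[0]
        rots = Rotation.random(20_000, rng=rng).as_matrix()
        coords = np.einsum("kij,lj->kli", rots, chain)
        prof = st.scd_from_chain_coords(coords)
        assert np.abs(prof.values).max() < 0.02

    def test_bounds_invariant(self, small_trajectory):
        traj, _ = small_trajectory
        for ct in ("cation", "anion"):
            prof = st.scd_profile(traj, ct)
            assert np.all(prof.values >= -0.5 - 1e-12)
            assert np.all(prof.values <= 1.0 + 1e-12)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            st.scd_from_chain_coords(np.zeros((1, 2, 3)))


class TestGauche:
    def test_explicit_sequence(self):
        chain = syn.chains_from_dihedrals(np.array([[180.0, 60.0, -60.0, 175.0]]))
        frac = st.is_gauche(st.dihedral_angles(chain)).mean()
        assert frac == 0.5

    def test_boundary_counts_as_trans(self):
        assert not st.is_gauche(np.array([120.0, -120.0])).any()
        assert st.is_gauche(np.array([119.999, -119.999])).all()

    def test_zero_gauche_trajectory(self):
        spec = SyntheticSpec(
            composition=IPAComposition(10, 10), n_per_leaflet=4, n_frames=10,
            p_gauche=0.0, seed=2, mean_area=0.45 * 4,
        )
        traj, _ = generate_trajectory(spec)
        for ct in ("cation", "anion"):
            stats = st.gauche_fractions(traj, ct)
            assert np.all(stats.fractions == 0.0)

    def test_binomial_recovery(self, small_trajectory):
        traj, gt = small_trajectory
        p = gt.spec.p_gauche
        stats = st.gauche_fractions(traj, "cation")
        sigma = math.sqrt(p * (1 - p) / stats.counts[0])
        assert np.all(np.abs(stats.fractions - p) < 4 * sigma)

    def test_fractions_bounded(self, small_trajectory):
        traj, _ = small_trajectory
        stats = st.gauche_fractions(traj, "anion")
        assert np.all((stats.fractions >= 0) & (stats.fractions <= 1))


class TestMiddleSegment:
    def test_window_for_asymmetric_compositions(self):
        # shorter chain sets the window upper bound
        comp = IPAComposition(14, 16)
        per_carbon = {c: float(c) for c in range(2, 16)}
        # carbons 2..14 -> mean of 2..14
        assert st.middle_segment_average(per_carbon, comp) == pytest.approx(8.0)
        comp2 = IPAComposition(12, 16)
        assert st.middle_segment_average(per_carbon, comp2) == pytest.approx(7.0)

    def test_cap_at_last_computable_carbon(self):
        comp = IPAComposition(14, 14)
        per_carbon = {c: 1.0 for c in range(2, 14)}  # S_CD stops at L-1 = 13
        assert st.middle_segment_average(per_carbon, comp) == pytest.approx(1.0)

    def test_uniform_profile_returns_constant(self):
        comp = IPAComposition(12, 12)
        both = {"cation": {c: 0.3 for c in range(2, 12)},
                "anion": {c: 0.3 for c in range(2, 12)}}
        assert st.middle_segment_average(both, comp) == pytest.approx(0.3)

    def test_two_chain_average(self):
        comp = IPAComposition(10, 10)
        both = {"cation": {c: 0.2 for c in range(2, 10)},
                "anion": {c: 0.4 for c in range(2, 10)}}
        assert st.middle_segment_average(both, comp) == pytest.approx(0.3)

    def test_empty_segment_errors(self):
        with pytest.raises(ValueError):
            st.middle_segment_average({}, IPAComposition(10, 10))
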