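"""RMSF, quasiharmonic entropy, superposition invariance, and SASA."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import piezorho as pz
from piezorho.thermo import KB_J
from piezorho.trajectory import CA_MASS_AMU, shrake_rupley_sasa


@pytest.fixture(scope="module")
def harmonic():
    spec = pz.EnsembleSimSpec(seed=4, n_frames=10_000, n_atoms=20,
                              force_constants=2.0)
    return pz.simulate_harmonic_trajectory(spec)


def rotate_translate(traj, seed=0):
    rng = np.random.default_rng(seed)
    R = Rotation.from_euler("xyz", rng.uniform(-np.pi, np.pi, 3)).as_matrix()
    shift = rng.uniform(-10, 10, 3)
    return pz.CoordinateTrajectory(coords=traj.coords @ R.T + shift,
                                   masses=traj.masses,
                                   residue_ids=traj.residue_ids)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        coords = np.tile(np.arange(30.0).reshape(10, 3), (5, 1, 1))
        traj = pz.CoordinateTrajectory(coords=coords, masses=np.full(10, CA_MASS_AMU),
                                       residue_ids=np.arange(33, 43))
        assert pz.rmsf_profile(traj).max() == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self, harmonic):
        """RMSF -> sigma*sqrt(3); exact check without superposition (the
        generator has no rigid-body motion), 2% with the default pipeline
        at a larger atom count."""
        traj, truth = harmonic
        prof = pz.rmsf_profile(traj, superpose_frames=False)
        assert prof.to_numpy() == pytest.approx(truth.rmsf, rel=0.05)
        assert prof.mean() == pytest.approx(truth.rmsf.mean(), rel=0.02)

    def test_default_pipeline_recovery_at_scale(self):
        spec = pz.EnsembleSimSpec(seed=9, n_frames=6000, n_atoms=100,
                                  force_constants=2.0)
        traj, truth = pz.simulate_harmonic_trajectory(spec)
        prof = pz.rmsf_profile(traj)  # superposition on
        assert prof.mean() == pytest.approx(truth.rmsf.mean(), rel=0.02)

    def test_rotation_translation_invariance(self, harmonic):
        traj, _ = harmonic
        moved = rotate_translate(traj, seed=1)
        p1, p2 = pz.rmsf_profile(traj), pz.rmsf_profile(moved)
        assert np.abs(p1.to_numpy() - p2.to_numpy()).max() < 1e-10

    def test_default_window_is_helix_range(self):
        spec = pz.EnsembleSimSpec(seed=2, n_frames=50, n_atoms=400,
                                  force_constants=2.0, first_residue=1)
        traj, _ = pz.simulate_harmonic_trajectory(spec)
        prof = pz.rmsf_profile(traj)
        assert prof.index.min() == 33 and prof.index.max() == 322
        assert pz.HELIX_WINDOW == (33, 322)

    def test_empty_selection_rejected(self, harmonic):
        traj, _ = harmonic
        with pytest.raises(ValueError, match="does not intersect"):
            pz.rmsf_profile(traj, residue_range=(4000, 5000))

    def test_delta_rmsf_detects_stiffening(self):
        soft = pz.simulate_harmonic_trajectory(
            pz.EnsembleSimSpec(seed=6, n_frames=3000, n_atoms=30,
                               force_constants=1.0))[0]
        stiff = pz.simulate_harmonic_trajectory(
            pz.EnsembleSimSpec(seed=7, n_frames=3000, n_atoms=30,
                               force_constants=4.0))[0]
        per_res, mean = pz.delta_rmsf(stiff, soft)
        assert mean < 0
        assert (per_res < 0).all()

    def test_condition_mismatch_rejected(self, harmonic):
        traj, _ = harmonic
        other = pz.simulate_harmonic_trajectory(
            pz.EnsembleSimSpec(seed=8, n_frames=100, n_atoms=10,
                               force_constants=2.0, first_residue=50))[0]
        with pytest.raises(ValueError, match="differ"):
            pz.delta_rmsf(traj, other)


class TestQuasiharmonicEntropy:
    def test_frozen_modes_give_zero_entropy(self):
        coords = np.tile(np.arange(30.0).reshape(10, 3), (50, 1, 1))
        traj = pz.CoordinateTrajectory(coords=coords, masses=np.full(10, CA_MASS_AMU),
                                       residue_ids=np.arange(33, 43))
        with pytest.warns(UserWarning):
            assert pz.quasiharmonic_entropy(traj) == 0.0

    def test_one_dimensional_oscillator_analytic_oracle(self):
        """Samples of a 1-D oscillator reproduce the quantum harmonic
        oscillator entropy at omega = sqrt(k/m)."""
        rng = np.random.default_rng(5)
        k_kcal, m_amu, T = 3.0, CA_MASS_AMU, 300.0
        kbt_kcal = KB_J * T * 6.02214076e23 / 4184.0
        x = rng.standard_normal(20_000) * math.sqrt(kbt_kcal / k_kcal)
        coords = np.zeros((20_000, 1, 3))
        coords[:, 0, 0] = x
        traj = pz.CoordinateTrajectory(coords=coords, masses=np.array([m_amu]),
                                       residue_ids=np.array([33]))
        with pytest.warns(UserWarning):  # two zero-variance axes dropped
            S = pz.quasiharmonic_entropy(traj, superpose_frames=False,
                                         drop_rigid_modes=0)
        k_si = k_kcal * 4184.0 / 6.02214076e23 / 1e-20  # J/m^2
        omega = math.sqrt(k_si / (m_amu * 1.66053906660e-27))
        S_exact = pz.harmonic_oscillator_entropy(np.array([omega]), T)
        assert S == pytest.approx(S_exact, rel=0.02)

    def test_sampled_spectrum_matches_analytic_truth(self, harmonic):
        traj, truth = harmonic
        S = pz.quasiharmonic_entropy(traj, superpose_frames=False,
                                     drop_rigid_modes=0)
        assert S == pytest.approx(truth.entropy, rel=0.02)

    def test_rotation_translation_invariance(self, harmonic):
        traj, _ = harmonic
        moved = rotate_translate(traj, seed=3)
        S1 = pz.quasiharmonic_entropy(traj)
        S2 = pz.quasiharmonic_entropy(moved)
        assert S1 == pytest.approx(S2, abs=1e-10)

    def test_entropy_increases_with_fluctuation_scale(self, harmonic):
        """Scaling all fluctuations up scales every eigenvalue up, so the
        entropy must not decrease."""
        traj, _ = harmonic
        mean = traj.coords.mean(axis=0)
        inflated = pz.CoordinateTrajectory(
            coords=mean + 1.5 * (traj.coords - mean), masses=traj.masses,
            residue_ids=traj.residue_ids)
        assert pz.quasiharmonic_entropy(inflated) > pz.quasiharmonic_entropy(traj)

    def test_split_half_stability(self, harmonic):
        traj, _ = harmonic
        half = traj.n_frames // 2
        first = pz.CoordinateTrajectory(coords=traj.coords[:half],
                                        masses=traj.masses,
                                        residue_ids=traj.residue_ids)
        second = pz.CoordinateTrajectory(coords=traj.coords[half:],
                                         masses=traj.masses,
                                         residue_ids=traj.residue_ids)
        S1 = pz.quasiharmonic_entropy(first)
        S2 = pz.quasiharmonic_entropy(second)
        assert S1 == pytest.approx(S2, rel=0.03)

    def test_classical_variant_differs_but_tracks(self, harmonic):
        traj, _ = harmonic
        Sq = pz.quasiharmonic_entropy(traj, superpose_frames=False,
                                      drop_rigid_modes=0)
        Sc = pz.quasiharmonic_entropy(traj, superpose_frames=False,
                                      drop_rigid_modes=0, classical=True)
        assert Sc != Sq
        assert Sc == pytest.approx(Sq, rel=0.5)  # same order of magnitude

    def test_too_few_frames_rejected(self, harmonic):
        traj, _ = harmonic
        single = pz.CoordinateTrajectory(coords=traj.coords[:1],
                                         masses=traj.masses,
                                         residue_ids=traj.residue_ids)
        with pytest.raises(ValueError, match="at least 2 frames"):
            pz.quasiharmonic_entropy(single)


class TestSASA:
    def test_single_atom_is_full_sphere(self):
        areas = shrake_rupley_sasa(np.zeros((1, 3)), radii=1.7, probe=1.4)
        assert areas[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2)

    def test_distant_atoms_unoccluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        areas = shrake_rupley_sasa(coords, radii=1.7)
        full = 4 * math.pi * (1.7 + 1.4) ** 2
        assert areas == pytest.approx([full, full])

    def test_buried_atom_loses_area(self):
        centre = np.zeros((1, 3))
        shell = 2.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                                [0, 0, 1], [0, 0, -1]], dtype=float)
        coords = np.vstack([centre, shell])
        areas = shrake_rupley_sasa(coords, radii=1.7)
        full = 4 * math.pi * (1.7 + 1.4) ** 2
        assert areas[0] < 0.5 * full


class TestPdbRoundTrip:
    def test_write_read_preserves_coordinates(self, tmp_path):
        spec = pz.EnsembleSimSpec(seed=1, n_frames=4, n_atoms=6)
        traj, _ = pz.simulate_harmonic_trajectory(spec)
        path = tmp_path / "traj.pdb"
        traj.to_pdb(path)
        back = pz.CoordinateTrajectory.from_pdb(path)
        assert back.coords.shape == traj.coords.shape
        assert np.abs(back.coords - traj.coords).max() < 1e-3  # PDB precision
        assert np.array_equal(back.residue_ids, traj.residue_ids)
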