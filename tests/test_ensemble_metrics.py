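"""Structural order metrics: Rg, free-energy profiles, contacts, PCA, turns."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from page4.ensemble_metrics import (Ensemble, EnsembleError, REGIONS,
                                    contact_map, contact_pca, ensemble_rg,
                                    free_energy_profile,
                                    pairwise_distance_distribution,
                                    pair_distances, radius_of_gyration,
                                    region_mean, turn_propensity)


def _straight_chain(L, spacing=3.8):
    xyz = np.zeros((L, 3))
    xyz[:, 0] = spacing * np.arange(L)
    return xyz


class TestRadiusOfGyration:
    def test_dumbbell(self):
        assert radius_of_gyration(np.array([[0., 0, 0], [10., 0, 0]])) == \
            pytest.approx(5.0)

    def test_coincident_points(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_unit_square(self):
        sq = np.array([[0., 0, 0], [1., 0, 0], [0., 1, 0], [1., 1, 0]])
        assert radius_of_gyration(sq) == pytest.approx(np.sqrt(0.5))

    def test_single_point_rejected(self):
        with pytest.raises(EnsembleError):
            radius_of_gyration(np.zeros((1, 3)))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(50, 3)) * 10
        base = radius_of_gyration(xyz)
        for seed in range(5):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            moved = xyz @ R.T + rng.normal(size=3) * 100
            assert abs(radius_of_gyration(moved) - base) < 1e-10


class TestFreeEnergyProfile:
    def test_two_bin_log_ratio_exact(self):
        # 100 samples in one bin, 272 in the other: dF = kT ln(272/100)
        x = np.concatenate([np.zeros(100), np.ones(272)])
        _, F = free_energy_profile(x, n_bins=5, kT=1.0)
        occupied = F[~np.isnan(F)]
        assert occupied.min() == 0.0
        assert occupied.max() == pytest.approx(np.log(272 / 100), rel=1e-12)

    def test_uniform_profile_flat(self):
        rng = np.random.default_rng(1)
        _, F = free_energy_profile(rng.random(100_000), n_bins=20)
        assert np.nanmax(np.abs(F)) < 0.1

    def test_gaussian_quadratic_shape(self):
        """F(mu±sigma) − F(mu) = kT/2 up to binning error."""
        rng = np.random.default_rng(2)
        x = rng.normal(5.0, 1.0, size=200_000)
        centers, F = free_energy_profile(x, n_bins=60)
        f = lambda v: F[np.argmin(np.abs(centers - v))]
        for v in (4.0, 6.0):
            assert f(v) - f(5.0) == pytest.approx(0.5, abs=0.1)

    def test_empty_bins_masked_not_infinite(self):
        x = np.concatenate([np.zeros(200), np.full(200, 10.0)])
        _, F = free_energy_profile(x, n_bins=10)
        assert not np.any(np.isinf(F))
        assert np.isnan(F).sum() == 8

    def test_degenerate_input_warns(self):
        with pytest.warns(UserWarning):
            centers, F = free_energy_profile(np.full(500, 2.0))
        assert centers.size == 1 and F[0] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(EnsembleError):
            free_energy_profile(np.arange(50))


class TestPairwiseDistances:
    def test_identical_conformers_point_mass(self):
        ens = Ensemble(np.repeat(_straight_chain(10)[None], 5, axis=0))
        _, p = pairwise_distance_distribution(ens, 1, 10, n_bins=7)
        assert p.max() == pytest.approx(1.0)

    def test_normalization(self):
        rng = np.random.default_rng(3)
        ens = Ensemble(rng.normal(size=(200, 10, 3)))
        _, p = pairwise_distance_distribution(ens, 2, 9)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_same_residue_rejected(self):
        ens = Ensemble(np.zeros((3, 10, 3)))
        with pytest.raises(EnsembleError):
            pairwise_distance_distribution(ens, 4, 4)


class TestContactMap:
    def test_sequence_separation_mask(self):
        ens = Ensemble(_straight_chain(10)[None])
        cm = contact_map(ens, cutoff=9.5, min_seq_sep=3)
        assert cm.matrix[0, 1] == 0.0          # adjacent pair masked
        assert cm.matrix[0, 2] == 0.0          # |i-j|=2 masked

    def test_spatially_close_distant_pair(self):
        xyz = _straight_chain(60, spacing=3.8)
        xyz[49] = xyz[4] + np.array([8.0, 0.0, 0.0])
        # re-embed neighbours so only the (5, 50) proximity matters
        cm = contact_map(Ensemble(xyz[None]))
        assert cm.matrix[4, 49] == 1.0
        assert cm.matrix[49, 4] == 1.0

    def test_symmetry_range_and_increment(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 15, 3)) * 6
        cm_n = contact_map(Ensemble(coords))
        assert np.allclose(cm_n.matrix, cm_n.matrix.T)
        assert cm_n.matrix.min() >= 0.0 and cm_n.matrix.max() <= 1.0
        cm_n1 = contact_map(Ensemble(np.vstack([coords, coords[:1]])))
        assert np.max(np.abs(cm_n1.matrix - cm_n.matrix)) <= 1.0 / 20 + 1e-12


def _two_state_toy(n_conformers=40):
    """Chains alternating between an N-side fold and a C-side fold.

    Type A brings residues 1 and 5 into contact, type B residues 4 and 8;
    the two contact sets are mutually exclusive across conformers.
    """
    L = 8
    frames = []
    for k in range(n_conformers):
        xyz = _straight_chain(L, spacing=4.0)
        if k % 2 == 0:
            xyz[0] = xyz[4] + np.array([0.0, 5.0, 0.0])
        else:
            xyz[7] = xyz[3] + np.array([0.0, 5.0, 0.0])
        frames.append(xyz)
    return Ensemble(np.stack(frames))


class TestContactPCA:
    def test_matches_bruteforce_eigendecomposition(self):
        """Modes/eigenvalues equal an explicit covariance eigh oracle."""
        rng = np.random.default_rng(5)
        ens = Ensemble(rng.normal(size=(50, 20, 3)) * 5)
        res = contact_pca(ens, n_modes=4)
        # oracle: build binary vectors by hand, eigh of population covariance
        iu, ju = np.triu_indices(20, k=3)
        d = np.linalg.norm(ens.coords[:, iu, :] - ens.coords[:, ju, :], axis=2)
        X = (d <= 9.5).astype(float)
        cov = np.cov(X.T, bias=True)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        assert np.allclose(res.eigenvalues, w[:4], atol=1e-8)
        for m in range(4):
            assert abs(abs(res.modes[m] @ v[:, m]) - 1.0) < 1e-8

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(6)
        ens = Ensemble(rng.normal(size=(30, 12, 3)) * 5)
        iu, ju = np.triu_indices(12, k=3)
        d = np.linalg.norm(ens.coords[:, iu, :] - ens.coords[:, ju, :], axis=2)
        X = (d <= 9.5).astype(float)
        trace = X.var(axis=0).sum()
        res = contact_pca(ens, n_modes=29)   # full spectrum for 30 conformers
        assert res.eigenvalues.sum() == pytest.approx(trace, abs=1e-8)

    def test_mutually_exclusive_contacts_anticorrelated_on_pc1(self):
        res = contact_pca(_two_state_toy(), n_modes=2)
        a = res.mode_coefficient(0, 1, 5)
        b = res.mode_coefficient(0, 4, 8)
        assert a * b < 0

    def test_sign_convention(self):
        res = contact_pca(_two_state_toy(), n_modes=2)
        for m in range(2):
            assert res.modes[m, np.argmax(np.abs(res.modes[m]))] > 0

    def test_orthonormal_modes(self):
        res = contact_pca(_two_state_toy(), n_modes=2)
        gram = res.modes @ res.modes.T
        assert np.allclose(gram, np.eye(2), atol=1e-8)

    def test_identical_conformers_degenerate(self):
        ens = Ensemble(np.repeat(_straight_chain(10)[None], 5, axis=0))
        with pytest.raises(EnsembleError):
            contact_pca(ens)


class TestTurnPropensity:
    def test_extended_chain_no_turns(self):
        ens = Ensemble(np.repeat(_straight_chain(20)[None], 3, axis=0))
        tp = turn_propensity(ens)
        assert np.nansum(tp) == 0.0
        assert np.isnan(tp[:3]).all() and np.isnan(tp[-3:]).all()

    def test_tight_hairpin_detected(self):
        # residues 4..7 (1-based) trace a U-turn: both interior angles 90
        # degrees and d(4, 7) = 3.8 A
        b = 3.8
        xyz = np.array([
            [-3 * b, 0, 0], [-2 * b, 0, 0], [-b, 0, 0],
            [0.0, 0, 0], [b, 0, 0], [b, b, 0], [0.0, b, 0],
            [-b, b, 0], [-2 * b, b, 0], [-3 * b, b, 0],
        ])
        ens = Ensemble(xyz[None])
        tp = turn_propensity(ens)
        assert np.linalg.norm(xyz[6] - xyz[3]) < 7.0
        assert tp[3] == 1.0

    def test_region_ordering_wt_vs_clk2(self, wt_ensemble, clk2_ensemble):
        """The expanded hyper-phosphorylated form loses turn structure in
        the transiently helical AP-1 binding region."""
        wt = region_mean(turn_propensity(wt_ensemble),
                         REGIONS["transient_helix"])
        clk2 = region_mean(turn_propensity(clk2_ensemble),
                           REGIONS["transient_helix"])
        assert wt > clk2


class TestEnsembleValidation:
    def test_nan_coordinates_rejected(self):
        bad = np.zeros((2, 5, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(EnsembleError):
            Ensemble(bad)

    def test_vectorised_rg_matches_scalar(self, clk2_ensemble):
        rg = ensemble_rg(clk2_ensemble)
        for k in (0, 7, 50):
            assert rg[k] == pytest.approx(
                radius_of_gyration(clk2_ensemble.coords[k]), rel=1e-12)
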