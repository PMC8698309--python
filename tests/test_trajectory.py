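import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caflex.errors import ParameterError, SampleError, ShapeError
from caflex.structure_io import Trajectory
from caflex.synthetic import (
    make_geometry,
    rigid_motion_trajectory,
    sample_gaussian_trajectory,
)
from caflex.trajectory import (
    CorrelationMatrix,
    TrajectoryAnalysis,
    block_summary,
    call_flexible_regions,
    classify_correlations,
    compare_profiles,
    dccm,
    radius_of_gyration,
    rmsd_series,
    rmsf_profile,
)


class TestRmsd:
    def test_rigid_motions_fit_to_zero(self, helix20):
        traj = rigid_motion_trajectory(helix20, 10, seed=0)
        res = rmsd_series(traj, helix20)
        assert res.series.max() <= 1e-8
        assert res.mean <= 1e-8

    def test_alternating_single_atom_without_fit(self):
        coords = np.zeros((4, 1, 3))
        coords[1::2, 0, 0] = 0.1  # Angstrom
        traj = Trajectory(coords)
        res = rmsd_series(traj, coords[0], fit=False)
        assert np.allclose(res.series, [0.0, 0.01, 0.0, 0.01])  # nm

    def test_matches_frame_loop_oracle(self, helix20, rng):
        coords = helix20.coords + rng.normal(scale=1.0, size=(20, 20, 3))
        traj = Trajectory(coords)
        res = rmsd_series(traj, helix20.coords, fit=False)
        expected = []
        for f in range(20):
            d = coords[f] - helix20.coords
            expected.append(np.sqrt((d**2).sum(axis=1).mean()) * 0.1)
        assert np.allclose(res.series, expected, atol=1e-12)
        assert res.mean == pytest.approx(np.mean(expected))
        assert res.se == pytest.approx(np.std(expected, ddof=1) / np.sqrt(20))

    def test_reference_size_mismatch(self, helix20):
        traj = Trajectory(np.zeros((2, 5, 3)))
        with pytest.raises(ShapeError):
            rmsd_series(traj, helix20)


class TestRmsf:
    def test_static_trajectory_all_zero(self, helix20):
        traj = Trajectory(np.tile(helix20.coords, (3, 1, 1)).reshape(3, 20, 3))
        assert rmsf_profile(traj).max() <= 1e-10

    def test_isotropic_gaussian_analytic_limit(self):
        # per-atom isotropic sigma = 0.1 A -> RMSF = sqrt(3)*0.1 A
        rng = np.random.default_rng(99)
        base = np.zeros((4, 3))
        base[:, 0] = np.arange(4) * 10.0
        coords = base + rng.normal(scale=0.1, size=(50_000, 4, 3))
        r = rmsf_profile(Trajectory(coords), fit=False)
        expected = np.sqrt(3) * 0.1 * 0.1  # nm
        assert np.abs(r - expected).max() <= 0.01 * expected

    def test_frame_order_invariant(self, helix20, rng):
        coords = helix20.coords + rng.normal(scale=0.5, size=(30, 20, 3))
        traj = Trajectory(coords)
        perm = rng.permutation(30)
        assert np.allclose(
            rmsf_profile(traj), rmsf_profile(Trajectory(coords[perm])), atol=1e-10
        )

    def test_self_concatenation_invariant(self, helix20, rng):
        coords = helix20.coords + rng.normal(scale=0.5, size=(15, 20, 3))
        double = np.concatenate([coords, coords])
        assert np.allclose(
            rmsf_profile(Trajectory(coords)),
            rmsf_profile(Trajectory(double)),
            atol=1e-10,
        )

    def test_single_frame_rejected(self, helix20):
        with pytest.raises(SampleError):
            rmsf_profile(Trajectory(helix20.coords[None]))


class TestRadiusOfGyration:
    def test_two_atoms(self):
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        assert radius_of_gyration(Trajectory(coords))[0] == pytest.approx(0.1)

    def test_coincident_atoms(self):
        coords = np.ones((1, 5, 3))
        assert radius_of_gyration(Trajectory(coords))[0] == 0.0

    def test_scaling(self, helix20):
        traj1 = Trajectory(helix20.coords[None])
        traj2 = Trajectory(3.0 * helix20.coords[None])
        assert radius_of_gyration(traj2)[0] == pytest.approx(
            3.0 * radius_of_gyration(traj1)[0]
        )


class TestDccm:
    def test_identical_displacements_fully_correlated(self):
        rng = np.random.default_rng(0)
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
        disp = rng.normal(size=(50, 1, 3))
        coords = base + np.tile(disp, (1, 4, 1))
        C = dccm(Trajectory(coords), fit=False)
        assert C.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_displacements_anticorrelated(self):
        rng = np.random.default_rng(0)
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0]])
        disp = rng.normal(size=(50, 3))
        coords = np.tile(base, (50, 1, 1))
        coords[:, 0] += disp
        coords[:, 1] -= disp
        coords[:, 2] += rng.normal(size=(50, 3))  # keep atom 2 mobile
        C = dccm(Trajectory(coords), fit=False)
        assert C.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_gaussian_trajectory_matches_analytic(self):
        base = make_geometry(10)
        rng = np.random.default_rng(5)
        A = rng.normal(size=(30, 30))
        cov = 0.05 * A @ A.T / 30
        traj, truth = sample_gaussian_trajectory(base, cov, n_frames=20_000, seed=6)
        C = dccm(traj, fit=False)
        assert np.nanmax(np.abs(C.matrix - truth["dccm"])) <= 0.02
        assert np.allclose(np.diag(C.matrix), 1.0)
        assert np.allclose(C.matrix, C.matrix.T)

    def test_zero_variance_atom_flagged(self):
        rng = np.random.default_rng(1)
        coords = np.zeros((20, 3, 3))
        coords[:, 0] = rng.normal(size=(20, 3))
        coords[:, 1] = rng.normal(size=(20, 3))
        coords[:, 2] = [50.0, 0, 0]  # motionless
        with pytest.warns(UserWarning, match="zero displacement variance"):
            C = dccm(Trajectory(coords), fit=False)
        assert np.isnan(C.matrix[2]).all()
        assert np.isnan(C.matrix[:, 2]).all()
        assert not np.isnan(C.matrix[0, 1])

    def test_window_restricts_frames(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(40, 4, 3)) + np.arange(4)[None, :, None] * 20
        full = dccm(Trajectory(coords), fit=False)
        tail = dccm(Trajectory(coords), window=slice(20, None), fit=False)
        manual = dccm(Trajectory(coords[20:]), fit=False)
        assert np.allclose(tail.matrix, manual.matrix)
        assert not np.allclose(tail.matrix, full.matrix)


class TestFlexibleRegions:
    def _profile(self):
        residues = np.arange(60, 81)
        rmsf = np.full(21, 0.1)
        seq = "NPWTNVWTDGLTSLDRYKGR"  # 20 letters for residues 61..80
        seq = "K" + seq  # residue 60
        rmsf[(residues >= 68) & (residues <= 76)] = 0.35
        return rmsf, residues, seq

    def test_single_region_with_sequence(self):
        rmsf, residues, seq = self._profile()
        regions = call_flexible_regions(rmsf, residues, seq)
        assert len(regions) == 1
        region = regions[0]
        assert (region.start_residue, region.end_residue) == (68, 76)
        assert region.sequence == seq[8:17]
        assert region.mean_rmsf == pytest.approx(0.35)

    def test_all_below_threshold(self):
        regions = call_flexible_regions(
            np.full(10, 0.1), np.arange(1, 11), "A" * 10
        )
        assert regions == []

    def test_threshold_is_inclusive(self):
        rmsf = np.array([0.1, 0.3, 0.1])
        regions = call_flexible_regions(rmsf, np.arange(1, 4), "AAA")
        assert len(regions) == 1
        assert regions[0].start_residue == regions[0].end_residue == 2

    def test_numbering_gap_splits_region(self):
        rmsf = np.array([0.4, 0.4])
        regions = call_flexible_regions(rmsf, np.array([10, 20]), "AA")
        assert len(regions) == 2

    def test_partitions_exactly_the_hot_residues(self, rng):
        rmsf = rng.uniform(0.0, 0.6, size=50)
        residues = np.arange(1, 51)
        regions = call_flexible_regions(rmsf, residues, "A" * 50)
        covered = set()
        for reg in regions:
            covered |= set(range(reg.start_residue, reg.end_residue + 1))
        assert covered == set(residues[rmsf >= 0.3])
        # idempotence: calling on the same profile gives the same regions
        assert call_flexible_regions(rmsf, residues, "A" * 50) == regions


class TestCompareProfiles:
    def test_identical_profiles_empty(self):
        p = np.linspace(0.1, 0.4, 10)
        cmp = compare_profiles(p, p.copy(), np.arange(1, 11))
        assert cmp.increased == [] and cmp.reduced == []

    def test_planted_increases_recovered(self):
        residues = np.arange(50, 70)
        wt = np.full(20, 0.2)
        mutant = wt.copy()
        for r in (59, 63, 64):
            mutant[residues == r] += 0.15
        cmp = compare_profiles(wt, mutant, residues)
        assert cmp.increased == [(59, 59), (63, 64)]
        assert cmp.reduced == []
        assert cmp.increased_residues.tolist() == [59, 63, 64]

    def test_zero_delta_reports_every_difference(self):
        wt = np.array([0.1, 0.2, 0.3])
        mutant = np.array([0.1, 0.25, 0.25])
        cmp = compare_profiles(wt, mutant, np.arange(1, 4), delta=0.0)
        # delta=0 calls every residue (>= 0 holds everywhere)
        assert set(cmp.increased_residues) | set(cmp.reduced_residues) >= {2, 3}

    def test_mapping_mismatch(self):
        from caflex.errors import AlignmentError

        with pytest.raises(AlignmentError):
            compare_profiles(np.zeros(3), np.zeros(4), np.arange(1, 5))


class TestClassifyCorrelations:
    def test_identity_matrix(self):
        C = CorrelationMatrix(np.eye(4), [str(i) for i in range(4)])
        bands = classify_correlations(C)
        assert (np.diag(bands) == 1).all()
        off = bands[~np.eye(4, dtype=bool)]
        assert (off == 0).all()

    def test_boundary_value_is_correlated(self):
        M = np.eye(2)
        M[0, 1] = M[1, 0] = 0.5
        bands = classify_correlations(CorrelationMatrix(M, ["1", "2"]))
        assert bands[0, 1] == 1.0
        M[0, 1] = M[1, 0] = -0.5
        bands = classify_correlations(CorrelationMatrix(M, ["1", "2"]))
        assert bands[0, 1] == -1.0

    def test_planted_two_block_structure(self):
        # blocks A and B move together, C against them
        base = make_geometry(12)
        v = np.zeros(36)
        v[0::3] = np.concatenate([np.ones(8), -np.ones(4)])  # x-displacement
        cov = np.outer(v, v) + 1e-4 * np.eye(36)
        traj, _ = sample_gaussian_trajectory(base, cov, n_frames=4000, seed=9)
        C = dccm(traj, fit=False)
        bands = classify_correlations(C)
        assert (bands[:8, :8] == 1).all()
        assert (bands[8:, 8:] == 1).all()
        assert (bands[:8, 8:] == -1).all()
        a_b = block_summary(C, (1, 8), (9, 12))
        assert a_b["band"] == "anticorrelated"

    def test_matches_brute_force_scan(self, rng):
        M = rng.uniform(-1, 1, size=(6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        C = CorrelationMatrix(M, [str(i) for i in range(6)])
        bands = classify_correlations(C)
        for i in range(6):
            for j in range(6):
                if M[i, j] >= 0.5:
                    assert bands[i, j] == 1
                elif M[i, j] <= -0.5:
                    assert bands[i, j] == -1
                else:
                    assert bands[i, j] == 0

    def test_region_outside_matrix(self):
        C = CorrelationMatrix(np.eye(3), ["1", "2", "3"])
        with pytest.raises(ParameterError):
            block_summary(C, (10, 12), (1, 2))


class TestTrajectoryAnalysis:
    def test_summary_shape(self, helix20):
        traj, _ = sample_gaussian_trajectory(
            helix20, 0.5 * np.eye(60), n_frames=200, seed=3
        )
        ana = TrajectoryAnalysis(
            traj, helix20, helix20.residue_numbers, helix20.sequence
        )
        summary = ana.summary()
        assert summary["n_frames"] == 200
        assert summary["rmsd_mean_nm"] > 0
        assert isinstance(summary["high_rmsf_regions"], list)

    def test_pca_window_uses_final_fraction(self, helix20):
        rng = np.random.default_rng(4)
        coords = helix20.coords + rng.normal(scale=0.3, size=(50, 20, 3))
        ana = TrajectoryAnalysis(Trajectory(coords))
        full = ana.pca(window_fraction=1.0)
        tail = ana.pca(window_fraction=0.8)
        assert len(tail.projections) == 40
        assert len(full.projections) == 50

    def test_rotation_invariance_of_dccm(self, helix20):
        rng = np.random.default_rng(8)
        coords = helix20.coords + rng.normal(scale=0.5, size=(60, 20, 3))
        C1 = dccm(Trajectory(coords))
        R = Rotation.from_euler("zx", [40, 25], degrees=True).as_matrix()
        C2 = dccm(Trajectory(coords @ R.T + np.array([3.0, 1.0, -2.0])))
        assert np.abs(C1.matrix - C2.matrix).max() <= 1e-8
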