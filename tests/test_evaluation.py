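"""Landmark machinery, warping index and robustness reporting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import echoreg as er
from echoreg import GeometryError, LandmarkPairs, RigidTransform, Volume3D


def random_pairs(rng, T, n=10, noise=0.0):
    src = rng.uniform(-40, 40, size=(n, 3))
    tgt = T.apply(src)
    if noise > 0:
        tgt = tgt + rng.normal(0, noise, size=tgt.shape)
    return LandmarkPairs(src, tgt)


class TestRigidFit:
    def test_identical_sets_give_identity(self, rng):
        pts = rng.uniform(-10, 10, size=(6, 3))
        T = er.fit_rigid_landmarks(LandmarkPairs(pts, pts))
        assert np.allclose(T.matrix, np.eye(4), atol=1e-9)

    def test_exact_recovery_of_known_transform(self, rng):
        truth = RigidTransform((4.2, -1.1, 2.8), (12.0, -25.0, 40.0), (3.0, 3.0, 3.0))
        pairs = random_pairs(rng, truth)
        fit = er.fit_rigid_landmarks(pairs)
        assert np.max(np.abs(fit.matrix - truth.matrix)) < 1e-9

    def test_never_returns_a_reflection(self, rng):
        src = rng.uniform(-10, 10, size=(8, 3))
        tgt = src * np.array([-1.0, 1.0, 1.0])  # mirrored correspondence
        fit = er.fit_rigid_landmarks(LandmarkPairs(src, tgt))
        assert np.linalg.det(fit.matrix[:3, :3]) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            er.fit_rigid_landmarks(LandmarkPairs(src, src + 1.0))

    def test_invariant_to_pair_relabeling(self, rng):
        truth = RigidTransform((1, 2, 3), (5, -5, 10))
        pairs = random_pairs(rng, truth, noise=0.5)
        perm = rng.permutation(len(pairs))
        shuffled = LandmarkPairs(pairs.source[perm], pairs.target[perm])
        a, b = er.fit_rigid_landmarks(pairs), er.fit_rigid_landmarks(shuffled)
        assert np.allclose(a.matrix, b.matrix, atol=1e-9)

    def test_equivariant_under_joint_rigid_motion(self, rng):
        truth = RigidTransform((1, -2, 3), (8, 4, -6))
        pairs = random_pairs(rng, truth, noise=0.3)
        G = RigidTransform((5, 5, -5), (10, 20, 30))
        moved = LandmarkPairs(G.apply(pairs.source), G.apply(pairs.target))
        a = er.fit_rigid_landmarks(pairs)
        b = er.fit_rigid_landmarks(moved)
        # conjugation: fitting the jointly moved sets gives G ∘ T ∘ G⁻¹
        expected = G.matrix @ a.matrix @ np.linalg.inv(G.matrix)
        assert np.allclose(b.matrix, expected, atol=1e-8)


class TestInitialError:
    def test_identical_sets(self, rng):
        pts = rng.uniform(size=(5, 3))
        stats = er.initial_error(LandmarkPairs(pts, pts))
        assert stats.mean == 0.0 and stats.std == 0.0

    def test_constant_345_offset(self, rng):
        pts = rng.uniform(size=(7, 3))
        stats = er.initial_error(LandmarkPairs(pts, pts + np.array([3.0, 4.0, 0.0])))
        assert stats.mean == pytest.approx(5.0) and stats.std == pytest.approx(0.0)

    def test_two_point_sample_std(self):
        src = np.zeros((2, 3))
        tgt = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        stats = er.initial_error(LandmarkPairs(src, tgt))
        assert stats.mean == pytest.approx(2.0)
        assert stats.std == pytest.approx(np.sqrt(2.0))


class TestTreLeaveOneOut:
    def test_exact_rigid_pairs_give_zero_tre(self, rng):
        truth = RigidTransform((2, -3, 1), (15, 5, -10), (1, 1, 1))
        stats = er.tre_leave_one_out(random_pairs(rng, truth))
        assert np.max(stats.distances) < 1e-9

    def test_one_fit_per_point(self, rng):
        pairs = random_pairs(rng, RigidTransform((1, 0, 0), (0, 0, 0)), n=4)
        stats = er.tre_leave_one_out(pairs)
        assert len(stats.distances) == 4

    def test_monotone_in_landmark_noise(self):
        # Monte-Carlo: expected TRE grows with landmark noise sigma
        truth = RigidTransform((3, -1, 2), (5, 10, -5))
        means = []
        for sigma in (0.5, 1.0, 2.0):
            rng = np.random.default_rng(100)
            tres = [
                er.tre_leave_one_out(random_pairs(rng, truth, noise=sigma)).mean
                for _ in range(100)
            ]
            means.append(np.mean(tres))
        assert means[0] < means[1] < means[2]

    def test_too_few_points_rejected(self, rng):
        pairs = random_pairs(rng, RigidTransform(), n=3)
        with pytest.raises(GeometryError):
            er.tre_leave_one_out(pairs)


class TestWarpingIndex:
    @pytest.fixture()
    def domain(self):
        return Volume3D(np.zeros((11, 11, 11)), spacing=(5.0, 5.0, 5.0))

    def test_zero_for_equal_transforms(self, domain):
        T = RigidTransform((1, 2, 3), (4, 5, 6), (10, 10, 10))
        assert er.warping_index(T, T, domain) == 0.0

    def test_pure_translation_closed_form(self, domain):
        a = RigidTransform((3, 4, 0), (0, 0, 0))
        b = RigidTransform.identity()
        assert er.warping_index(a, b, domain) == pytest.approx(5.0, abs=1e-12)

    def test_rotation_matches_per_voxel_oracle(self, domain):
        # independent brute-force oracle built from an explicit rotation matrix
        center = domain.center_world
        T_est = RigidTransform((0, 0, 0), (2.0, 0, 0), center)
        T_true = RigidTransform.identity(center)
        omega = er.warping_index(T_true, T_est, domain)
        R = Rotation.from_euler("x", 2.0, degrees=True).as_matrix()
        pts = domain.grid_world_points()
        mapped = (pts - center) @ R.T + center
        oracle = np.mean(np.linalg.norm(pts - mapped, axis=1))
        assert omega == pytest.approx(oracle, abs=1e-9)

    def test_pseudo_metric_properties(self, domain, rng):
        Ts = [
            RigidTransform(rng.uniform(-3, 3, 3), rng.uniform(-5, 5, 3), domain.center_world)
            for _ in range(3)
        ]
        a, b, c = Ts
        assert er.warping_index(a, b, domain) == pytest.approx(
            er.warping_index(b, a, domain), abs=1e-12
        )
        wab = er.warping_index(a, b, domain)
        wbc = er.warping_index(b, c, domain)
        wac = er.warping_index(a, c, domain)
        assert wac <= wab + wbc + 1e-12

    def test_masked_domain_restricts_voxels(self):
        mask_data = np.zeros((5, 5, 5))
        mask_data[0, 0, 0] = 1.0
        mask = er.BinaryMask(mask_data, spacing=(1, 1, 1), origin=(0, 0, 0))
        a = RigidTransform((0, 0, 0), (0, 0, 90), center=(0, 0, 0))
        assert er.warping_index(a, RigidTransform.identity(), mask) == pytest.approx(0.0)

    def test_empty_mask_rejected(self):
        mask = er.BinaryMask(np.zeros((4, 4, 4)))
        with pytest.raises(er.ValidationError):
            er.warping_index(RigidTransform(), RigidTransform(), mask)


class TestRandomRigidTransform:
    def test_zero_bounds_give_identity(self, rng):
        T = er.random_rigid_transform(rng, 0.0, 0.0)
        assert np.allclose(T.params, 0.0)

    def test_bounds_and_mean_of_uniform_draws(self):
        rng = np.random.default_rng(77)
        draws = np.array(
            [er.random_rigid_transform(rng, 5.0, 5.0).params for _ in range(1000)]
        )
        assert draws.min() >= 0.0 and draws.max() <= 5.0
        se = 5 / np.sqrt(12) / np.sqrt(1000)
        assert np.all(np.abs(draws.mean(axis=0) - 2.5) < 3 * se)

    def test_symmetric_mode_covers_negative_range(self):
        rng = np.random.default_rng(78)
        draws = np.array(
            [er.random_rigid_transform(rng, 5.0, 5.0, symmetric=True).params for _ in range(200)]
        )
        assert draws.min() < 0.0 and draws.min() >= -5.0

    def test_same_seed_reproduces_transform(self):
        a = er.random_rigid_transform(np.random.default_rng(9), 5, 5)
        b = er.random_rigid_transform(np.random.default_rng(9), 5, 5)
        assert np.array_equal(a.params, b.params)


class TestRobustnessReport:
    def test_empty_report_rate_is_nan(self):
        report = er.RobustnessReport()
        assert np.isnan(report.success_rate)

    def test_rate_recomputable_from_flags(self):
        report = er.RobustnessReport(
            omegas=[1.0, 4.0, 2.0, np.inf],
            true_transforms=[RigidTransform()] * 4,
            est_transforms=[RigidTransform()] * 4,
            successes=[True, False, True, False],
        )
        assert report.success_rate == pytest.approx(100 * 2 / 4)
        d = report.to_dict()
        assert d["success_rate_percent"] == pytest.approx(
            100 * sum(d["successes"]) / d["n_trials"]
        )

    def test_infinite_threshold_accepts_everything(self, prob_maps):
        us_map, mr_map = prob_maps
        report = er.robustness_study(
            us_map,
            mr_map,
            reference=RigidTransform.identity(us_map.center_world),
            n_trials=2,
            cfg=er.OptimizerConfig(max_iterations=3),
            threshold=np.inf,
            rng=np.random.default_rng(5),
        )
        assert report.success_rate == 100.0


class TestLandmarkCsv:
    def test_roundtrip(self, tmp_path, rng):
        pairs = random_pairs(rng, RigidTransform((1, 2, 3), (4, 5, 6)))
        path = tmp_path / "landmarks.csv"
        pairs.to_csv(path)
        back = LandmarkPairs.from_csv(path)
        assert np.allclose(back.source, pairs.source)
        assert np.allclose(back.target, pairs.target)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(er.ValidationError):
            LandmarkPairs.from_csv(path)
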