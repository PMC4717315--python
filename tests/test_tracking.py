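import numpy as np
import pytest

from tamflow.synthdata import BundleSpec, PhantomConfig, generate_phantom
from tamflow.tracking import (OrientationField, TrackingParams,
                              classify_seed_voxels, estimate_orientations,
                              propagate_streamline, track_seed_region)
from tamflow.volumes import AffineTransform


def uniform_field(shape=(40, 40, 40), voxel=2.0, direction=(1.0, 0.0, 0.0),
                  dispersion=0.0):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    dirs = np.zeros(shape + (2, 3))
    dirs[..., 0, :] = d
    weights = np.zeros(shape + (2,))
    weights[..., 0] = 1.0
    disp = np.full(shape, dispersion)
    iso = np.zeros(shape, dtype=bool)
    return OrientationField(dirs, weights, disp, iso,
                            AffineTransform.scaling(voxel))


class TestEstimateOrientations:
    def test_in_bundle_direction_matches_tangent(self, phantom_config, phantom):
        tensors, _, _ = phantom
        field = estimate_orientations(tensors)
        bundle = phantom_config.bundles[0]
        dense, tang = bundle.resample(1.0)
        i = len(dense) // 2
        vox = tuple(np.round(dense[i] / 2.0).astype(int))
        d1 = field.directions[vox][0]
        ang = np.degrees(np.arccos(min(abs(float(d1 @ tang[i])), 1.0)))
        assert ang < 5.0

    def test_isotropic_voxel_flagged(self):
        data = np.broadcast_to(np.eye(3) * 1e-3, (4, 4, 4, 3, 3)).copy()
        from tamflow.volumes import TensorVolume
        field = estimate_orientations(TensorVolume(data, np.eye(4)))
        assert field.isotropic.all()

    def test_orthogonal_crossing_recovers_both_directions(self):
        b1 = BundleSpec(np.array([[10.0, 32.0, 32.0], [54.0, 32.0, 32.0]]), 4.0, 1)
        b2 = BundleSpec(np.array([[32.0, 10.0, 32.0], [32.0, 54.0, 32.0]]), 4.0, 2)
        cfg = PhantomConfig(grid_shape=(32, 32, 32), bundles=[b1, b2],
                            target_labels={1: "A", 2: "B"}, background_fa=0.0,
                            bundle_fa=0.75, rng_seed=0)
        tensors, _, _ = generate_phantom(cfg)
        field = estimate_orientations(tensors)
        vox = (16, 16, 16)  # the crossing
        assert field.weights[vox][1] > 0, "second direction expected"
        got = field.directions[vox]
        for want in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            best = min(np.degrees(np.arccos(np.clip(abs(got @ want), 0, 1))))
            assert best < 15.0

    def test_dispersion_decreases_with_fa(self, phantom):
        tensors, _, _ = phantom
        field = estimate_orientations(tensors)
        fa = tensors.fractional_anisotropy()
        assert field.dispersion_deg[fa > 0.7].mean() < field.dispersion_deg[
            (fa > 0.05) & (fa < 0.2)].mean()


class TestPropagateStreamline:
    def test_straight_line_in_uniform_field(self):
        field = uniform_field()
        params = TrackingParams(step_mm=0.5, max_steps=2000)
        s = propagate_streamline(field, np.array([40.0, 40.0, 40.0]), params,
                                 rng=np.random.default_rng(0))
        # all points on the x-axis line through the seed
        assert np.allclose(s.points[:, 1], 40.0, atol=1e-9)
        assert np.allclose(s.points[:, 2], 40.0, atol=1e-9)
        assert s.termination_reason == "boundary"
        steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.allclose(steps, 0.5, atol=1e-6)

    def test_max_steps_cap(self):
        field = uniform_field(shape=(400, 8, 8), voxel=2.0)
        params = TrackingParams(step_mm=0.5, max_steps=100)
        s = propagate_streamline(field, np.array([400.0, 8.0, 8.0]), params,
                                 rng=np.random.default_rng(0))
        # each side capped at 100 steps
        assert s.termination_reason == "max_steps"
        assert len(s.points) == 201

    def test_curvature_discontinuity_terminates(self):
        # two half-spaces with orthogonal directions: the 90 degree turn
        # exceeds the 80 degree threshold
        field = uniform_field(shape=(40, 40, 40))
        field.directions[20:, :, :, 0, :] = (0.0, 1.0, 0.0)
        params = TrackingParams(step_mm=0.5, curvature_threshold_deg=80.0)
        s = propagate_streamline(field, np.array([30.0, 40.0, 40.0]), params,
                                 rng=np.random.default_rng(0))
        assert "curvature" in (s.termination_reason,
                               s.termination_reason_backward)
        # the forward half stops at the interface voxel boundary
        assert s.points[:, 0].max() < 41.0

    def test_seed_in_csf_degenerate(self):
        field = uniform_field()
        csf = np.ones(field.shape, dtype=bool)
        s = propagate_streamline(field, np.array([40.0, 40.0, 40.0]),
                                 TrackingParams(), csf,
                                 rng=np.random.default_rng(0))
        assert len(s.points) == 1
        assert s.termination_reason == "csf"

    def test_seed_outside_grid_rejected(self):
        field = uniform_field()
        with pytest.raises(ValueError, match="seed outside"):
            propagate_streamline(field, np.array([1000.0, 0.0, 0.0]))


class TestTrackSeedRegion:
    def test_streamline_count(self, orientation_field, phantom):
        _, _, csf = phantom
        params = TrackingParams(n_streamlines_per_voxel=10)
        b = track_seed_region(orientation_field, [(32, 26, 24)], params,
                              csf.data, rng_seed=0)
        assert len(b) == 10

    def test_determinism(self, orientation_field, phantom):
        _, _, csf = phantom
        params = TrackingParams(n_streamlines_per_voxel=5)
        b1 = track_seed_region(orientation_field, [(32, 26, 24), (31, 26, 24)],
                               params, csf.data, rng_seed=3)
        b2 = track_seed_region(orientation_field, [(32, 26, 24), (31, 26, 24)],
                               params, csf.data, rng_seed=3)
        assert len(b1) == len(b2)
        for s1, s2 in zip(b1, b2):
            assert np.array_equal(s1.points, s2.points)

    def test_step_length_invariant_and_caps(self, orientation_field, phantom):
        _, _, csf = phantom
        params = TrackingParams(n_streamlines_per_voxel=5, max_steps=300)
        b = track_seed_region(orientation_field, [(25, 38, 33)], params,
                              csf.data, rng_seed=1)
        for s in b:
            if len(s.points) > 1:
                steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
                assert np.allclose(steps, 0.5, atol=1e-6)
            assert len(s.points) <= 2 * params.max_steps + 1

    def test_bundle_seed_reaches_target(self, phantom_config, phantom,
                                        orientation_field):
        """>= 80% of streamlines seeded inside a bundle reach its target."""
        tensors, labels, csf = phantom
        bundle = phantom_config.bundles[0]
        dense, _ = bundle.resample(1.0)
        vox = tuple(np.round(dense[len(dense) // 2] / 2.0).astype(int))
        params = TrackingParams(n_streamlines_per_voxel=100)
        b = track_seed_region(orientation_field, [vox], params, csf.data,
                              rng_seed=4)
        inv = np.linalg.inv(tensors.affine.matrix)
        hit = 0
        for s in b:
            v = np.round(s.points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((v >= 0) & (v < np.asarray(tensors.shape)), axis=1)
            if (labels.data[tuple(v[ok].T)] == bundle.target_label).any():
                hit += 1
        assert hit / len(b) >= 0.80


class TestBundleIO:
    def test_trk_tck_roundtrip_and_sidecar(self, orientation_field, phantom,
                                           tmp_path):
        import nibabel.streamlines as nibs

        tensors, _, csf = phantom
        params = TrackingParams(n_streamlines_per_voxel=3, max_steps=200)
        b = track_seed_region(orientation_field, [(25, 38, 33)], params,
                              csf.data, rng_seed=9)
        b.save_trk(tmp_path / "b.trk", tensors.affine.matrix, tensors.shape)
        b.save_tck(tmp_path / "b.tck")
        for name in ("b.trk", "b.tck"):
            back = nibs.load(str(tmp_path / name))
            assert len(back.streamlines) == len(b)
            assert np.allclose(back.streamlines[0], b.streamlines[0].points,
                               atol=1e-4)
        df = b.sidecar_table(kept_mask=[True] * len(b))
        assert len(df) == len(b)
        assert set(df["termination_forward"]).issubset(
            {"csf", "loop", "max_steps", "curvature", "boundary", "isotropic"})


class TestSamplingStability:
    def test_doubling_streamlines_stabilizes_classification(
            self, phantom_config, phantom, orientation_field):
        """Per-target classification fractions change by < 5 percentage
        points between 1000 and 2000 streamlines for one seed voxel
        (law of large numbers)."""
        tensors, labels, csf = phantom
        masks = {l: labels.data == l for l in (1, 2, 3)}
        dense, _ = phantom_config.bundles[0].resample(1.0)
        vox = tuple(np.round(dense[len(dense) // 2] / 2.0).astype(int))
        fracs = {}
        for n in (1000, 2000):
            params = TrackingParams(n_streamlines_per_voxel=n, max_steps=500)
            res = classify_seed_voxels(orientation_field, [vox], masks, params,
                                       csf.data, rng_seed=8)
            counts = res[vox]["counts"]
            fracs[n] = {l: counts[l] / n for l in counts}
        for l in (1, 2, 3):
            assert abs(fracs[1000][l] - fracs[2000][l]) < 0.05


class TestClassifySeedVoxels:
    def test_pure_bundle_voxel_classified(self, phantom_config, phantom,
                                          orientation_field):
        tensors, labels, csf = phantom
        b1 = phantom_config.bundles[0]
        dense, _ = b1.resample(1.0)
        vox = tuple(np.round(dense[len(dense) // 2] / 2.0).astype(int))
        masks = {l: labels.data == l for l in (1, 2, 3)}
        params = TrackingParams(n_streamlines_per_voxel=30)
        res = classify_seed_voxels(orientation_field, [vox], masks, params,
                                   csf.data, rng_seed=5)
        rec = res[vox]
        assert rec["predominant"] == 1
        assert sum(rec["counts"].values()) <= 3 * 30  # multi-target possible

    def test_empty_target_list_rejected(self, orientation_field):
        with pytest.raises(ValueError, match="target"):
            classify_seed_voxels(orientation_field, [(10, 10, 10)], {})

    def test_classification_matches_nearest_bundle(self, phantom_config,
                                                   phantom, orientation_field):
        """Seed voxels inside each bundle tube map to that bundle's label
        for >= 90% of classifiable voxels."""
        tensors, labels, csf = phantom
        masks = {l: labels.data == l for l in (1, 2, 3)}
        params = TrackingParams(n_streamlines_per_voxel=20)
        seeds, truth = [], {}
        for bundle in phantom_config.bundles[:2]:
            dense, _ = bundle.resample(1.0)
            for frac in (0.35, 0.5, 0.65):
                v = tuple(np.round(dense[int(frac * len(dense))] / 2.0).astype(int))
                seeds.append(v)
                truth[v] = bundle.target_label
        res = classify_seed_voxels(orientation_field, seeds, masks, params,
                                   csf.data, rng_seed=6)
        good = sum(res[v]["predominant"] == truth[v] for v in truth)
        assert good / len(truth) >= 0.9
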