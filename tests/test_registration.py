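"""Rigid transforms, pairwise estimation, stack registration, assembly."""

import numpy as np
import pytest
from scipy import ndimage

from tracerspread import (
    PhantomSpec,
    RigidTransform2D,
    SliceStack,
    assemble_volume,
    equalize_brightness,
    estimate_rigid_transform,
    make_phantom,
    maximum_projection,
    register_stack,
)
from tracerspread.registration import VolumeGrid, _chain_errors, _ncc


def textured_image(seed=0, shape=(64, 96)):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    return (img - img.min()) / np.ptp(img) * 200.0


class TestTransformAlgebra:
    @pytest.mark.parametrize("seed", range(8))
    def test_compose_with_inverse_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform2D(angle_deg=rng.uniform(-30, 30),
                             dx=rng.uniform(-10, 10),
                             dy=rng.uniform(-10, 10))
        assert t.compose(t.inverse()).is_identity(tol=1e-9)
        assert t.inverse().compose(t).is_identity(tol=1e-9)

    def test_composition_matches_sequential_warps(self):
        img = textured_image(1)
        t1 = RigidTransform2D(4.0, 2.0, -1.0)
        t2 = RigidTransform2D(-2.5, -1.0, 3.0)
        seq = t2.warp(t1.warp(img))
        joint = t2.compose(t1).warp(img)
        # interiors agree up to double-interpolation smoothing
        assert _ncc(seq, joint, margin=12) > 0.995

    def test_identity_is_neutral(self):
        t = RigidTransform2D(3.0, 1.0, 2.0)
        i = RigidTransform2D.identity()
        assert t.compose(i) == t


class TestEstimateRigid:
    def test_identical_images_give_identity(self):
        img = textured_image(2)
        t = estimate_rigid_transform(img, img)
        assert abs(t.angle_deg) < 0.05
        assert abs(t.dx) < 0.05 and abs(t.dy) < 0.05

    def test_pure_translation_recovered_vs_integer_shift_oracle(self):
        img = textured_image(3)
        applied = RigidTransform2D(0.0, dx=3.0, dy=-2.0)
        moving = applied.warp(img)
        # oracle: exhaustive integer-shift search maximizing NCC
        best = (-2.0, None)
        for dy in range(-6, 7):
            for dx in range(-6, 7):
                s = _ncc(img, RigidTransform2D(0, dx, dy).warp(moving))
                if s > best[0]:
                    best = (s, (dx, dy))
        assert best[1] == (-3, 2)
        est = estimate_rigid_transform(img, moving)
        assert est.dx == pytest.approx(-3.0, abs=0.25)
        assert est.dy == pytest.approx(2.0, abs=0.25)

    def test_pure_rotation_recovered_vs_angle_grid_oracle(self):
        img = textured_image(4)
        moving = RigidTransform2D(2.0, 0, 0).warp(img)
        # oracle: exhaustive scan over a fine angle grid
        grid = np.arange(-4, 4.001, 0.05)
        scores = [_ncc(img, RigidTransform2D(a, 0, 0).warp(moving))
                  for a in grid]
        assert grid[int(np.argmax(scores))] == pytest.approx(-2.0, abs=0.1)
        est = estimate_rigid_transform(img, moving)
        assert est.angle_deg == pytest.approx(-2.0, abs=0.2)

    def test_constant_image_rejected(self):
        img = np.full((32, 32), 7.0)
        with pytest.raises(ValueError):
            estimate_rigid_transform(img, img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_rigid_transform(np.zeros((4, 4)), np.zeros((5, 5)))


def _make_stack(seed=5, n=5, misalign=True):
    spec = PhantomSpec(
        shape=(n, 48, 64), seed=seed,
        translation_sigma_px=3.0 if misalign else 0.0,
        rotation_sigma_deg=1.5 if misalign else 0.0)
    slices, truth = make_phantom(spec)
    stack = SliceStack(slices=slices, in_plane_um=spec.in_plane_um,
                       axial_um=spec.axial_um)
    return stack, truth


@pytest.fixture(scope="module")
def registered_misaligned():
    stack, truth = _make_stack()
    registered, transforms = register_stack(stack, "nuclei")
    return stack, truth, registered, transforms


class TestRegisterStack:
    def test_recovers_ground_truth_misalignments(self, registered_misaligned):
        stack, truth, _, transforms = registered_misaligned
        errs = _chain_errors(transforms, truth.transforms, len(stack) // 2)
        # at this small frame size, angle precision is lever-arm limited;
        # the sub-pixel/sub-degree bar is exercised on the full-size phantom
        assert (errs <= 1.0).all(axis=1).mean() >= 0.8

    def test_aligned_stack_yields_identity_transforms(self):
        stack, _ = _make_stack(misalign=False)
        _, transforms = register_stack(stack, "nuclei")
        for t in transforms:
            assert abs(t.angle_deg) < 0.5
            assert abs(t.dx) < 0.5 and abs(t.dy) < 0.5

    def test_second_registration_pass_is_near_identity(
            self, registered_misaligned):
        _, _, registered, _ = registered_misaligned
        _, second = register_stack(registered, "nuclei")
        for t in second:
            assert abs(t.angle_deg) < 0.6
            assert abs(t.dx) < 0.6 and abs(t.dy) < 0.6

    def test_single_slice_rejected(self):
        stack, _ = _make_stack()
        with pytest.raises(ValueError):
            register_stack(SliceStack(slices=stack.slices[:1],
                                      in_plane_um=10.4, axial_um=70.0),
                           "nuclei")

    def test_resampling_preserves_intensity_range(
            self, registered_misaligned):
        stack, _, registered, _ = registered_misaligned
        lo = min(float(s[c].min()) for s in stack.slices for c in s)
        hi = max(float(s[c].max()) for s in stack.slices for c in s)
        for sl in registered.slices:
            for c, img in sl.items():
                assert img.min() >= lo - 1e-6
                assert img.max() <= hi + 1e-6


class TestEqualizeBrightness:
    def make_stack(self):
        spec = PhantomSpec(shape=(6, 48, 64), seed=8, translation_sigma_px=0,
                           rotation_sigma_deg=0, noise_sigma=0)
        slices, _ = make_phantom(spec)
        return SliceStack(slices=slices, in_plane_um=10.4, axial_um=70.0)

    def test_equal_means_left_untouched(self):
        stack = self.make_stack()
        out = equalize_brightness(stack, "nuclei")
        mids = [float(s["nuclei"][s["nuclei"] > 0].mean())
                for s in out.slices]
        assert np.allclose(mids, np.median(mids), rtol=0.02)

    def test_rescaled_slice_is_brought_back(self):
        stack = self.make_stack()
        stack.slices[2]["nuclei"] = stack.slices[2]["nuclei"] * 0.5
        out = equalize_brightness(stack, "nuclei")
        means = [float(s["nuclei"][s["nuclei"] > 0].mean())
                 for s in out.slices]
        assert means[2] == pytest.approx(np.median(means), rel=0.01)

    def test_other_channels_bit_identical(self):
        stack = self.make_stack()
        out = equalize_brightness(stack, "nuclei")
        for a, b in zip(stack.slices, out.slices):
            np.testing.assert_array_equal(a["tracer"], b["tracer"])


class TestAssembleVolume:
    def test_shape_and_spacing_under_defaults(self):
        spec = PhantomSpec(shape=(10, 64, 64), seed=3,
                           translation_sigma_px=0, rotation_sigma_deg=0)
        slices, _ = make_phantom(spec)
        vol = assemble_volume(SliceStack(slices=slices, in_plane_um=10.4,
                                         axial_um=70.0))
        assert vol.shape == (10, 64, 64)
        assert vol.spacing_um == (70.0, 10.4, 10.4)

    def test_mask_covers_true_mask(self):
        spec = PhantomSpec(shape=(10, 64, 64), seed=3,
                           translation_sigma_px=0, rotation_sigma_deg=0)
        slices, truth = make_phantom(spec)
        vol = assemble_volume(SliceStack(slices=slices, in_plane_um=10.4,
                                         axial_um=70.0))
        overlap = (vol.mask & truth.mask).sum() / truth.mask.sum()
        assert overlap >= 0.95

    def test_mask_invariant_to_tracer_scaling(self):
        spec = PhantomSpec(shape=(8, 48, 64), seed=4,
                           translation_sigma_px=0, rotation_sigma_deg=0)
        slices, _ = make_phantom(spec)
        stack = SliceStack(slices=slices, in_plane_um=10.4, axial_um=70.0)
        v1 = assemble_volume(stack)
        for sl in slices:
            sl["tracer"] = sl["tracer"] * 0.3
        v2 = assemble_volume(SliceStack(slices=slices, in_plane_um=10.4,
                                        axial_um=70.0))
        assert v1.mask.sum() == v2.mask.sum()


class TestMaximumProjection:
    def make_volume(self, data):
        return VolumeGrid(channels={"t": data}, spacing_um=(70, 10.4, 10.4),
                          mask=np.ones(data.shape, bool))

    def test_constant_volume_projects_to_constant(self):
        vol = self.make_volume(np.full((3, 4, 5), 2.5))
        for axis in ("horizontal", "coronal", "sagittal"):
            assert (maximum_projection(vol, axis, "t") == 2.5).all()

    def test_single_voxel_appears_once_per_projection(self):
        data = np.zeros((3, 4, 5))
        data[1, 2, 3] = 9.0
        vol = self.make_volume(data)
        for axis in ("horizontal", "coronal", "sagittal"):
            proj = maximum_projection(vol, axis, "t")
            assert (proj == 9.0).sum() == 1

    def test_2x2x2_matches_brute_force(self):
        data = np.arange(8, dtype=float).reshape(2, 2, 2)
        vol = self.make_volume(data)
        np.testing.assert_array_equal(
            maximum_projection(vol, "horizontal", "t"), data.max(axis=0))
        np.testing.assert_array_equal(
            maximum_projection(vol, "coronal", "t"), data.max(axis=1))
        np.testing.assert_array_equal(
            maximum_projection(vol, "sagittal", "t"), data.max(axis=2))

    def test_projection_bounds_every_projected_voxel(self):
        rng = np.random.default_rng(0)
        data = rng.random((4, 5, 6))
        vol = self.make_volume(data)
        proj = maximum_projection(vol, "horizontal", "t")
        assert (proj[None, :, :] >= data - 1e-12).all()

    def test_unknown_axis_rejected(self):
        vol = self.make_volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            maximum_projection(vol, "diagonal", "t")
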