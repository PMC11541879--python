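"""Sobel gradients, axial cropping, organoid and lumen masks."""

import numpy as np
import pytest

from conftest import dice
from organotomo import (
    GradientStack,
    PhantomSpec,
    RITomogram,
    generate_organoid_phantom,
    segment_lumen,
    segment_organoid,
    sobel_gradient_stack,
    zcrop_by_gradient,
)


def _tomo(values, spacing=(1.0, 1.0, 2.0)):
    return RITomogram(values=np.asarray(values, dtype=float), voxel_spacing_um=spacing)


class TestSobel:
    def test_constant_slice_has_zero_gradient(self):
        g = sobel_gradient_stack(_tomo(np.full((8, 8, 3), 1.337)))
        assert np.all(g.values == 0)
        assert np.all(g.per_slice_mean == 0)

    def test_step_edge_magnitude_is_four_delta(self):
        """A vertical step of height Δn reads 4Δn under the 3x3 kernel."""
        dn = 0.01
        v = np.full((10, 10, 1), 1.337)
        v[5:, :, :] += dn  # step along x between columns 4 and 5
        g = sobel_gradient_stack(_tomo(v))
        interior = g.values[4:6, 2:8, 0]  # edge columns away from borders
        assert interior == pytest.approx(4 * dn)
        assert np.all(g.values[:3, :, 0] == 0)

    def test_gradient_magnitude_rotation_isotropy(self):
        rng = np.random.default_rng(0)
        v = rng.normal(1.337, 0.01, (12, 12, 2))
        g = sobel_gradient_stack(_tomo(v))
        g_rot = sobel_gradient_stack(_tomo(np.rot90(v, axes=(0, 1)).copy()))
        assert np.allclose(g_rot.values, np.rot90(g.values, axes=(0, 1)))

    def test_too_small_inplane_rejected(self):
        with pytest.raises(ValueError):
            sobel_gradient_stack(_tomo(np.ones((2, 8, 3))))


class TestZCrop:
    def _stack_with_content(self, z_lo, z_hi, nz=40):
        v = np.full((16, 16, nz), 1.337)
        v[4:12, 4:12, z_lo:z_hi] = 1.36
        return sobel_gradient_stack(_tomo(v))

    def test_confined_content_returns_exact_interval(self):
        g = self._stack_with_content(10, 21)
        assert zcrop_by_gradient(g) == (10, 21)

    def test_uniform_profile_returns_full_range(self):
        g = GradientStack(
            values=np.ones((4, 4, 7)), per_slice_mean=np.ones(7)
        )
        assert zcrop_by_gradient(g) == (0, 7)

    def test_high_threshold_keeps_only_argmax_slice(self):
        means = np.array([0.1, 0.5, 1.0, 0.4, 0.2])
        g = GradientStack(values=np.ones((4, 4, 5)), per_slice_mean=means)
        assert zcrop_by_gradient(g, rel_threshold=0.999) == (2, 3)

    def test_idempotent_on_cropped_stack(self):
        g = self._stack_with_content(10, 21)
        z0, z1 = zcrop_by_gradient(g)
        cropped = GradientStack(
            values=g.values[:, :, z0:z1], per_slice_mean=g.per_slice_mean[z0:z1]
        )
        assert zcrop_by_gradient(cropped) == (0, z1 - z0)

    def test_all_zero_gradient_rejected(self):
        g = sobel_gradient_stack(_tomo(np.full((8, 8, 3), 1.337)))
        with pytest.raises(ValueError, match="content"):
            zcrop_by_gradient(g)

    def test_threshold_out_of_range_rejected(self):
        g = self._stack_with_content(1, 3, nz=5)
        with pytest.raises(ValueError):
            zcrop_by_gradient(g, rel_threshold=1.5)


class TestSegmentOrganoid:
    def test_noise_free_phantom_dice(self, cyst_spec):
        from dataclasses import replace

        tomo, truth = generate_organoid_phantom(replace(cyst_spec, noise_sd=0.0))
        grad = sobel_gradient_stack(tomo)
        z_range = zcrop_by_gradient(grad)
        masks = segment_organoid(tomo, grad, z_range)
        assert len(masks) >= 1
        assert dice(masks[0].values, truth.organoid_mask) >= 0.95

    def test_mask_confined_to_z_range(self, cyst_phantom):
        tomo, _ = cyst_phantom
        grad = sobel_gradient_stack(tomo)
        z0, z1 = 8, 32
        masks = segment_organoid(tomo, grad, (z0, z1))
        for m in masks:
            assert not m.values[:, :, :z0].any()
            assert not m.values[:, :, z1:].any()
            assert m.z_range == (z0, z1)

    def test_all_background_volume_returns_empty(self):
        rng = np.random.default_rng(0)
        tomo = _tomo(1.337 + rng.normal(0, 0.002, (40, 40, 20)))
        grad = sobel_gradient_stack(tomo)
        with pytest.warns(UserWarning):
            masks = segment_organoid(tomo, grad, (0, 20))
        assert masks == []

    def test_two_separated_phantoms_two_labels(self):
        canvas = np.full((150, 70, 40), 1.337)
        truths = []
        for cx, seed in ((35, 10), (115, 11)):
            spec = PhantomSpec(
                voxel_spacing_um=(1.0, 1.0, 2.0), volume_shape_vox=(60, 60, 40),
                outer_radius_um=20.0, shell_thickness_um=9.0, noise_sd=0.0, seed=seed,
            )
            t, tr = generate_organoid_phantom(spec)
            region = canvas[cx - 30 : cx + 30, 5:65, :]
            canvas[cx - 30 : cx + 30, 5:65, :] = np.where(tr.organoid_mask, t.values, region)
            truths.append((cx, tr))
        tomo = _tomo(canvas)
        grad = sobel_gradient_stack(tomo)
        masks = segment_organoid(tomo, grad, zcrop_by_gradient(grad))
        assert len(masks) == 2
        # each mask matches one truth component
        for cx, tr in truths:
            full_truth = np.zeros_like(canvas, dtype=bool)
            full_truth[cx - 30 : cx + 30, 5:65, :] = tr.organoid_mask
            best = max(dice(m.values, full_truth) for m in masks)
            assert best >= 0.95

    def test_supervised_classifier_path(self, cyst_phantom):
        tomo, truth = cyst_phantom
        grad = sobel_gradient_stack(tomo)
        # sparse annotations: a handful of voxels of each class
        labels = np.zeros(tomo.shape, dtype=np.uint8)
        rng = np.random.default_rng(0)
        fg = np.argwhere(truth.organoid_mask)
        bg = np.argwhere(~truth.organoid_mask)
        for x, y, z in fg[rng.choice(len(fg), 300, replace=False)]:
            labels[x, y, z] = 2
        for x, y, z in bg[rng.choice(len(bg), 300, replace=False)]:
            labels[x, y, z] = 1
        masks = segment_organoid(tomo, grad, (0, tomo.shape[2]), labels=labels)
        assert masks
        assert dice(masks[0].values, truth.organoid_mask) >= 0.9

    def test_single_class_annotation_rejected(self, cyst_phantom):
        tomo, _ = cyst_phantom
        grad = sobel_gradient_stack(tomo)
        labels = np.zeros(tomo.shape, dtype=np.uint8)
        labels[0, 0, 0] = 2
        with pytest.raises(ValueError, match="2 classes"):
            segment_organoid(tomo, grad, (0, tomo.shape[2]), labels=labels)


class TestSegmentLumen:
    def test_cyst_lumen_dice(self, cyst_phantom):
        tomo, truth = cyst_phantom
        grad = sobel_gradient_stack(tomo)
        masks = segment_organoid(tomo, grad, zcrop_by_gradient(grad))
        lumen = segment_lumen(tomo, masks[0])
        assert dice(lumen.values, truth.lumen_mask) >= 0.9

    def test_solid_ball_has_empty_lumen(self, uniform_ball):
        tomo, _ = uniform_ball
        grad = sobel_gradient_stack(tomo)
        masks = segment_organoid(tomo, grad, zcrop_by_gradient(grad))
        with pytest.warns(UserWarning):
            lumen = segment_lumen(tomo, masks[0])
        assert lumen.voxel_count == 0

    def test_lumen_contained_in_organoid(self, cyst_phantom):
        tomo, _ = cyst_phantom
        grad = sobel_gradient_stack(tomo)
        masks = segment_organoid(tomo, grad, zcrop_by_gradient(grad))
        lumen = segment_lumen(tomo, masks[0])
        assert lumen.voxel_count > 0
        filled = masks[0].values.copy()
        assert (lumen.values <= filled).all() or lumen.values.sum() < masks[0].voxel_count

    def test_empty_mask_rejected(self, cyst_phantom):
        tomo, _ = cyst_phantom
        from organotomo import VolumeMask

        with pytest.raises(ValueError, match="empty"):
            segment_lumen(tomo, VolumeMask(np.zeros(tomo.shape, dtype=bool)))
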