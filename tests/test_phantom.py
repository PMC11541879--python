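"""Phantom generator: determinism, geometry, density statistics, growth."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage, stats

from organotomo.types import (
    LABEL_DEAD,
    LABEL_DEBRIS,
    LABEL_LIVE,
    PhantomSpec,
)
from organotomo.phantom import (
    GeometryError,
    generate_organoid_phantom,
    generate_tileset,
    generate_timelapse,
)


class TestGeneratePhantom:
    def test_deterministic_under_fixed_seed(self, cyst_spec):
        a, _ = generate_organoid_phantom(cyst_spec)
        b, _ = generate_organoid_phantom(cyst_spec)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self, cyst_spec):
        a, _ = generate_organoid_phantom(cyst_spec)
        b, _ = generate_organoid_phantom(replace(cyst_spec, seed=cyst_spec.seed + 1))
        assert not np.array_equal(a.values, b.values)

    def test_dead_fraction_zero_only_live_and_debris_labels(self, cyst_spec):
        spec = replace(cyst_spec, dead_fraction=0.0, noise_sd=0.0)
        _, truth = generate_organoid_phantom(spec)
        labels = np.unique(truth.live_dead_labels)
        assert LABEL_DEAD not in labels
        assert LABEL_LIVE in labels

    def test_uniform_sphere_density_exact_and_volume_analytic(self, uniform_ball, uniform_ball_spec):
        tomo, truth = uniform_ball
        rho = (tomo.values - tomo.n_medium) / 0.185
        assert rho[truth.organoid_mask] == pytest.approx(0.1, abs=1e-12)
        assert truth.true_mean_density == pytest.approx(0.1, abs=1e-12)
        analytic = 4.0 / 3.0 * np.pi * uniform_ball_spec.outer_radius_um**3
        assert truth.true_volume_um3 == pytest.approx(analytic, rel=0.02)

    @pytest.mark.parametrize("dead_fraction,mean,sd", [(0.0, 0.115, 0.050), (1.0, 0.101, 0.048)])
    def test_density_statistics_recovered(self, dead_fraction, mean, sd):
        """In-shell voxel density means match the generating live/dead stats."""
        spec = PhantomSpec(
            voxel_spacing_um=(1.0, 1.0, 2.0),
            volume_shape_vox=(110, 110, 56),
            outer_radius_um=45.0,
            shell_thickness_um=18.0,
            dead_fraction=dead_fraction,
            noise_sd=0.0,
            seed=11,
        )
        tomo, truth = generate_organoid_phantom(spec)
        shell = truth.organoid_mask & ~truth.lumen_mask
        rho = (tomo.values - tomo.n_medium)[shell] / 0.185
        # one density draw per ~10 µm cell: the effective n is the cell count
        cell_vol = 4 / 3 * np.pi * 5**3
        n_cells = shell.sum() * 2.0 / cell_vol
        sem = sd / np.sqrt(n_cells)
        assert abs(rho.mean() - mean) < 3 * sem + 0.002  # 0.002: clipping bias margin

    def test_lumen_disjoint_from_shell_and_single_component(self, cyst_phantom):
        _, truth = cyst_phantom
        shell = truth.organoid_mask & ~truth.lumen_mask
        assert not (truth.lumen_mask & shell).any()
        _, n = ndimage.label(truth.organoid_mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_debris_lives_in_lumen(self, cyst_phantom):
        _, truth = cyst_phantom
        debris = truth.live_dead_labels == LABEL_DEBRIS
        assert debris.sum() > 0
        assert (debris <= truth.lumen_mask).all()

    def test_geometry_too_large_raises(self, cyst_spec):
        with pytest.raises(GeometryError):
            generate_organoid_phantom(replace(cyst_spec, outer_radius_um=100.0,
                                              shell_thickness_um=30.0))

    def test_multilobular_geometry(self):
        spec = PhantomSpec(
            geometry_kind="multilobular",
            voxel_spacing_um=(1.0, 1.0, 2.0),
            volume_shape_vox=(80, 80, 40),
            outer_radius_um=30.0,
            shell_thickness_um=8.0,
            n_lobes=3,
            seed=4,
        )
        tomo, truth = generate_organoid_phantom(spec)
        _, n = ndimage.label(truth.organoid_mask, structure=np.ones((3, 3, 3)))
        assert n == 1
        # lobed body is not a sphere: volume well below the bounding ball
        assert truth.true_volume_um3 < 0.9 * 4 / 3 * np.pi * 30**3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shell_thickness_um=40.0, outer_radius_um=30.0)
        with pytest.raises(ValueError):
            PhantomSpec(dead_fraction=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-0.1)


class TestTimelapse:
    def test_zero_growth_constant_volume(self, cyst_spec):
        spec = replace(cyst_spec, growth_rate_per_h=0.0, n_frames=4)
        frames = generate_timelapse(spec)
        vols = [tr.true_volume_um3 for _, tr in frames]
        assert all(v == pytest.approx(vols[0], rel=1e-3) for v in vols)

    def test_exponential_growth_slope(self):
        spec = PhantomSpec(
            voxel_spacing_um=(1.0, 1.0, 2.0),
            volume_shape_vox=(80, 80, 40),
            outer_radius_um=25.0,
            shell_thickness_um=10.0,
            growth_rate_per_h=0.02,
            frame_interval_h=1.0,
            n_frames=10,
            seed=2,
        )
        frames = generate_timelapse(spec)
        t = np.array([tomo.timestamp_h for tomo, _ in frames])
        v = np.array([tr.true_volume_um3 for _, tr in frames])
        slope = stats.linregress(t, np.log(v)).slope
        assert slope == pytest.approx(0.02, rel=0.05)  # voxelization tolerance

    def test_growth_exceeding_bounds_names_frame(self, cyst_spec):
        spec = replace(cyst_spec, outer_radius_um=35.0, shell_thickness_um=12.0,
                       growth_rate_per_h=0.5, n_frames=5)
        with pytest.raises(GeometryError, match="frame"):
            generate_timelapse(spec)

    def test_dead_fraction_schedule_decreases_density(self, cyst_spec):
        spec = replace(cyst_spec, growth_rate_per_h=0.0, n_frames=4, noise_sd=0.0)
        frames = generate_timelapse(spec, dead_fraction_schedule=[0.0, 0.3, 0.6, 1.0])
        dens = [tr.true_mean_density for _, tr in frames]
        assert all(b < a + 0.004 for a, b in zip(dens, dens[1:]))
        assert dens[-1] < dens[0]

    def test_single_frame_rejected(self, cyst_spec):
        with pytest.raises(ValueError):
            generate_timelapse(replace(cyst_spec, n_frames=1))


class TestTileset:
    SPEC = PhantomSpec(
        voxel_spacing_um=(0.5, 0.5, 2.0),
        volume_shape_vox=(96, 96, 10),
        outer_radius_um=30.0,
        shell_thickness_um=12.0,
        noise_sd=0.002,
        seed=5,
    )

    def test_zero_jitter_true_equals_nominal(self):
        ts, truth, _ = generate_tileset(self.SPEC, grid=(2, 2), overlap_um=15.0, jitter_vox=0)
        assert truth.true_offsets_vox == ts.nominal_offsets_vox

    def test_single_tile_grid(self):
        ts, truth, master = generate_tileset(self.SPEC, grid=(1, 1), overlap_um=15.0, jitter_vox=0)
        assert len(ts.tiles) == 1
        assert np.array_equal(ts.tiles[0].values, master.values)

    def test_jitter_bounded_and_recorded(self):
        ts, truth, master = generate_tileset(self.SPEC, grid=(2, 2), overlap_um=15.0, jitter_vox=5)
        for (tx, ty), (nx, ny) in zip(truth.true_offsets_vox, ts.nominal_offsets_vox):
            assert abs(tx - nx) <= 5 and abs(ty - ny) <= 5
        # tiles really are cut at the true offsets
        for tile, (ox, oy) in zip(ts.tiles, truth.true_offsets_vox):
            assert np.array_equal(
                tile.values, master.values[ox : ox + 96, oy : oy + 96, :]
            )

    def test_overlap_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_tileset(self.SPEC, grid=(2, 2), overlap_um=1.0, jitter_vox=0)
        with pytest.raises(ValueError):
            generate_tileset(self.SPEC, grid=(2, 2), overlap_um=15.0, jitter_vox=40)
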