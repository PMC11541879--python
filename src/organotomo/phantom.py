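"""Synthetic organoid tomogram generator.

Produces 3D refractive-index phantoms that emulate Matrigel-embedded
intestinal organoids as seen by low-coherence holotomography: an
epithelial shell of cell-sized density domains around a lumen that
collects low-density exfoliated debris, on a uniform medium background
with additive sensor noise.  Every phantom ships with exact ground truth
(masks, per-voxel live/dead labels, volume, mean density, tile offsets),
which stands in for the fluorescence staining a real validation would
use.

The generator is deliberately geometric, not optical: there is no
diffraction, no transfer function, no aberration.  What it reproduces is
the *statistical* structure the downstream analysis depends on —
between-cell density variance, live/dead density separation, exponential
growth, tile overlap with stage jitter.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import (
    ALPHA_PROTEIN,
    LABEL_BACKGROUND,
    LABEL_DEAD,
    LABEL_DEBRIS,
    LABEL_LIVE,
    PhantomSpec,
    PhantomTruth,
    RITomogram,
    TileSet,
)

__all__ = [
    "GeometryError",
    "generate_organoid_phantom",
    "generate_timelapse",
    "generate_tileset",
]


class GeometryError(ValueError):
    """Requested geometry does not fit the requested volume shape."""


def _physical_grids(shape, spacing):
    """Voxel-centre coordinates (µm) relative to the volume centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * d
        for n, d in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _solid_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Solid organoid region (shell plus lumen) as a boolean volume."""
    shape = spec.volume_shape_vox
    spacing = spec.voxel_spacing_um
    R = spec.outer_radius_um
    n_fit = 2 if spec.allow_axial_clip else 3
    for n, d in list(zip(shape, spacing))[:n_fit]:
        if R >= (n - 1) / 2.0 * d:
            raise GeometryError(
                f"outer radius {R} µm does not fit volume of extent "
                f"{[round(n * d, 2) for n, d in zip(shape, spacing)]} µm"
            )
    X, Y, Z = _physical_grids(shape, spacing)
    if spec.geometry_kind == "enterocystic":
        solid = X * X + Y * Y + Z * Z <= R * R
    else:  # multilobular: central body plus budded lobes, overall extent R
        body_r = 0.65 * R
        lobe_r = 0.35 * R
        solid = X * X + Y * Y + Z * Z <= body_r * body_r
        # deterministic lobe directions from the spec seed
        for _ in range(spec.n_lobes):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            cx, cy, cz = body_r * v
            solid |= (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= lobe_r * lobe_r
    if not solid.any():
        raise GeometryError("volume too small: organoid region is empty")
    return solid


def _partition_shell(spec, solid):
    """Split the solid region into shell and enclosed lumen.

    The lumen is the set of interior voxels deeper than the shell
    thickness, measured as Euclidean distance (in µm, anisotropy-aware)
    to the outside of the organoid.
    """
    depth = ndimage.distance_transform_edt(solid, sampling=spec.voxel_spacing_um)
    lumen = depth > spec.shell_thickness_um
    shell = solid & ~lumen
    return shell, lumen


def _voronoi_cell_labels(shell, spacing, cell_diameter_um, rng):
    """Assign each shell voxel to a cell-sized Voronoi domain.

    One density draw per domain reproduces the between-cell variance
    that the subvolume statistics rely on.
    """
    idx = np.argwhere(shell)
    shell_vol = len(idx) * float(np.prod(spacing))
    cell_vol = 4.0 / 3.0 * np.pi * (cell_diameter_um / 2.0) ** 3
    n_cells = max(1, int(round(shell_vol / cell_vol)))
    seeds = idx[rng.choice(len(idx), size=min(n_cells, len(idx)), replace=False)]
    tree = cKDTree(seeds * np.asarray(spacing))
    _, owner = tree.query(idx * np.asarray(spacing), workers=-1)
    labels = np.zeros(shell.shape, dtype=np.int32)
    labels[tuple(idx.T)] = owner + 1  # 0 = not shell
    return labels, len(seeds)


def _debris_blobs(spec, lumen, rng):
    """Spherical debris blobs (2–5 µm radius) scattered in the lumen."""
    debris = np.zeros(lumen.shape, dtype=bool)
    centers = np.argwhere(lumen)
    if len(centers) == 0 or spec.debris_count == 0:
        return debris
    X, Y, Z = _physical_grids(lumen.shape, spec.voxel_spacing_um)
    picks = centers[rng.choice(len(centers), size=spec.debris_count, replace=True)]
    for c in picks:
        r = rng.uniform(2.0, 5.0)
        cx = (c[0] - (lumen.shape[0] - 1) / 2.0) * spec.voxel_spacing_um[0]
        cy = (c[1] - (lumen.shape[1] - 1) / 2.0) * spec.voxel_spacing_um[1]
        cz = (c[2] - (lumen.shape[2] - 1) / 2.0) * spec.voxel_spacing_um[2]
        debris |= (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r * r
    return debris & lumen


def generate_organoid_phantom(spec: PhantomSpec) -> tuple[RITomogram, PhantomTruth]:
    """Generate one synthetic organoid tomogram with ground truth.

    The RI field is ``n_medium + alpha * rho + N(0, noise_sd)`` where the
    density ``rho`` is drawn once per cell-sized Voronoi domain of the
    epithelial shell (live or dead distribution according to
    ``dead_fraction``), set to a small constant in the lumen fluid, drawn
    from the dead distribution inside debris blobs, and zero in the
    medium.  Negative density draws are clipped at zero (physical density
    is nonnegative); the additive noise term separately produces
    sub-medium RI voxels.

    Returns
    -------
    (RITomogram, PhantomTruth)
        Tomogram plus masks, per-voxel class labels, and exact volume and
        (pre-noise) mean density.
    """
    rng = np.random.default_rng(spec.seed)
    solid = _solid_mask(spec, rng)
    shell, lumen = _partition_shell(spec, solid)

    rho = np.zeros(spec.volume_shape_vox, dtype=np.float64)
    labels = np.full(spec.volume_shape_vox, LABEL_BACKGROUND, dtype=np.uint8)

    if spec.uniform_density is not None:
        rho[solid] = spec.uniform_density
        labels[solid] = LABEL_LIVE
    else:
        cell_labels, n_cells = _voronoi_cell_labels(
            shell, spec.voxel_spacing_um, spec.cell_diameter_um, rng
        )
        is_dead_cell = rng.random(n_cells) < spec.dead_fraction
        cell_density = np.where(
            is_dead_cell,
            rng.normal(spec.dead_density_mean, spec.dead_density_sd, n_cells),
            rng.normal(spec.live_density_mean, spec.live_density_sd, n_cells),
        )
        cell_density = np.clip(cell_density, 0.0, None)
        lut = np.concatenate([[0.0], cell_density])
        rho[shell] = lut[cell_labels[shell]]
        lab_lut = np.concatenate(
            [[LABEL_BACKGROUND], np.where(is_dead_cell, LABEL_DEAD, LABEL_LIVE)]
        ).astype(np.uint8)
        labels[shell] = lab_lut[cell_labels[shell]]

        rho[lumen] = spec.lumen_density
        debris = _debris_blobs(spec, lumen, rng)
        if debris.any():
            rho[debris] = max(0.0, rng.normal(spec.dead_density_mean, spec.dead_density_sd))
            labels[debris] = LABEL_DEBRIS

    n = spec.n_medium + ALPHA_PROTEIN * rho
    if spec.noise_sd > 0:
        n = n + rng.normal(0.0, spec.noise_sd, size=n.shape)

    voxvol = float(np.prod(spec.voxel_spacing_um))
    truth = PhantomTruth(
        organoid_mask=solid,
        lumen_mask=lumen,
        live_dead_labels=labels,
        true_volume_um3=float(solid.sum()) * voxvol,
        true_mean_density=float(rho[solid].mean()),
    )
    tomo = RITomogram(
        values=n,
        voxel_spacing_um=spec.voxel_spacing_um,
        n_medium=spec.n_medium,
        identifier=f"phantom-{spec.geometry_kind}-seed{spec.seed}",
    )
    return tomo, truth


def generate_timelapse(
    spec: PhantomSpec,
    dead_fraction_schedule: list[float] | None = None,
) -> list[tuple[RITomogram, PhantomTruth]]:
    """Generate a time-lapse series with exponential volume growth.

    The organoid's linear scale is multiplied by ``exp(k * t / 3)`` so
    the true volume follows ``V(t) = V0 * exp(k * t)`` with
    ``k = growth_rate_per_h`` and ``t = frame_index * frame_interval_h``.
    Shell thickness scales with the radius so the geometry is exactly
    self-similar.  An optional per-frame ``dead_fraction_schedule``
    emulates a cytotoxic (cisplatin-like) response.

    Raises
    ------
    GeometryError
        Naming the first frame whose grown geometry no longer fits the
        volume bounds.
    """
    if spec.n_frames < 2:
        raise ValueError("a time-lapse needs n_frames >= 2")
    if dead_fraction_schedule is not None and len(dead_fraction_schedule) != spec.n_frames:
        raise ValueError("dead_fraction_schedule must have one entry per frame")
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_frames) % (2**31)
    frames = []
    for i in range(spec.n_frames):
        t = i * spec.frame_interval_h
        s = float(np.exp(spec.growth_rate_per_h * t / 3.0))
        frame_spec = replace(
            spec,
            outer_radius_um=spec.outer_radius_um * s,
            shell_thickness_um=spec.shell_thickness_um * s,
            dead_fraction=(
                dead_fraction_schedule[i]
                if dead_fraction_schedule is not None
                else spec.dead_fraction
            ),
            n_frames=1,
            seed=int(seeds[i]),
        )
        try:
            tomo, truth = generate_organoid_phantom(frame_spec)
        except GeometryError as e:
            raise GeometryError(f"frame {i} (t = {t} h): {e}") from e
        tomo.timestamp_h = t
        tomo.identifier = f"phantom-t{t:05.1f}h-seed{spec.seed}"
        frames.append((tomo, truth))
    return frames


def generate_tileset(
    spec: PhantomSpec,
    grid: tuple[int, int],
    overlap_um: float = 15.0,
    jitter_vox: int = 5,
) -> tuple[TileSet, PhantomTruth, RITomogram]:
    """Cut a master phantom into laterally overlapping tiles.

    A single master phantom is generated on an enlarged lateral canvas
    and cut into ``rows x cols`` tiles of shape ``spec.volume_shape_vox``
    with the configured nominal overlap.  Each tile's true cut position
    is its nominal grid position plus independent uniform integer jitter
    in ``[-jitter_vox, +jitter_vox]`` per lateral axis, emulating the
    limited precision of the motorized stage.

    Returns
    -------
    (TileSet, PhantomTruth, RITomogram)
        The tile set (carrying nominal offsets), the master phantom's
        ground truth with ``true_offsets_vox`` filled in (absolute
        master-volume coordinates of each tile's corner), and the master
        tomogram itself — the oracle a stitched mosaic is compared to.
    """
    rows, cols = grid
    nx, ny, nz = spec.volume_shape_vox
    dx = spec.voxel_spacing_um[0]
    ov = int(round(overlap_um / dx))
    if ov < 4:
        raise ValueError(f"overlap of {overlap_um} µm is {ov} voxels; need >= 4")
    if ov >= min(nx, ny):
        raise ValueError("tiles smaller than the overlap")
    if jitter_vox < 0 or jitter_vox >= ov:
        raise ValueError("jitter must be nonnegative and smaller than the overlap")

    margin = jitter_vox
    master_shape = (
        nx + (cols - 1) * (nx - ov) + 2 * margin,
        ny + (rows - 1) * (ny - ov) + 2 * margin,
        nz,
    )
    # scale the organoid to fill the mosaic field of view
    master_extent = min(master_shape[0] * dx, master_shape[1] * spec.voxel_spacing_um[1])
    radius = min(spec.outer_radius_um, 0.45 * master_extent)
    master_spec = replace(
        spec,
        volume_shape_vox=master_shape,
        outer_radius_um=radius,
        shell_thickness_um=min(spec.shell_thickness_um, radius),
        allow_axial_clip=True,
    )
    master, truth = generate_organoid_phantom(master_spec)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7113]).generate_state(1)[0])
    tiles, nominals, trues = [], [], []
    for r in range(rows):
        for c in range(cols):
            ox_nom = margin + c * (nx - ov)
            oy_nom = margin + r * (ny - ov)
            jx = int(rng.integers(-jitter_vox, jitter_vox + 1))
            jy = int(rng.integers(-jitter_vox, jitter_vox + 1))
            ox, oy = ox_nom + jx, oy_nom + jy
            tile = RITomogram(
                values=master.values[ox : ox + nx, oy : oy + ny, :].copy(),
                voxel_spacing_um=spec.voxel_spacing_um,
                n_medium=spec.n_medium,
                origin_um=(ox * dx, oy * spec.voxel_spacing_um[1]),
                identifier=f"tile-r{r}c{c}",
            )
            tiles.append(tile)
            nominals.append((ox_nom, oy_nom))
            trues.append((ox, oy))
    truth.true_offsets_vox = trues
    tileset = TileSet(tiles=tiles, nominal_offsets_vox=nominals, overlap_um=overlap_um)
    return tileset, truth, master
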