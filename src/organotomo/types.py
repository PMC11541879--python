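"""Core data containers for refractive-index tomography analysis.

Conventions
-----------
* Volumes are ``float`` (RI) or ``bool`` (masks) numpy arrays indexed
  ``[x, y, z]``; the axial index ``z = 0`` is the slice nearest the
  coverslip.
* All coordinates are 0-based; ranges are half-open ``[lo, hi)``.
* Physical sizes are micrometres, times are hours, densities are g/mL
  (numerically equal to pg/µm³), masses are ng.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Specific refractive increment of protein, mL/g.  RI elevation per unit
#: mass concentration: n = n_medium + ALPHA_PROTEIN * rho.
ALPHA_PROTEIN: float = 0.185

#: Default refractive index of the imaging medium (not stated by typical
#: instrument metadata; must be recorded explicitly).
DEFAULT_N_MEDIUM: float = 1.337


@dataclass
class RITomogram:
    """A 3D refractive-index field with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Refractive index per voxel (dimensionless, finite).
    voxel_spacing_um : tuple of float
        ``(dx, dy, dz)`` voxel pitch in µm, strictly positive.
    n_medium : float
        Refractive index of the surrounding medium; the reference for
        density conversion.
    origin_um : tuple of float
        ``(x, y)`` stage coordinate of voxel (0, 0), µm.
    timestamp_h : float
        Time since the start of the series, hours.
    identifier : str
        Free-form identifier (file stem, tile index, ...).
    """

    values: np.ndarray
    voxel_spacing_um: tuple[float, float, float]
    n_medium: float = DEFAULT_N_MEDIUM
    origin_um: tuple[float, float] = (0.0, 0.0)
    timestamp_h: float = 0.0
    identifier: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"tomogram must be 3D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tomogram contains non-finite RI values")
        self.voxel_spacing_um = tuple(float(s) for s in self.voxel_spacing_um)
        if len(self.voxel_spacing_um) != 3 or any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError(f"voxel spacing must be 3 positive lengths, got {self.voxel_spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_spacing_um
        return dx * dy * dz

    def with_values(self, values: np.ndarray, **changes) -> "RITomogram":
        return replace(self, values=values, **changes)


@dataclass
class VolumeMask:
    """Boolean volume aligned to a tomogram, delimiting an analysis region."""

    values: np.ndarray
    label: str = ""
    z_range: tuple[int, int] | None = None  # half-open [z0, z1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


# Masks only differ by role; distinct names keep signatures self-documenting.
OrganoidMask = VolumeMask
LumenMask = VolumeMask


@dataclass
class TileSet:
    """Laterally tiled tomograms to be stitched into a mosaic.

    ``nominal_offsets_vox`` are the stage-reported (ox, oy) integer voxel
    positions of each tile's (0, 0) corner in mosaic coordinates.
    """

    tiles: list[RITomogram]
    nominal_offsets_vox: list[tuple[int, int]]
    overlap_um: float

    def __post_init__(self) -> None:
        if len(self.tiles) != len(self.nominal_offsets_vox):
            raise ValueError("one nominal offset per tile required")
        if not self.tiles:
            raise ValueError("empty tile set")
        sp0 = self.tiles[0].voxel_spacing_um
        nz0 = self.tiles[0].shape[2]
        for t in self.tiles[1:]:
            if t.voxel_spacing_um != sp0 or t.shape[2] != nz0:
                raise ValueError("all tiles must share voxel spacing and slice count")
        self.nominal_offsets_vox = [(int(ox), int(oy)) for ox, oy in self.nominal_offsets_vox]

    @property
    def overlap_vox(self) -> int:
        return int(round(self.overlap_um / self.tiles[0].voxel_spacing_um[0]))


@dataclass
class GradientStack:
    """Per-slice Sobel gradient magnitude of a tomogram (RI per voxel)."""

    values: np.ndarray
    per_slice_mean: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.per_slice_mean = np.asarray(self.per_slice_mean, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("gradient stack must be 3D")
        if self.per_slice_mean.shape != (self.values.shape[2],):
            raise ValueError("per_slice_mean must have one entry per axial slice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class OffsetEstimate:
    """Calibrated lateral offset between a pair of adjacent tiles."""

    pair: tuple[int, int]
    offset_vox: tuple[int, int]
    pearson_r: float
    overlap_vox: int
    fallback: bool = False  # True when the overlap had zero variance


@dataclass
class DepthCodedProjection:
    """Depth-color-coded maximum-intensity projection of a gradient stack."""

    intensity: np.ndarray  # (nx, ny) column max
    depth_um: np.ndarray  # (nx, ny) axial position of the max, µm
    rgb: np.ndarray  # (nx, ny, 3) float in [0, 1]
    colormap_name: str


@dataclass
class FeatureRecord:
    """Morphometric summary of one region at one timepoint."""

    timestamp_h: float
    region: str  # "organoid" | "lumen"
    volume_um3: float
    mean_density: float  # g/mL == pg/µm³
    dry_mass_ng: float
    mean_ri: float
    normalized_volume: float = float("nan")
    normalized_density: float = float("nan")
    normalized_mass: float = float("nan")


@dataclass
class GroupComparison:
    """Two-sample comparison of subvolume densities (unpaired t test)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    test_variant: str = "student"  # "student" (pooled) | "welch"


@dataclass
class PhantomSpec:
    """Parameters of a synthetic organoid tomogram.

    Defaults reproduce the measured density statistics of live- and
    dead-cell-dominant epithelial regions (g/mL): live 0.115 ± 0.050,
    dead 0.101 ± 0.048, with medium RI 1.337 and the instrument's
    lateral/axial voxel pitch 0.155/0.947 µm.  Tests may use coarser
    spacings; the statistics are what the analysis relies on.
    """

    geometry_kind: str = "enterocystic"  # "enterocystic" | "multilobular"
    outer_radius_um: float = 30.0
    shell_thickness_um: float = 12.0
    n_lobes: int = 3
    voxel_spacing_um: tuple[float, float, float] = (0.155, 0.155, 0.947)
    volume_shape_vox: tuple[int, int, int] = (96, 96, 48)
    n_medium: float = DEFAULT_N_MEDIUM
    live_density_mean: float = 0.115
    live_density_sd: float = 0.050
    dead_density_mean: float = 0.101
    dead_density_sd: float = 0.048
    dead_fraction: float = 0.0
    debris_count: int = 3
    noise_sd: float = 0.002
    growth_rate_per_h: float = 0.02
    frame_interval_h: float = 1.0
    n_frames: int = 1
    seed: int = 0
    # Cell-scale texture: Voronoi domains of roughly this diameter get one
    # density draw each, so subvolume cubes contain whole-cell-like regions.
    cell_diameter_um: float = 10.0
    # Density of lumen fluid outside debris blobs (g/mL); small but nonzero
    # so the lumen reads slightly above the medium, as in real tomograms.
    lumen_density: float = 0.02
    # When set, every in-organoid voxel gets exactly this density: a uniform
    # calibration phantom (no cell texture, no debris).
    uniform_density: float | None = None
    # Allow the organoid to be clipped by the axial bounds (the instrument's
    # depth range is limited; large organoids always are).  Lateral clipping
    # is still a geometry error.
    allow_axial_clip: bool = False

    def __post_init__(self) -> None:
        if self.geometry_kind not in ("enterocystic", "multilobular"):
            raise ValueError(f"unknown geometry kind {self.geometry_kind!r}")
        if not (0 < self.shell_thickness_um <= self.outer_radius_um):
            # equality => solid (lumen-free) phantom
            raise ValueError("need 0 < shell_thickness_um <= outer_radius_um")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacings must be positive")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


# Label codes used in PhantomTruth.live_dead_labels.
LABEL_BACKGROUND = 0
LABEL_LIVE = 1
LABEL_DEAD = 2
LABEL_DEBRIS = 3


@dataclass
class PhantomTruth:
    """Ground truth accompanying a synthetic phantom.

    Stands in for the fluorescence live/dead labels of a stained
    acquisition: every voxel carries its generating class, and the masks
    and scalar summaries are exact by construction.
    """

    organoid_mask: np.ndarray  # bool, solid organoid (shell + lumen)
    lumen_mask: np.ndarray  # bool, enclosed cavity (including debris)
    live_dead_labels: np.ndarray  # uint8 per-voxel label codes
    true_volume_um3: float
    true_mean_density: float
    true_offsets_vox: list[tuple[int, int]] = field(default_factory=list)
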