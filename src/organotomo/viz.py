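"""Depth-color-coded maximum-intensity projections.

Renders a 3D gradient stack onto a single plane: each pixel takes the
maximum gradient along z, colored by the axial position of that maximum,
so 2D figures retain the axial structure of the organoid.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps

from .types import DepthCodedProjection, GradientStack

__all__ = ["depth_coded_mip", "save_projection_png"]


def depth_coded_mip(
    gradient: GradientStack,
    colormap: str = "turbo",
    z_range: tuple[int, int] | None = None,
    voxel_spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DepthCodedProjection:
    """Depth-coded maximum-intensity projection of a gradient stack.

    Per lateral position the maximum over ``z_range`` is taken (ties
    toward smaller z, so an all-zero column reports depth 0).  Hue
    encodes the depth of the maximum through ``colormap``; brightness
    encodes the intensity normalized to the image's own maximum (pure
    display scaling — quantitation never reads from projections).
    """
    nz = gradient.shape[2]
    z0, z1 = z_range if z_range is not None else (0, nz)
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or invalid z_range {(z0, z1)} for {nz} slices")
    sub = gradient.values[:, :, z0:z1]
    zmax = sub.argmax(axis=2)  # first max -> smaller z on ties
    intensity = np.take_along_axis(sub, zmax[:, :, None], axis=2)[:, :, 0]
    dz = voxel_spacing_um[2]
    depth_um = (zmax + z0) * dz
    depth_norm = (zmax + z0) / max(nz - 1, 1)
    cmap = colormaps[colormap]
    rgb = np.asarray(cmap(depth_norm))[:, :, :3]
    peak = intensity.max()
    value = intensity / peak if peak > 0 else np.zeros_like(intensity)
    rgb = rgb * value[:, :, None]
    return DepthCodedProjection(
        intensity=intensity, depth_um=depth_um, rgb=rgb, colormap_name=colormap
    )


def save_projection_png(
    proj: DepthCodedProjection, path: str | Path, depth_extent_um: float | None = None
) -> Path:
    """Save a projection as PNG with its depth color bar."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    # memory (x, y) -> image rows = y
    ax.imshow(np.transpose(proj.rgb, (1, 0, 2)), origin="lower")
    ax.set_xlabel("x (vox)")
    ax.set_ylabel("y (vox)")
    sm = plt.cm.ScalarMappable(
        cmap=proj.colormap_name,
        norm=plt.Normalize(0, depth_extent_um or proj.depth_um.max() or 1.0),
    )
    fig.colorbar(sm, ax=ax, label="depth (µm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
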