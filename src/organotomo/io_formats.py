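"""Reading and writing volumetric stacks, masks, tables and configuration.

Conventions (stable across the package):

* TIFF page ``k`` is axial slice ``z = k``; within a page, rows map to
  ``y`` and columns to ``x``.  In memory, volumes are indexed
  ``[x, y, z]``.
* ``z = 0`` is the slice nearest the coverslip.
* All coordinates 0-based; ranges half-open ``[lo, hi)``.
* Feature tables are CSV with unit-suffixed column names
  (``volume_um3``, ``density_g_per_ml``, ``mass_ng``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import RITomogram, VolumeMask

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
    "write_truth_table",
    "read_truth_table",
    "load_config",
    "save_config",
]

_DESC_KEY = "organotomo"


def _pages_to_volume(pages: np.ndarray) -> np.ndarray:
    # pages: (z, y, x) -> memory (x, y, z)
    return np.ascontiguousarray(pages.transpose(2, 1, 0))


def _volume_to_pages(volume: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(volume.transpose(2, 1, 0))


def write_stack(tomogram: RITomogram, path: str | Path) -> Path:
    """Write a tomogram as an OME-TIFF stack (one page per axial slice).

    Voxel spacing is recorded in the OME pixel-size fields; the medium
    RI, origin and timestamp go into the image description so a round
    trip through :func:`read_stack` is lossless.
    """
    path = Path(path)
    dx, dy, dz = tomogram.voxel_spacing_um
    desc = {
        "n_medium": tomogram.n_medium,
        "origin_um": list(tomogram.origin_um),
        "timestamp_h": tomogram.timestamp_h,
        "identifier": tomogram.identifier,
    }
    tifffile.imwrite(
        path,
        _volume_to_pages(tomogram.values.astype(np.float32)),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "Description": json.dumps({_DESC_KEY: desc}),
        },
    )
    return path


def read_stack(
    path: str | Path,
    voxel_spacing_um: tuple[float, float, float] | None = None,
    n_medium: float | None = None,
    ri_offset: float | None = None,
    ri_slope: float | None = None,
) -> RITomogram:
    """Read a multi-page TIFF / OME-TIFF stack as an RI tomogram.

    Spacing must be embedded (OME pixel sizes, as written by
    :func:`write_stack`) or supplied explicitly — it is never assumed.
    Integer-encoded stacks additionally require the affine intensity→RI
    rescale ``ri = ri_offset + ri_slope * raw``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        pages = series.asarray()
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise ValueError(f"{path}: expected a single-channel z-stack, got shape {pages.shape}")
        meta = _embedded_metadata(tf)
    spacing = voxel_spacing_um or meta.get("voxel_spacing_um")
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing embedded; pass voxel_spacing_um=(dx, dy, dz) explicitly"
        )
    if np.issubdtype(pages.dtype, np.integer):
        if ri_offset is None or ri_slope is None:
            raise ValueError(
                f"{path}: integer-encoded stack requires ri_offset and ri_slope"
            )
        values = ri_offset + ri_slope * pages.astype(np.float64)
    else:
        values = pages.astype(np.float64)
    desc = meta.get("desc", {})
    return RITomogram(
        values=_pages_to_volume(values),
        voxel_spacing_um=tuple(spacing),
        n_medium=n_medium if n_medium is not None else desc.get("n_medium", RITomogram.n_medium),
        origin_um=tuple(desc.get("origin_um", (0.0, 0.0))),
        timestamp_h=desc.get("timestamp_h", 0.0),
        identifier=desc.get("identifier", path.stem),
    )


def _embedded_metadata(tf: tifffile.TiffFile) -> dict:
    meta: dict = {}
    ome = tf.ome_metadata
    if ome:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is not None and all(
            f"PhysicalSize{a}" in px.attrib for a in "XYZ"
        ):
            meta["voxel_spacing_um"] = tuple(
                float(px.attrib[f"PhysicalSize{a}"]) for a in "XYZ"
            )
        desc_el = root.find(".//ome:Image/ome:Description", ns)
        if desc_el is not None and desc_el.text:
            try:
                meta["desc"] = json.loads(desc_el.text).get(_DESC_KEY, {})
            except json.JSONDecodeError:
                pass
    return meta


def write_mask(mask: VolumeMask | np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit {0, 255} TIFF stack."""
    path = Path(path)
    values = mask.values if isinstance(mask, VolumeMask) else np.asarray(mask)
    if values.dtype != bool:
        raise ValueError("mask must be boolean")
    tifffile.imwrite(
        path,
        _volume_to_pages(values.astype(np.uint8) * 255),
        photometric="minisblack",
    )
    return path


def read_mask(path: str | Path, label: str = "") -> VolumeMask:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return VolumeMask(values=_pages_to_volume(pages) > 0, label=label or Path(path).stem)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV (one-line unit-suffixed header)."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


_TRUTH_SCHEMA = {"true_volume_um3", "true_mean_density", "n_medium"}


def write_truth_table(truth_dict: dict, path: str | Path) -> Path:
    """Write a phantom ground-truth summary as JSON (schema-checked)."""
    missing = _TRUTH_SCHEMA - truth_dict.keys()
    if missing:
        raise ValueError(f"truth table missing required keys: {sorted(missing)}")
    path = Path(path)
    path.write_text(json.dumps(truth_dict, indent=2, default=float))
    return path


def read_truth_table(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    missing = _TRUTH_SCHEMA - data.keys()
    if missing:
        raise ValueError(f"truth table missing required keys: {sorted(missing)}")
    return data


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
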