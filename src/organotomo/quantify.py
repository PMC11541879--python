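"""Volume, protein density and dry mass from masked RI volumes.

The refractive index of biological material rises linearly with the
mass concentration of dissolved and structural protein:

    n(v) = n_medium + alpha * rho(v),      alpha = 0.185 mL/g

so the per-voxel protein density is ``rho = (n - n_medium) / alpha`` in
g/mL, numerically equal to pg/µm³.  Volume is the exact in-mask voxel
count times the voxel volume; dry mass is mean density times volume
(pg -> ng).  Longitudinal tracks are normalized against the first
timepoint of the series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ALPHA_PROTEIN, FeatureRecord, RITomogram, VolumeMask

__all__ = [
    "density_map",
    "region_features",
    "region_histogram",
    "track_features",
    "fit_growth",
]

PG_PER_NG = 1000.0


def density_map(tomogram: RITomogram, alpha: float = ALPHA_PROTEIN) -> np.ndarray:
    """Per-voxel protein density (g/mL) from the RI field.

    No clipping: voxels below the medium RI (possible under noise) map
    to negative densities and are retained, keeping means unbiased under
    symmetric noise.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if tomogram.n_medium is None or not np.isfinite(tomogram.n_medium):
        raise ValueError("tomogram has no n_medium; density conversion needs a reference RI")
    return (tomogram.values - tomogram.n_medium) / alpha


def region_features(
    tomogram: RITomogram,
    mask: VolumeMask,
    alpha: float = ALPHA_PROTEIN,
    region: str = "organoid",
) -> FeatureRecord:
    """Volume, mean density, dry mass and mean RI of a masked region."""
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    if mask.shape != tomogram.shape:
        raise ValueError("mask not aligned to tomogram")
    m = mask.values
    rho = density_map(tomogram, alpha)[m]
    volume_um3 = mask.voxel_count * tomogram.voxel_volume_um3
    mean_density = float(rho.mean())
    # g/mL == pg/µm³; density * volume is pg, report ng
    dry_mass_ng = mean_density * volume_um3 / PG_PER_NG
    return FeatureRecord(
        timestamp_h=tomogram.timestamp_h,
        region=region,
        volume_um3=volume_um3,
        mean_density=mean_density,
        dry_mass_ng=dry_mass_ng,
        mean_ri=float(tomogram.values[m].mean()),
    )


def region_histogram(
    tomogram: RITomogram,
    mask: VolumeMask,
    bin_edges: np.ndarray,
    alpha: float = ALPHA_PROTEIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-voxel protein density restricted to the mask.

    The mask designates the region of interest so non-organoid voxels
    never enter the distribution.  Out-of-range voxels are clipped into
    the outer bins so the counts always sum to the in-mask voxel count.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    rho = density_map(tomogram, alpha)[mask.values]
    rho = np.clip(rho, bin_edges[0], np.nextafter(bin_edges[-1], -np.inf))
    counts, edges = np.histogram(rho, bins=bin_edges)
    return counts, edges


_NORM_COLUMNS = {
    "volume_um3": "normalized_volume",
    "mean_density": "normalized_density",
    "dry_mass_ng": "normalized_mass",
}


def track_features(
    series: list[tuple[RITomogram, dict[str, VolumeMask]]],
    alpha: float = ALPHA_PROTEIN,
) -> pd.DataFrame:
    """Longitudinal feature table over a time-lapse series.

    ``series`` is a list of ``(tomogram, {region_name: mask})`` frames.
    One row per frame per region; ``normalized_*`` columns divide by the
    region's first-frame value (first row of each region is exactly 1).
    """
    if not series:
        raise ValueError("empty series")
    records = []
    for tomo, masks in series:
        for region, mask in masks.items():
            rec = region_features(tomo, mask, alpha, region=region)
            records.append(rec.__dict__)
    df = pd.DataFrame.from_records(records).sort_values(
        ["region", "timestamp_h"], kind="stable"
    )
    for src, dst in _NORM_COLUMNS.items():
        first = df.groupby("region")[src].transform("first")
        if (first == 0).any():
            bad = df.loc[first == 0, "region"].unique().tolist()
            raise ValueError(f"first-frame value of {src} is zero for {bad}; cannot normalize")
        df[dst] = df[src] / first
    return df.reset_index(drop=True)


def fit_growth(
    times_h: np.ndarray, volumes_um3: np.ndarray
) -> tuple[float, float]:
    """Exponential growth rate (1/h) from a volume-vs-time track.

    Least-squares slope of ``log(volume)`` against time, with its
    standard error.  Requires >= 3 frames of positive volume.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(volumes_um3, dtype=float)
    if t.size != v.size or t.size < 3:
        raise ValueError("growth fit needs >= 3 matched (time, volume) points")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive for a log-linear growth fit")
    res = stats.linregress(t, np.log(v))
    return float(res.slope), float(res.stderr)
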