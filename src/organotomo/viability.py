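"""Subvolume partitioning and live/dead density statistics.

Single-cell instance segmentation inside organoids is impeded by
indistinct cell boundaries, so viability statistics operate on fixed
cubic subvolumes instead: the masked volume is tiled into cubes large
enough to contain an entire enterocyte (50 µm laterally, 10 µm axially
by default), the mean protein density of the in-mask voxels of each
cube is one sample, and groups of cubes (vehicle vs drug, live-dominant
vs dead-dominant) are compared with a two-tailed unpaired t test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .types import (
    ALPHA_PROTEIN,
    LABEL_DEAD,
    LABEL_DEBRIS,
    LABEL_LIVE,
    GroupComparison,
    RITomogram,
    VolumeMask,
)
from .quantify import density_map

__all__ = [
    "partition_subvolumes",
    "compare_groups",
    "classify_subvolumes",
    "DegenerateVarianceError",
]

DEFAULT_CUBE_LATERAL_UM = 50.0
DEFAULT_CUBE_AXIAL_UM = 10.0
DEFAULT_MIN_COVERAGE = 0.5


class DegenerateVarianceError(ValueError):
    """Both samples have zero variance but different means."""


def partition_subvolumes(
    tomogram: RITomogram,
    mask: VolumeMask,
    alpha: float = ALPHA_PROTEIN,
    cube_lateral_um: float = DEFAULT_CUBE_LATERAL_UM,
    cube_axial_um: float = DEFAULT_CUBE_AXIAL_UM,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    group: str = "",
    truth_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tile the masked volume into cubes and summarize density per cube.

    A fixed grid of ``cube_lateral_um x cube_lateral_um x cube_axial_um``
    boxes is anchored at the minimum corner of the mask's bounding box
    (so cube content does not depend on empty padding).  Per cube, the
    mean density is taken over in-mask voxels only; ``coverage`` is the
    in-mask fraction of the (nominal) cube, and cubes below
    ``min_coverage`` are dropped.

    If a phantom's per-voxel label volume is supplied, each cube also
    gets a ``truth_label`` of ``live-dominant`` or ``dead-dominant`` by
    majority of its in-mask labeled voxels.

    Returns a table with columns ``cube_i/j/k``, ``centroid_x/y/z_um``,
    ``mean_density_g_per_ml``, ``coverage``, ``n_voxels``, ``group`` and
    optionally ``truth_label``.
    """
    if mask.voxel_count == 0:
        raise ValueError("empty mask")
    dx, dy, dz = tomogram.voxel_spacing_um
    cx = max(1, int(round(cube_lateral_um / dx)))
    cy = max(1, int(round(cube_lateral_um / dy)))
    cz = max(1, int(round(cube_axial_um / dz)))
    rho = density_map(tomogram, alpha)
    m = mask.values
    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    cube_vox = cx * cy * cz
    rows = []
    for i, x0 in enumerate(range(lo[0], hi[0], cx)):
        for j, y0 in enumerate(range(lo[1], hi[1], cy)):
            for k, z0 in enumerate(range(lo[2], hi[2], cz)):
                sl = (
                    slice(x0, min(x0 + cx, m.shape[0])),
                    slice(y0, min(y0 + cy, m.shape[1])),
                    slice(z0, min(z0 + cz, m.shape[2])),
                )
                inmask = m[sl]
                n_vox = int(inmask.sum())
                if n_vox == 0:
                    continue
                coverage = n_vox / cube_vox
                if coverage < min_coverage:
                    continue
                row = {
                    "cube_i": i,
                    "cube_j": j,
                    "cube_k": k,
                    "centroid_x_um": (x0 + cx / 2) * dx,
                    "centroid_y_um": (y0 + cy / 2) * dy,
                    "centroid_z_um": (z0 + cz / 2) * dz,
                    "mean_density_g_per_ml": float(rho[sl][inmask].mean()),
                    "coverage": coverage,
                    "n_voxels": n_vox,
                    "group": group,
                }
                if truth_labels is not None:
                    lab = truth_labels[sl][inmask]
                    n_live = int((lab == LABEL_LIVE).sum())
                    n_dead = int(((lab == LABEL_DEAD) | (lab == LABEL_DEBRIS)).sum())
                    row["truth_label"] = (
                        "dead-dominant" if n_dead >= n_live else "live-dominant"
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def _summarize(sample) -> tuple[float, float, int]:
    """(mean, sd, n) from raw data or an already-summarized triple."""
    if isinstance(sample, tuple) and len(sample) == 3:
        mean, sd, n = sample
        return float(mean), float(sd), int(n)
    arr = np.asarray(sample, dtype=float)
    if arr.size < 2:
        raise ValueError("each sample needs n >= 2")
    sd = 0.0 if np.ptp(arr) == 0 else float(arr.std(ddof=1))
    return float(arr.mean()), sd, int(arr.size)


def compare_groups(a, b, variant: str = "student") -> GroupComparison:
    """Two-tailed unpaired t test between two density samples.

    ``a`` and ``b`` are either raw 1D samples or ``(mean, sd, n)``
    summary triples; both routes give identical results for matching
    summaries.  ``variant="student"`` (default) pools the variance;
    ``variant="welch"`` uses the unequal-variance statistic with
    Welch–Satterthwaite degrees of freedom.

    Zero variance in both groups with equal means yields t = 0, p = 1 by
    convention; with unequal means the statistic is undefined and a
    :class:`DegenerateVarianceError` is raised.
    """
    ma, sa, na = _summarize(a)
    mb, sb, nb = _summarize(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    if variant == "student":
        df = na + nb - 2.0
        sp2 = ((na - 1) * sa**2 + (nb - 1) * sb**2) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variant == "welch":
        va, vb = sa**2 / na, sb**2 / nb
        se = np.sqrt(va + vb)
        if se > 0:
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        else:
            df = na + nb - 2.0
    else:
        raise ValueError(f"unknown test variant {variant!r}")
    if se == 0:
        if ma == mb:
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                "zero variance in both groups with unequal means"
            )
    else:
        t_stat = (ma - mb) / se
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return GroupComparison(
        mean_a=ma, mean_b=mb, sd_a=sa, sd_b=sb,
        sem_a=sa / np.sqrt(na), sem_b=sb / np.sqrt(nb),
        n_a=na, n_b=nb,
        t_statistic=float(t_stat), degrees_of_freedom=float(df), p_value=float(p),
        test_variant=variant,
    )


def classify_subvolumes(
    table: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Optional convenience: threshold cube densities into live/dead calls.

    A cube is ``dead-like`` iff its mean density is below ``threshold``.
    Returns the table with a ``call`` column, the viability fraction
    (live-like cubes / all cubes), and its 95% Wilson score interval.
    """
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    out = table.copy()
    out["call"] = np.where(
        out["mean_density_g_per_ml"] < threshold, "dead-like", "live-like"
    )
    n = len(out)
    n_live = int((out["call"] == "live-like").sum())
    frac = n_live / n if n else float("nan")
    lo, hi = proportion_confint(n_live, n, alpha=0.05, method="wilson") if n else (np.nan, np.nan)
    return out, frac, (float(lo), float(hi))
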