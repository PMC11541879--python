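"""Gradient computation, axial cropping, and organoid/lumen masking.

Sample-induced aberrations blur organoid boundaries in raw RI volumes;
a per-slice Sobel gradient restores sharp outlines, the mean gradient
per slice identifies the in-focus axial range, and masks are inferred
either by a supervised pixel classifier trained on sparse annotations
(a stand-in for an interactive tool) or by an unsupervised fallback
that thresholds the smoothed RI deviation from the medium.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier

from .types import GradientStack, LumenMask, OrganoidMask, RITomogram

__all__ = [
    "sobel_gradient_stack",
    "zcrop_by_gradient",
    "segment_organoid",
    "segment_lumen",
]

DEFAULT_ZCROP_THRESHOLD = 0.2

_SOBEL_DERIV = np.array([1.0, 0.0, -1.0])
_SOBEL_SMOOTH = np.array([1.0, 2.0, 1.0])


def sobel_gradient_stack(tomogram: RITomogram) -> GradientStack:
    """Per-slice Sobel gradient magnitude of an RI volume.

    Each XY slice is convolved with the standard 3x3 Sobel pair
    (reflective borders); the magnitude is ``sqrt(Gx^2 + Gy^2)``.  Slices
    are independent: no smoothing couples adjacent z planes.
    """
    v = tomogram.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("in-plane extent must be at least 3x3 for a Sobel gradient")
    v = v.astype(np.float64)
    gx = ndimage.correlate1d(
        ndimage.correlate1d(v, _SOBEL_DERIV, axis=0, mode="reflect"),
        _SOBEL_SMOOTH, axis=1, mode="reflect",
    )
    gy = ndimage.correlate1d(
        ndimage.correlate1d(v, _SOBEL_DERIV, axis=1, mode="reflect"),
        _SOBEL_SMOOTH, axis=0, mode="reflect",
    )
    mag = np.hypot(gx, gy)
    return GradientStack(
        values=mag,
        per_slice_mean=mag.mean(axis=(0, 1)),
        source=tomogram.identifier,
    )


def zcrop_by_gradient(
    gradient: GradientStack, rel_threshold: float = DEFAULT_ZCROP_THRESHOLD
) -> tuple[int, int]:
    """Axial range of in-focus content, as a half-open slice interval.

    Returns the smallest ``[z0, z1)`` containing every slice whose mean
    gradient is at least ``rel_threshold`` times the maximum per-slice
    mean.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    means = gradient.per_slice_mean
    peak = means.max()
    if peak <= 0:
        raise ValueError("gradient stack has no content (all-zero per-slice means)")
    keep = np.flatnonzero(means >= rel_threshold * peak)
    return int(keep[0]), int(keep[-1]) + 1


def _ellipsoid_struct(radius_um: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element of physical radius on an anisotropic grid."""
    r_vox = [max(1, int(round(radius_um / d))) for d in spacing]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) / max(r, 1) for r in r_vox], indexing="ij", sparse=True
    )
    return sum(g * g for g in grids) <= 1.0


def _smooth_slices(volume: np.ndarray, sigma_vox: float) -> np.ndarray:
    # 2D smoothing per XY slice; axial slices stay independent
    return ndimage.gaussian_filter(volume, sigma=(sigma_vox, sigma_vox, 0.0), mode="nearest")


def _voxel_features(tomogram: RITomogram, gradient: GradientStack) -> np.ndarray:
    """Small fixed feature bank: multi-scale smoothed RI and gradient."""
    feats = [
        tomogram.values,
        _smooth_slices(tomogram.values, 1.0),
        _smooth_slices(tomogram.values, 3.0),
        gradient.values,
        _smooth_slices(gradient.values, 1.0),
        _smooth_slices(gradient.values, 3.0),
    ]
    return np.stack([f.astype(np.float32) for f in feats], axis=-1)


def _postprocess(
    candidate: np.ndarray,
    tomogram: RITomogram,
    z_range: tuple[int, int],
    min_volume_um3: float,
    closing_radius_um: float,
) -> list[OrganoidMask]:
    # Fill holes with tolerance: dim (low-density) cells punch windows
    # through the thresholded epithelial shell, so a plain per-slice hole
    # fill leaks.  Dilating by the closing radius bridges windows up to
    # twice that width, the fill then captures the lumen, and eroding by
    # the same radius restores the outer boundary (exactly, for locally
    # convex surfaces).  All distances are physical (anisotropy-aware).
    sampling = tomogram.voxel_spacing_um
    # speckle guard: tiny components would be welded together by the
    # dilation and survive the round trip; drop them first
    lab0, n0 = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
    if n0:
        sizes = np.bincount(lab0.ravel())
        sizes[0] = 0
        min_seed = max(1, int(round(0.05 * min_volume_um3 / tomogram.voxel_volume_um3)))
        candidate = np.isin(lab0, np.flatnonzero(sizes >= min_seed))
    # pad so the dilated surface never touches the array border (the EDT
    # round trip would otherwise under-erode there)
    pad = [max(1, int(np.ceil(closing_radius_um / d)) + 1) for d in sampling]
    padded = np.pad(candidate, [(p, p) for p in pad])
    dilated = ndimage.distance_transform_edt(~padded, sampling=sampling) <= closing_radius_um
    for z in range(dilated.shape[2]):
        dilated[:, :, z] = ndimage.binary_fill_holes(dilated[:, :, z])
    closed = ndimage.distance_transform_edt(dilated, sampling=sampling) > closing_radius_um
    closed = closed[pad[0] : -pad[0], pad[1] : -pad[1], pad[2] : -pad[2]]
    closed |= candidate
    for z in range(closed.shape[2]):
        closed[:, :, z] = ndimage.binary_fill_holes(closed[:, :, z])
    labels, n = ndimage.label(closed, structure=np.ones((3, 3, 3), dtype=bool))
    min_vox = max(1, int(round(min_volume_um3 / tomogram.voxel_volume_um3)))
    masks = []
    for k in range(1, n + 1):
        m = labels == k
        if m.sum() < min_vox:
            continue
        masks.append(
            OrganoidMask(values=m, label=f"organoid-{len(masks) + 1}", z_range=z_range)
        )
    masks.sort(key=lambda m: -m.voxel_count)
    return masks


def segment_organoid(
    tomogram: RITomogram,
    gradient: GradientStack,
    z_range: tuple[int, int],
    labels: np.ndarray | None = None,
    min_volume_um3: float = 500.0,
    closing_radius_um: float = 8.0,
    random_state: int = 0,
) -> list[OrganoidMask]:
    """Infer organoid-occupied regions within the in-focus z range.

    Two routes share the same contract (features + optional sparse
    labels -> masks):

    * **supervised** — ``labels`` marks a sparse subset of voxels as
      background (1) or organoid (2), 0 elsewhere; a random-forest pixel
      classifier over a fixed multi-scale feature bank (smoothed RI and
      gradient magnitude) is trained on them and applied to the cropped
      volume.  This stands in for interactive annotation tools.
    * **unsupervised fallback** (``labels=None``) — Otsu threshold on
      the slice-smoothed RI deviation from the medium.

    Either way, the candidate is morphologically closed, hole-filled per
    slice, stripped of components smaller than ``min_volume_um3``, and
    split into 26-connected components (largest first).  Masks never
    extend outside ``z_range``.
    """
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= tomogram.shape[2]):
        raise ValueError(f"invalid z_range {z_range} for {tomogram.shape[2]} slices")
    candidate = np.zeros(tomogram.shape, dtype=bool)
    if labels is not None:
        classes = np.unique(labels[labels > 0])
        if classes.size < 2:
            raise ValueError("supervised segmentation needs annotations from >= 2 classes")
        feats = _voxel_features(tomogram, gradient)
        train = labels > 0
        clf = RandomForestClassifier(
            n_estimators=50, random_state=random_state, n_jobs=1
        )
        clf.fit(feats[train], labels[train])
        sub = feats[:, :, z0:z1].reshape(-1, feats.shape[-1])
        pred = clf.predict(sub).reshape(tomogram.shape[0], tomogram.shape[1], z1 - z0)
        candidate[:, :, z0:z1] = pred == 2
    else:
        dev = _smooth_slices(tomogram.values - tomogram.n_medium, 1.0)
        sub = dev[:, :, z0:z1]
        if np.ptp(sub) == 0:
            return []
        thr = threshold_otsu(sub.ravel())
        raw = tomogram.values - tomogram.n_medium
        sigma_noise = 1.4826 * float(np.median(np.abs(raw - np.median(raw))))
        if thr <= 3.0 * sigma_noise:
            # no real contrast: Otsu is splitting the noise distribution
            warnings.warn("no foreground above the noise floor; empty result",
                          stacklevel=2)
            return []
        candidate[:, :, z0:z1] = dev[:, :, z0:z1] > thr
        # recover dim epithelium: voxels above a weak *unsmoothed* threshold
        # that are connected to the strong candidate (reconstruction by
        # dilation).  Raw values keep the boundary placement exact; the
        # noise floor keeps background speckle out of the weak set.
        weak = np.zeros_like(candidate)
        weak[:, :, z0:z1] = raw[:, :, z0:z1] > max(0.25 * thr, 3.0 * sigma_noise)
        candidate = ndimage.binary_propagation(candidate, mask=candidate | weak)
    masks = _postprocess(candidate, tomogram, z_range, min_volume_um3, closing_radius_um)
    if not masks:
        warnings.warn("segmentation produced no components above the minimum volume",
                      stacklevel=2)
    return masks


def segment_lumen(
    tomogram: RITomogram,
    organoid: OrganoidMask,
    rel_gradient_threshold: float = 1.0,
    min_lumen_fraction: float = 0.02,
    opening_radius_um: float = 5.0,
) -> LumenMask:
    """Segment the enclosed lumen of a (solid) organoid mask.

    The lumen candidate is the low-density interior of the per-slice
    hole-filled mask: voxels whose protein-scale RI deviation falls
    below a robust threshold between the cavity-fluid level and the
    epithelium median, intersected with low-gradient voxels.  The
    largest 26-connected component is smoothed by a morphological
    opening at the cell scale (removing single-cell bumps of dim
    epithelium), hole-filled per slice (debris belongs to the lumen),
    and must be genuinely enclosed by the mask; otherwise the lumen is
    empty and a warning is issued.
    """
    if organoid.voxel_count == 0:
        raise ValueError("organoid mask is empty")
    filled = organoid.values.copy()
    for z in range(filled.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(filled[:, :, z])
    dev_sm = _smooth_slices(tomogram.values - tomogram.n_medium, 1.0)
    dev = dev_sm[filled]
    p_low, med = np.percentile(dev, [5, 50])
    if med - p_low <= 0:
        warnings.warn("no density contrast inside mask; empty lumen", stacklevel=2)
        return LumenMask(values=np.zeros_like(filled), label="lumen")
    thr = p_low + 0.3 * (med - p_low)  # seeds: clearly fluid-like
    thr_extent = p_low + 0.5 * (med - p_low)  # extent: fluid/epithelium midpoint
    grad_sm = _smooth_slices(sobel_gradient_stack(tomogram).values, 1.0)
    shell_like = filled & (dev_sm >= thr)
    # p75 rather than the median: piecewise-constant cell interiors push
    # half the shell's gradient to (near) the noise floor, which is also
    # where the lumen fluid sits
    ref = float(np.percentile(grad_sm[shell_like], 75)) if shell_like.any() else 0.0
    if ref == 0.0:
        ref = float(grad_sm[filled].mean())
    grad_thr = rel_gradient_threshold * ref
    low = np.zeros_like(filled)
    low[filled] = dev_sm[filled] < thr
    low &= grad_sm < grad_thr
    labels, n = ndimage.label(low, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        warnings.warn("open or absent lumen; returning empty mask", stacklevel=2)
        return LumenMask(values=np.zeros_like(filled), label="lumen")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    cc = labels == counts.argmax()
    struct = _ellipsoid_struct(opening_radius_um, tomogram.voxel_spacing_um)
    cc = ndimage.binary_opening(cc, structure=struct)
    # the smoothed interface gradient vetoes a few voxels of lumen rim in
    # the seed set; recover the rim by a *bounded* geodesic dilation
    # within the low-density region (unbounded propagation would leak
    # through dim epithelial cells and out of the cavity)
    low_density = filled & (dev_sm < thr_extent)
    cc = ndimage.binary_dilation(cc, mask=low_density | cc, iterations=3)
    for z in range(cc.shape[2]):
        cc[:, :, z] = ndimage.binary_fill_holes(cc[:, :, z])
    cc &= filled
    enclosed_violation = ndimage.binary_dilation(
        cc, structure=np.ones((3, 3, 3), dtype=bool)
    ) & ~filled
    frac_open = enclosed_violation.sum() / max(1, cc.sum())
    if cc.sum() < min_lumen_fraction * filled.sum() or frac_open > 0.05:
        warnings.warn("open or absent lumen; returning empty mask", stacklevel=2)
        return LumenMask(values=np.zeros_like(filled), label="lumen")
    return LumenMask(values=cc, label="lumen", z_range=organoid.z_range)
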