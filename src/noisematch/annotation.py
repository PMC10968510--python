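"""Gold-standard lesion annotation via the modified PERCIST threshold.

Lesions are delineated as connected components of voxels whose SUV
exceeds a liver-background-derived cutoff::

    threshold = 1.5 * SUVmean + 2 * SD

where SUVmean and SD are measured in a normal-liver background region
of interest (ROI).  Contours drawn on one reconstruction can be
transferred to another grid by nearest-neighbour resampling in
physical coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _cc_label
from skimage.measure import regionprops

from .core import LesionMask, SUVImage, connectivity_for


@dataclass(frozen=True)
class PercistParams:
    """Coefficients of the modified PERCIST lesion threshold."""

    mean_coefficient: float = 1.5
    sd_coefficient: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_coefficient <= 0 or self.sd_coefficient <= 0:
            raise ValueError("PERCIST coefficients must be positive")


@dataclass(frozen=True)
class ROISpec:
    """A circular/spherical background ROI in physical units.

    ``center_offset_mm`` displaces the ROI from the liver centre.  The
    default diameter (30 mm) is the standard normal-liver reference
    region size for PERCIST-style reads; it is configurable.
    """

    center_offset_mm: tuple[float, ...] = (0.0, 0.0)
    diameter_mm: float = 30.0


@dataclass
class ROIStats:
    """Summary statistics of SUV inside a background ROI."""

    suv_mean: float
    suv_sd: float
    n_voxels: int
    roi_location: tuple = ()

    def __post_init__(self) -> None:
        if self.suv_mean <= 0:
            raise ValueError("ROI SUVmean must be positive")
        if self.suv_sd < 0:
            raise ValueError("ROI SD must be nonnegative")
        if self.n_voxels < 2:
            raise ValueError("ROI must contain at least 2 voxels")


def roi_mask(shape, spacing, center_vox, diameter_mm: float) -> np.ndarray:
    """Boolean mask of a circle/sphere of ``diameter_mm`` centred (in
    voxel coordinates, 0-based) at ``center_vox``."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(
        ((g - c) * sp) ** 2 for g, c, sp in zip(grids, center_vox, spacing)
    )
    return r2 <= (diameter_mm / 2.0) ** 2


def measure_roi(image: SUVImage, center_vox, diameter_mm: float = 30.0) -> ROIStats:
    """Measure mean and sample SD (n-1 denominator) of SUV in a ROI."""
    mask = roi_mask(image.shape, image.spacing, center_vox, diameter_mm)
    vals = image.voxels[mask]
    if vals.size < 2:
        raise ValueError("ROI contains fewer than 2 voxels")
    return ROIStats(
        suv_mean=float(vals.mean()),
        suv_sd=float(vals.std(ddof=1)),
        n_voxels=int(vals.size),
        roi_location=(tuple(center_vox), diameter_mm),
    )


def percist_threshold(roi: ROIStats, params: PercistParams | None = None) -> float:
    """Modified PERCIST lesion cutoff: 1.5 x SUVmean + 2 x SD.

    Linear in both ROI statistics, hence equivariant under a global
    rescaling of the image.
    """
    params = params or PercistParams()
    return params.mean_coefficient * roi.suv_mean + params.sd_coefficient * roi.suv_sd


def segment_lesions(
    image: SUVImage | np.ndarray,
    threshold: float,
    min_size: int = 1,
    spacing=None,
) -> LesionMask:
    """Label connected supra-threshold components, dropping small ones.

    Components are voxels with SUV strictly greater than ``threshold``,
    connected under 8-connectivity (2-D) / 26-connectivity (3-D).
    Components with fewer than ``min_size`` voxels are removed and the
    survivors relabeled contiguously.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(image, SUVImage):
        voxels = image.voxels
        spacing = image.spacing
    else:
        voxels = np.asarray(image)
        spacing = tuple(spacing) if spacing is not None else (1.0,) * voxels.ndim
    binary = voxels > threshold
    labels = _cc_label(binary, connectivity=connectivity_for(binary.ndim))
    if min_size > 1 and labels.max():
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_size)
        keep = keep[keep > 0]
        remap = np.zeros(counts.size, dtype=np.int32)
        remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
        labels = remap[labels]
    return LesionMask(labels.astype(np.int32), spacing=spacing)


def transfer_contours(
    mask: LesionMask,
    source_spacing,
    target_shape,
    target_spacing,
) -> LesionMask:
    """Resample a label mask onto another grid by nearest neighbour.

    Grids are aligned at the voxel-centre origin (0-based indices, no
    offsets); a target voxel takes the label of the nearest source
    voxel centre in mm.  Components that shrink below one target voxel
    are dropped with a warning and survivors are relabeled.
    """
    src = np.asarray(mask.labels)
    source_spacing = tuple(float(s) for s in source_spacing)
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_shape) != src.ndim or len(source_spacing) != src.ndim:
        raise ValueError("dimensionality mismatch between grids")
    src_extent = [(n - 1) * sp for n, sp in zip(src.shape, source_spacing)]
    tgt_extent = [(n - 1) * sp for n, sp in zip(target_shape, target_spacing)]
    if any(t > s + max(source_spacing) for s, t in zip(src_extent, tgt_extent)):
        # target reaches beyond the source field of view by more than
        # one voxel: treat as disjoint/incompatible extents
        raise ValueError("target grid extends beyond the source physical extent")
    idx = np.ogrid[tuple(slice(0, n) for n in target_shape)]
    nearest = tuple(
        np.clip(
            np.rint(g * tsp / ssp).astype(np.intp), 0, n - 1
        )
        for g, tsp, ssp, n in zip(idx, target_spacing, source_spacing, src.shape)
    )
    out = src[nearest]
    n_src = mask.n_components
    present = np.unique(out)
    present = present[present > 0]
    if len(present) < n_src:
        lost = sorted(set(range(1, n_src + 1)) - set(present.tolist()))
        warnings.warn(
            f"contour transfer dropped components {lost} "
            "(smaller than one target voxel)",
            stacklevel=2,
        )
    remap = np.zeros(n_src + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return LesionMask(remap[out], spacing=target_spacing)


def component_centroids_mm(mask: LesionMask) -> dict[int, tuple[float, ...]]:
    """Physical-coordinate centroid of each labeled component."""
    out = {}
    for prop in regionprops(np.asarray(mask.labels)):
        out[prop.label] = tuple(
            c * sp for c, sp in zip(prop.centroid, mask.spacing)
        )
    return out
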