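"""Background-noise quantification: COV summaries and paired tests.

The single noise metric is the coefficient of variation (COV) of SUV in
a normal-liver background ROI — sample SD over mean.  Reconstructions
are compared with classical paired t-tests on per-subject COV values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotation import ROISpec, ROIStats, measure_roi, roi_mask
from .core import LesionMask, SUVImage

__all__ = ["CovSummary", "compute_cov", "summarize_cov", "paired_cov_test"]


@dataclass
class CovSummary:
    """Per-subject background COV values for one reconstruction."""

    profile_name: str
    per_subject_cov: list[float]
    mean_cov: float
    sd_cov: float
    n_subjects: int

    @classmethod
    def from_values(cls, profile_name: str, values) -> "CovSummary":
        values = [float(v) for v in values]
        arr = np.asarray(values)
        return cls(
            profile_name=profile_name,
            per_subject_cov=values,
            mean_cov=float(arr.mean()),
            sd_cov=float(arr.std(ddof=1)) if len(values) > 1 else 0.0,
            n_subjects=len(values),
        )


def compute_cov(roi: ROIStats) -> float:
    """COV = SD / mean of SUV within the background ROI."""
    if roi.suv_mean <= 0:
        raise ValueError("ROI SUVmean must be positive to form a COV")
    return roi.suv_sd / roi.suv_mean


def _roi_center(image: SUVImage, roi_spec: ROISpec) -> tuple[float, ...]:
    return tuple(
        (n - 1) / 2.0 + off / sp
        for n, off, sp in zip(image.shape, roi_spec.center_offset_mm, image.spacing)
    )


_AVOIDANCE_OFFSETS_MM = [
    (0.0, 0.0),
    (10.0, 0.0), (-10.0, 0.0), (0.0, 10.0), (0.0, -10.0),
    (14.0, 14.0), (-14.0, 14.0), (14.0, -14.0), (-14.0, -14.0),
    (20.0, 0.0), (-20.0, 0.0), (0.0, 20.0), (0.0, -20.0),
]


def subject_background_cov(
    image: SUVImage,
    roi_spec: ROISpec | None = None,
    gold: LesionMask | None = None,
) -> float:
    """Background COV for one subject from a fixed ROI placement.

    If a gold mask is given, the ROI is shifted through a small set of
    candidate liver-interior offsets until it clears all lesions (the
    background ROI must sample normal liver); if no candidate clears,
    the least-overlapping one is used with a warning.
    """
    roi_spec = roi_spec or ROISpec()
    base = _roi_center(image, roi_spec)
    if gold is None or gold.n_components == 0:
        return compute_cov(measure_roi(image, base, roi_spec.diameter_mm))
    lesioned = np.asarray(gold.labels) > 0
    best_center, best_overlap = base, None
    for off in _AVOIDANCE_OFFSETS_MM:
        center = tuple(
            b + o / sp for b, o, sp in zip(base, off, image.spacing)
        )
        mask = roi_mask(image.shape, image.spacing, center, roi_spec.diameter_mm)
        overlap = int(np.count_nonzero(mask & lesioned))
        if overlap == 0:
            return compute_cov(measure_roi(image, center, roi_spec.diameter_mm))
        if best_overlap is None or overlap < best_overlap:
            best_center, best_overlap = center, overlap
    warnings.warn(
        "no lesion-free background ROI placement found; "
        f"using least-overlapping candidate ({best_overlap} voxels)",
        stacklevel=2,
    )
    return compute_cov(measure_roi(image, best_center, roi_spec.diameter_mm))


def summarize_cov(
    images,
    roi_spec: ROISpec | None = None,
    n_subjects: int = 25,
    golds=None,
    profile_name: str | None = None,
) -> CovSummary:
    """Across-subject COV summary over the first ``n_subjects`` images.

    Mirrors the study convention of characterizing each reconstruction
    from the same fixed number of subjects (default 25), taken in
    subject-ID order.
    """
    images = list(images)
    if len(images) < n_subjects:
        raise ValueError(
            f"need at least {n_subjects} subjects, got {len(images)}"
        )
    images = images[:n_subjects]
    golds = list(golds)[:n_subjects] if golds is not None else [None] * n_subjects
    values = [
        subject_background_cov(img, roi_spec, gold)
        for img, gold in zip(images, golds)
    ]
    name = profile_name or (images[0].profile_name if images else "")
    return CovSummary.from_values(name, values)


def paired_cov_test(
    summary_a: CovSummary, summary_b: CovSummary
) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject COV differences.

    Degenerate cases follow the natural limits: identical lists give
    (t=0, p=1); a constant nonzero shift with zero difference variance
    gives p=0 with a warning.
    """
    a = np.asarray(summary_a.per_subject_cov, dtype=float)
    b = np.asarray(summary_b.per_subject_cov, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired test requires the same subjects in the same order")
    if a.size < 2:
        raise ValueError("paired test requires n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        warnings.warn(
            "zero variance of paired differences; reporting p = 0",
            stacklevel=2,
        )
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
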