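"""Synthetic DOTATATE-like liver PET phantoms with calibrated noise.

Each phantom is a 2-D axial "subject": an elliptical liver of uniform
background uptake in a low-uptake surround, optional focal hepatic
lesions, plus a correlated Gaussian noise field.  The pre-smoothing
noise amplitude of every reconstruction profile is calibrated by Monte
Carlo so that the *measured* background coefficient of variation (COV,
SD/mean of SUV in a standard liver ROI) matches the profile's target in
expectation.  Noise is characterized by COV only — no projection-space
or count-statistics simulation is attempted, because COV is the single
noise metric the emulated study design varies.

Multi-profile cohorts render the same anatomy and the same unit noise
field once per profile, so that profiles differ only in noise amplitude
and smoothing — the defining property of list-mode re-reconstructions
of a single acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label as _cc_label

from .annotation import PercistParams, roi_mask
from .core import (
    PROFILES,
    SET1_PROFILES,
    LesionMask,
    ReconProfile,
    SUVImage,
    connectivity_for,
    get_profile,
)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "CohortSpec",
    "Subject",
    "CalibrationError",
    "calibrate_noise_amplitude",
    "generate_phantom",
    "generate_cohort",
    "partition_lesions",
    "sample_lesions",
    "gold_threshold",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Lesion radius range (mm) and peak contrast range (multiples of the
#: liver background SUVmean) used when sampling abnormal subjects.
#: The contrast floor sits just above the annotatability limit of the
#: noisiest cohort (1.5 + 2 x COV 0.198 ~ 1.9), so the lesion
#: population spans faint, near-detection-limit foci through clearly
#: visible ones — the regime in which background noise level actually
#: interacts with detectability.
LESION_RADIUS_MM = (4.0, 15.0)
LESION_CONTRAST = (2.0, 5.0)


class CalibrationError(RuntimeError):
    """Noise-amplitude calibration failed."""


@dataclass(frozen=True)
class LesionSpec:
    """One focal lesion: a radially tapered uptake bump.

    The bump adds ``(peak_contrast - 1) * background * (1 - (r/R)^2)``
    inside radius ``R`` so the un-smoothed lesion peak equals
    ``peak_contrast`` times the background SUVmean.
    """

    center: tuple[float, ...]  # voxel coordinates
    radius: float  # mm
    peak_contrast: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("lesion radius must be positive")
        if self.peak_contrast <= 1:
            raise ValueError("peak_contrast must exceed 1 (background)")


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one rendered subject; the seed fixes the output."""

    grid_shape: tuple[int, ...] = (128, 128)
    spacing: tuple[float, ...] = (2.5, 2.5)
    liver_center: tuple[float, ...] | None = None  # voxel coords; grid centre
    liver_semiaxes_mm: tuple[float, ...] | None = None
    background_suv_mean: float = 5.0
    outside_suv: float = 1.0
    lesions: tuple[LesionSpec, ...] = ()
    profile: ReconProfile = PROFILES["Set1-QClear"]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_suv_mean <= 0:
            raise ValueError("background_suv_mean must be positive")
        center = self.liver_center or tuple(
            (n - 1) / 2.0 for n in self.grid_shape
        )
        semi = self.liver_semiaxes_mm or tuple(
            f * n * sp / 2.0
            for f, n, sp in zip((0.68, 0.48), self.grid_shape, self.spacing)
        )
        object.__setattr__(self, "liver_center", tuple(center))
        object.__setattr__(self, "liver_semiaxes_mm", tuple(semi))
        for c, a, n, sp in zip(center, semi, self.grid_shape, self.spacing):
            if c * sp - a < -sp or c * sp + a > (n - 1) * sp + sp:
                raise ValueError("liver region does not fit inside the grid")

    def liver_mask(self) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in self.grid_shape)]
        d2 = sum(
            (((g - c) * sp) / a) ** 2
            for g, c, sp, a in zip(
                grids, self.liver_center, self.spacing, self.liver_semiaxes_mm
            )
        )
        return d2 <= 1.0


# --------------------------------------------------------------------------
# noise calibration
# --------------------------------------------------------------------------

_CALIBRATION_CACHE: dict[tuple, float] = {}


def _unit_noise_roi_sd(
    grid_shape,
    spacing,
    roi,
    smoothing_fwhm: float,
    n_mc: int,
    seed: int,
) -> tuple[float, float]:
    """Mean and standard error of the in-ROI sample SD of a unit-variance
    white noise field after Gaussian smoothing."""
    sigma_vox = tuple(
        smoothing_fwhm * FWHM_TO_SIGMA / sp for sp in spacing
    )
    rng = np.random.default_rng(seed)
    sds = np.empty(n_mc)
    for k in range(n_mc):
        field_k = gaussian_filter(rng.standard_normal(grid_shape), sigma_vox)
        sds[k] = field_k[roi].std(ddof=1)
    return float(sds.mean()), float(sds.std(ddof=1) / np.sqrt(n_mc))


def calibrate_noise_amplitude(
    profile: ReconProfile,
    grid_shape=(128, 128),
    spacing=(2.5, 2.5),
    roi_center_vox=None,
    roi_diameter_mm: float = 30.0,
    background_suv_mean: float = 5.0,
    smoothing_fwhm: float | None = None,
    n_mc: int = 200,
    seed: int = 20_003,
) -> float:
    """Pre-smoothing noise SD that realizes the profile's target COV.

    The measured background COV is the in-ROI sample SD over the ROI
    mean.  The post-smoothing SD of a unit-amplitude field is estimated
    by Monte Carlo with the exact ROI estimator, so the calibration
    inherits the estimator's own small-sample behaviour; the amplitude
    is then the closed-form rescaling ``target_cov * mean / E[SD_unit]``
    (the measured SD is exactly linear in the amplitude).  With no
    smoothing the filter is the identity and the amplitude reduces to
    ``target_cov * background_suv_mean``.
    """
    if profile.target_cov <= 0:
        raise ValueError("target_cov must be positive")
    fwhm = profile.smoothing_fwhm if smoothing_fwhm is None else smoothing_fwhm
    if fwhm == 0:
        return profile.target_cov * background_suv_mean
    grid_shape = tuple(int(n) for n in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    center = tuple(
        roi_center_vox
        if roi_center_vox is not None
        else ((n - 1) / 2.0 for n in grid_shape)
    )
    key = (
        profile.target_cov, grid_shape, spacing, center,
        roi_diameter_mm, background_suv_mean, fwhm, n_mc, seed,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    roi = roi_mask(grid_shape, spacing, center, roi_diameter_mm)
    if roi.sum() < 2:
        raise CalibrationError("calibration ROI contains fewer than 2 voxels")
    sd_unit, se = _unit_noise_roi_sd(grid_shape, spacing, roi, fwhm, n_mc, seed)
    if not np.isfinite(sd_unit) or sd_unit <= 0:
        raise CalibrationError(
            f"unit-noise ROI SD estimate degenerate (sd={sd_unit}, se={se})"
        )
    amp = profile.target_cov * background_suv_mean / sd_unit
    _CALIBRATION_CACHE[key] = amp
    return amp


# --------------------------------------------------------------------------
# phantom rendering
# --------------------------------------------------------------------------


def _clean_image(spec: PhantomSpec) -> np.ndarray:
    img = np.full(spec.grid_shape, spec.outside_suv, dtype=np.float64)
    img[spec.liver_mask()] = spec.background_suv_mean
    for les in spec.lesions:
        img += _lesion_bump(spec, les)
    return img


def _lesion_bump(spec: PhantomSpec, les: LesionSpec) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    r2 = sum(
        ((g - c) * sp) ** 2
        for g, c, sp in zip(grids, les.center, spec.spacing)
    )
    prof = np.clip(1.0 - r2 / les.radius**2, 0.0, None)
    return (les.peak_contrast - 1.0) * spec.background_suv_mean * prof


def _sigma_vox(fwhm_mm: float, spacing) -> tuple[float, ...]:
    return tuple(fwhm_mm * FWHM_TO_SIGMA / sp for sp in spacing)


def _render(
    clean: np.ndarray,
    unit_noise: np.ndarray,
    spec: PhantomSpec,
    profile: ReconProfile,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, gold_binary) for one profile from shared fields."""
    amp = calibrate_noise_amplitude(
        profile,
        grid_shape=spec.grid_shape,
        spacing=spec.spacing,
        background_suv_mean=spec.background_suv_mean,
    )
    sig = _sigma_vox(profile.smoothing_fwhm, spec.spacing)
    img = gaussian_filter(clean + amp * unit_noise, sig)
    np.clip(img, 0.0, None, out=img)
    gold_signal = gaussian_filter(clean, sig)
    thr = gold_threshold(spec)
    return img.astype(np.float32), gold_signal > thr


def gold_threshold(spec: PhantomSpec, params: PercistParams | None = None) -> float:
    """Lesion-defining cutoff of the noise-free background (SD = 0):
    the modified PERCIST rule degenerates to 1.5 x background SUVmean."""
    params = params or PercistParams()
    return params.mean_coefficient * spec.background_suv_mean


def _smoothed_peak_factor(radius_mm: float, spacing, fwhm_mm: float) -> float:
    """Peak of the unit-height lesion profile after Gaussian smoothing,
    evaluated on a small local patch."""
    if fwhm_mm == 0:
        return 1.0
    half = int(np.ceil((radius_mm + 4 * fwhm_mm * FWHM_TO_SIGMA) / min(spacing))) + 1
    n = 2 * half + 1
    grids = np.ogrid[tuple(slice(0, n) for _ in spacing)]
    r2 = sum(((g - half) * sp) ** 2 for g, sp in zip(grids, spacing))
    prof = np.clip(1.0 - r2 / radius_mm**2, 0.0, None)
    return float(gaussian_filter(prof, _sigma_vox(fwhm_mm, spacing)).max())


def _sample_lesion(
    rng: np.random.Generator,
    spec: PhantomSpec,
    placed: list[LesionSpec],
    max_fwhm: float,
    max_attempts: int = 300,
) -> LesionSpec:
    """Rejection-sample one lesion that (a) fits inside the liver,
    (b) keeps a non-confluence margin from already placed lesions and
    (c) keeps a supra-threshold core after the strongest smoothing."""
    sep_margin = 2.0 * max_fwhm * FWHM_TO_SIGMA + float(np.mean(spec.spacing))
    # radii must leave room inside the liver: cap at half the minor
    # semi-axis (inactive at the default geometry)
    r_hi = min(LESION_RADIUS_MM[1], 0.5 * min(spec.liver_semiaxes_mm))
    r_lo = min(LESION_RADIUS_MM[0], r_hi)
    for _ in range(max_attempts):
        radius = rng.uniform(r_lo, r_hi)
        contrast = rng.uniform(*LESION_CONTRAST)
        # supra-threshold core after smoothing: smoothed bump peak must
        # exceed half the background (threshold 1.5*bg on a bg plateau),
        # with 10% headroom against discretization
        if (contrast - 1.0) * _smoothed_peak_factor(
            radius, spec.spacing, max_fwhm
        ) <= 0.55:
            continue
        u = rng.standard_normal(len(spec.grid_shape))
        u /= np.linalg.norm(u)
        u *= rng.uniform() ** (1.0 / len(spec.grid_shape))
        center = tuple(
            c + ui * max(a - radius - sp, 0.0) / sp
            for c, ui, a, sp in zip(
                spec.liver_center, u, spec.liver_semiaxes_mm, spec.spacing
            )
        )
        ok = True
        for other in placed:
            d = np.sqrt(
                sum(
                    ((a - b) * sp) ** 2
                    for a, b, sp in zip(center, other.center, spec.spacing)
                )
            )
            if d < radius + other.radius + sep_margin:
                ok = False
                break
        if ok:
            return LesionSpec(center=center, radius=radius, peak_contrast=contrast)
    raise RuntimeError(
        f"could not place lesion after {max_attempts} attempts "
        f"({len(placed)} already placed)"
    )


def sample_lesions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    n_lesions: int,
    max_fwhm: float | None = None,
) -> tuple[LesionSpec, ...]:
    """Sample ``n_lesions`` mutually non-confluent lesions for a subject."""
    if not 0 <= n_lesions <= 10:
        raise ValueError("lesions per subject must be in [0, 10]")
    max_fwhm = max_fwhm if max_fwhm is not None else spec.profile.smoothing_fwhm
    placed: list[LesionSpec] = []
    for _ in range(n_lesions):
        placed.append(_sample_lesion(rng, spec, placed, max_fwhm))
    return tuple(placed)


def generate_phantom(
    spec: PhantomSpec,
    max_retries: int = 20,
) -> tuple[SUVImage, LesionMask]:
    """Render one phantom and its gold lesion mask.

    The gold mask marks voxels where the *noise-free* rendered signal
    exceeds the noise-free-background lesion cutoff, labeled under the
    package connectivity convention.  A lesion whose core drops below
    the cutoff after smoothing is resampled (bounded retries).  The
    same spec (including seed) always yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    lesions = list(spec.lesions)
    for _ in range(max_retries + 1):
        work = replace(spec, lesions=tuple(lesions))
        clean = _clean_image(work)
        unit_noise = rng.standard_normal(spec.grid_shape)
        img, gold_bin = _render(clean, unit_noise, work, work.profile)
        thr = gold_threshold(work)
        sig = _sigma_vox(work.profile.smoothing_fwhm, work.spacing)
        gold_signal = gaussian_filter(clean, sig)
        failed = [
            i
            for i, les in enumerate(lesions)
            if gold_signal[tuple(int(round(c)) for c in les.center)] <= thr
        ]
        labels = _cc_label(gold_bin, connectivity=connectivity_for(gold_bin.ndim))
        if not failed and labels.max() == len(lesions):
            image = SUVImage(
                img,
                spacing=work.spacing,
                subject_id=f"S{spec.seed:05d}",
                profile_name=work.profile.name,
            )
            return image, LesionMask(labels.astype(np.int32), spacing=work.spacing)
        if failed:
            for i in failed:
                others = [l for j, l in enumerate(lesions) if j != i]
                lesions[i] = _sample_lesion(
                    rng, work, others, work.profile.smoothing_fwhm
                )
        else:
            raise RuntimeError(
                f"gold mask has {labels.max()} components for "
                f"{len(lesions)} lesions (confluent placement)"
            )
    raise RuntimeError("lesion resampling did not converge within retry budget")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Composition and rendering parameters of a synthetic cohort."""

    n_subjects: int
    n_normal: int
    n_abnormal: int
    total_lesions: int
    profiles: tuple[str, ...]
    base_seed: int = 0
    grid_shape: tuple[int, ...] = (128, 128)
    spacing: tuple[float, ...] = (2.5, 2.5)
    background_suv_mean: float = 5.0
    outside_suv: float = 1.0

    def __post_init__(self) -> None:
        if self.n_normal + self.n_abnormal != self.n_subjects:
            raise ValueError("n_normal + n_abnormal must equal n_subjects")
        if self.n_abnormal > 0 and not (
            self.n_abnormal <= self.total_lesions <= 10 * self.n_abnormal
        ):
            raise ValueError(
                "total_lesions must allow 1..10 lesions per abnormal subject"
            )
        if self.n_abnormal == 0 and self.total_lesions != 0:
            raise ValueError("lesions require abnormal subjects")
        for name in self.profiles:
            get_profile(name)

    @classmethod
    def set1(cls, base_seed: int = 0, **overrides) -> "CohortSpec":
        """Default emulation of the modern-scanner cohort: 83 subjects
        (42 normal / 41 abnormal, 134 lesions), five reconstructions."""
        return cls(
            n_subjects=83,
            n_normal=42,
            n_abnormal=41,
            total_lesions=134,
            profiles=tuple(SET1_PROFILES),
            base_seed=base_seed,
            **overrides,
        )

    @classmethod
    def set1_desk(cls, base_seed: int = 0, **overrides) -> "CohortSpec":
        """Desk-scale low-noise cohort for the sweep experiments: the
        default composition scaled to 66 subjects (33 normal / 33
        abnormal, 107 lesions) on a 64 x 64 grid, preserving the
        normal/abnormal balance and lesion load per abnormal subject.
        A 60/20/20 split gives 40 training subjects."""
        overrides.setdefault("grid_shape", (64, 64))
        return cls(
            n_subjects=66,
            n_normal=33,
            n_abnormal=33,
            total_lesions=107,
            profiles=tuple(SET1_PROFILES),
            base_seed=base_seed,
            **overrides,
        )

    @classmethod
    def set2_desk(cls, base_seed: int = 1_000_000, **overrides) -> "CohortSpec":
        """Desk-scale high-noise cohort: 98 subjects (53 normal / 45
        abnormal, 187 lesions) on a 64 x 64 grid — the default
        composition scaled by the same factor as the low-noise desk
        cohort (98/123 ~ 66/83), preserving the two cohorts' relative
        sizes and hence the in-domain condition's data advantage."""
        overrides.setdefault("grid_shape", (64, 64))
        return cls(
            n_subjects=98,
            n_normal=53,
            n_abnormal=45,
            total_lesions=187,
            profiles=("Set2-OSEM",),
            base_seed=base_seed,
            **overrides,
        )

    @classmethod
    def set2(cls, base_seed: int = 0, **overrides) -> "CohortSpec":
        """Default emulation of the older-scanner cohort: 123 subjects
        (67 normal / 56 abnormal, 233 lesions), one reconstruction."""
        return cls(
            n_subjects=123,
            n_normal=67,
            n_abnormal=56,
            total_lesions=233,
            profiles=("Set2-OSEM",),
            base_seed=base_seed,
            **overrides,
        )


@dataclass
class Subject:
    """One generated subject, rendered under each cohort profile."""

    subject_id: str
    index: int
    is_abnormal: bool
    n_lesions: int
    images: dict[str, SUVImage] = field(default_factory=dict)
    gold: dict[str, LesionMask] = field(default_factory=dict)


def partition_lesions(
    total_lesions: int, n_abnormal: int, base_seed: int
) -> list[int]:
    """Deterministic near-even partition of the lesion total over the
    abnormal subjects, each count in [1, 10]; the remainder lesions go
    to a base_seed-shuffled subset of subjects."""
    if n_abnormal == 0:
        if total_lesions:
            raise ValueError("cannot partition lesions over zero subjects")
        return []
    if not n_abnormal <= total_lesions <= 10 * n_abnormal:
        raise ValueError("infeasible lesion partition")
    base, rem = divmod(total_lesions, n_abnormal)
    counts = np.full(n_abnormal, base, dtype=int)
    order = np.random.default_rng(base_seed).permutation(n_abnormal)
    counts[order[:rem]] += 1
    assert counts.sum() == total_lesions and counts.min() >= 1 and counts.max() <= 10
    return counts.tolist()


def generate_cohort(cohort: CohortSpec) -> list[Subject]:
    """Generate every subject of a cohort.

    Multi-profile cohorts share anatomy and the unit noise field across
    profiles per subject, so profiles differ only by noise amplitude
    and smoothing.  The summed gold component count over abnormal
    subjects equals ``cohort.total_lesions`` exactly, for every profile.
    """
    rng = np.random.default_rng(cohort.base_seed)
    abnormal_idx = set(
        rng.permutation(cohort.n_subjects)[: cohort.n_abnormal].tolist()
    )
    counts = partition_lesions(
        cohort.total_lesions, cohort.n_abnormal, cohort.base_seed
    )
    profiles = [get_profile(name) for name in cohort.profiles]
    max_fwhm = max(p.smoothing_fwhm for p in profiles)
    subjects: list[Subject] = []
    abn_rank = 0
    for idx in range(cohort.n_subjects):
        seed = cohort.base_seed + idx
        is_abn = idx in abnormal_idx
        n_les = counts[abn_rank] if is_abn else 0
        if is_abn:
            abn_rank += 1
        base_spec = PhantomSpec(
            grid_shape=cohort.grid_shape,
            spacing=cohort.spacing,
            background_suv_mean=cohort.background_suv_mean,
            outside_suv=cohort.outside_suv,
            profile=profiles[0],
            seed=seed,
        )
        srng = np.random.default_rng(seed)
        lesions = sample_lesions(srng, base_spec, n_les, max_fwhm=max_fwhm)
        clean = _clean_image(replace(base_spec, lesions=lesions))
        unit_noise = srng.standard_normal(cohort.grid_shape)
        subj = Subject(
            subject_id=f"{'A' if is_abn else 'N'}{idx:04d}",
            index=idx,
            is_abnormal=is_abn,
            n_lesions=n_les,
        )
        for prof in profiles:
            img, gold_bin = _render(
                clean, unit_noise, replace(base_spec, lesions=lesions), prof
            )
            labels = _cc_label(
                gold_bin, connectivity=connectivity_for(gold_bin.ndim)
            )
            if labels.max() != n_les:
                raise RuntimeError(
                    f"subject {idx}: {labels.max()} gold components for "
                    f"{n_les} lesions under profile {prof.name}"
                )
            subj.images[prof.name] = SUVImage(
                img,
                spacing=cohort.spacing,
                subject_id=subj.subject_id,
                profile_name=prof.name,
            )
            subj.gold[prof.name] = LesionMask(
                labels.astype(np.int32), spacing=cohort.spacing
            )
        subjects.append(subj)
    return subjects
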