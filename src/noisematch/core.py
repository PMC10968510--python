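"""Core domain containers shared across the package.

Images carry standardized uptake values (SUV): tracer concentration
normalized by injected dose and body weight, the native unit of clinical
PET reading.  A :class:`ReconProfile` abstracts a scanner/reconstruction
combination into the two quantities that matter for this package: the
background noise level it produces (as a coefficient of variation, COV,
of SUV in normal liver) and an effective smoothing kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label


@dataclass(frozen=True)
class ReconProfile:
    """A named noise/smoothing profile emulating one reconstruction.

    Parameters
    ----------
    name:
        Registry label, e.g. ``"Set1-VPFXS-2min"``.
    acquisition_time:
        Acquisition duration in minutes.  Metadata only: noise is
        calibrated per profile to ``target_cov`` rather than derived
        from a count-statistics law, because measured COV across
        reconstructions does not follow the ideal inverse-square-root
        scaling with time.
    target_cov:
        Background liver COV (SD/mean of SUV) this profile is
        calibrated to reproduce.
    smoothing_fwhm:
        Full width at half maximum, in mm, of the Gaussian kernel that
        emulates the reconstruction's effective resolution (including
        any post-reconstruction filter).
    voxel_size:
        Native in-plane voxel size of the emulated reconstruction, in
        mm.  Metadata: phantoms are rendered on a common grid and
        resolution differences are folded into ``smoothing_fwhm``.
    """

    name: str
    acquisition_time: float
    target_cov: float
    smoothing_fwhm: float
    voxel_size: tuple[float, ...] = (3.64, 3.64)

    def __post_init__(self) -> None:
        if self.target_cov <= 0:
            raise ValueError("target_cov must be positive")
        if self.acquisition_time <= 0:
            raise ValueError("acquisition_time must be positive")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be nonnegative")


#: Registered profiles.  COV targets are the published per-reconstruction
#: liver-background values; smoothing widths are emulation choices:
#: BSREM regularization smooths more than the 5 mm post-filtered OSEM
#: reconstructions, and the older scanner's coarse native voxels add a
#: little effective blur on top of its 5 mm filter.
PROFILES: dict[str, ReconProfile] = {
    p.name: p
    for p in (
        ReconProfile("Set1-QClear", 5.0, 0.091, 6.5, (2.73, 2.73)),
        ReconProfile("Set1-VPFXS-5min", 5.0, 0.098, 5.0, (3.64, 3.64)),
        ReconProfile("Set1-VPFXS-4min", 4.0, 0.102, 5.0, (3.64, 3.64)),
        ReconProfile("Set1-VPFXS-3min", 3.0, 0.110, 5.0, (3.64, 3.64)),
        ReconProfile("Set1-VPFXS-2min", 2.0, 0.121, 5.0, (3.64, 3.64)),
        ReconProfile("Set2-OSEM", 5.0, 0.198, 5.5, (4.69, 4.69)),
    )
}

#: Profile names in increasing order of target COV.
PROFILE_ORDER: tuple[str, ...] = (
    "Set1-QClear",
    "Set1-VPFXS-5min",
    "Set1-VPFXS-4min",
    "Set1-VPFXS-3min",
    "Set1-VPFXS-2min",
    "Set2-OSEM",
)

SET1_PROFILES: tuple[str, ...] = PROFILE_ORDER[:5]


def get_profile(name: str) -> ReconProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown reconstruction profile {name!r}; "
            f"registered: {sorted(PROFILES)}"
        ) from None


@dataclass
class SUVImage:
    """An SUV-valued voxel grid with physical spacing and provenance."""

    voxels: np.ndarray
    spacing: tuple[float, ...]
    subject_id: str = ""
    profile_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if len(self.spacing) != self.voxels.ndim:
            raise ValueError("spacing must have one entry per image axis")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("SUV image contains non-finite values")
        if self.voxels.min() < 0:
            raise ValueError("SUV image contains negative values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


def connectivity_for(ndim: int) -> int:
    """Connectivity order used throughout: 8-connectivity in 2-D,
    26-connectivity in 3-D (the most permissive choice, consistent with
    treating nearby supra-threshold voxels as one non-confluent lesion)."""
    return ndim


@dataclass
class LesionMask:
    """Labeled lesion components aligned to an :class:`SUVImage`.

    ``labels`` holds 0 for background and 1..n for the n components;
    labels are contiguous.
    """

    labels: np.ndarray
    spacing: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("lesion mask labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("lesion mask labels must be nonnegative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(
            present, np.arange(1, len(present) + 1)
        ):
            raise ValueError("lesion labels must be contiguous 1..n")
        if not self.spacing:
            self.spacing = (1.0,) * self.labels.ndim

    @property
    def n_components(self) -> int:
        return int(self.labels.max())

    @classmethod
    def from_binary(cls, binary: np.ndarray, spacing=None) -> "LesionMask":
        binary = np.asarray(binary).astype(bool)
        labels = _cc_label(binary, connectivity=connectivity_for(binary.ndim))
        return cls(
            labels.astype(np.int32),
            spacing=tuple(spacing) if spacing is not None else (1.0,) * binary.ndim,
        )
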