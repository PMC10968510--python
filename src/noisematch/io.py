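"""NIfTI image exchange, configuration files and run manifests.

Images and masks travel as NIfTI (the affine carries the voxel spacing);
cohort manifests as CSV; run manifests as JSON capturing the config
snapshot, seeds and produced paths so any stage can be re-executed
deterministically.
"""

from __future__ import annotations

import json
import datetime as _dt
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import LesionMask, SUVImage
from .phantom import CohortSpec, Subject

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "RunManifest",
    "load_cohort_config",
    "write_cohort",
    "read_cohort",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    for i, sp in enumerate(spacing[:3]):
        aff[i, i] = sp
    return aff


def _spacing_from(img: nib.Nifti1Image, ndim: int) -> tuple[float, ...]:
    return tuple(float(z) for z in img.header.get_zooms()[:ndim])


def write_image(image: SUVImage, path) -> None:
    """Write an SUV image as NIfTI; float32 voxels, spacing in header."""
    nib.save(
        nib.Nifti1Image(
            np.asarray(image.voxels, dtype=np.float32), _affine(image.spacing)
        ),
        str(path),
    )


def read_image(path, subject_id: str = "", profile_name: str = "") -> SUVImage:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot read NIfTI image {path}: {exc}") from exc
    return SUVImage(
        np.clip(data, 0.0, None),
        spacing=_spacing_from(img, data.ndim),
        subject_id=subject_id or Path(path).stem.split(".")[0],
        profile_name=profile_name,
    )


def write_mask(mask: LesionMask, path) -> None:
    nib.save(
        nib.Nifti1Image(
            np.asarray(mask.labels, dtype=np.int32), _affine(mask.spacing)
        ),
        str(path),
    )


def read_mask(path) -> LesionMask:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"cannot read NIfTI mask {path}: {exc}") from exc
    return LesionMask(
        data.astype(np.int32), spacing=_spacing_from(img, data.ndim)
    )


@dataclass
class RunManifest:
    """Everything needed to re-execute a stage deterministically."""

    stage: str
    config: dict
    seeds: dict
    outputs: list = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        self.version = self.version or __version__
        self.timestamp = self.timestamp or _dt.datetime.now().isoformat(
            timespec="seconds"
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_cohort_config(path) -> CohortSpec:
    """Read a CohortSpec from a YAML mapping; ``preset: set1|set2``
    selects the default emulations, other keys override fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    preset = raw.pop("preset", None)
    for key in ("grid_shape", "spacing", "profiles"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if preset == "set1":
        return CohortSpec.set1(**raw)
    if preset == "set2":
        return CohortSpec.set2(**raw)
    return CohortSpec(**raw)


def write_cohort(subjects: list[Subject], out_dir, spec: CohortSpec | None = None):
    """Write one image + gold mask per subject per profile, plus a CSV
    manifest (subject_id, profile, n_lesions, paths) and a JSON run
    manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        for prof, img in s.images.items():
            ipath = out / f"{s.subject_id}_{prof}_suv.nii.gz"
            mpath = out / f"{s.subject_id}_{prof}_gold.nii.gz"
            write_image(img, ipath)
            write_mask(s.gold[prof], mpath)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "profile": prof,
                    "abnormal": int(s.is_abnormal),
                    "n_lesions": s.n_lesions,
                    "image": ipath.name,
                    "gold": mpath.name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    RunManifest(
        stage="simulate",
        config=asdict(spec) if spec is not None else {},
        seeds={"base_seed": spec.base_seed if spec is not None else None},
        outputs=[r["image"] for r in rows] + [r["gold"] for r in rows],
    ).write(out / "run_manifest.json")
    return manifest


def read_cohort(in_dir) -> list[Subject]:
    """Reassemble subjects from a directory written by write_cohort."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    subjects: dict[str, Subject] = {}
    for idx, row in manifest.iterrows():
        sid = row["subject_id"]
        subj = subjects.setdefault(
            sid,
            Subject(
                subject_id=sid,
                index=len(subjects),
                is_abnormal=bool(row["abnormal"]),
                n_lesions=int(row["n_lesions"]),
            ),
        )
        subj.images[row["profile"]] = read_image(
            in_dir / row["image"], subject_id=sid, profile_name=row["profile"]
        )
        subj.gold[row["profile"]] = read_mask(in_dir / row["gold"])
    return list(subjects.values())
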