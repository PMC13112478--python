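"""Shared containers and I/O for 4D cine volumes, label maps, manifests and run logs.

All downstream stages consume :class:`Cine4D` / :class:`LabelMap4D` built here, so
geometry (spacing, affine) has a single authority.  Distances everywhere in the
package are in millimetres, computed in world space through the NIfTI affine with
the voxel-centre convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND",
    "LVB",
    "LVM",
    "RVB",
    "FOREGROUND_CLASSES",
    "CLASS_NAMES",
    "Cine4D",
    "LabelMap4D",
    "SubjectManifest",
    "centered_affine",
    "read_cine",
    "write_cine",
    "read_labels",
    "write_labels",
    "load_manifest",
    "example_manifest",
    "write_run_log",
]

# Segmentation class codes, fixed across the whole package.
BACKGROUND = 0
LVB = 1  # left-ventricular blood pool
LVM = 2  # left-ventricular myocardium
RVB = 3  # right-ventricular blood pool
FOREGROUND_CLASSES = (LVB, LVM, RVB)
CLASS_NAMES = {BACKGROUND: "background", LVB: "LVB", LVM: "LVM", RVB: "RVB"}

_ANISOTROPY_TOL = 0.01  # relative spread of voxel edges tolerated silently


def centered_affine(shape: Sequence[int], spacing_mm: Sequence[float]) -> np.ndarray:
    """Diagonal voxel-to-world affine placing the world origin at the volume centre."""
    shape = np.asarray(shape[:3], dtype=float)
    spacing = np.asarray(spacing_mm, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing
    return affine


def _validate_geometry(voxels: np.ndarray, spacing: np.ndarray, affine: np.ndarray) -> None:
    if voxels.ndim != 4:
        raise ValueError(f"expected 4D (x,y,z,phase) array, got shape {voxels.shape}")
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive edges, got {spacing}")
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 voxel-to-world map")


@dataclass
class Cine4D:
    """Isotropic cine series: dense (x, y, z, phase) scalars with shared geometry."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    frame_ms: float = 50.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:  # single-phase promotion
            self.voxels = self.voxels[..., np.newaxis]
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        _validate_geometry(self.voxels, self.spacing_mm, self.affine)

    @property
    def n_phases(self) -> int:
        return self.voxels.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def phase(self, index: int) -> np.ndarray:
        return self.voxels[..., index]

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def world_coordinates(self) -> np.ndarray:
        """(x,y,z,3) array of voxel-centre world coordinates in mm."""
        idx = np.indices(self.grid_shape, dtype=float)
        ijk = np.stack([idx[0], idx[1], idx[2], np.ones(self.grid_shape)], axis=-1)
        return ijk @ self.affine.T[:, :3]

    def with_voxels(self, voxels: np.ndarray) -> "Cine4D":
        return dataclasses.replace(self, voxels=voxels)


@dataclass
class LabelMap4D(Cine4D):
    """Per-phase integer labels (0 background, 1 LVB, 2 LVM, 3 RVB) on a cine grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = np.ascontiguousarray(self.voxels.astype(np.uint8, copy=False))
        bad = np.setdiff1d(np.unique(self.voxels), [BACKGROUND, *FOREGROUND_CLASSES])
        if bad.size:
            raise ValueError(f"label values outside {{0,1,2,3}}: {bad.tolist()}")

    def mask(self, class_code: int, phase: int) -> np.ndarray:
        return self.voxels[..., phase] == class_code

    def matches_geometry(self, other: Cine4D, atol_mm: float = 1e-6) -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol_mm)
            and np.allclose(self.affine, other.affine, atol=atol_mm)
        )


VALID_COHORTS = ("D1", "D2")
VALID_GROUPS = ("healthy", "HFpEF", "HFrEF")


@dataclass
class SubjectManifest:
    subject_id: str
    cohort: str
    group: str
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in VALID_COHORTS:
            raise ValueError(f"cohort {self.cohort!r} not in {VALID_COHORTS}")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group {self.group!r} not in {VALID_GROUPS}; allowed: {VALID_GROUPS}")
        if self.cohort == "D1" and self.group != "healthy":
            raise ValueError(f"cohort D1 contains healthy volunteers only (subject {self.subject_id})")


def _check_isotropy(spacing: np.ndarray) -> None:
    if spacing.max() - spacing.min() > _ANISOTROPY_TOL * spacing.mean():
        warnings.warn(
            f"anisotropic voxel spacing {spacing.tolist()} mm; distances assume the "
            "affine is authoritative",
            stacklevel=3,
        )


def _read_nifti(path: str | Path, default_frame_ms: float):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    elif data.ndim != 4:
        raise ValueError(f"{path}: expected 3D or 4D NIfTI, got {data.ndim}D")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    _check_isotropy(spacing)
    zooms = img.header.get_zooms()
    frame_ms = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else default_frame_ms
    return data, spacing, np.asarray(img.affine, dtype=float), frame_ms


def read_cine(path: str | Path, default_frame_ms: float = 50.0) -> Cine4D:
    """Load a 3D/4D NIfTI as a cine series; 3D inputs become single-phase 4D."""
    data, spacing, affine, frame_ms = _read_nifti(path, default_frame_ms)
    return Cine4D(data.astype(np.float32), spacing, affine, frame_ms)


def read_labels(path: str | Path, default_frame_ms: float = 50.0) -> LabelMap4D:
    data, spacing, affine, frame_ms = _read_nifti(path, default_frame_ms)
    return LabelMap4D(data.astype(np.uint8), spacing, affine, frame_ms)


def _write_nifti(cine: Cine4D, path: str | Path, dtype) -> None:
    img = nib.Nifti1Image(cine.voxels.astype(dtype), cine.affine)
    zooms = (*cine.spacing_mm, cine.frame_ms)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="msec")
    nib.save(img, str(path))


def write_cine(cine: Cine4D, path: str | Path) -> None:
    _write_nifti(cine, path, np.float32)


def write_labels(labels: LabelMap4D, path: str | Path) -> None:
    _write_nifti(labels, path, np.uint8)


def load_manifest(path: str | Path) -> list[SubjectManifest]:
    """Read a subject manifest (CSV or JSON) and validate records.

    Required columns/keys: subject_id, cohort, group.  Any further columns are
    collected into ``paths``.  Duplicate subject ids are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text() or "[]")
    else:
        try:
            frame = pd.read_csv(path, dtype=str)
        except pd.errors.EmptyDataError:
            return []
        records = frame.to_dict(orient="records")
    manifests: list[SubjectManifest] = []
    seen: set[str] = set()
    for rec in records:
        rec = {k: v for k, v in rec.items() if v is not None and not (isinstance(v, float) and np.isnan(v))}
        sid = str(rec.pop("subject_id"))
        if sid in seen:
            raise ValueError(f"duplicated subject_id {sid!r} in manifest {path}")
        seen.add(sid)
        cohort, group = str(rec.pop("cohort")), str(rec.pop("group"))
        manifests.append(SubjectManifest(sid, cohort, group, paths=rec))
    return manifests


def example_manifest(
    n_d1_healthy: int = 15,
    n_d2_healthy: int = 10,
    n_hfpef: int = 5,
    n_hfref: int = 5,
) -> list[SubjectManifest]:
    """Synthetic manifest mirroring the study cohort structure.

    Defaults reproduce the two-cohort composition used throughout the
    package's experiments: 15 healthy 1.5T subjects (D1) plus 20 3T subjects
    (D2: 10 healthy, 5 HFpEF, 5 HFrEF).
    """
    subjects = [SubjectManifest(f"d1_h{i:02d}", "D1", "healthy") for i in range(n_d1_healthy)]
    subjects += [SubjectManifest(f"d2_h{i:02d}", "D2", "healthy") for i in range(n_d2_healthy)]
    subjects += [SubjectManifest(f"d2_pef{i:02d}", "D2", "HFpEF") for i in range(n_hfpef)]
    subjects += [SubjectManifest(f"d2_ref{i:02d}", "D2", "HFrEF") for i in range(n_hfref)]
    return subjects


def write_run_log(path: str | Path, config: dict, seed: int | None = None) -> dict:
    """Write a JSON sidecar recording the configuration hash, seed and versions."""
    import cardiac4d

    payload = {
        "config": config,
        "config_sha256": hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "cardiac4d": cardiac4d.__version__,
            "numpy": np.__version__,
            "nibabel": nib.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
    return payload
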