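"""In-memory containers for 3-D brain volumes, label atlases and masks.

All volumes are plain scalar grids with a voxel spacing in millimetres and
a voxel-to-world affine. NIfTI-1 serialisation goes through nibabel; the
affine written to the header is the one carried by the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: PET voxel size used throughout: in-plane 0.3875 mm, axial 0.775 mm.
DEFAULT_SPACING = (0.3875, 0.3875, 0.775)


def spacing_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Diagonal voxel->world affine for a volume with its corner at the origin."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3-D scalar grid plus geometry (voxel spacing in mm, 4x4 affine)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "VolumeImage":
        """New volume with the same geometry but different voxel data."""
        return VolumeImage(data, spacing=self.spacing, affine=self.affine.copy())

    def same_geometry(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def center_mm(self) -> np.ndarray:
        """World coordinates of the geometric centre of the grid."""
        center_vox = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return (self.affine @ np.append(center_vox, 1.0))[:3]

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing=spacing,
                   affine=np.asarray(img.affine))


@dataclass
class MaskVolume:
    """Binary mask aligned to a VolumeImage geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("mask is empty")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class LabelAtlas:
    """Integer-labelled ROI atlas plus a label -> abbreviation name table.

    Label 0 is reserved for background. Each named ROI is a spatially
    contiguous block of voxels, large enough (>= 50 voxels) that a fully
    affected region can survive the cluster-extent filter downstream.
    """

    labels: np.ndarray
    names: dict[int, str]
    fullnames: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def roi_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    def save_names(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tabbrev\tfullname\n")
            for lab in sorted(self.names):
                full = self.fullnames.get(lab, self.names[lab])
                fh.write(f"{lab}\t{self.names[lab]}\t{full}\n")

    @classmethod
    def load(cls, labels_path: str | Path, names_path: str | Path) -> "LabelAtlas":
        img = nib.load(str(labels_path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        names: dict[int, str] = {}
        fullnames: dict[int, str] = {}
        with open(names_path) as fh:
            next(fh)  # header
            for line in fh:
                lab, abbrev, full = line.rstrip("\n").split("\t")
                names[int(lab)] = abbrev
                fullnames[int(lab)] = full
        return cls(np.asarray(img.dataobj).astype(np.int32), names,
                   fullnames=fullnames, spacing=spacing,
                   affine=np.asarray(img.affine))
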