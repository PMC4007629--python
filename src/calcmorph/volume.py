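"""CT-like volumes, label maps, and file IO.

Coordinate convention: 0-based voxel indices, voxel-centre sampling,
right-handed axes; world position of voxel (i, j, k) is
``origin + index * spacing``. DICOM/NRRD direction matrices other than the
identity are not resampled — the reader warns and keeps the axis-aligned
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError

__all__ = ["Volume3D", "LabelMap", "read_volume", "write_volume",
           "write_labels", "write_mesh"]


def _spacing3(spacing) -> np.ndarray:
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise DataError(f"voxel spacing must be positive on all axes, got {spacing!r}")
    return s


@dataclass
class Volume3D:
    """A scalar attenuation grid (HU) with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise DataError("volume data must be a non-empty 3-D array")
        self.spacing = _spacing3(self.spacing)
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def world_to_index(self, point_mm) -> np.ndarray:
        """Continuous voxel index of a world-space point."""
        return (np.asarray(point_mm, float) - self.origin) / self.spacing

    def index_to_world(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, float) * self.spacing


@dataclass
class LabelMap:
    """Integer labels aligned voxel-for-voxel with a Volume3D; 0 = background."""

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("label map must hold integers")
        if self.labels.ndim != 3 or self.labels.min(initial=0) < 0:
            raise DataError("label map must be a 3-D array of non-negative labels")
        self.spacing = _spacing3(self.spacing)
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def counts(self) -> dict[int, int]:
        """Voxel count per nonzero label."""
        vals, cnts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts) if v != 0}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SITK_SUFFIXES = {".nrrd", ".nhdr", ".mha", ".mhd"}


def read_volume(path, spacing_override=None) -> Volume3D:
    """Read a volume from NIfTI, NRRD/MetaImage, or a DICOM series directory.

    ``spacing_override`` replaces the stored voxel spacing (mm) when given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume path does not exist: {path}")
    if path.is_dir():
        vol = _read_dicom_series(path)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        vol = _read_nifti(path)
    elif path.suffix.lower() in _SITK_SUFFIXES:
        vol = _read_sitk(path)
    else:
        raise DataError(f"unrecognised volume format: {path}")
    if spacing_override is not None:
        vol.spacing = _spacing3(spacing_override)
    return vol


def _read_nifti(path: Path) -> Volume3D:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DataError(f"{path}: expected a 3-D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        warnings.warn(f"{path}: non-axis-aligned NIfTI affine; using voxel sizes "
                      "only and ignoring rotation", stacklevel=2)
    return Volume3D(data=data, spacing=spacing, origin=affine[:3, 3])


def _sitk_to_volume(img) -> Volume3D:
    import SimpleITK as sitk

    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        warnings.warn("non-identity direction matrix; axes kept axis-aligned",
                      stacklevel=3)
    # sitk arrays come back (z, y, x); store (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return Volume3D(data=data, spacing=np.asarray(img.GetSpacing()),
                    origin=np.asarray(img.GetOrigin()))


def _read_sitk(path: Path) -> Volume3D:
    import SimpleITK as sitk

    return _sitk_to_volume(sitk.ReadImage(str(path)))


def _read_dicom_series(path: Path) -> Volume3D:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise DataError(f"no DICOM series found in directory {path}")
    reader.SetFileNames(files)
    return _sitk_to_volume(reader.Execute())


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD/MetaImage."""
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag(np.append(vol.spacing, 1.0))
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))
    elif path.suffix.lower() in _SITK_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0).astype(np.float32))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise DataError(f"unrecognised volume output format: {path}")


def write_labels(labels: LabelMap, path) -> None:
    """Write a label map as NIfTI with integer dtype."""
    import nibabel as nib

    path = Path(path)
    if not (path.suffix == ".nii" or path.name.endswith(".nii.gz")):
        raise DataError(f"label maps are written as NIfTI, got {path}")
    affine = np.diag(np.append(labels.spacing, 1.0))
    affine[:3, 3] = labels.origin
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int32), affine), str(path))


def write_mesh(mesh, path) -> None:
    """Write a surface mesh as PLY or STL (by extension)."""
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise DataError(f"meshes are written as PLY or STL, got {path}")
    mesh.export(str(path))
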