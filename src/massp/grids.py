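"""Volume containers and NIfTI input/output.

All volumes participating in one pipeline run must live on the same sampling
grid: identical shape, voxel size and affine. Voxel coordinates are 0-based
array indices; world (mm) coordinates are obtained through the affine. All
internal distances are expressed in voxel units and converted to mm only when
a physical quantity (volume, thickness) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "check_same_grid",
]

_SEMANTICS = ("sdf", "contrast", "prior", "posterior", "thickness")


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid shared by all volumes of a run.

    Parameters
    ----------
    shape : tuple of 3 int
        Array dimensions.
    voxel_size : tuple of 3 float
        Voxel edge lengths in mm, strictly positive.
    affine : (4, 4) ndarray
        Voxel-index to world-mm mapping; must be invertible.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {vox}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vox)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, n: int, voxel_mm: float = 1.0) -> "VolumeGrid":
        """Cubic grid of side ``n`` with isotropic voxels."""
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls((n, n, n), (voxel_mm,) * 3, affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def matches(self, other: "VolumeGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.affine, other.affine, atol=tol)
        )


def check_same_grid(*grids: VolumeGrid) -> VolumeGrid:
    """Verify that all grids are identical; return the common grid.

    Raises ``ValueError`` on the first mismatch — grid incompatibilities are
    rejected before any computation starts.
    """
    if not grids:
        raise ValueError("no grids given")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.matches(g):
            raise ValueError(
                f"grid mismatch: {ref.shape}/{ref.voxel_size} vs {g.shape}/{g.voxel_size}"
            )
    return ref


@dataclass
class ScalarVolume:
    """Real-valued field on a grid (SDF, contrast, prior, posterior, thickness)."""

    grid: VolumeGrid
    values: np.ndarray
    semantics: str = "contrast"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.semantics not in _SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.semantics in ("prior", "posterior"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"{self.semantics} volume has negative values")


@dataclass
class LabelVolume:
    """Integer-labelled volume; 0 is reserved for background."""

    grid: VolumeGrid
    labels: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.rint(labels), atol=0):
                raise ValueError("label volume contains non-integer values")
            labels = np.rint(labels).astype(np.int32)
        self.labels = labels.astype(np.int32, copy=False)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        present = [int(v) for v in np.unique(self.labels) if v != 0]
        if not self.label_table:
            self.label_table = {v: f"structure_{v}" for v in present}
        else:
            self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
            missing = [v for v in present if v not in self.label_table]
            if missing:
                raise ValueError(f"labels {missing} absent from label_table")

    @property
    def structure_ids(self) -> list[int]:
        return sorted(self.label_table)

    def mask(self, structure_id: int) -> np.ndarray:
        return self.labels == structure_id

    def volume_mm3(self, structure_id: int) -> float:
        return float(np.count_nonzero(self.labels == structure_id)) * self.grid.voxel_volume


def _grid_from_image(img: nib.Nifti1Image) -> VolumeGrid:
    if img.ndim != 3:
        raise ValueError(f"expected a 3D image, got {img.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(tuple(img.shape), zooms, np.asarray(img.affine, dtype=float))


def read_volume(path: str | Path, kind: str = "scalar") -> ScalarVolume | LabelVolume:
    """Read a NIfTI-1 volume as a scalar field or a label volume.

    ``kind="label"`` requires integer-valued data (integer dtype, or floats
    that are exactly integral).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_image(img)
    data = np.asanyarray(img.dataobj)
    if kind == "scalar":
        return ScalarVolume(grid, np.asarray(data, dtype=np.float64))
    if kind == "label":
        return LabelVolume(grid, data)
    raise ValueError(f"kind must be 'label' or 'scalar', got {kind!r}")


def write_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; float64 for scalars, int32 for labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, str(path))
    return path
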