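"""Grid/affine data model shared by all pipeline stages.

Conventions: RAS world coordinates in mm, 0-based voxel indices,
voxel-center convention (voxel (i,j,k) maps to ``affine @ (i,j,k,1)``).
Registration *estimation* is out of scope — affines are inputs and are
only applied here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AffineTransform",
    "TensorVolume",
    "LabelVolume",
    "ScalarVolume",
    "voxel_to_world",
    "world_to_voxel",
    "apply_affine_points",
]

# NIfTI "lower triangular" ordering of the 6 unique tensor components.
_TENSOR_COMPONENTS = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 homogeneous spatial transform in mm units."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last affine row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise np.linalg.LinAlgError("singular affine")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def scaling(cls, voxel_size_mm: float, origin_mm=(0.0, 0.0, 0.0)) -> "AffineTransform":
        m = np.eye(4)
        m[:3, :3] *= float(voxel_size_mm)
        m[:3, 3] = origin_mm
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.ndim(points) == 1 else out


def voxel_to_world(index, affine: AffineTransform | np.ndarray) -> np.ndarray:
    """World-mm coordinates of voxel center(s) ``index`` (0-based)."""
    if not isinstance(affine, AffineTransform):
        affine = AffineTransform(affine)
    return affine.apply(np.asarray(index, dtype=float))


def world_to_voxel(points, affine: AffineTransform | np.ndarray) -> np.ndarray:
    """Continuous voxel coordinates of world point(s); round for indices."""
    if not isinstance(affine, AffineTransform):
        affine = AffineTransform(affine)
    return affine.inverse().apply(np.asarray(points, dtype=float))


def apply_affine_points(points: np.ndarray, affine: AffineTransform | np.ndarray) -> np.ndarray:
    """Map Nx3 points through an affine (errors on singular matrices)."""
    if not isinstance(affine, AffineTransform):
        affine = AffineTransform(affine)
    return affine.apply(points)


@dataclass
class _GriddedVolume:
    data: np.ndarray
    affine: AffineTransform

    def __post_init__(self) -> None:
        if not isinstance(self.affine, AffineTransform):
            self.affine = AffineTransform(self.affine)
        self.data = np.asarray(self.data)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine.matrix[:3, :3], axis=0)

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world-mm voxel centers."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return self.affine.apply(idx.reshape(-1, 3)).reshape(*self.shape, 3)

    def contains_world(self, points: np.ndarray) -> np.ndarray:
        vox = world_to_voxel(points, self.affine)
        vox = np.atleast_2d(vox)
        lo = vox >= -0.5
        hi = vox <= np.asarray(self.shape) - 0.5
        ok = (lo & hi).all(axis=1)
        return ok if np.ndim(points) > 1 else bool(ok[0])


@dataclass
class ScalarVolume(_GriddedVolume):
    """A scalar field on a voxel grid (masks, potentials, FA maps)."""

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine.matrix)
        img.header.set_sform(self.affine.matrix, code=1)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), AffineTransform(img.affine))


@dataclass
class LabelVolume(_GriddedVolume):
    """Integer region labels on a voxel grid with a label-name map."""

    label_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data).astype(np.int32)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine.matrix)
        img.header.set_sform(self.affine.matrix, code=1)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, label_names: dict) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), AffineTransform(img.affine), label_names)


@dataclass
class TensorVolume(_GriddedVolume):
    """Per-voxel symmetric 3x3 tensors (diffusion, mm^2/s) on a grid.

    ``data`` has shape (nx, ny, nz, 3, 3); symmetry is enforced, and
    eigenvalues are expected to be non-negative (checked on request via
    :meth:`validate`, not on every construction, for speed).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.ndim != 5 or self.data.shape[3:] != (3, 3):
            raise ValueError(f"tensor data must be (nx,ny,nz,3,3), got {self.data.shape}")
        if not np.allclose(self.data, np.swapaxes(self.data, -1, -2), atol=1e-10):
            raise ValueError("tensors must be symmetric")

    def validate(self) -> None:
        evals = np.linalg.eigvalsh(self.data.reshape(-1, 3, 3))
        if evals.min() < -1e-12:
            raise ValueError(f"negative tensor eigenvalue: {evals.min():g}")

    def principal_directions(self):
        """Eigen-decomposition, descending eigenvalues.

        Returns ``(evals, evecs)`` with shapes (...,3) and (...,3,3);
        ``evecs[..., :, m]`` is the m-th eigenvector.
        """
        evals, evecs = np.linalg.eigh(self.data)
        order = np.argsort(evals, axis=-1)[..., ::-1]
        evals = np.take_along_axis(evals, order, axis=-1)
        evecs = np.take_along_axis(evecs, order[..., None, :], axis=-1)
        return evals, evecs

    def fractional_anisotropy(self) -> np.ndarray:
        evals = np.linalg.eigvalsh(self.data)
        md = evals.mean(axis=-1, keepdims=True)
        num = ((evals - md) ** 2).sum(axis=-1)
        den = (evals**2).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * num / den)
        return np.where(den > 0, fa, 0.0)

    def to_nifti(self) -> nib.Nifti1Image:
        comp = np.stack(
            [self.data[..., i, j] for (i, j) in _TENSOR_COMPONENTS], axis=-1
        ).astype(np.float32)
        img = nib.Nifti1Image(comp, self.affine.matrix)
        img.header.set_sform(self.affine.matrix, code=1)
        img.header.set_intent("symmetric matrix", (3,))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "TensorVolume":
        img = nib.load(str(path))
        comp = np.asanyarray(img.dataobj)
        if comp.shape[-1] != 6:
            raise ValueError("expected a 6-component symmetric-tensor NIfTI")
        full = np.zeros(comp.shape[:3] + (3, 3), dtype=float)
        for c, (i, j) in enumerate(_TENSOR_COMPONENTS):
            full[..., i, j] = comp[..., c]
            full[..., j, i] = comp[..., c]
        return cls(full, AffineTransform(img.affine))


def trilinear_sample(data: np.ndarray, affine: AffineTransform, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate a scalar grid at world-mm points.

    Points outside the grid are clamped to the boundary.
    """
    vox = np.atleast_2d(world_to_voxel(points, affine))
    shape = np.asarray(data.shape[:3])
    vox = np.clip(vox, 0.0, shape - 1.0)
    i0 = np.floor(vox).astype(int)
    i0 = np.minimum(i0, shape - 2)
    i0 = np.maximum(i0, 0)
    f = vox - i0
    out = np.zeros(len(vox), dtype=float)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                out += w * data[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out[0] if np.ndim(points) == 1 else out
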