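"""Voxel grids, coordinate transforms, volumes, masks and streamline containers.

All streamline coordinates live in world millimetres (scanner space), matching
the TCK convention; voxel indices are derived on demand.  Voxel ownership is
half-open: voxel ``i`` owns continuous indices in ``[i - 0.5, i + 0.5)`` per
axis, i.e. voxel centers sit at integer continuous indices.  Indexing is
0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "Volume",
    "BinaryMask",
    "AffineTransform",
    "Tractogram",
    "world_to_voxel",
    "world_to_voxel_many",
    "voxel_to_world",
    "apply_transform",
    "binarize",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
        raise ValueError("affine bottom row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass(frozen=True)
class ImageGrid:
    """A 3-D voxel lattice with a voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @classmethod
    def from_spacing(
        cls,
        dims: tuple[int, int, int],
        voxel_size: float | tuple[float, float, float],
        origin: tuple[float, float, float] | None = None,
    ) -> "ImageGrid":
        """Axis-aligned grid.  Default origin centers the grid on world 0."""
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
        if np.any(vs <= 0):
            raise ValueError("voxel_size must be positive")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(vs)
        if origin is None:
            origin = -(np.asarray(dims, dtype=float) - 1.0) / 2.0 * vs
        affine[:3, 3] = origin
        return cls(tuple(dims), affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageGrid):
            return NotImplemented
        return self.dims == other.dims and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.dims, self.affine.tobytes()))


@dataclass
class Volume:
    """A real scalar field sampled on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must all be finite")


@dataclass
class BinaryMask:
    """A {0,1} label field sampled on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {values.shape} != grid dims {self.grid.dims}"
            )
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.values = values.astype(np.uint8)

    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class AffineTransform:
    """World-mm -> world-mm affine map (e.g. subject -> template)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _check_affine(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: np.ndarray,
        center: np.ndarray | None = None,
    ) -> "AffineTransform":
        """Rigid map rotating about ``center`` (world mm) then translating."""
        m = np.eye(4)
        rotation = np.asarray(rotation, dtype=float)
        m[:3, :3] = rotation
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        m[:3, 3] = c - rotation @ c + np.asarray(translation, dtype=float)
        return cls(m)

    @property
    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]


@dataclass
class Tractogram:
    """An ordered collection of world-space streamlines.

    Each streamline is an (n, 3) float array of world-mm coordinates with
    n >= 2 and all coordinates finite.  ``len(tractogram)`` is the number of
    streamlines (NOS).
    """

    streamlines: list[np.ndarray]
    reference_grid: ImageGrid
    name: str = "tractogram"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("tractogram name must be nonempty")
        checked = []
        for i, s in enumerate(self.streamlines):
            s = np.asarray(s, dtype=float)
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) array")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            checked.append(s)
        self.streamlines = checked

    def __len__(self) -> int:
        return len(self.streamlines)


def world_to_voxel_many(
    points: np.ndarray, grid: ImageGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Map (n, 3) world points to integer voxel indices.

    Returns ``(indices, inside)`` where ``indices`` is (n, 3) int and
    ``inside`` flags points whose owning voxel lies within the grid.  Indices
    of outside points are clipped-free (may be negative or >= dims).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    inv = grid.inverse_affine
    cont = points @ inv[:3, :3].T + inv[:3, 3]
    idx = np.floor(cont + 0.5).astype(np.int64)
    dims = np.asarray(grid.dims)
    inside = np.all((idx >= 0) & (idx < dims), axis=1)
    return idx, inside


def world_to_voxel(point: np.ndarray, grid: ImageGrid) -> tuple[int, int, int] | None:
    """Voxel index owning a single world point, or None when out of grid."""
    idx, inside = world_to_voxel_many(np.asarray(point, dtype=float)[None, :], grid)
    if not inside[0]:
        return None
    return tuple(int(v) for v in idx[0])


def voxel_to_world(indices: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """World-mm coordinates of voxel centers for (n, 3) integer indices."""
    indices = np.atleast_2d(np.asarray(indices, dtype=float))
    return indices @ grid.affine[:3, :3].T + grid.affine[:3, 3]


def binarize(volume: Volume) -> BinaryMask:
    """1 where the volume is strictly positive, 0 elsewhere."""
    return BinaryMask(volume.grid, (volume.values > 0).astype(np.uint8))


def _resample_nearest(
    values: np.ndarray,
    source_grid: ImageGrid,
    transform: AffineTransform,
    target_grid: ImageGrid,
    fill: float = 0.0,
) -> np.ndarray:
    """Pull-back resampling: each target voxel takes the value of the source
    voxel owning its back-transformed center."""
    ii, jj, kk = np.meshgrid(
        *(np.arange(d) for d in target_grid.dims), indexing="ij"
    )
    centers = voxel_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]), target_grid
    )
    back = transform.inverse.apply_points(centers)
    idx, inside = world_to_voxel_many(back, source_grid)
    out = np.full(len(centers), fill, dtype=values.dtype)
    src = idx[inside]
    out[inside] = values[src[:, 0], src[:, 1], src[:, 2]]
    return out.reshape(target_grid.dims)


def apply_transform(obj, transform: AffineTransform, target_grid: ImageGrid | None = None):
    """Map a streamline array, Tractogram, BinaryMask or Volume through a
    world->world affine.

    Streamlines are mapped pointwise.  Masks and volumes are resampled onto
    ``target_grid`` (default: the object's own grid) by nearest neighbour, so
    a mask stays exactly {0, 1}.
    """
    if isinstance(obj, np.ndarray):
        return transform.apply_points(obj)
    if isinstance(obj, Tractogram):
        grid = target_grid if target_grid is not None else obj.reference_grid
        return Tractogram(
            [transform.apply_points(s) for s in obj.streamlines], grid, obj.name
        )
    if isinstance(obj, BinaryMask):
        grid = target_grid if target_grid is not None else obj.grid
        vals = _resample_nearest(obj.values, obj.grid, transform, grid)
        return BinaryMask(grid, vals)
    if isinstance(obj, Volume):
        grid = target_grid if target_grid is not None else obj.grid
        vals = _resample_nearest(obj.values, obj.grid, transform, grid)
        return Volume(grid, vals)
    raise TypeError(f"cannot transform object of type {type(obj)!r}")
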