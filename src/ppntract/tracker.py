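"""Probabilistic streamline propagation over a discrete orientation field.

The propagation scheme follows the arc-step family of probabilistic trackers:
at each step a direction is drawn with probability proportional to lobe
amplitude, restricted to a curvature cone around the incoming tangent, and the
point advances along a circular arc of fixed arc-length whose initial tangent
is the incoming direction and whose final tangent is the drawn direction.
Orientation information is a per-voxel mixture of discrete lobes (unit
direction + amplitude, antipodally symmetric) rather than a spherical-harmonic
fODF; field lookup is nearest-voxel.  Tracking is bidirectional from each
seed: two half-tracks are launched with opposite signs of the initial
direction and concatenated through the shared seed point.

Default parameterization: step = 1.25 x voxel size, maximum angle per step =
30 degrees x (step / voxel size) = 37.5 degrees, amplitude cutoff 0.025,
1000 seeds per voxel at full scale (scaled to 10 by default for desk-scale
cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageGrid, BinaryMask, Tractogram

__all__ = [
    "TrackingParams",
    "OrientationField",
    "resolve_params",
    "sample_direction",
    "propagate",
    "track_from_seed_mask",
]

BACKGROUND_AMPLITUDE = 0.01


@dataclass(frozen=True)
class TrackingParams:
    seeds_per_voxel: int = 10
    step_factor: float = 1.25
    angle_factor_deg: float = 30.0
    cutoff: float = 0.025
    max_length_mm: float = 120.0
    min_points: int = 2

    def __post_init__(self) -> None:
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0, 1)")
        if self.step_factor <= 0:
            raise ValueError("step_factor must be positive")
        if not 0 < self.angle_factor_deg * self.step_factor < 90:
            raise ValueError("resolved max angle must lie in (0, 90) degrees")
        if self.max_length_mm <= 0:
            raise ValueError("max_length_mm must be positive")


def resolve_params(voxel_size_mm: float, params: TrackingParams) -> tuple[float, float]:
    """Resolve (step_mm, max_angle_deg) from the voxel size.

    step = step_factor x voxel size; max angle = angle_factor x step / voxel
    size, which is constant (37.5 degrees at the defaults) regardless of voxel
    size since step/voxel = step_factor.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    step = params.step_factor * voxel_size_mm
    max_angle = params.angle_factor_deg * step / voxel_size_mm
    return step, max_angle


class OrientationField:
    """Per-voxel lobe mixtures standing in for fiber ODFs.

    ``dirs`` is (X, Y, Z, K, 3) with unit rows, ``amps`` (X, Y, Z, K) with
    zero padding for voxels holding fewer than K lobes.  Voxels flagged
    ``isotropic`` model orientation-free background: a single lobe whose
    direction is drawn uniformly at sampling time, with a fixed low amplitude
    (0.01, below the default 0.025 cutoff, so tracking terminates there).
    """

    def __init__(
        self,
        grid: ImageGrid,
        dirs: np.ndarray,
        amps: np.ndarray,
        isotropic: np.ndarray | None = None,
    ) -> None:
        dirs = np.asarray(dirs, dtype=float)
        amps = np.asarray(amps, dtype=float)
        if dirs.shape[:3] != grid.dims or dirs.shape[-1] != 3:
            raise ValueError("dirs must have shape grid.dims + (K, 3)")
        if amps.shape != dirs.shape[:-1]:
            raise ValueError("amps must have shape grid.dims + (K,)")
        if not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise ValueError("amplitudes must be finite and nonnegative")
        norms = np.linalg.norm(dirs, axis=-1)
        active = amps > 0
        if not np.allclose(norms[active], 1.0, atol=1e-6):
            raise ValueError("active lobe directions must be unit-norm")
        self.grid = grid
        self.dirs = dirs
        self.amps = amps
        if isotropic is None:
            isotropic = np.zeros(grid.dims, dtype=bool)
        self.isotropic = np.asarray(isotropic, dtype=bool)
        self._inv = grid.inverse_affine

    @classmethod
    def background(cls, grid: ImageGrid) -> "OrientationField":
        """A field of pure isotropic background (no coherent orientation)."""
        dims = grid.dims
        dirs = np.zeros(dims + (1, 3))
        dirs[..., 0, 2] = 1.0
        amps = np.full(dims + (1,), BACKGROUND_AMPLITUDE)
        return cls(grid, dirs, amps, np.ones(dims, dtype=bool))

    def lobes_at(self, voxel: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(directions, amplitudes) of the active lobes at one voxel."""
        a = self.amps[voxel]
        keep = a > 0
        return self.dirs[voxel][keep], a[keep]

    def max_amplitude(self, voxel: tuple[int, int, int]) -> float:
        return float(self.amps[voxel].max(initial=0.0))

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int] | None:
        c = self._inv[:3, :3] @ point + self._inv[:3, 3]
        i = int(np.floor(c[0] + 0.5))
        j = int(np.floor(c[1] + 0.5))
        k = int(np.floor(c[2] + 0.5))
        d = self.grid.dims
        if 0 <= i < d[0] and 0 <= j < d[1] and 0 <= k < d[2]:
            return (i, j, k)
        return None


def _uniform_sphere(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def sample_direction(
    field: OrientationField,
    point: np.ndarray,
    previous_direction: np.ndarray | None,
    max_angle_deg: float,
    rng: np.random.Generator,
    cutoff: float = 0.025,
) -> np.ndarray | None:
    """Draw one propagation direction at ``point``, or None to terminate.

    Candidate lobes are those with amplitude >= cutoff whose direction
    (antipodal sign resolved toward the incoming tangent) lies within the
    curvature cone; one is drawn with probability proportional to amplitude.
    With no previous direction (seeding) all above-cutoff lobes compete and
    the caller uses the drawn orientation for both launch signs.
    """
    voxel = field.voxel_of(np.asarray(point, dtype=float))
    if voxel is None:
        raise ValueError(f"point {point} is outside the field grid")
    dirs, amps = field.lobes_at(voxel)
    if len(amps) == 0:
        return None
    keep = amps >= cutoff
    dirs, amps = dirs[keep], amps[keep]
    if len(amps) == 0:
        return None
    if field.isotropic[voxel]:
        # single orientation-free lobe: any direction is equally likely
        d = _uniform_sphere(rng)
        if previous_direction is None:
            return d
        if d @ previous_direction < 0:
            d = -d
        if d @ previous_direction < np.cos(np.deg2rad(max_angle_deg)):
            return None
        return d
    if previous_direction is not None:
        prev = np.asarray(previous_direction, dtype=float)
        dots = dirs @ prev
        signs = np.where(dots < 0, -1.0, 1.0)
        dirs = dirs * signs[:, None]
        cone = np.abs(dots) >= np.cos(np.deg2rad(max_angle_deg))
        dirs, amps = dirs[cone], amps[cone]
        if len(amps) == 0:
            return None
    choice = rng.choice(len(amps), p=amps / amps.sum())
    return dirs[choice].copy()


def _arc_step(point: np.ndarray, t_prev: np.ndarray, t_new: np.ndarray, step: float) -> np.ndarray:
    """Advance along a circular arc of arc-length ``step`` whose initial
    tangent is t_prev and final tangent t_new; straight when they coincide."""
    c = float(np.clip(t_prev @ t_new, -1.0, 1.0))
    theta = float(np.arccos(c))
    if theta < 1e-12:
        return point + step * t_new
    chord = 2.0 * (step / theta) * np.sin(theta / 2.0)
    bis = t_prev + t_new
    bis /= np.linalg.norm(bis)
    return point + chord * bis


def _half_track(
    seed: np.ndarray,
    init_dir: np.ndarray,
    field: OrientationField,
    step: float,
    max_angle: float,
    cutoff: float,
    max_length: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    points: list[np.ndarray] = []
    p = seed
    t = init_dir
    length = 0.0
    while length + step <= max_length:
        nxt = sample_direction(field, p, t, max_angle, rng, cutoff)
        if nxt is None:
            break
        q = _arc_step(p, t, nxt, step)
        if field.voxel_of(q) is None:
            break
        points.append(q)
        p, t = q, nxt
        length += step
    return points


def propagate(
    seed_point: np.ndarray,
    field: OrientationField,
    params: TrackingParams,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Track bidirectionally from one seed point.

    Returns an (n, 3) streamline, or None when the seed is rejected (no
    above-cutoff orientation at the seed, or fewer than ``min_points`` total).
    """
    seed_point = np.asarray(seed_point, dtype=float)
    if field.voxel_of(seed_point) is None:
        raise ValueError("seed point lies outside the grid")
    vs = float(np.min(field.grid.voxel_size))
    step, max_angle = resolve_params(vs, params)
    d0 = sample_direction(field, seed_point, None, max_angle, rng, params.cutoff)
    if d0 is None:
        return None
    half = params.max_length_mm / 2.0
    fwd = _half_track(seed_point, d0, field, step, max_angle, params.cutoff, half, rng)
    bwd = _half_track(seed_point, -d0, field, step, max_angle, params.cutoff, half, rng)
    pts = bwd[::-1] + [seed_point] + fwd
    if len(pts) < params.min_points:
        return None
    return np.array(pts)


def track_from_seed_mask(
    seed_mask: BinaryMask,
    field: OrientationField,
    params: TrackingParams,
    rng: np.random.Generator,
    name: str = "tracked",
) -> Tractogram:
    """Seed ``seeds_per_voxel`` uniform points in each mask voxel and track.

    Seed voxels are visited in lexicographic order so the result is fully
    determined by the generator state.
    """
    if seed_mask.grid != field.grid:
        raise ValueError("seed mask and field must share a grid")
    voxels = np.argwhere(seed_mask.values > 0)
    if len(voxels) == 0:
        raise ValueError("seed mask is empty")
    A, b = field.grid.affine[:3, :3], field.grid.affine[:3, 3]
    streamlines = []
    for v in voxels:
        # uniform continuous indices within the voxel's half-open cube
        offs = rng.uniform(-0.5, 0.5, size=(params.seeds_per_voxel, 3))
        pts = (v + offs) @ A.T + b
        for p in pts:
            s = propagate(p, field, params, rng)
            if s is not None:
                streamlines.append(s)
    return Tractogram(streamlines, field.grid, name)
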