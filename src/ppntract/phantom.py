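"""Synthetic phantom cohort emulating pallido-tegmental connectivity.

The phantom stands in for a diffusion-MRI cohort: a template "brain" on a
40 x 48 x 32 grid of 1.25 mm isotropic voxels holds spherical ROIs for the
two pallidal segments (GPi, GPe), the pedunculopontine nucleus (PPN) and six
exclusion nuclei per hemisphere (caudate, putamen, accumbens, STN, SNc, SNr),
plus a thin midsagittal slab.  Six true bundles (GPi-ipsilateral,
GPe-ipsilateral and midline-crossing GPi-contralateral, per hemisphere)
follow smooth curves from the pallidal seed down to the PPN; distractor
bundles run from the pallidum into exclusion nuclei.  Each pallidal ROI is
partitioned into limbic (anterior), associative (central) and sensorimotor
(posterior) territories by an exact rank-based tercile split along the
anteroposterior axis.

Connectivity effects are encoded twice, consistently:

* ground-truth per-bundle streamline counts are Poisson draws around
  ``n_true x multiplier``, where the multiplier composes the GPi/GPe ratio
  (default 2.0), the right/left ratio (default 1.25) and per-hemisphere
  contralateral factors;
* the orientation-field tube cross-section of each bundle scales with the
  same multiplier (radius proportional to its square root), so streamline
  counts obtained by actually *tracking* the phantom inherit the same
  ordering: the expected tracked count is roughly seeds/voxel x covered seed
  voxels x success probability, and the covered-voxel count scales with the
  tube cross-section.

Per-subject variability is a rigid spatial jitter (bounded translation and
rotation) applied to the whole scene; its inverse is stored as the exact
subject-to-template transform, standing in for a registration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import (
    AffineTransform,
    BinaryMask,
    ImageGrid,
    Tractogram,
    Volume,
    apply_transform,
    voxel_to_world,
)
from .tracker import BACKGROUND_AMPLITUDE, OrientationField

__all__ = [
    "BundleSpec",
    "PhantomConfig",
    "SyntheticSubject",
    "bundle_multiplier",
    "expected_counts",
    "ground_truth_counts",
    "simulate_cohort_counts",
    "generate_orientation_field",
    "generate_subject",
    "generate_cohort",
    "sample_curve",
    "TERRITORIES",
]

TERRITORIES = ("limbic", "associative", "sensorimotor")

TRUE_BUNDLES = (
    "L_GPi_ipsi",
    "R_GPi_ipsi",
    "L_GPe_ipsi",
    "R_GPe_ipsi",
    "L_GPi_contra",
    "R_GPi_contra",
)


@dataclass(frozen=True)
class BundleSpec:
    """One bundle: a smooth curve, an expected count, and jitter widths.

    ``control_points`` start at the seed (pallidal) end.  ``n_true`` is the
    base expected streamline count *before* the effect multipliers.
    ``dispersion_mm`` jitters interior control points per streamline;
    endpoints are pinned more tightly (``endpoint_dispersion_mm``) so that
    essentially every ground-truth streamline starts in the seed ROI and
    terminates inside the target ROI.
    """

    name: str
    control_points: np.ndarray
    n_true: float
    dispersion_mm: float = 1.0
    endpoint_dispersion_mm: float = 0.5
    crosses_midline: bool = False
    distractor: bool = False

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] < 3:
            raise ValueError(f"bundle {self.name!r}: need >= 3 control points")
        object.__setattr__(self, "control_points", cp)
        if self.n_true < 0 or self.dispersion_mm < 0:
            raise ValueError(f"bundle {self.name!r}: n_true and dispersion must be >= 0")


def _mirror(points) -> np.ndarray:
    p = np.asarray(points, dtype=float).copy()
    p[:, 0] *= -1
    return p


def _default_rois() -> dict[str, tuple[tuple[float, float, float], float]]:
    right = {
        # pallidal segments are elongated anteroposteriorly (ellipsoid semi-axes)
        "GPi": ((9.5, 6.0, 6.0), (2.6, 5.5, 2.6)),
        "GPe": ((17.0, 6.0, 6.0), (2.6, 5.5, 2.6)),
        "PPN": ((5.0, -12.0, -12.0), 3.0),
        "caudate": ((7.0, 16.0, 10.0), 2.0),
        "putamen": ((14.0, 14.0, 2.0), 2.0),
        "accumbens": ((5.0, 18.0, -4.0), 2.0),
        "STN": ((12.0, -20.0, 6.0), 2.0),
        "SNc": ((8.0, -22.0, -8.0), 2.0),
        "SNr": ((14.0, -22.0, -2.0), 2.0),
    }
    rois = {}
    for name, (c, r) in right.items():
        rois[f"{name}_R"] = (c, r)
        rois[f"{name}_L"] = ((-c[0], c[1], c[2]), r)
    return rois


def _default_bundles() -> list[BundleSpec]:
    gpi_ipsi = [(9.5, 6, 6), (9.5, 6, -1), (9.5, 2, -5), (7, -8, -9), (5, -12, -12)]
    gpe_ipsi = [(17, 6, 6), (17.5, 5, -2), (15, 0, -7), (10, -7, -10), (5, -12, -12)]
    gpi_contra = [(9.5, 6, 6), (9.5, 5, -2), (6, -3, -7), (0, -9, -11), (-5, -12, -12)]
    gpi_caud = [(9.5, 6, 6), (8.5, 11, 8), (7, 16, 10)]
    gpe_put = [(17, 6, 6), (15.5, 10, 4), (14, 14, 2)]
    out = []
    for side, mir in (("R", False), ("L", True)):
        f = _mirror if mir else (lambda p: np.asarray(p, dtype=float))
        out += [
            BundleSpec(f"{side}_GPi_ipsi", f(gpi_ipsi), 200.0),
            BundleSpec(f"{side}_GPe_ipsi", f(gpe_ipsi), 200.0),
            BundleSpec(f"{side}_GPi_contra", f(gpi_contra), 200.0, crosses_midline=True),
            BundleSpec(f"{side}_GPi_caudate", f(gpi_caud), 100.0, distractor=True),
            BundleSpec(f"{side}_GPe_putamen", f(gpe_put), 100.0, distractor=True),
        ]
    return out


@dataclass
class PhantomConfig:
    dims: tuple[int, int, int] = (40, 48, 32)
    voxel_size: float = 1.25
    rois: dict = field(default_factory=_default_rois)
    midline_thickness_voxels: int = 2
    bundles: list = field(default_factory=_default_bundles)
    gpi_over_gpe_ratio: float = 2.0
    right_over_left_ratio: float = 1.25
    contra_factor_left: float = 1.25
    contra_factor_right: float = 0.85
    tube_radius_voxels: float = 1.5
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 3.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for knob in ("gpi_over_gpe_ratio", "right_over_left_ratio",
                     "contra_factor_left", "contra_factor_right"):
            if getattr(self, knob) <= 0:
                raise ValueError(f"{knob} must be > 0")
        grid = self.grid
        lo = voxel_to_world(np.zeros((1, 3)), grid)[0]
        hi = voxel_to_world(np.asarray(grid.dims)[None, :] - 1, grid)[0]
        for name, (center, radius) in self.rois.items():
            c = np.asarray(center, dtype=float)
            axes = _roi_semi_axes(radius)
            if np.any(c - axes < lo) or np.any(c + axes > hi):
                raise ValueError(f"ROI {name!r} does not fit inside the grid")
        # left/right mirror symmetry of the ROI layout about the midline
        for name, (center, radius) in self.rois.items():
            if name.endswith("_R"):
                twin = self.rois.get(name[:-2] + "_L")
                if twin is None or not np.allclose(
                    _mirror(np.asarray(center)[None, :])[0], twin[0]
                ) or not np.allclose(_roi_semi_axes(twin[1]), _roi_semi_axes(radius)):
                    raise ValueError(f"ROI {name!r} lacks a mirror-symmetric twin")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid.from_spacing(self.dims, self.voxel_size)


@dataclass
class SyntheticSubject:
    subject_id: int
    grid: ImageGrid
    masks: dict  # ROI name -> BinaryMask (subject space), incl. "midline"
    territory_masks: dict  # e.g. "GPi_L_associative" -> BinaryMask
    field: OrientationField
    tractograms: dict  # bundle name -> ground-truth Tractogram
    true_counts: dict  # bundle name -> realized Poisson count
    to_template: AffineTransform


def bundle_multiplier(config: PhantomConfig, name: str) -> float:
    """Compose the effect-size multiplier for one bundle from the knobs."""
    parts = name.split("_")
    side, segment = parts[0], parts[1]
    kind = parts[2] if len(parts) > 2 else "ipsi"
    if kind not in ("ipsi", "contra"):
        return 1.0  # distractors carry no effect structure
    m = 1.0
    if segment == "GPi":
        m *= config.gpi_over_gpe_ratio
    if side == "R":
        m *= config.right_over_left_ratio
    if kind == "contra":
        m *= config.contra_factor_left if side == "L" else config.contra_factor_right
    return m


def expected_counts(config: PhantomConfig) -> dict[str, float]:
    """Expected (pre-Poisson) ground-truth count per bundle."""
    return {
        b.name: b.n_true * bundle_multiplier(config, b.name) for b in config.bundles
    }


def ground_truth_counts(config: PhantomConfig, rng: np.random.Generator) -> dict[str, int]:
    """Realized per-bundle counts: Poisson draws around the expected counts."""
    return {
        name: int(rng.poisson(lam)) for name, lam in expected_counts(config).items()
    }


def simulate_cohort_counts(
    config: PhantomConfig, n_subjects: int, seed: int | None = None
) -> pd.DataFrame:
    """Ground-truth NOS table for a cohort, skipping mask/field generation.

    This is the fast path used for count-level simulations (power and type-I
    error studies): it draws exactly the same Poisson counts a full
    ``generate_subject`` would record, keyed by the same derived seeds.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    master = config.master_seed if seed is None else seed
    rows = []
    for sid in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([master, sid]))
        counts = ground_truth_counts(config, rng)
        for b in config.bundles:
            if not b.distractor:
                rows.append({"subject_id": sid, "bundle": b.name, "nos": counts[b.name]})
    return pd.DataFrame(rows)


def sample_curve(control_points: np.ndarray, spacing_mm: float = 1.0) -> np.ndarray:
    """Sample a natural cubic spline through the control points at roughly
    even arc spacing (chord-length parameterization)."""
    cp = np.asarray(control_points, dtype=float)
    t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    if t[-1] <= 0:
        raise ValueError("degenerate curve: zero total chord length")
    spline = CubicSpline(t, cp, bc_type="natural")
    n = max(2, int(np.ceil(t[-1] / spacing_mm)) + 1)
    return spline(np.linspace(0.0, t[-1], n))


def _roi_semi_axes(radius) -> np.ndarray:
    return np.broadcast_to(np.asarray(radius, dtype=float), (3,))


def _sphere_mask(grid: ImageGrid, center, radius) -> BinaryMask:
    """Voxelize a sphere (scalar radius) or axis-aligned ellipsoid (3-vector
    of semi-axes) by the voxel-center-inside test."""
    axes = _roi_semi_axes(radius)
    centers = _voxel_centers(grid)
    rel = (centers - np.asarray(center, dtype=float)) / axes
    inside = np.einsum("ij,ij->i", rel, rel) <= 1.0
    return BinaryMask(grid, inside.reshape(grid.dims).astype(np.uint8))


_CENTER_CACHE: dict = {}


def _voxel_centers(grid: ImageGrid) -> np.ndarray:
    key = (grid.dims, grid.affine.tobytes())
    if key not in _CENTER_CACHE:
        ii, jj, kk = np.meshgrid(*(np.arange(d) for d in grid.dims), indexing="ij")
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        _CENTER_CACHE[key] = voxel_to_world(idx, grid)
    return _CENTER_CACHE[key]


def _slab_mask(grid: ImageGrid, thickness_voxels: int, voxel_size: float) -> BinaryMask:
    half = thickness_voxels * voxel_size / 2.0
    centers = _voxel_centers(grid)
    inside = np.abs(centers[:, 0]) <= half
    return BinaryMask(grid, inside.reshape(grid.dims).astype(np.uint8))


def _territory_labels(roi: BinaryMask) -> Volume:
    """Exact tercile partition of an ROI along the anteroposterior axis.

    Voxels are ranked by world y (posterior first; z then lexicographic index
    break ties) and split into three near-equal contiguous chunks:
    1 = sensorimotor (posterior), 2 = associative (central), 3 = limbic
    (anterior).  The chunks are disjoint and their union is the ROI.
    """
    idx = np.argwhere(roi.values > 0)
    if len(idx) < 3:
        raise ValueError("ROI too small to partition into three territories")
    world = voxel_to_world(idx, roi.grid)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2], world[:, 2], world[:, 1]))
    labels = np.zeros(roi.grid.dims, dtype=np.int16)
    n = len(idx)
    bounds = [0, n // 3, n - n // 3, n]
    for lab, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        sel = idx[order[a:b]]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = lab
    return Volume(roi.grid, labels)


def template_masks(config: PhantomConfig) -> tuple[dict, dict]:
    """ROI masks and territory masks on the template grid."""
    grid = config.grid
    masks = {
        name: _sphere_mask(grid, center, radius)
        for name, (center, radius) in config.rois.items()
    }
    masks["midline"] = _slab_mask(grid, config.midline_thickness_voxels, config.voxel_size)
    territories = {}
    for seg in ("GPi", "GPe"):
        for side in ("L", "R"):
            labels = _territory_labels(masks[f"{seg}_{side}"])
            for lab, terr in ((1, "sensorimotor"), (2, "associative"), (3, "limbic")):
                territories[f"{seg}_{side}_{terr}"] = BinaryMask(
                    grid, (labels.values == lab).astype(np.uint8)
                )
    return masks, territories


def generate_orientation_field(
    grid: ImageGrid,
    centerlines: list[tuple[str, np.ndarray, float]],
    rng: np.random.Generator,
) -> OrientationField:
    """Build the lobe-mixture field from bundle centerlines.

    ``centerlines`` holds (name, control_points world mm, tube_radius_mm)
    triples.  Every voxel whose center lies within a bundle's tube receives
    one lobe per bundle: the unit tangent of the nearest centerline sample,
    with amplitude drawn uniform in [0.3, 1.0].  Voxels inside several tubes
    hold several lobes (crossing fibers).  All other voxels are isotropic
    background at amplitude 0.01, below the default tracking cutoff.
    """
    vs = float(np.min(grid.voxel_size))
    per_voxel: dict[tuple[int, int, int], list[np.ndarray]] = {}
    inv = grid.inverse_affine
    dims = np.asarray(grid.dims)
    for _, control_points, radius_mm in centerlines:
        samples = sample_curve(control_points, spacing_mm=0.5 * vs)
        tangents = np.gradient(samples, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        r_vox = radius_mm / vs
        span = int(np.ceil(r_vox))
        offs = np.array(
            [
                (i, j, k)
                for i in range(-span, span + 1)
                for j in range(-span, span + 1)
                for k in range(-span, span + 1)
            ]
        )
        best: dict[tuple[int, int, int], tuple[float, np.ndarray]] = {}
        cont = samples @ inv[:3, :3].T + inv[:3, 3]
        near = np.floor(cont + 0.5).astype(int)
        A, b0 = grid.affine[:3, :3], grid.affine[:3, 3]
        for s_idx in range(len(samples)):
            vv = near[s_idx] + offs
            ok = np.all((vv >= 0) & (vv < dims), axis=1)
            vv = vv[ok]
            centers = vv @ A.T + b0
            d = np.linalg.norm(centers - samples[s_idx], axis=1)
            close = d <= radius_mm
            for v, dist in zip(vv[close], d[close]):
                key = (int(v[0]), int(v[1]), int(v[2]))
                if key not in best or dist < best[key][0]:
                    best[key] = (dist, tangents[s_idx])
        for key, (_, tang) in best.items():
            per_voxel.setdefault(key, []).append(tang)
    k_max = max((len(v) for v in per_voxel.values()), default=1)
    dirs = np.zeros(grid.dims + (k_max, 3))
    amps = np.zeros(grid.dims + (k_max,))
    isotropic = np.ones(grid.dims, dtype=bool)
    dirs[..., :, 2] = 1.0  # placeholder direction for padding/background
    amps[..., 0] = BACKGROUND_AMPLITUDE
    # deterministic order: iterate voxels lexicographically
    for key in sorted(per_voxel):
        lobes = per_voxel[key]
        isotropic[key] = False
        amps[key] = 0.0
        for li, tang in enumerate(lobes):
            dirs[key][li] = tang
            amps[key][li] = rng.uniform(0.3, 1.0)
        for li in range(len(lobes), k_max):
            dirs[key][li] = (0.0, 0.0, 1.0)
    return OrientationField(grid, dirs, amps, isotropic)


def _draw_jitter(config: PhantomConfig, rng: np.random.Generator) -> AffineTransform:
    """Rigid template->subject jitter: bounded rotation about the grid center
    plus bounded translation."""
    t = rng.uniform(-config.max_translation_mm, config.max_translation_mm, size=3)
    angle = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    if config.max_translation_mm == 0 and config.max_rotation_deg == 0:
        return AffineTransform.identity()
    return AffineTransform.from_rotation_translation(R, t, center=np.zeros(3))


def _check_rois_in_grid(config: PhantomConfig, jitter: AffineTransform) -> None:
    grid = config.grid
    lo = voxel_to_world(np.zeros((1, 3)), grid)[0]
    hi = voxel_to_world(np.asarray(grid.dims)[None, :] - 1, grid)[0]
    R = jitter.matrix[:3, :3]
    for name, (center, radius) in config.rois.items():
        c = jitter.apply_points(np.asarray(center, dtype=float)[None, :])[0]
        # axis-aligned half-extents of the rigidly rotated ellipsoid
        r = np.sqrt(((R * _roi_semi_axes(radius)) ** 2).sum(axis=1))
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(
                f"ROI {name!r} leaves the grid after subject jitter; "
                "reduce max_translation_mm / max_rotation_deg"
            )


def generate_subject(
    config: PhantomConfig, subject_id: int, seed: int
) -> SyntheticSubject:
    """Generate one fully ground-truthed synthetic subject.

    Reproducible: the generator state is derived from ``(seed, subject_id)``
    only.  The whole template scene (masks, territories, bundle centerlines)
    is mapped through a per-subject rigid jitter; ground-truth streamline
    counts are Poisson draws around the effect-adjusted expected counts; the
    orientation field is built from the jittered centerlines; the stored
    transform is the exact inverse of the jitter (subject -> template).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_id)]))
    counts = ground_truth_counts(config, rng)
    jitter = _draw_jitter(config, rng)
    _check_rois_in_grid(config, jitter)
    grid = config.grid

    tmpl_masks, tmpl_terr = template_masks(config)
    masks = {k: apply_transform(m, jitter, grid) for k, m in tmpl_masks.items()}
    territory_masks = {k: apply_transform(m, jitter, grid) for k, m in tmpl_terr.items()}

    centerlines = []
    for b in config.bundles:
        cp = jitter.apply_points(b.control_points)
        radius_mm = (
            config.tube_radius_voxels
            * np.sqrt(bundle_multiplier(config, b.name))
            * config.voxel_size
        )
        centerlines.append((b.name, cp, radius_mm))
    field = generate_orientation_field(grid, centerlines, rng)

    tractograms = {}
    for b, (_, cp, _) in zip(config.bundles, centerlines):
        n = counts[b.name]
        streamlines = []
        for _ in range(n):
            jcp = cp.copy()
            jcp[1:-1] += rng.normal(scale=b.dispersion_mm, size=(len(cp) - 2, 3))
            jcp[0] += rng.normal(scale=b.endpoint_dispersion_mm, size=3)
            jcp[-1] += rng.normal(scale=b.endpoint_dispersion_mm, size=3)
            streamlines.append(sample_curve(jcp, spacing_mm=1.0))
        tractograms[b.name] = Tractogram(streamlines, grid, b.name) if streamlines else Tractogram([], grid, b.name)

    return SyntheticSubject(
        subject_id=subject_id,
        grid=grid,
        masks=masks,
        territory_masks=territory_masks,
        field=field,
        tractograms=tractograms,
        true_counts=counts,
        to_template=jitter.inverse,
    )


def generate_cohort(config: PhantomConfig, n_subjects: int) -> list[SyntheticSubject]:
    """Deterministic cohort: subject i is generated from (master_seed, i)."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    return [
        generate_subject(config, sid, config.master_seed) for sid in range(n_subjects)
    ]
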