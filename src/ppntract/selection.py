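"""Seed/include/exclude bundle selection and pallidotegmental ROI protocol.

Selection semantics mirror the MRtrix tckgen conventions: an *include* region
must be intersected anywhere along the streamline's course (not terminated
in); touching any *exclude* region rejects the whole streamline.  Streamline
membership in a voxel is decided on the polyline densified at half-voxel
spacing, so thin masks (the one/two-slice midline slab) cannot be tunnelled
through between vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, ImageGrid, Tractogram, world_to_voxel_many

__all__ = [
    "SelectionSpec",
    "BundleResult",
    "streamline_intersects",
    "visited_voxels",
    "select_bundle",
    "build_pallidotegmental_specs",
    "EXCLUSION_NUCLEI",
    "BUNDLE_NAMES",
]

EXCLUSION_NUCLEI = ("caudate", "putamen", "accumbens", "STN", "SNc", "SNr")

#: canonical bundle labels, one per reconstructed pallidotegmental tract
BUNDLE_NAMES = (
    "L_GPi_ipsi",
    "R_GPi_ipsi",
    "L_GPe_ipsi",
    "R_GPe_ipsi",
    "L_GPi_contra",
    "R_GPi_contra",
)


@dataclass
class SelectionSpec:
    """One named bundle definition: seed + all-of includes + none-of excludes."""

    name: str
    seed_mask: BinaryMask
    include_masks: list[BinaryMask]
    exclude_masks: list[BinaryMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        grids = [self.seed_mask.grid] + [m.grid for m in self.include_masks] + [
            m.grid for m in self.exclude_masks
        ]
        if any(g != grids[0] for g in grids[1:]):
            raise ValueError(f"spec {self.name!r}: all masks must share one grid")
        for m in self.exclude_masks:
            if np.any(self.seed_mask.values & m.values):
                raise ValueError(f"spec {self.name!r}: seed overlaps an exclude mask")


@dataclass
class BundleResult:
    name: str
    tractogram: Tractogram
    nos: int
    rejected_not_seeded: int
    rejected_include: int
    rejected_exclude: int

    @property
    def n_input(self) -> int:
        return (
            self.nos
            + self.rejected_not_seeded
            + self.rejected_include
            + self.rejected_exclude
        )


def densify(points: np.ndarray, max_spacing_mm: float) -> np.ndarray:
    """Insert evenly spaced samples along each chord so that no gap exceeds
    ``max_spacing_mm``; original vertices are preserved."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return points
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        chord = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(chord / max_spacing_mm)))
        ts = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + ts * (b - a))
    return np.vstack(out)


def visited_voxels(points: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Unique in-grid voxel indices visited by the streamline, sampled at
    half-voxel spacing along each chord.  Returns an (m, 3) int array."""
    spacing = 0.5 * float(np.min(grid.voxel_size))
    dense = densify(points, spacing)
    idx, inside = world_to_voxel_many(dense, grid)
    idx = idx[inside]
    if len(idx) == 0:
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def _touches(visited: np.ndarray, mask: BinaryMask) -> bool:
    if len(visited) == 0:
        return False
    return bool(mask.values[visited[:, 0], visited[:, 1], visited[:, 2]].any())


def streamline_intersects(points: np.ndarray, mask: BinaryMask) -> bool:
    """True iff the densified streamline enters any mask voxel."""
    return _touches(visited_voxels(points, mask.grid), mask)


def select_bundle(tractogram: Tractogram, spec: SelectionSpec) -> BundleResult:
    """Filter a tractogram down to the streamlines satisfying ``spec``.

    A streamline is kept iff it (a) emanates from the seed mask, (b) touches
    no exclude mask, and (c) intersects every include mask.  Because tracking
    is bidirectional the seed point is an interior vertex, so the seed
    criterion accepts a streamline whose first point lies in the seed mask
    *or* whose course passes through it; a streamline never touching the seed
    is rejected.  Rejection causes are tallied with exclude taking precedence
    over missed include, matching the behaviour of exclusion regions that
    kill a track on contact.  Selection preserves input order and is
    idempotent.
    """
    grid = spec.seed_mask.grid
    kept: list[np.ndarray] = []
    n_not_seeded = n_include = n_exclude = 0
    for s in tractogram.streamlines:
        visited = visited_voxels(s, grid)
        idx, inside = world_to_voxel_many(s[:1], grid)
        starts_in_seed = inside[0] and spec.seed_mask.values[tuple(idx[0])]
        if not starts_in_seed and not _touches(visited, spec.seed_mask):
            n_not_seeded += 1
            continue
        if any(_touches(visited, m) for m in spec.exclude_masks):
            n_exclude += 1
            continue
        if not all(_touches(visited, m) for m in spec.include_masks):
            n_include += 1
            continue
        kept.append(s)
    selected = Tractogram(kept, grid, spec.name) if kept else Tractogram([], grid, spec.name)
    return BundleResult(
        name=spec.name,
        tractogram=selected,
        nos=len(kept),
        rejected_not_seeded=n_not_seeded,
        rejected_include=n_include,
        rejected_exclude=n_exclude,
    )


def build_pallidotegmental_specs(
    masks: dict[str, BinaryMask],
    include_contralateral_nuclei_in_ipsi: bool = False,
) -> list[SelectionSpec]:
    """Build the six pallidotegmental selection specs from named ROI masks.

    Expected mask keys: ``GPi_L/R``, ``GPe_L/R``, ``PPN_L/R``, each exclusion
    nucleus as ``<nucleus>_L/R`` (caudate, putamen, accumbens, STN, SNc, SNr)
    and ``midline``.

    Per hemisphere: the GPi-ipsilateral spec seeds in the GPi, requires the
    ipsilateral PPN, and excludes the GPe, the six ipsilateral nuclei and the
    midline slab; the GPe-ipsilateral spec swaps the pallidal roles; the
    GPi-contralateral spec seeds in the GPi, requires the *contralateral* PPN
    and excludes only the contralateral nuclei (the midline slab must stay
    crossable).  No GPe-contralateral spec is produced.
    """
    required = ["midline"]
    for side in ("L", "R"):
        required += [f"GPi_{side}", f"GPe_{side}", f"PPN_{side}"]
        required += [f"{n}_{side}" for n in EXCLUSION_NUCLEI]
    for key in required:
        if key not in masks:
            raise KeyError(f"missing ROI mask: {key!r}")

    specs = []
    for side, other in (("L", "R"), ("R", "L")):
        nuclei_ipsi = [masks[f"{n}_{side}"] for n in EXCLUSION_NUCLEI]
        nuclei_contra = [masks[f"{n}_{other}"] for n in EXCLUSION_NUCLEI]
        ipsi_extra = nuclei_contra if include_contralateral_nuclei_in_ipsi else []
        specs.append(
            SelectionSpec(
                name=f"{side}_GPi_ipsi",
                seed_mask=masks[f"GPi_{side}"],
                include_masks=[masks[f"PPN_{side}"]],
                exclude_masks=[masks[f"GPe_{side}"], *nuclei_ipsi, *ipsi_extra, masks["midline"]],
            )
        )
        specs.append(
            SelectionSpec(
                name=f"{side}_GPe_ipsi",
                seed_mask=masks[f"GPe_{side}"],
                include_masks=[masks[f"PPN_{side}"]],
                exclude_masks=[masks[f"GPi_{side}"], *nuclei_ipsi, *ipsi_extra, masks["midline"]],
            )
        )
        specs.append(
            SelectionSpec(
                name=f"{side}_GPi_contra",
                seed_mask=masks[f"GPi_{side}"],
                include_masks=[masks[f"PPN_{other}"]],
                exclude_masks=list(nuclei_contra),
            )
        )
    order = {n: i for i, n in enumerate(BUNDLE_NAMES)}
    specs.sort(key=lambda s: order[s.name])
    return specs
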