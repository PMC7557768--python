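"""Track-density maps, group maximum-probability maps and overlap statistics.

Two map products are built from selected bundles:

* whole-tract maximum-probability maps (MPMs): per-subject track-density maps
  are registered to the template, binarized and summed, then thresholded to
  retain voxels covered in at least half of the sample;
* PPN connectivity clusters: the per-subject density map is first restricted
  to the pallidal ROI, thresholded at a fraction (default 25%) of its maximum
  density to suppress low-density voxels, registered to the template, and
  only then binarized/summed into a cluster MPM.

Topography is quantified as percentage overlap between a cluster MPM (A) and
a functional-territory MPM (B): ``100 * |A n B| / |B|`` in voxels, which is
deliberately normalized by the territory and hence asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .core import (
    AffineTransform,
    BinaryMask,
    ImageGrid,
    Tractogram,
    Volume,
    apply_transform,
    binarize,
)
from .selection import visited_voxels

__all__ = [
    "DensityMap",
    "MPM",
    "track_density_map",
    "mask_density",
    "threshold_relative",
    "maximum_probability_map",
    "percentage_overlap",
    "subject_connectivity_cluster",
    "tract_mpm_from_subject_densities",
]


@dataclass
class DensityMap:
    """Per-voxel count of distinct streamlines traversing each voxel."""

    volume: Volume
    bundle: str = ""
    subject: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.volume.values

    @property
    def grid(self) -> ImageGrid:
        return self.volume.grid


@dataclass
class MPM:
    """Voxelwise subject-coverage counts with a retention threshold."""

    volume: Volume
    n_subjects: int
    retention_fraction: float = 0.5

    @property
    def cut(self) -> int:
        return ceil(self.retention_fraction * self.n_subjects)

    @property
    def thresholded(self) -> BinaryMask:
        return BinaryMask(self.volume.grid, (self.volume.values >= self.cut).astype(np.uint8))


def track_density_map(tractogram: Tractogram, grid: ImageGrid) -> DensityMap:
    """Count, per voxel, the number of distinct streamlines visiting it.

    Each streamline contributes at most 1 to any voxel; the visited-voxel set
    is computed on the polyline densified at half-voxel spacing.
    """
    counts = np.zeros(grid.dims, dtype=np.int64)
    for s in tractogram.streamlines:
        idx = visited_voxels(s, grid)
        if len(idx):
            counts[idx[:, 0], idx[:, 1], idx[:, 2]] += 1
    return DensityMap(Volume(grid, counts), bundle=tractogram.name)


def mask_density(density: DensityMap, roi: BinaryMask) -> DensityMap:
    """Voxelwise product of a density map with a binary ROI."""
    if roi.grid != density.grid:
        raise ValueError("density map and ROI must share a grid")
    return DensityMap(
        Volume(density.grid, density.values * roi.values),
        bundle=density.bundle,
        subject=density.subject,
    )


def threshold_relative(density: DensityMap, fraction: float = 0.25) -> BinaryMask:
    """Retain voxels with density >= fraction x (map maximum).

    The referent is the per-map maximum density value; an all-zero map yields
    an all-zero mask.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    vmax = density.values.max(initial=0)
    if vmax <= 0:
        return BinaryMask(density.grid, np.zeros(density.grid.dims, dtype=np.uint8))
    return BinaryMask(
        density.grid, (density.values >= fraction * vmax).astype(np.uint8)
    )


def maximum_probability_map(
    masks: list[BinaryMask], retention_fraction: float = 0.5
) -> tuple[MPM, BinaryMask]:
    """Sum binary subject maps voxelwise; threshold at ceil(fraction x N).

    "At least half of the sample" resolves to count >= ceil(N/2), exact at
    both even and odd N.
    """
    if len(masks) < 2:
        raise ValueError("an MPM needs at least 2 subject masks")
    grid = masks[0].grid
    if any(m.grid != grid for m in masks[1:]):
        raise ValueError("all masks must share one grid")
    if not 0 < retention_fraction <= 1:
        raise ValueError("retention_fraction must be in (0, 1]")
    counts = np.zeros(grid.dims, dtype=np.int64)
    for m in masks:
        counts += m.values
    mpm = MPM(Volume(grid, counts), n_subjects=len(masks), retention_fraction=retention_fraction)
    return mpm, mpm.thresholded


def percentage_overlap(a: BinaryMask, b: BinaryMask) -> float:
    """Percentage of B's voxels also covered by A: 100 x |A n B| / |B|."""
    if a.grid != b.grid:
        raise ValueError("masks must share a grid")
    nb = b.count()
    if nb == 0:
        raise ValueError("percentage overlap is undefined for an empty reference mask")
    inter = int(np.sum(a.values & b.values))
    return 100.0 * inter / nb


def subject_connectivity_cluster(
    bundle: Tractogram,
    pallidal_roi: BinaryMask,
    subject_to_template: AffineTransform,
    template_grid: ImageGrid,
    fraction: float = 0.25,
) -> BinaryMask:
    """Per-subject PPN connectivity cluster on the template grid.

    Step order: track-density map in subject space -> restrict to the pallidal
    ROI -> relative threshold (default 25% of the map maximum) -> register the
    thresholded mask to the template by nearest neighbour.
    """
    density = track_density_map(bundle, pallidal_roi.grid)
    masked = mask_density(density, pallidal_roi)
    thresholded = threshold_relative(masked, fraction)
    return apply_transform(thresholded, subject_to_template, template_grid)


def tract_mpm_from_subject_densities(
    densities: list[DensityMap],
    transforms: list[AffineTransform],
    template_grid: ImageGrid,
    retention_fraction: float = 0.5,
) -> tuple[MPM, BinaryMask]:
    """Whole-tract MPM: register each subject density map to the template,
    binarize (> 0), then sum and threshold."""
    if len(densities) != len(transforms):
        raise ValueError("need one transform per density map")
    masks = []
    for d, t in zip(densities, transforms):
        reg = apply_transform(d.volume, t, template_grid)
        masks.append(binarize(reg))
    return maximum_probability_map(masks, retention_fraction)
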