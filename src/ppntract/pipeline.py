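"""End-to-end phantom pipeline: simulate -> track -> select -> map -> test.

Mirrors the study design: per subject, probabilistic tractography is seeded
in each pallidal segment, the six pallidotegmental bundles are isolated by
seed/include/exclude selection, per-bundle streamline counts (NOS) are
recorded, track-density maps and PPN connectivity clusters are registered to
the template and aggregated into maximum-probability maps, cluster/territory
percentage overlaps are tabulated, and the seven paired Wilcoxon comparisons
are run on the NOS table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import apply_transform
from .density import (
    maximum_probability_map,
    percentage_overlap,
    subject_connectivity_cluster,
    track_density_map,
    tract_mpm_from_subject_densities,
)
from .phantom import TERRITORIES, PhantomConfig, generate_subject
from .selection import BUNDLE_NAMES, build_pallidotegmental_specs, select_bundle
from .stats import run_nos_comparisons, summarize_nos
from .tracker import TrackingParams, track_from_seed_mask
from .tract_io import RunConfig

log = logging.getLogger("ppntract")

__all__ = ["PipelineResult", "phantom_config_from_run", "run_pipeline", "write_outputs"]

SEED_ROIS = ("GPi_L", "GPi_R", "GPe_L", "GPe_R")


@dataclass
class PipelineResult:
    config: RunConfig
    nos_table: pd.DataFrame  # subject_id, bundle, nos, rejected_include, rejected_exclude
    nos_summary: pd.DataFrame
    tests: pd.DataFrame
    overlaps: pd.DataFrame  # bundle, hemisphere, territory, percent_overlap
    tract_mpms: dict = field(default_factory=dict)
    cluster_mpms: dict = field(default_factory=dict)
    territory_mpms: dict = field(default_factory=dict)


def phantom_config_from_run(config: RunConfig) -> PhantomConfig:
    return PhantomConfig(
        gpi_over_gpe_ratio=config.gpi_over_gpe_ratio,
        right_over_left_ratio=config.right_over_left_ratio,
        max_translation_mm=config.max_translation_mm,
        max_rotation_deg=config.max_rotation_deg,
        master_seed=config.master_seed,
    )


def _seed_roi_of(bundle_name: str) -> str:
    side, segment, _ = bundle_name.split("_")
    return f"{segment}_{side}"


def run_pipeline(
    config: RunConfig, phantom_config: PhantomConfig | None = None
) -> PipelineResult:
    pcfg = phantom_config or phantom_config_from_run(config)
    params = TrackingParams(seeds_per_voxel=config.seeds_per_voxel)
    template_grid = pcfg.grid

    nos_rows = []
    cluster_masks: dict[str, list] = {b: [] for b in BUNDLE_NAMES}
    densities: dict[str, list] = {b: [] for b in BUNDLE_NAMES}
    transforms: dict[str, list] = {b: [] for b in BUNDLE_NAMES}
    territory_subject_masks: dict[str, list] = {}

    for sid in range(config.n_subjects):
        subject = generate_subject(pcfg, sid, config.master_seed)
        tracked = {}
        for roi in SEED_ROIS:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, sid, 7, SEED_ROIS.index(roi)])
            )
            tracked[roi] = track_from_seed_mask(
                subject.masks[roi], subject.field, params, rng, name=f"s{sid}_{roi}"
            )
            log.info("subject %d: tracked %d streamlines from %s", sid, len(tracked[roi]), roi)
        specs = build_pallidotegmental_specs(subject.masks)
        for spec in specs:
            result = select_bundle(tracked[_seed_roi_of(spec.name)], spec)
            log.info(
                "subject %d: %s kept %d / %d (exclude %d, include %d)",
                sid, spec.name, result.nos, result.n_input,
                result.rejected_exclude, result.rejected_include,
            )
            nos_rows.append(
                {
                    "subject_id": sid,
                    "bundle": spec.name,
                    "nos": result.nos,
                    "rejected_include": result.rejected_include,
                    "rejected_exclude": result.rejected_exclude,
                }
            )
            roi_mask = subject.masks[_seed_roi_of(spec.name)]
            cluster_masks[spec.name].append(
                subject_connectivity_cluster(
                    result.tractogram, roi_mask, subject.to_template,
                    template_grid, config.density_fraction,
                )
            )
            densities[spec.name].append(
                track_density_map(result.tractogram, subject.grid)
            )
            transforms[spec.name].append(subject.to_template)
        for key, mask in subject.territory_masks.items():
            territory_subject_masks.setdefault(key, []).append(
                apply_transform(mask, subject.to_template, template_grid)
            )

    nos_table = pd.DataFrame(nos_rows)
    nos_summary = summarize_nos(nos_table)
    results = run_nos_comparisons(nos_table, alpha=config.alpha)
    tests = pd.DataFrame(
        [
            {
                "comparison": r.name,
                "n_total": r.n_total,
                "n_effective": r.n_effective,
                "W": r.statistic,
                "p_two_sided": r.p_two_sided,
                "method": r.method,
                "significant": r.significant,
            }
            for r in results
        ]
    )

    tract_mpms, cluster_mpms, territory_mpms = {}, {}, {}
    for b in BUNDLE_NAMES:
        tract_mpms[b] = tract_mpm_from_subject_densities(
            densities[b], transforms[b], template_grid, config.mpm_fraction
        )
        cluster_mpms[b] = maximum_probability_map(cluster_masks[b], config.mpm_fraction)
    for key, masks in territory_subject_masks.items():
        territory_mpms[key] = maximum_probability_map(masks, config.mpm_fraction)

    overlap_rows = []
    for b in BUNDLE_NAMES:
        side, segment, _ = b.split("_")
        a_mask = cluster_mpms[b][1]
        for terr in TERRITORIES:
            b_mask = territory_mpms[f"{segment}_{side}_{terr}"][1]
            overlap_rows.append(
                {
                    "bundle": b,
                    "hemisphere": side,
                    "territory": terr,
                    "percent_overlap": percentage_overlap(a_mask, b_mask),
                }
            )
    overlaps = pd.DataFrame(overlap_rows)

    return PipelineResult(
        config=config,
        nos_table=nos_table,
        nos_summary=nos_summary,
        tests=tests,
        overlaps=overlaps,
        tract_mpms=tract_mpms,
        cluster_mpms=cluster_mpms,
        territory_mpms=territory_mpms,
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the CSV tables and NIfTI group maps for a pipeline run."""
    from pathlib import Path

    from .tract_io import write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.nos_table.to_csv(out / "nos.csv", index=False)
    result.nos_summary.to_csv(out / "nos_summary.csv", index=False)
    result.tests.to_csv(out / "tests.csv", index=False)
    result.overlaps.to_csv(out / "overlap.csv", index=False)
    for b, (mpm, mask) in result.tract_mpms.items():
        write_volume(mpm.volume, out / f"tract_mpm_{b}.nii.gz")
        write_mask(mask, out / f"tract_mpm_{b}_thresholded.nii.gz")
    for b, (mpm, mask) in result.cluster_mpms.items():
        write_volume(mpm.volume, out / f"cluster_mpm_{b}.nii.gz")
        write_mask(mask, out / f"cluster_mpm_{b}_thresholded.nii.gz")
    log.info("wrote pipeline outputs to %s", out)
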