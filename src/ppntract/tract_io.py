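"""Tractogram (TCK), volume (NIfTI-1) and run-configuration I/O.

TCK is the native tractogram format (MRtrix dialect: float32 triples,
streamlines delimited by NaN triples, EOF marked by an Inf triple); NIfTI-1
carries volumes and masks.  Serialization is delegated to nibabel; writers
are deterministic (no timestamps), so identical inputs produce byte-identical
files.  The run configuration is a flat YAML key/value file whose keys mirror
the pipeline parameter names.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.tck import TckFile

from .core import BinaryMask, ImageGrid, Tractogram, Volume

__all__ = [
    "TckFormatError",
    "ConfigError",
    "RunConfig",
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_config",
    "save_config",
]

log = logging.getLogger("ppntract")


class TckFormatError(ValueError):
    """Raised when a TCK file violates the format (names the bad field)."""


class ConfigError(ValueError):
    """Raised when a run configuration value is out of range (names the key)."""


# ---------------------------------------------------------------- tractograms

def write_tractogram(
    tractogram: Tractogram, path, step_size_mm: float | None = None
) -> None:
    """Write a tractogram as TCK; header records streamline count and, when
    given, the tracking step size."""
    path = Path(path)
    header = {}
    if step_size_mm is not None:
        header["step_size"] = repr(float(step_size_mm))
    streamlines = [s.astype(np.float32) for s in tractogram.streamlines]
    nib_t = NibTractogram(streamlines, affine_to_rasmm=np.eye(4))
    TckFile(nib_t, header=header).save(str(path))
    log.info("wrote %d streamlines to %s", len(tractogram), path)


def read_tractogram(path, reference_grid: ImageGrid, name: str | None = None) -> Tractogram:
    """Read a TCK tractogram (world-mm coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.readline().rstrip(b"\n")
    if magic != b"mrtrix tracks":
        raise TckFormatError(
            f"{path}: bad magic_number {magic!r}, expected b'mrtrix tracks'"
        )
    try:
        loaded = nib.streamlines.load(str(path))
    except Exception as exc:  # surface the offending header field when known
        raise TckFormatError(f"{path}: malformed TCK header ({exc})") from exc
    streamlines = [np.asarray(s, dtype=float) for s in loaded.streamlines]
    return Tractogram(streamlines, reference_grid, name or path.stem)


# -------------------------------------------------------------------- volumes

def write_volume(volume: Volume, path) -> None:
    data = volume.values
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, volume.grid.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = ImageGrid(tuple(int(d) for d in data.shape), img.affine)
    return Volume(grid, np.asarray(data))


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(Volume(mask.grid, mask.values.astype(np.int32)), path)


def read_mask(path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(v.grid, v.values.astype(np.uint8))


# --------------------------------------------------------------- run configs

@dataclass
class RunConfig:
    """Pipeline-wide parameters and thresholds.

    density_fraction is the relative track-density threshold (fraction of the
    per-map maximum), mpm_fraction the group retention fraction ("at least
    half of the sample" at the default 0.5), alpha the two-sided significance
    level.
    """

    n_subjects: int = 20
    seeds_per_voxel: int = 10
    density_fraction: float = 0.25
    mpm_fraction: float = 0.5
    alpha: float = 0.05
    master_seed: int = 0
    gpi_over_gpe_ratio: float = 2.0
    right_over_left_ratio: float = 1.25
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 3.0
    out_dir: str = "ppntract_out"

    def __post_init__(self) -> None:
        if not 0 < self.density_fraction < 1:
            raise ConfigError(
                f"density_fraction must be in (0, 1), got {self.density_fraction}"
            )
        if not 0 < self.mpm_fraction <= 1:
            raise ConfigError(f"mpm_fraction must be in (0, 1], got {self.mpm_fraction}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.seeds_per_voxel < 1:
            raise ConfigError(f"seeds_per_voxel must be >= 1, got {self.seeds_per_voxel}")


def load_config(path) -> RunConfig:
    """Load a flat YAML config; absent keys take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


# ----------------------------------------------------- phantom subject files

def write_orientation_field(field_obj, path, iso_path) -> None:
    """Store an orientation field as a 4-D volume of per-lobe quadruples
    (dx, dy, dz, amplitude) plus a companion isotropic-flag volume."""
    X, Y, Z, K, _ = field_obj.dirs.shape
    quad = np.zeros((X, Y, Z, K * 4), dtype=np.float32)
    for k in range(K):
        quad[..., 4 * k : 4 * k + 3] = field_obj.dirs[..., k, :]
        quad[..., 4 * k + 3] = field_obj.amps[..., k]
    img = nib.Nifti1Image(quad, field_obj.grid.affine)
    nib.save(img, str(path))
    iso = nib.Nifti1Image(field_obj.isotropic.astype(np.int32), field_obj.grid.affine)
    nib.save(iso, str(iso_path))


def read_orientation_field(path, iso_path):
    from .tracker import OrientationField

    img = nib.load(str(path))
    quad = np.asanyarray(img.dataobj)
    X, Y, Z, K4 = quad.shape
    K = K4 // 4
    grid = ImageGrid((X, Y, Z), img.affine)
    dirs = np.zeros((X, Y, Z, K, 3))
    amps = np.zeros((X, Y, Z, K))
    for k in range(K):
        dirs[..., k, :] = quad[..., 4 * k : 4 * k + 3]
        amps[..., k] = quad[..., 4 * k + 3]
    iso = np.asanyarray(nib.load(str(iso_path)).dataobj).astype(bool)
    # renormalize against float32 storage round-off
    norms = np.linalg.norm(dirs, axis=-1, keepdims=True)
    np.divide(dirs, norms, out=dirs, where=norms > 0)
    return OrientationField(grid, dirs, amps, iso)


def write_transform(transform, path) -> None:
    np.savetxt(str(path), transform.matrix, fmt="%.17g")


def read_transform(path):
    from .core import AffineTransform

    return AffineTransform(np.loadtxt(str(path)))


def write_subject(subject, directory) -> None:
    """Write one synthetic subject: NIfTI ROI/territory masks, the 4-D
    orientation field, ground-truth TCK bundles, the subject->template
    transform and a CSV manifest of true counts."""
    d = Path(directory)
    (d / "masks").mkdir(parents=True, exist_ok=True)
    (d / "territories").mkdir(exist_ok=True)
    (d / "truth").mkdir(exist_ok=True)
    for name, mask in subject.masks.items():
        write_mask(mask, d / "masks" / f"{name}.nii.gz")
    for name, mask in subject.territory_masks.items():
        write_mask(mask, d / "territories" / f"{name}.nii.gz")
    write_orientation_field(subject.field, d / "field.nii.gz", d / "field_iso.nii.gz")
    for name, t in subject.tractograms.items():
        write_tractogram(t, d / "truth" / f"{name}.tck")
    write_transform(subject.to_template, d / "transform.txt")
    rows = [{"bundle": k, "true_count": v} for k, v in sorted(subject.true_counts.items())]
    import pandas as pd

    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)


def read_subject(directory, subject_id: int = -1):
    """Reload a subject directory written by :func:`write_subject`."""
    from .phantom import SyntheticSubject

    import pandas as pd

    d = Path(directory)
    masks = {
        p.name.removesuffix(".nii.gz"): read_mask(p)
        for p in sorted((d / "masks").glob("*.nii.gz"))
    }
    territory_masks = {
        p.name.removesuffix(".nii.gz"): read_mask(p)
        for p in sorted((d / "territories").glob("*.nii.gz"))
    }
    field_obj = read_orientation_field(d / "field.nii.gz", d / "field_iso.nii.gz")
    grid = field_obj.grid
    tractograms = {
        p.name.removesuffix(".tck"): read_tractogram(p, grid)
        for p in sorted((d / "truth").glob("*.tck"))
    }
    manifest = pd.read_csv(d / "manifest.csv")
    counts = dict(zip(manifest["bundle"], manifest["true_count"].astype(int)))
    return SyntheticSubject(
        subject_id=subject_id,
        grid=grid,
        masks=masks,
        territory_masks=territory_masks,
        field=field_obj,
        tractograms=tractograms,
        true_counts=counts,
        to_template=read_transform(d / "transform.txt"),
    )
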