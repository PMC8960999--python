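"""NIfTI-1 volume I/O and structured run configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import Phantom, PhantomConfig
from .tracking import TrackingParams


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI-1 scalar volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    affine = img.affine
    if affine is None:
        raise ValueError(f"{path}: missing affine")
    return np.asarray(data), np.asarray(affine, dtype=float)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3-D scalar volume as NIfTI-1 (.nii or .nii.gz)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = data.astype(np.uint8) if data.dtype == bool else data
    nib.save(nib.Nifti1Image(out, np.asarray(affine, dtype=float)), str(path))
    return path


def write_phantom(phantom: Phantom, outdir: str | Path) -> Path:
    """Write one subject's volumes (.nii.gz) and a JSON truth manifest."""
    outdir = Path(outdir) / phantom.subject_id
    outdir.mkdir(parents=True, exist_ok=True)
    aff = phantom.grid.affine
    for name, mask in phantom.masks.named().items():
        write_volume(mask, aff, outdir / f"{name}.nii.gz")
    write_volume(phantom.jacobian, aff, outdir / "jacobian.nii.gz")
    truth = phantom.truth
    manifest = {
        "subject_id": phantom.subject_id,
        "true_vim_centroid_L": truth.true_vim_centroid_L.tolist(),
        "true_vim_centroid_R": truth.true_vim_centroid_R.tolist(),
        "scp_width_mm": truth.scp_width_mm,
        "jitter_applied": {k: v.tolist() for k, v in truth.jitter_applied.items()},
        "confounds": truth.confounds,
        "landmarks": {"ac": phantom.landmarks.ac.tolist(),
                      "pc": phantom.landmarks.pc.tolist()},
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.  Lengths in mm, seeds explicit."""

    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)
    n_subjects: int = 5
    seed: int = 0
    localisation_fraction: float = 0.2
    atlas_ml_offset_mm: float = 12.5
    output_dir: str = "cdvim_run"
    write_volumes: bool = True


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "phantom" in kwargs:
        kwargs["phantom"] = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in kwargs["phantom"].items()
        })
    if "tracking" in kwargs:
        kwargs["tracking"] = TrackingParams(**kwargs["tracking"])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    Path(path).write_text(yaml.safe_dump(plain(config), sort_keys=True))
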