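"""NIfTI-1 round trips, checkpoints, and run manifests."""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .model_zoo import ModelConfig, SegmentationModel, build_model
from .types import BrainMask, TissueProbMap, Volume3D

__all__ = [
    "read_volume", "write_volume",
    "read_probmap", "write_probmap",
    "read_mask", "write_mask",
    "save_checkpoint", "load_checkpoint",
    "write_manifest",
]

PathLike = Union[str, Path]
CHANNEL_DESC = "channels=GM,WM,CSF"


def _affine_or_eye(affine, spacing) -> np.ndarray:
    if affine is not None:
        return np.asarray(affine, dtype=np.float64)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: Volume3D, path: PathLike) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.values, dtype=np.float32),
        _affine_or_eye(volume.affine, volume.spacing),
    )
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: PathLike) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; a 3D scalar volume is required")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, np.float32), spacing=spacing,
                    affine=np.asarray(img.affine))


def write_probmap(probmap: TissueProbMap, path: PathLike) -> None:
    # channel axis goes last (the NIfTI 4th dimension)
    data = np.moveaxis(np.asarray(probmap.values, np.float32), 0, -1)
    img = nib.Nifti1Image(data, _affine_or_eye(probmap.affine, probmap.spacing))
    img.header["descrip"] = CHANNEL_DESC.encode()
    nib.save(img, str(path))


def read_probmap(path: PathLike) -> TissueProbMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}D; a 4D probability map is required")
    if data.shape[-1] != 3:
        raise ValueError(f"{path} has {data.shape[-1]} channels; expected 3 (GM, WM, CSF)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueProbMap(np.moveaxis(np.asarray(data, np.float32), -1, 0),
                         spacing=spacing, affine=np.asarray(img.affine))


def write_mask(mask: BrainMask, path: PathLike) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), np.eye(4))
    nib.save(img, str(path))


def read_mask(path: PathLike) -> BrainMask:
    img = nib.load(str(Path(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("a brain mask must be 3D")
    return BrainMask(data > 0)


def save_checkpoint(model: SegmentationModel, path: PathLike) -> None:
    """Weights plus the embedded model configuration, as one .npz file."""
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __config__=np.frombuffer(
        model.cfg.to_json().encode(), dtype=np.uint8), **state)


def load_checkpoint(path: PathLike) -> SegmentationModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(str(path)) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
        state = {k[len("param:"):]: data[k] for k in data.files if k.startswith("param:")}
    model = build_model(cfg)
    model.load_state_dict(state)
    model.eval()
    return model


def write_manifest(path: PathLike, stage: str, seed: int, config: object) -> None:
    from . import __version__

    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
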