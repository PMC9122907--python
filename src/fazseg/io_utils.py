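"""Image and checkpoint I/O.

Images are 8-bit PNG/TIFF scaled to [0, 1] on read; masks round-trip
exactly as 0/255 PNG.  A checkpoint is a single ``.npz`` weight file
with a JSON sidecar holding the architecture config, so checkpoints are
self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .models import ArchitectureConfig, SegmentationModel, build_model

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "save_checkpoint", "load_checkpoint", "load_config"]


def load_config(path) -> ArchitectureConfig:
    """Read an architecture config from a JSON or YAML file.

    Keys mirror the ``ArchitectureConfig`` field names.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return ArchitectureConfig.from_dict(data)

_SUPPORTED = {".png", ".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF; intensities scaled to [0, 1] float32."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValueError(f"unsupported image format: {path}")
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as e:
        raise ValueError(f"cannot read image {path}: {e}") from e
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: only 8-bit images are supported, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 4:      # drop alpha
        arr = arr[:, :, :3]
    return (arr.astype(np.float32) / 255.0)


def write_image(img, path):
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    path = Path(path)
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask PNG as a 0/1 uint8 array."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr >= 0.5).astype(np.uint8)


def write_mask(mask, path):
    """Write a binary mask as 0/255 8-bit PNG (exact round-trip)."""
    path = Path(path)
    m = np.asarray(mask)
    iio.imwrite(path, ((m > 0).astype(np.uint8) * 255))


def save_checkpoint(model: SegmentationModel, path):
    """Weights to ``<path>`` (npz) + config sidecar ``<path>.json``."""
    path = Path(path)
    state = model.state_dict()
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(model.config.to_json())


def load_checkpoint(path, input_size=None) -> SegmentationModel:
    """Rebuild a model from a checkpoint written by ``save_checkpoint``."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar}")
    config = ArchitectureConfig.from_json(sidecar.read_text())
    model = build_model(config, seed=0, input_size=input_size)
    with np.load(path) as data:
        state = model.state_dict()
        if set(data.files) != set(state):
            raise ValueError(f"checkpoint {path} does not match the config")
        for key, target in state.items():
            target[...] = data[key]
    return model
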