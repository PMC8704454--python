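"""Image/mask readers and writers and run-configuration handling.

Images are 8- or 16-bit grayscale PNG/TIFF, rescaled to [0, 1] on read; the
original bit depth is recorded so writes quantize symmetrically.  Masks mark
corrupted pixels with any nonzero value.  A run's configuration snapshot is
written next to its outputs so every run is reproducible from the snapshot
alone.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .pipeline import CompletionConfig, CompletionResult

__all__ = ["read_image", "read_mask", "write_image", "write_result",
           "load_config", "dump_config"]

_DEPTHS = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a square grayscale image; returns (values in [0,1], bit depth).

    RGB(A) input is converted to luminance with a warning; float input is
    assumed to already be in [0, 1].
    """
    raw = iio.imread(path)
    if raw.ndim == 3:
        warnings.warn(f"{path}: color input converted to luminance", stacklevel=2)
        rgb = raw[..., :3].astype(float)
        raw = (0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1]
               + 0.0722 * rgb[..., 2]).astype(raw.dtype)
    if raw.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image")
    if raw.shape[0] != raw.shape[1]:
        raise ValueError(
            f"{path}: non-square image {raw.shape} not supported "
            "(the cortical grid is N x N)")
    bits = _DEPTHS.get(raw.dtype)
    if bits is None:
        img = np.asarray(raw, dtype=float)
        if img.max() > 1.0 or img.min() < 0.0:
            raise ValueError(f"{path}: float image values must lie in [0, 1]")
        return img, 8
    return raw.astype(float) / (2**bits - 1), bits


def read_mask(path: str | Path, expected_shape=None) -> np.ndarray:
    """Read an occlusion mask: any nonzero pixel means corrupted."""
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[..., :3].max(axis=-1)
    mask = np.asarray(raw) != 0
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match image shape "
            f"{tuple(expected_shape)}")
    return mask


def write_image(image: np.ndarray, path: str | Path, bits: int = 8) -> None:
    """Clip to [0, 1], quantize to the stored bit depth, and write."""
    if bits not in (8, 16):
        raise ValueError("bit depth must be 8 or 16")
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    scale = 2**bits - 1
    quant = np.round(img * scale).astype(np.uint8 if bits == 8 else np.uint16)
    iio.imwrite(Path(path), quant)


def dump_config(config: CompletionConfig, path: str | Path) -> None:
    data = {k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool)
                else v)
            for k, v in dataclasses.asdict(config).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path: str | Path) -> CompletionConfig:
    """Load a completion configuration from a YAML snapshot."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(CompletionConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("n_orientations", "n_frequencies", "n_phases"):
        if key in data and data[key] is not None:
            data[key] = int(data[key])
    if data.get("half_width") is not None:
        data["half_width"] = int(data["half_width"])
    if data.get("spline_order") is not None:
        data["spline_order"] = int(data["spline_order"])
    return CompletionConfig(**data)


def write_result(result: CompletionResult, out_dir: str | Path,
                 bits: int = 8, log_text: str = "") -> Path:
    """Write completed image + config snapshot (+ optional log) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(result.image, out / "completed.png", bits=bits)
    dump_config(result.config, out / "config.yaml")
    lines = [f"mode: {result.mode}", f"iterations: {result.iterations}"]
    if result.masked_rmse is not None:
        lines.append(f"masked_rmse: {result.masked_rmse:.6f}")
    if log_text:
        lines.append(log_text)
    (out / "run.log").write_text("\n".join(lines) + "\n")
    return out
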