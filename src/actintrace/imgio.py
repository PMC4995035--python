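"""Image reading/writing and flat key-value configuration files."""

from __future__ import annotations

import ast
from pathlib import Path

import numpy as np

__all__ = ["FormatError", "read_image", "write_image", "read_config", "write_config"]


class FormatError(Exception):
    """Unreadable or unsupported image file."""


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Load a TIFF/PNG micrograph as a float image in [0, 1].

    Integer images are scaled by their dtype range.  RGB images are
    converted by luminance unless ``channel`` selects a single stained
    channel (e.g. the red actin channel of a composite).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] in (3, 4) and arr.shape[0] < arr.shape[-1]:
        arr = np.moveaxis(arr, 0, -1)
    # scale to [0, 1] before any channel mixing
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(float) / info.max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if channel is not None:
            arr = arr[..., channel]
        else:
            arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {arr.shape} in {path}")
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a float image: TIFF as float32, PNG as 16-bit grayscale."""
    path = Path(path)
    img = np.asarray(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img.astype(np.float32))
    else:
        import imageio.v3 as iio

        if img.ndim == 2:
            scaled = np.clip(img, 0.0, 1.0)
            iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))
        else:
            iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def write_config(path: str | Path, values: dict) -> None:
    """Write a flat ``key = value`` configuration file."""
    lines = [f"{k} = {v!r}" for k, v in sorted(values.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` configuration file."""
    values: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"malformed config line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        try:
            values[key] = ast.literal_eval(val)
        except (ValueError, SyntaxError):
            values[key] = val
    return values
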