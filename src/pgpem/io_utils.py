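"""Image and manifest I/O for the command-line tools.

Images travel as single-channel TIFF (32-bit float for intensities, 8-bit
0/255 for masks) or single-channel PNG; every CLI command drops a JSON run
manifest recording the resolved configuration, seed, input digests and
output files, so deterministic runs are reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from . import __version__
from .simulate import RawImage

__all__ = ["read_image", "write_image", "write_mask", "read_mask", "RunManifest"]

log = logging.getLogger("pgpem")


def read_image(path: str | Path, pixel_pitch: float = 50.0) -> RawImage:
    """Read a single-channel TIFF/PNG as a float image.

    Integer inputs are promoted to float (with a logged note); multi-channel
    images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ValueError(
            f"multi-channel image with {arr.shape[-1]} channels; a single-channel "
            "grayscale image is required"
        )
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        log.info("promoting %s-bit integer image %s to float", arr.dtype.itemsize * 8, path.name)
    return RawImage(pixels=arr.astype(np.float64), pixel_pitch=pixel_pitch)


def write_image(image: RawImage | np.ndarray, path: str | Path) -> Path:
    """Write intensities as 32-bit float single-channel TIFF."""
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, pixels.astype(np.float32))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as 8-bit TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path).pixels > 0


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written next to every command's outputs."""

    command: str
    resolved_config: dict
    seed: int = 0
    input_hashes: dict = field(default_factory=dict)
    output_files: list = field(default_factory=list)
    tool_version: str = __version__

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_hashes[p.name] = _digest(p)

    def add_output(self, path: str | Path) -> None:
        self.output_files.append(str(path))

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "manifest.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command,
            "resolved_config": self.resolved_config,
            "seed": self.seed,
            "input_hashes": self.input_hashes,
            "output_files": self.output_files,
            "tool_version": self.tool_version,
        }
        out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        return out
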