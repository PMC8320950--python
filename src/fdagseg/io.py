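"""Reading and writing images, edge maps and label maps.

Input rasters (PNG/TIFF/PGM, 8- or 16-bit) are rescaled to [0, 1] floats
on read.  Edge-strength maps are written both as 16-bit PNG (scaled to
the full range) and as float TIFF; label maps as 16-bit PNG and CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_image",
    "write_edge_map_png",
    "write_float_tiff",
    "write_label_map",
    "read_label_map",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image and rescale intensities to [0, 1] floats.

    Integer images are divided by their dtype maximum; float images are
    assumed to already be in [0, 1].  Alpha channels are dropped; single
    and three-channel images are supported.
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def write_edge_map_png(path: str | Path, edge_map: np.ndarray) -> None:
    """Write an edge-strength map in [0, 1] as a 16-bit PNG."""
    scaled = np.clip(np.asarray(edge_map, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))


def write_float_tiff(path: str | Path, array: np.ndarray) -> None:
    """Write a map as a 32-bit float TIFF (lossless inspection format)."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label map as 16-bit PNG (.png) or CSV (.csv)."""
    labels = np.asarray(labels)
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, labels, fmt="%d", delimiter=",")
    else:
        if labels.max() > 65535:
            raise ValueError("too many labels for a 16-bit PNG")
        iio.imwrite(path, labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read an integer label map from 16-bit PNG or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, dtype=np.int64, delimiter=",")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int64)
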