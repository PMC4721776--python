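"""Reading and writing 8-bit grayscale images and binary masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Read an image as an 8-bit grayscale array.

    Color inputs are converted by luminance (ITU-R 601, Pillow "L" mode).
    """
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_gray(path: str | Path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as a {0,255} grayscale PNG."""
    write_gray(path, np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return (read_gray(path) > 127).astype(np.uint8)
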