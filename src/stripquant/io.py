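"""Reading and writing strip images (8-bit PNG/TIFF via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError
from .quant import StripImage


def read_image(path: str | Path, px_per_mm: float = 20.0) -> StripImage:
    """Load an 8-bit grayscale or RGB strip photograph.

    Paletted or alpha images are converted to RGB; 16-bit inputs are
    rejected (the pipeline is defined on the 0-255 scale).
    """
    with Image.open(path) as im:
        if im.mode in ("L", "RGB"):
            pass
        elif im.mode in ("P", "RGBA", "LA"):
            im = im.convert("RGB")
        else:
            raise InputError(f"unsupported image mode {im.mode!r} in {path}")
        pixels = np.asarray(im, dtype=np.uint8)
    return StripImage(pixels, px_per_mm=px_per_mm)


def write_image(image: StripImage, path: str | Path) -> None:
    """Write a StripImage as an 8-bit PNG or TIFF (by extension)."""
    px = image.pixels
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    Image.fromarray(px).save(path)
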