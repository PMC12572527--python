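"""Display mapping and classifier preprocessing for DRRs.

``intensity_to_display`` converts physical projector output to a [0, 1]
presentation image in radiograph polarity (denser anatomy renders brighter).
``resize_bicubic`` pads to square and resamples to the classifier input size
(default 224×224) with bicubic interpolation.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image

from .core import DataError, DomainError, DRRImage

__all__ = ["intensity_to_display", "resize_bicubic", "pad_to_square"]


def intensity_to_display(
    image: DRRImage,
    mode: str = "neg_log",
    window: Optional[Tuple[float, float]] = None,
    invert: bool = False,
) -> DRRImage:
    """Map a projector output to the display domain ([0, 1]).

    ``neg_log`` maps intensity ``I`` to the attenuation scale ``−ln(I/i0)``
    (line-integral inputs are already on that scale and pass through), then
    min–max normalizes, so denser tissue is brighter — the radiograph
    convention.  ``linear`` skips the log.  An optional ``(center, width)``
    window clips the pre-normalization values.  A constant image maps to all
    zeros.  ``invert`` flips polarity after normalization.
    """
    if image.domain not in ("intensity", "line_integral"):
        raise DomainError(f"cannot display-map a {image.domain!r} image")
    if mode not in ("neg_log", "linear"):
        raise DataError(f"unknown display mode {mode!r}")
    data = np.asarray(image.data, dtype=float)

    if mode == "neg_log" and image.domain == "intensity":
        floor = image.i0 * 1e-12
        data = -np.log(np.maximum(data, floor) / image.i0)
    elif mode == "linear" and image.domain == "intensity":
        # attenuation-monotone linear scale
        data = image.i0 - data

    if window is not None:
        center, width = window
        if width <= 0:
            raise DataError("window width must be positive")
        lo, hi = center - width / 2.0, center + width / 2.0
        data = np.clip(data, lo, hi)

    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        data = (data - lo) / (hi - lo)
    else:
        data = np.zeros_like(data)
    if invert:
        data = 1.0 - data
    return image.with_data(data, domain="display")


def pad_to_square(data: np.ndarray, fill: Optional[float] = None) -> np.ndarray:
    """Pad a 2D array symmetrically to square with ``fill`` (default: its min)."""
    h, w = data.shape
    if h == w:
        return data
    if fill is None:
        fill = float(data.min())
    side = max(h, w)
    out = np.full((side, side), fill, dtype=float)
    top = (side - h) // 2
    left = (side - w) // 2
    out[top : top + h, left : left + w] = data
    return out


def _resize_array(data: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(np.ascontiguousarray(data, dtype=np.float32), mode="F")
    resized = img.resize((size, size), Image.Resampling.BICUBIC)
    return np.asarray(resized, dtype=float)


def resize_bicubic(
    image: Union[DRRImage, np.ndarray], size: int = 224
) -> Union[DRRImage, np.ndarray]:
    """Bicubic resample of a display-domain image to ``size × size``.

    Non-square inputs are first padded symmetrically with the image minimum,
    preserving anatomical proportions.  The output is clipped to [0, 1].
    Accepts a :class:`DRRImage` (display domain enforced) or a bare array.
    """
    if size < 8:
        raise DataError("resize target must be at least 8 pixels")
    if isinstance(image, DRRImage):
        if image.domain != "display":
            raise DomainError("resize_bicubic expects a display-domain image")
        data = np.asarray(image.data, dtype=float)
    else:
        data = np.asarray(image, dtype=float)
    if data.ndim != 2:
        raise DataError("resize_bicubic expects a 2D image")

    padded = pad_to_square(data)
    out = np.clip(_resize_array(padded, size), 0.0, 1.0)

    if isinstance(image, DRRImage):
        side = max(data.shape)
        scale = side / size
        dv, du = image.pixel_spacing
        return DRRImage(
            data=out,
            pixel_spacing=(dv * scale, du * scale),
            domain="display",
            technique=image.technique,
            i0=image.i0,
        )
    return out
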