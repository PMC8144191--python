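"""Shared thresholding helper for the segmentation stages."""

from __future__ import annotations

import numpy as np
from skimage import filters


def threshold_image(image: np.ndarray, method: str | float = "otsu") -> float | None:
    """Return a global threshold, or ``None`` for a constant image.

    ``method`` is "otsu", "isodata", a number, or "fixed:<value>".
    Automatic methods on a constant image yield no foreground; callers
    treat ``None`` as an empty segmentation rather than an error.
    """
    image = np.asarray(image)
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if isinstance(method, str) and method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    if image.size == 0 or np.ptp(image) == 0:
        return None
    if method == "otsu":
        return float(filters.threshold_otsu(image))
    if method == "isodata":
        return float(filters.threshold_isodata(image))
    raise ValueError(f"unknown threshold method {method!r}")
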