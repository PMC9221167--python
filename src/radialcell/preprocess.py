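"""Morphology-channel denoising and contrast enhancement.

Classical filters (median / Gaussian) stand in for learned denoising; the
downstream contract only needs segmentable cell/nucleus contrast.  CLAHE
(contrast-limited adaptive histogram equalization) boosts local contrast
tile-wise before thresholding.

The drug channel is never contrast-enhanced before quantification: the
intensity statistics assume a linear scale, which histogram equalization
destroys.  CLAHE exists purely for segmentation support.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure
from skimage.filters import gaussian as _gaussian
from skimage.filters import median as _median

from .frames import ConfigurationError, ImageFrame

DENOISERS = ("median", "gaussian", "none")


def denoise(
    frame: ImageFrame, method: str = "median", window_px: int = 3
) -> ImageFrame:
    """Denoise a frame; ``none`` is the identity.

    ``window_px`` is the median footprint edge (odd, >= 3) or, for the
    Gaussian, window_px / 3 is used as sigma.
    """
    if method not in DENOISERS:
        raise ConfigurationError(f"unknown denoiser {method!r}")
    if method == "none":
        return frame.with_pixels(frame.pixels.copy())
    if method == "median":
        if window_px < 3 or window_px % 2 == 0:
            raise ConfigurationError("median window must be odd and >= 3")
        footprint = np.ones((window_px, window_px), dtype=bool)
        out = _median(frame.pixels, footprint=footprint)
    else:
        sigma = window_px / 3.0
        if sigma <= 0:
            raise ConfigurationError("gaussian sigma must be > 0")
        out = _gaussian(frame.pixels, sigma=sigma, preserve_range=True)
    return frame.with_pixels(np.clip(out, 0.0, None))


def clahe(
    frame: ImageFrame,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> ImageFrame:
    """Contrast-limited adaptive histogram equalization.

    Input is normalized to [0, 1] internally; output stays in [0, 1].
    A constant frame passes through unchanged (as a zero image).
    """
    if clip_limit <= 0:
        raise ConfigurationError("clip_limit must be > 0")
    rows, cols = tile_grid
    h, w = frame.shape
    if rows < 1 or cols < 1:
        raise ConfigurationError("tile_grid entries must be >= 1")
    if h // rows < 1 or w // cols < 1:
        raise ConfigurationError("tile larger than image")
    img = frame.pixels
    span = np.ptp(img)
    if span == 0:
        return frame.with_pixels(np.zeros_like(img))
    norm = (img - img.min()) / span
    kernel = (max(1, h // rows), max(1, w // cols))
    out = exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clip_limit)
    return frame.with_pixels(out)
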