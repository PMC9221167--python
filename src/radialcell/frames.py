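"""Core in-memory containers shared by all pipeline stages.

An :class:`ImageFrame` is one channel of a two-channel acquisition: either
the *morphology* channel (lipid/autofluorescence contrast: bright cytoplasm,
dark nuclei) used for segmentation, or the *drug* channel (labeled-compound
fluorescence) used for quantification.  A :class:`LabelMap` is the usual
integer raster where 0 is background and each positive value identifies one
segmented object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CHANNELS = ("morphology", "drug")


class ConfigurationError(ValueError):
    """A parameter value violates an operation's contract."""


class FormatError(ValueError):
    """An on-disk input does not match the expected file format."""


@dataclass
class ImageFrame:
    """One channel's 2D intensity grid plus acquisition metadata.

    Parameters
    ----------
    pixels
        2D array of nonnegative intensities (photon counts or a.u.).
    channel
        ``"morphology"`` or ``"drug"``.
    pixel_size_um
        Lateral pixel size in micrometers.  Default corresponds to a
        90 x 90 um field of view rastered over 512 x 512 pixels.
    time_min
        Minutes post-transfection (>= 0).
    dose_nM
        Compound dose in nanomolar (>= 0).
    treatment
        Free-text condition label (e.g. ``"galnac_aso"``, ``"control"``).
    """

    pixels: np.ndarray
    channel: str = "morphology"
    pixel_size_um: float = 90.0 / 512.0
    time_min: float = 0.0
    dose_nM: float = 0.0
    treatment: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ConfigurationError(
                f"frame must be 2D, got shape {self.pixels.shape}"
            )
        if self.channel not in CHANNELS:
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        if not np.all(self.pixels >= 0):
            raise ConfigurationError("frame intensities must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.time_min < 0 or self.dose_nM < 0:
            raise ConfigurationError("time_min and dose_nM must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ImageFrame":
        """Return a copy carrying ``pixels`` but identical metadata."""
        return replace(self, pixels=pixels)


@dataclass
class LabelMap:
    """Integer object-id raster; 0 = background, k > 0 = object k.

    ``kind`` distinguishes cell from nucleus maps.  Nucleus maps label each
    nucleus with its *parent cell id*, so the two nuclei of a binucleated
    cell share one label value.
    """

    labels: np.ndarray
    kind: str = "cell"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ConfigurationError("label map must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ConfigurationError("label map must be integer-valued")
        if self.labels.min() < 0:
            raise ConfigurationError("labels must be nonnegative")
        if self.kind not in ("cell", "nucleus"):
            raise ConfigurationError(f"unknown label kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Sorted array of positive object ids present in the map."""
        out = np.unique(self.labels)
        return out[out > 0]
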