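"""File formats, metadata sidecars, acquisition arithmetic, run config.

On-disk contract: single-plane grayscale TIFF — 32-bit float for intensity
frames, 16-bit unsigned for label maps — with acquisition metadata in a
JSON sidecar (``<image>.json``) rather than TIFF tags, for portability
across TIFF dialects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import tifffile

from .frames import ConfigurationError, FormatError, ImageFrame, LabelMap

_SIDECAR_KEYS = ("channel", "pixel_size_um", "time_min", "dose_nM", "treatment")


def frame_time(n_rows: int, n_cols: int, dwell_us: float) -> float:
    """Raster acquisition time in seconds: rows x cols x dwell (us).

    A 400 x 400 px raster at 10 us/pixel takes 1.6 s.
    """
    if n_rows <= 0 or n_cols <= 0 or dwell_us <= 0:
        raise ConfigurationError("frame_time arguments must be positive")
    return n_rows * n_cols * dwell_us / 1e6


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame(path: str | Path, frame: ImageFrame) -> None:
    """Write an intensity frame as 32-bit float TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, frame.pixels.astype(np.float32))
    meta = {k: getattr(frame, k) for k in _SIDECAR_KEYS}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_frame(path: str | Path, **overrides) -> ImageFrame:
    """Read a single-plane grayscale TIFF as an :class:`ImageFrame`.

    Metadata comes from the sidecar when present; keyword overrides win.
    Multi-plane or RGB input is rejected — split channels/planes first.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-plane grayscale image, got shape "
            f"{arr.shape}; split multi-plane/RGB TIFFs into single channels"
        )
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    meta.update(overrides)
    return ImageFrame(np.asarray(arr, dtype=np.float64), **meta)


def write_labels(path: str | Path, labels: LabelMap) -> None:
    """Write a label map as 16-bit unsigned TIFF."""
    if labels.labels.max() > np.iinfo(np.uint16).max:
        raise FormatError("label ids exceed 16-bit range")
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_labels(path: str | Path, kind: str = "cell") -> LabelMap:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be a single 2D plane")
    return LabelMap(arr.astype(np.int32), kind=kind)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; JSON-serializable.

    Either ``morphology``/``drug`` point at input TIFFs, or ``simulate``
    names a generator preset.  Unknown keys in a config file are rejected
    rather than silently ignored.
    """

    out_dir: str = "results"
    morphology: str | None = None
    drug: str | None = None
    cell_masks: str | None = None
    nucleus_masks: str | None = None
    simulate: str | None = None  # preset name
    n_cells: int = 30
    seed: int = 0
    denoiser: str = "median"
    denoise_window: int = 3
    clahe_clip: float = 0.01
    clahe_grid: tuple[int, int] = (8, 8)
    min_cell_area: int = 200
    min_nucleus_area: int = 30
    n_bands: int = 5
    theta: float = 0.75

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ConfigurationError("n_bands must be >= 1")
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        if self.simulate is None and (self.morphology is None or self.drug is None):
            raise ConfigurationError(
                "config needs either input frames (morphology+drug) or simulate"
            )
        for attr in ("morphology", "drug", "cell_masks", "nucleus_masks"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} file not found: {p}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        if "clahe_grid" in data:
            data["clahe_grid"] = tuple(data["clahe_grid"])
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, quoted in provenance."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
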