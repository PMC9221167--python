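"""Per-cell and per-region intensity statistics, and the viability filter.

The central quantities, per cell:

* ``Ic``, ``In`` — summed drug-channel intensity over the whole cell and
  over its nucleus (nuclear signal is excluded from uptake measures);
* ``I_bar = (Ic - In) / (Sc - Sn)`` — cytoplasmic intensity per pixel, the
  normalized uptake of one cell;
* per radial band Ri: ``I_Ri`` (band intensity sum), ``S_Ri`` (band pixel
  count), ``Ibar_Ri = I_Ri / S_Ri`` and the band's share of the total,
  ``Perc_Ri = I_Ri / sum_j I_Rj x 100%``.

Dead/dying cells lose membrane integrity and fill passively with compound,
nucleus included; the viability classifier flags a cell as dead when its
nuclear mean intensity approaches its cytoplasmic mean (and clears a floor
above background), automating the exclusion of such cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import ConfigurationError, ImageFrame, LabelMap
from .radial import RadialMap
from .segmentation import CellObject


class DegenerateCellError(ValueError):
    """Sc == Sn: no cytoplasm to normalize over."""


@dataclass
class RegionFeatures:
    region_index: int
    I_Ri: float
    S_Ri: int
    Ibar_Ri: float | None  # None when the band is empty
    Perc_Ri: float


@dataclass
class CellFeatures:
    cell_id: int
    Ic: float
    In: float
    Sc: int
    Sn: int
    I_bar: float
    viable: bool | None = None  # None = not classified (e.g. no nucleus)
    region_features: list[RegionFeatures] = field(default_factory=list)
    zero_signal: bool = False  # cytoplasmic total was 0; Perc set to 0


@dataclass
class ViabilityCount:
    total_viable: int
    total: int

    @property
    def cv_percent(self) -> float:
        return compute_cv(self)


def cell_intensity(drug: ImageFrame, cell: CellObject) -> tuple[float, float, float]:
    """Whole-cell and nuclear intensity sums and the normalized intensity.

    Returns ``(Ic, In, I_bar)`` with ``I_bar = (Ic - In)/(Sc - Sn)``.
    """
    if cell.Sc <= cell.Sn:
        raise DegenerateCellError(
            f"cell {cell.cell_id}: Sc={cell.Sc} <= Sn={cell.Sn}"
        )
    px = drug.pixels
    Ic = float(px[cell.cell_mask].sum())
    In = float(px[cell.nucleus_mask].sum()) if cell.nucleus_masks else 0.0
    I_bar = (Ic - In) / (cell.Sc - cell.Sn)
    return Ic, In, I_bar


def region_features(drug: ImageFrame, rmap: RadialMap) -> list[RegionFeatures]:
    """Per-band sums, means and percentage shares over one cell's bands.

    If the total cytoplasmic intensity is zero every percentage is 0
    (callers can detect this via the all-zero sums).  An empty band has
    ``Ibar_Ri = None`` — undefined, not zero.
    """
    if rmap.region is None or rmap.n_bands < 1:
        raise ConfigurationError("partition_regions must run before region_features")
    px = drug.pixels
    out: list[RegionFeatures] = []
    sums = []
    counts = []
    for k in range(1, rmap.n_bands + 1):
        m = rmap.region == k
        sums.append(float(px[m].sum()))
        counts.append(int(m.sum()))
    total = math.fsum(sums)
    for k, (s, c) in enumerate(zip(sums, counts), start=1):
        out.append(
            RegionFeatures(
                region_index=k,
                I_Ri=s,
                S_Ri=c,
                Ibar_Ri=(s / c) if c > 0 else None,
                Perc_Ri=(s / total * 100.0) if total > 0 else 0.0,
            )
        )
    return out


def classify_viability(
    features: CellFeatures, theta: float = 0.75, background_floor: float = 0.0
) -> bool:
    """Viability flag from the nuclear-fill signature.

    Dead iff nuclear mean In/Sn >= theta x cytoplasmic mean AND the
    nuclear mean exceeds ``background_floor`` (use 3x the frame's
    background median, see :func:`frame_background`).  Returns True for
    viable.  Requires a nucleus (Sn > 0).
    """
    if features.Sn == 0:
        raise ConfigurationError(
            f"cell {features.cell_id}: no nucleus, viability unavailable"
        )
    nuc_mean = features.In / features.Sn
    cyto_mean = (features.Ic - features.In) / (features.Sc - features.Sn)
    dead = nuc_mean >= theta * cyto_mean and nuc_mean > background_floor
    return not dead


def compute_cv(counts: ViabilityCount) -> float:
    """Cell viability percentage: viable / total x 100."""
    if counts.total <= 0:
        raise ConfigurationError("total cell count must be > 0")
    if not 0 <= counts.total_viable <= counts.total:
        raise ConfigurationError("viable count out of range")
    return counts.total_viable / counts.total * 100.0


def frame_background(drug: ImageFrame, cells: LabelMap) -> float:
    """Median drug intensity outside all cells — the per-frame QC baseline.

    No background is subtracted from any statistic; this value only feeds
    the viability floor and QC reporting.
    """
    outside = cells.labels == 0
    if not outside.any():
        return 0.0
    return float(np.median(drug.pixels[outside]))


def extract_cell_features(
    drug: ImageFrame,
    cell: CellObject,
    rmap: RadialMap | None = None,
    theta: float = 0.75,
    background_floor: float = 0.0,
) -> CellFeatures:
    """Full feature record for one cell (intensities, bands, viability)."""
    Ic, In, I_bar = cell_intensity(drug, cell)
    feats = CellFeatures(
        cell_id=cell.cell_id, Ic=Ic, In=In, Sc=cell.Sc, Sn=cell.Sn, I_bar=I_bar
    )
    if cell.Sn > 0:
        feats.viable = classify_viability(feats, theta=theta, background_floor=background_floor)
    if rmap is not None:
        feats.region_features = region_features(drug, rmap)
        feats.zero_signal = all(rf.I_Ri == 0 for rf in feats.region_features)
    return feats
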