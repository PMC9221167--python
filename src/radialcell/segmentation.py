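"""Cell and nucleus segmentation, border-cell exclusion, per-cell objects.

The built-in baseline segments the morphology channel with a classical
Otsu-threshold -> hole-filling -> distance-transform-watershed chain.  It is
deliberately simple: the quantification downstream only needs closed cell
masks and a dark-nucleus split.  Masks produced by external tools can be
imported instead via :func:`import_masks` and flow through the identical
downstream path.

Conventions: 0-based (row, col) coordinates; 4-connectivity throughout; an
object's boundary is the set of object pixels 4-adjacent to a non-object
pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .frames import FormatError, ImageFrame, LabelMap

#: 4-connectivity structuring element
CROSS = ndi.generate_binary_structure(2, 1)


class SegmentationError(ValueError):
    """Raised when masks violate the cell/nucleus containment contract."""


@dataclass
class CellObject:
    """One segmented cell: its mask, nucleus masks and pixel areas.

    ``Sc`` is the whole-cell pixel count and ``Sn`` the summed nucleus pixel
    count, the two areas entering the normalized-intensity formula
    I_bar = (Ic - In) / (Sc - Sn).
    """

    cell_id: int
    cell_mask: np.ndarray
    nucleus_masks: list[np.ndarray]
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_masks = [np.asarray(m, dtype=bool) for m in self.nucleus_masks]
        if self.Sc == 0:
            raise SegmentationError(f"cell {self.cell_id}: empty mask")
        for m in self.nucleus_masks:
            if np.any(m & ~self.cell_mask):
                raise SegmentationError(
                    f"cell {self.cell_id}: nucleus mask leaves the cell mask"
                )
        if self.nucleus_masks and self.Sn >= self.Sc:
            raise SegmentationError(
                f"cell {self.cell_id}: nucleus area Sn={self.Sn} >= Sc={self.Sc}"
            )

    @property
    def Sc(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def Sn(self) -> int:
        return int(sum(m.sum() for m in self.nucleus_masks))

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_masks)

    @property
    def nucleus_mask(self) -> np.ndarray:
        """Union of all nucleus masks (all-False if anucleate)."""
        out = np.zeros_like(self.cell_mask)
        for m in self.nucleus_masks:
            out |= m
        return out

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask


def segment_cells(
    morphology: ImageFrame,
    min_area_px: int = 200,
    smoothing_sigma: float = 2.0,
    split_min_distance: int = 10,
) -> LabelMap:
    """Segment cells from a preprocessed morphology frame.

    Otsu foreground threshold -> binary hole filling (recovers the dark
    nuclei swallowed by the threshold) -> distance-transform watershed to
    split touching cells -> discard components smaller than
    ``min_area_px``.  A blank frame yields an empty map, not an error.
    """
    img = np.asarray(morphology.pixels, dtype=float)
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="cell")
    fg = smoothed > threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(fg, structure=CROSS)
    if not fg.any():
        return LabelMap(np.zeros(img.shape, dtype=np.int32), kind="cell")

    dist = ndi.distance_transform_edt(fg)
    dist_s = gaussian(dist, sigma=2.0, preserve_range=True)
    peaks = peak_local_max(
        dist_s, min_distance=split_min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0, structure=CROSS)
    if markers.max() == 0:  # degenerate: no peaks, fall back to components
        labels, _ = ndi.label(fg, structure=CROSS)
    else:
        labels = watershed(-dist_s, markers=markers, mask=fg, connectivity=1)

    # enforce minimum area and connected components under 4-connectivity
    out = np.zeros(img.shape, dtype=np.int32)
    next_id = 1
    for k in np.unique(labels):
        if k == 0:
            continue
        comp, n = ndi.label(labels == k, structure=CROSS)
        for j in range(1, n + 1):
            m = comp == j
            if m.sum() >= min_area_px:
                out[m] = next_id
                next_id += 1
    return LabelMap(out, kind="cell")


def segment_nuclei(
    morphology: ImageFrame,
    cells: LabelMap,
    min_area_px: int = 30,
) -> LabelMap:
    """Detect dark nuclei within each segmented cell.

    Within each cell, pixels below a per-cell Otsu threshold form nucleus
    candidates; connected components of at least ``min_area_px`` pixels are
    kept and labeled with the *parent cell id*.  Cells may legitimately end
    up with 0, 1 or 2+ nuclei.
    """
    img = np.asarray(morphology.pixels, dtype=float)
    out = np.zeros(cells.shape, dtype=np.int32)
    for cid in cells.ids():
        cell_mask = cells.labels == cid
        vals = img[cell_mask]
        if np.ptp(vals) == 0:
            continue
        thr = threshold_otsu(vals)
        cand = cell_mask & (img < thr)
        # a nucleus may not touch the cell boundary ring: erode candidates
        # clipped to the cell so segmentation noise at the rim is dropped
        comp, n = ndi.label(cand, structure=CROSS)
        for j in range(1, n + 1):
            m = comp == j
            if m.sum() >= min_area_px and not np.any(m & boundary(cell_mask)):
                out[m] = cid
    return LabelMap(out, kind="nucleus")


def boundary(mask: np.ndarray) -> np.ndarray:
    """Object pixels 4-adjacent to a non-object pixel (or the frame edge)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=CROSS, border_value=0)
    return mask & ~eroded


def exclude_border_cells(cells: LabelMap) -> LabelMap:
    """Remove every label with a pixel on the outermost row or column.

    Idempotent; cells cut off by the frame edge cannot be quantified whole.
    """
    lab = cells.labels
    edge_ids = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    edge_ids = edge_ids[edge_ids > 0]
    out = lab.copy()
    out[np.isin(out, edge_ids)] = 0
    return LabelMap(out, kind=cells.kind)


def build_cell_objects(
    cells: LabelMap,
    nuclei: LabelMap,
    border_cells: LabelMap | None = None,
) -> list[CellObject]:
    """Assemble one :class:`CellObject` per surviving cell label.

    Nuclei are matched to cells by label value (nucleus maps carry parent
    ids).  A nucleus component overlapping two cells is an assignment error.
    Pass the pre-exclusion map as ``border_cells`` to set ``touches_border``
    flags on the survivors.

    Cells without a detected nucleus are returned too (flag via
    ``n_nuclei == 0``); they are excluded from radial analysis downstream
    but retain whole-cell intensity.
    """
    if cells.shape != nuclei.shape:
        raise FormatError("cell and nucleus maps differ in shape")
    objects: list[CellObject] = []
    nuc = nuclei.labels
    for cid in cells.ids():
        cell_mask = cells.labels == cid
        nuc_here = nuc == cid
        outside = np.unique(nuc[cell_mask & (nuc > 0) & (nuc != cid)])
        if outside.size:
            raise SegmentationError(
                f"nucleus label(s) {outside.tolist()} overlap cell {cid}"
            )
        # clip to the parent cell: segmentation noise may push a nucleus
        # pixel across the cell boundary
        nuc_here &= cell_mask
        comp, n = ndi.label(nuc_here, structure=CROSS)
        masks = [comp == j for j in range(1, n + 1)]
        touches = bool(
            cell_mask[0, :].any()
            or cell_mask[-1, :].any()
            or cell_mask[:, 0].any()
            or cell_mask[:, -1].any()
        )
        objects.append(
            CellObject(
                cell_id=int(cid),
                cell_mask=cell_mask,
                nucleus_masks=masks,
                touches_border=touches,
            )
        )
    return objects


def import_masks(
    cell_labels: np.ndarray, nucleus_labels: np.ndarray
) -> tuple[LabelMap, LabelMap, int]:
    """Validate externally produced label rasters.

    Nucleus ids need not match cell ids: each nucleus component is
    reassigned to the cell containing the majority of its pixels and
    clipped to it.  Returns cell and nucleus :class:`LabelMap` plus the
    count of nucleus pixels that fell outside their parent cell (or any
    cell) and were dropped, so callers can warn.
    """
    cell_labels = np.asarray(cell_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    if cell_labels.ndim != 2 or nucleus_labels.ndim != 2:
        raise FormatError("imported masks must be 2D label rasters")
    if cell_labels.shape != nucleus_labels.shape:
        raise FormatError(
            f"mask shape mismatch: {cell_labels.shape} vs {nucleus_labels.shape}"
        )
    cells = LabelMap(cell_labels.astype(np.int32), kind="cell")
    out = np.zeros(cell_labels.shape, dtype=np.int32)
    n_dropped = 0
    comp, n = ndi.label(nucleus_labels > 0, structure=CROSS)
    for j in range(1, n + 1):
        m = comp == j
        parents = cell_labels[m]
        hit = parents[parents > 0]
        if hit.size == 0:
            n_dropped += int(m.sum())
            continue
        parent = int(np.bincount(hit).argmax())
        keep = m & (cell_labels == parent)
        n_dropped += int(m.sum() - keep.sum())
        out[keep] = parent
    return cells, LabelMap(out, kind="nucleus"), n_dropped
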