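"""Synthetic two-channel microscopy scenes with exact ground truth.

Emulates the kind of field the pipeline is built for: ~25-45 rounded
suspension cells per frame, dark nuclei on bright cytoplasm in the
morphology channel (lipid/autofluorescence contrast, with optional bright
lipid-droplet speckles), and a drug channel whose per-cell intensity
pattern follows one of four subcellular distribution profiles:

``peripheral``
    mass concentrated near the cell membrane (radial ratio ~ 0), the
    pattern of receptor-mediated uptake arrested at the surface;
``perinuclear``
    mass concentrated near the nucleus (radial ratio ~ 1), the pattern of
    trafficked cargo;
``polar_focal``
    one bright 60-degree angular sector, the sparse focal adhesion pattern;
``uniform``
    cytoplasm AND nucleus filled uniformly — the passive-diffusion
    signature of dead/dying cells, used to exercise the viability filter.

For viable profiles the noise-free drug channel integrates to exactly
``uptake_density x cytoplasm_area`` per cell with zero nuclear signal, so
every downstream statistic has a closed-form expectation.  Detection noise
is Poisson shot noise plus Gaussian read noise, clipped at zero.

Three presets mirror the study conditions the pipeline targets:
``hepatocyte_galnac`` (peripheral, density 10), ``hepatocyte_ps``
(polar_focal, density 2 — a built-in 5:1 uptake contrast), and
``macrophage`` (polar_focal, density 10 for either treatment).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .frames import ConfigurationError, ImageFrame, LabelMap
from .radial import radial_ratio
from .segmentation import CellObject

PROFILES = ("peripheral", "perinuclear", "polar_focal", "uniform")

#: width (sigma) of the Gaussian radial profiles, in radial-ratio units
PROFILE_SIGMA = 0.15
#: polar_focal: sector half-angle (30 deg) and out-of-sector floor
SECTOR_HALF_ANGLE = np.pi / 6.0
SECTOR_FLOOR = 0.10
#: dead cells fill at this multiple of the viable density
DEAD_FILL_FACTOR = 1.5

MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Could not place all requested cells without overlap."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} cells after "
            f"{MAX_PLACEMENT_ATTEMPTS} attempts each"
        )


@dataclass
class SceneParams:
    """Generator configuration; defaults are the package's study conditions."""

    image_height_px: int = 512
    image_width_px: int = 512
    n_cells: int = 30
    cell_radius_range_px: tuple[float, float] = (10.0, 16.0)
    nucleus_fraction_range: tuple[float, float] = (0.35, 0.50)
    binucleate_prob: float = 0.3
    dead_prob: float = 0.2
    profile: str = "peripheral"
    uptake_density: float = 10.0
    noise_read_sd: float = 1.0
    seed: int = 0
    irregularity: float = 0.2
    droplet_rate: float = 0.002  # lipid droplets per cytoplasmic pixel
    border_margin_px: float | None = None  # None -> cells fully interior

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1 or self.n_cells < 1:
            raise ConfigurationError("image size and n_cells must be positive")
        lo, hi = self.cell_radius_range_px
        if not (0 < lo <= hi):
            raise ConfigurationError("cell_radius_range_px must be ordered, > 0")
        flo, fhi = self.nucleus_fraction_range
        if not (0 < flo <= fhi < 1):
            raise ConfigurationError("nucleus_fraction_range must be in (0,1), ordered")
        for p in (self.binucleate_prob, self.dead_prob):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must be in [0,1]")
        if self.profile not in PROFILES:
            raise ConfigurationError(f"unknown profile {self.profile!r}")
        if self.uptake_density < 0 or self.noise_read_sd < 0:
            raise ConfigurationError("density and read noise must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneParams":
        d = json.loads(text)
        for k in ("cell_radius_range_px", "nucleus_fraction_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


#: exported presets (see module docstring)
PRESETS: dict[str, SceneParams] = {
    "hepatocyte_galnac": SceneParams(profile="peripheral", uptake_density=10.0),
    "hepatocyte_ps": SceneParams(profile="polar_focal", uptake_density=2.0),
    "macrophage": SceneParams(profile="polar_focal", uptake_density=10.0),
}


@dataclass
class SceneTruth:
    """Exact ground truth for one generated scene."""

    cell_labels: LabelMap
    nucleus_labels: LabelMap
    per_cell: list[dict] = field(default_factory=list)

    def cell_ids(self) -> np.ndarray:
        return self.cell_labels.ids()

    def record(self, cell_id: int) -> dict:
        for rec in self.per_cell:
            if rec["cell_id"] == cell_id:
                return rec
        raise KeyError(cell_id)


def sample_cell_shape(
    frame_shape: tuple[int, int],
    center: tuple[float, float],
    radius_px: float,
    irregularity: float = 0.0,
    rng: np.random.Generator | None = None,
    clip_to_frame: bool = False,
) -> np.ndarray:
    """Draw one star-convex cell blob as a boolean mask.

    The outline is a radius-perturbed circle r(theta) = R (1 + a f(theta))
    with f a smooth unit-amplitude sum of low-order cosine harmonics and
    a = ``irregularity``; irregularity 0 yields the discrete disk and uses
    no randomness.  The mask always contains ``center``.
    """
    if radius_px < 3:
        raise ConfigurationError(f"radius {radius_px} px too small (min 3)")
    if not 0 <= irregularity <= 1:
        raise ConfigurationError("irregularity must be in [0,1]")
    h, w = frame_shape
    cr, cc = center
    r_max = radius_px * (1 + irregularity)
    if not clip_to_frame and (
        cr - r_max < -0.5 or cc - r_max < -0.5 or cr + r_max > h - 0.5 or cc + r_max > w - 0.5
    ):
        raise ConfigurationError("cell mask does not fit in the frame")

    if irregularity == 0:
        f = None
    else:
        rng = rng if rng is not None else np.random.default_rng(0)
        ks = np.arange(2, 6)
        amps = rng.uniform(0.3, 1.0, size=ks.size)
        phases = rng.uniform(0, 2 * np.pi, size=ks.size)

        def f(theta: np.ndarray) -> np.ndarray:
            v = sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))
            return v / np.abs(amps).sum()  # unit amplitude bound

    r0 = max(0, int(np.floor(cr - r_max)) - 1)
    r1 = min(h, int(np.ceil(cr + r_max)) + 2)
    c0 = max(0, int(np.floor(cc - r_max)) - 1)
    c1 = min(w, int(np.ceil(cc + r_max)) + 2)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    dr = rows - cr
    dc = cols - cc
    dist = np.hypot(dr, dc)
    if f is None:
        local = dist <= radius_px
    else:
        theta = np.arctan2(dc, dr)
        local = dist <= radius_px * (1 + irregularity * f(theta))
    mask = np.zeros(frame_shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    mask[int(round(cr)), int(round(cc))] = True
    return mask


def _place_cells(params: SceneParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping cells; returns masks + metadata."""
    h, w = params.image_height_px, params.image_width_px
    occupied = np.zeros((h, w), dtype=bool)
    cells = []
    lo, hi = params.cell_radius_range_px
    for i in range(params.n_cells):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            radius = rng.uniform(lo, hi)
            r_max = radius * (1 + params.irregularity)
            margin = params.border_margin_px
            if margin is None:
                margin = r_max + 1
            cr = rng.uniform(margin, h - 1 - margin) if h - 1 > 2 * margin else (h - 1) / 2
            cc = rng.uniform(margin, w - 1 - margin) if w - 1 > 2 * margin else (w - 1) / 2
            mask = sample_cell_shape(
                (h, w), (cr, cc), radius, params.irregularity, rng, clip_to_frame=True
            )
            grown = ndi.binary_dilation(mask, iterations=2)
            if not np.any(grown & occupied):
                occupied |= grown
                cells.append({"center": (cr, cc), "radius": radius, "mask": mask})
                break
        else:
            raise PlacementError(placed=len(cells), requested=params.n_cells)
    return cells


def _make_nuclei(
    cell: dict, params: SceneParams, rng: np.random.Generator, n_nuclei: int
) -> list[np.ndarray]:
    """Star-convex nuclei, eroded-clipped so a cytoplasmic ring always remains."""
    h_w = cell["mask"].shape
    frac = rng.uniform(*params.nucleus_fraction_range)
    interior = ndi.binary_erosion(cell["mask"], iterations=3)
    masks = []
    if n_nuclei == 1:
        centers = [cell["center"]]
        nuc_r = frac * cell["radius"]
    else:
        axis = rng.uniform(0, 2 * np.pi)
        off = 0.40 * cell["radius"]
        cr, cc = cell["center"]
        centers = [
            (cr + off * np.cos(axis), cc + off * np.sin(axis)),
            (cr - off * np.cos(axis), cc - off * np.sin(axis)),
        ]
        nuc_r = 0.7 * frac * cell["radius"]
    nuc_r = max(3.0, nuc_r)
    for cen in centers:
        m = sample_cell_shape(
            h_w, cen, nuc_r, params.irregularity / 2, rng, clip_to_frame=True
        )
        m &= interior
        if m.sum() >= 4:
            masks.append(m)
    if not masks:  # guarantee at least a minimal nucleus at the center
        m = np.zeros(h_w, dtype=bool)
        r, c = np.round(cell["center"]).astype(int)
        m[r - 1 : r + 2, c - 1 : c + 2] = True
        masks = [m & interior if (m & interior).sum() >= 4 else m]
    return masks


def generate_scene(
    params: SceneParams, noise: bool = True
) -> tuple[ImageFrame, ImageFrame, SceneTruth]:
    """Generate one two-channel scene and its ground truth.

    Returns (morphology frame, drug frame, truth).  With ``noise=False``
    both frames are the noise-free expectations, on which the generator's
    conservation guarantees hold exactly.
    """
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    h, w = params.image_height_px, params.image_width_px
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    per_cell = []
    for i, cell in enumerate(cells, start=1):
        cell_labels[cell["mask"]] = i
        dead = bool(rng.random() < params.dead_prob)
        n_nuclei = 2 if rng.random() < params.binucleate_prob else 1
        nuclei = _make_nuclei(cell, params, rng, n_nuclei)
        for m in nuclei:
            nucleus_labels[m] = i
        per_cell.append(
            {
                "cell_id": i,
                "dead": dead,
                "profile": "uniform" if dead else params.profile,
                "uptake_density": params.uptake_density,
                "n_nuclei": len(nuclei),
                "sector_angle": float(rng.uniform(0, 2 * np.pi)),
                "touches_border": bool(
                    cell["mask"][0, :].any()
                    or cell["mask"][-1, :].any()
                    or cell["mask"][:, 0].any()
                    or cell["mask"][:, -1].any()
                ),
            }
        )
    truth = SceneTruth(
        cell_labels=LabelMap(cell_labels, kind="cell"),
        nucleus_labels=LabelMap(nucleus_labels, kind="nucleus"),
        per_cell=per_cell,
    )
    morph = render_morphology_channel(truth, params, rng=np.random.default_rng(rng.integers(2**31)))
    drug = render_drug_channel(truth, params)
    if noise:
        morph = add_noise(morph, params.noise_read_sd, seed=int(rng.integers(2**31)))
        drug = add_noise(drug, params.noise_read_sd, seed=int(rng.integers(2**31)))
    return morph, drug, truth


def expected_profile_weights(
    truth: SceneTruth, cell_id: int, profile: str, sector_angle: float = 0.0
) -> np.ndarray:
    """Noise-free per-pixel weight field (unnormalized) for one viable cell.

    Shared by the renderer and by tests that need the analytic per-band
    mass of a profile.
    """
    cell_mask = truth.cell_labels.labels == cell_id
    nuc_mask = nucleus_mask_of(truth, cell_id)
    obj = CellObject(cell_id=cell_id, cell_mask=cell_mask, nucleus_masks=[nuc_mask])
    rmap = radial_ratio(obj)
    r = rmap.ratio
    cyto = rmap.cytoplasm_mask
    w = np.zeros(cell_mask.shape)
    if profile == "peripheral":
        w[cyto] = np.exp(-(r[cyto] ** 2) / (2 * PROFILE_SIGMA**2))
    elif profile == "perinuclear":
        w[cyto] = np.exp(-((r[cyto] - 1.0) ** 2) / (2 * PROFILE_SIGMA**2))
    elif profile == "polar_focal":
        cen = np.array(ndi.center_of_mass(nuc_mask))
        rows, cols = np.nonzero(cyto)
        ang = np.arctan2(cols - cen[1], rows - cen[0])
        delta = np.angle(np.exp(1j * (ang - sector_angle)))
        w[rows, cols] = np.where(
            np.abs(delta) <= SECTOR_HALF_ANGLE, 1.0, SECTOR_FLOOR
        )
    else:
        raise ConfigurationError(f"unknown viable profile {profile!r}")
    return w


def nucleus_mask_of(truth: SceneTruth, cell_id: int) -> np.ndarray:
    return truth.nucleus_labels.labels == cell_id


def render_drug_channel(truth: SceneTruth, params: SceneParams) -> ImageFrame:
    """Noise-free drug-channel expectation image.

    Viable cells: profile-shaped weights scaled so the cytoplasmic sum is
    exactly density x cytoplasm-area, nucleus 0.  Dead cells: uniform fill
    of cell AND nucleus at ``DEAD_FILL_FACTOR`` x density.
    """
    img = np.zeros(truth.cell_labels.shape)
    for rec in truth.per_cell:
        cid = rec["cell_id"]
        cell_mask = truth.cell_labels.labels == cid
        nuc_mask = nucleus_mask_of(truth, cid)
        density = rec["uptake_density"]
        if rec["profile"] == "uniform":
            img[cell_mask] = DEAD_FILL_FACTOR * density
            continue
        cyto = cell_mask & ~nuc_mask
        w = expected_profile_weights(
            truth, cid, rec["profile"], rec.get("sector_angle", 0.0)
        )
        total = w[cyto].sum()
        if total > 0:
            img[cyto] = w[cyto] * (density * cyto.sum() / total)
    return ImageFrame(img, channel="drug")


def render_morphology_channel(
    truth: SceneTruth,
    params: SceneParams,
    rng: np.random.Generator | None = None,
    bg_level: float = 5.0,
    nucleus_level: float = 40.0,
    cytoplasm_level: float = 120.0,
    droplet_level: float = 150.0,
) -> ImageFrame:
    """Noise-free morphology-channel expectation image.

    Intensity ordering background < nucleus < cytoplasm by construction;
    optional bright droplet speckles model lipid droplets.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    img = np.full(truth.cell_labels.shape, bg_level)
    cells = truth.cell_labels.labels > 0
    nuclei = truth.nucleus_labels.labels > 0
    img[cells] = cytoplasm_level
    img[nuclei] = nucleus_level
    if params.droplet_rate > 0:
        cyto = cells & ~nuclei
        rows, cols = np.nonzero(cyto)
        n_droplets = rng.poisson(params.droplet_rate * rows.size)
        if n_droplets > 0 and rows.size:
            pick = rng.integers(0, rows.size, size=n_droplets)
            spots = np.zeros(img.shape, dtype=bool)
            spots[rows[pick], cols[pick]] = True
            spots = ndi.binary_dilation(spots, iterations=1) & cyto
            img[spots] += droplet_level
    return ImageFrame(img, channel="morphology")


def add_noise(frame: ImageFrame, read_sd: float, seed: int) -> ImageFrame:
    """Poisson shot noise + Gaussian read noise, clipped at zero."""
    if read_sd < 0:
        raise ConfigurationError("read_sd must be >= 0")
    rng = np.random.default_rng(seed)
    shot = rng.poisson(frame.pixels).astype(float)
    if read_sd > 0:
        shot += rng.normal(0.0, read_sd, size=frame.shape)
    return frame.with_pixels(np.clip(shot, 0.0, None))


def truth_cell_objects(truth: SceneTruth) -> list[CellObject]:
    """Build CellObjects directly from ground-truth masks (bypassing
    segmentation), for tests and noise-free analyses."""
    from .segmentation import build_cell_objects

    return build_cell_objects(truth.cell_labels, truth.nucleus_labels)
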