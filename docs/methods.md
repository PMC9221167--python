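# Methods

## Pipeline overview

Four stages, each usable on its own: (a) preprocessing of the morphology
channel, (b) cell and nucleus segmentation, (c) per-cell feature
extraction (radial partition + intensity statistics), (d) condition-level
aggregation. The drug channel passes through untouched until stage (c):
intensity statistics assume a linear scale, so contrast enhancement is
never applied to it.

## Radial partition

The core primitive assigns each cytoplasmic pixel `p` the ratio
`r = d_cell / (d_cell + d_nuc)`, the relative position between cell
membrane (`r = 0`) and nucleus edge (`r = 1`).

**Distance convention.** Both distances are measured to the object
contour, taken to run midway between pixel centers: `d_cell` is the
Euclidean distance transform of the cell mask minus ½ px, `d_nuc` the EDT
of the nucleus complement minus ½ px. The half-pixel offset removes the
lattice bias of nearest-boundary-pixel distances; on a concentric-disk
phantom (nucleus radius 5, cell radius 15) the ratio tracks the continuous
closed form `(b − r)/(b − a)` to within a few hundredths everywhere. For
binucleated cells `d_nuc` is the distance to the nearest nucleus
(EDT of the union complement).

A line-of-sight construction — cast a ray from the nucleus centroid
through the pixel and intersect both contours — is the natural mental
model for round cells but is undefined whenever the ray exits a non-convex
mask, so the distance-transform form is the implementation and the ray
construction (`oracle_ray_ratio`) is retained purely as an independent
cross-check. On star-convex phantoms (disks, 1.5:1 ellipses, mildly
perturbed stars) the two agree with RMS ≈ 0.015–0.022 over sampled
cytoplasm pixels; the tests bound it at 0.05.

**Banding.** Equal-width, half-open bins with the top edge closed:
band `k = floor(r·B) + 1`, clipped so `r = 1` lands in band `B` (default
`B = 5`). Band 1 is membrane-adjacent, band B nucleus-adjacent. The bands
partition the cytoplasm exactly (`Σ_k S_Rk = Sc − Sn`, asserted). The
nucleus is reported as a separate compartment, never as a band; published
five-region schemes disagree on whether "region 5" means the innermost
cytoplasmic shell or the nucleus itself, so the naming is left to the
caller and the geometry is unambiguous. Degenerate pixels with
`d_cell + d_nuc = 0` would take ratio 0.5 and be counted in a diagnostic;
under the interface convention both distances are ≥ ½ px on the cytoplasm,
so the counter stays at 0 in practice.

## Intensity statistics

Per cell: `Ic`, `In` are raw sums (no gamma or bit-depth rescaling between
segmentation and quantification), `Ī = (Ic − In)/(Sc − Sn)`. Per band:
`Ī_Ri = I_Ri/S_Ri` (undefined — reported as missing, not 0 — for an empty
band) and `Perc_Ri = I_Ri/Σ_j I_Rj × 100`, with all percentages defined as
0 and flagged when the cytoplasmic total is 0. Band sums are accumulated
with compensated summation so `Σ Perc_Ri = 100` to 1e−9 and
`Σ I_Ri = Ic − In` exactly.

No background is subtracted anywhere; the per-frame background (median
intensity outside all cells) is reported for QC and feeds the viability
floor only.

## Viability filter

Membrane-compromised cells fill passively with compound, nucleus included,
while viable cells exclude it from the nucleus. A cell is flagged dead iff

    In/Sn ≥ θ · (Ic − In)/(Sc − Sn)   and   In/Sn > 3 × background median.

θ defaults to 0.75: the nuclear mean of a truly filled cell matches its
cytoplasmic mean (ratio 1), a viable cell sits near 0, and 0.75 leaves
headroom for shot noise on both sides. The floor suppresses false "dead"
calls on near-zero cells (e.g. untreated controls, where both means are
noise). Cells with no detectable nucleus are not classified; they keep
whole-cell intensities but are excluded from radial analysis and
aggregates. Against generator truth at 20–30% dead cells the filter
agrees with the ground-truth flags for ≥ 95% of cells (measured 100% at
the default noise level).

## Segmentation baseline

Otsu threshold on the preprocessed morphology frame → 4-connected hole
filling (recovers dark nuclei swallowed by the threshold) → smoothed
distance-transform watershed (peak markers ≥ 10 px apart) → discard
components < 200 px. Nuclei: per-cell Otsu on the within-cell intensities,
keep dark components ≥ 30 px that do not touch the cell's boundary ring,
labeled with the parent cell id. Defaults are sized to the generator's
scale (cells ~10–16 px radius on 512² frames) and configurable. Cells
touching the outermost row/column are removed before quantification
(idempotent, purely geometric rule). Externally produced label rasters can
be imported instead; nucleus components are reassigned to the cell holding
the majority of their pixels, clipped to it, and orphan pixels counted.

This baseline is intentionally classical. Learned denoisers or pixel
classifiers can replace stages (a)–(b) — the CLI keeps a `--denoiser` flag
and a mask-import path — without touching the quantification contract.

## Preprocessing

Median (default 3×3) or Gaussian denoising, then CLAHE with an 8×8 tile
grid and clip limit 0.01 on [0, 1]-normalized input. A constant frame is a
fixed point of every step. CLAHE parameters only matter insofar as Otsu
separates foreground afterwards; they were not tuned beyond that.

## Synthetic scenes

The generator emulates fields of rounded suspension cells: star-convex
radius-perturbed polygons (cosine harmonics 2–5, perturbation amplitude =
`irregularity`, default 0.2), placed by rejection sampling with a 2 px
separation margin and ≤ 1000 attempts per cell (clean abort reporting the
achieved count). Nuclei are smaller star-convex blobs eroded-clipped into
the cell interior; 30% of cells are binucleated (typical of rodent
hepatocyte populations), with nucleus/cell radius fraction drawn from
(0.35, 0.5).

Drug-channel profiles, as weights over the radial ratio `r`:

* `peripheral`: `exp(−r²/2σ²)`, σ = 0.15 — membrane-bound uptake;
* `perinuclear`: `exp(−(r−1)²/2σ²)` — trafficked cargo;
* `polar_focal`: a random 60° sector at weight 1, 0.1 elsewhere — sparse
  focal adherence with bright granularities;
* `uniform` (dead): cell *and* nucleus filled at 1.5× the viable density —
  passive diffusion exceeds active uptake.

Viable-cell weights are normalized so the noise-free cytoplasmic sum is
exactly `uptake_density × cytoplasm_area` and the nuclear sum is 0, giving
every downstream statistic a closed-form expectation. The morphology
channel uses fixed levels (background 5, nucleus 40, cytoplasm 120 a.u.)
plus optional droplet speckles at rate 0.002/px. Noise is
`Poisson(expectation) + N(0, read_sd²)` clipped at 0, read_sd = 1 by
default; all randomness flows from a single integer seed
(bit-identical reruns).

Presets encode the study conditions the pipeline targets:
`hepatocyte_galnac` (peripheral, density 10), `hepatocyte_ps`
(polar_focal, density 2) — a built-in 5:1 uptake contrast between
receptor-targeted and untargeted compound in viable hepatocytes — and
`macrophage` (polar_focal, density 10 regardless of conjugation). Density
and noise levels are free parameters chosen once at plausible
photon-count scales, not fitted to any instrument.

The generator shares the radial-ratio primitive with the pipeline (the
profiles are *defined* on that coordinate); independence of the geometric
check therefore rests on the ray-casting oracle, and independence of the
recovery checks on the fact that segmentation, band assignment and
statistics are computed blind to the truth masks. What the generator does
not model: optical point-spread blur, 3D structure, photobleaching,
cell-to-cell density variation within a condition, and touching/overlapping
cells. Passing tests therefore validate the measurement chain, not
segmentation robustness on hard real-world fields — the mask-import path
exists for that.

## Aggregation and statistics

Means and sample SD (n−1; SD of a single cell reported as 0 with
`n_cells = 1` visible) of `Ī` and `Perc_Ri` over viable cells per
(treatment, dose, time) group. Contrasts use the fold change of means and
Welch's two-sample two-sided t-test — chosen because condition variances
are visibly unequal — with an exact permutation test as cross-check (they
agree within ~0.01 at n = 8/arm; the permutation p bottoms out at 2/20
for 3+3 samples). Raw p-values, no multiplicity correction. Time courses
attach the sign of the Theil–Sen slope of each band's mean share.

**Fold-change recovery.** With 40 viable cells per arm, 20% dead cells
injected and removed automatically, the full pipeline recovers the
presets' 5:1 contrast at ~4.6 (within the ±15% acceptance band). The
small low bias is a property of the noise model: zero-clipped read noise
adds ~0.08 a.u./px of positive background to both arms, which inflates
the low-density arm relatively more. It is left uncorrected — the
measurement model subtracts no background.

## Problem sizes

Tests and the acceptance script run on 256–512 px frames with 6–30 cells
and 40 cells per contrast arm — the per-frame cell counts of the targeted
acquisitions, scaled to a handful of frames per condition. All quantities
reported by `scripts/acceptance.py` are recomputed from scratch on every
invocation under the given seed.

## Known limitations

* The border-exclusion rule is strictly geometric (any pixel on the frame
  edge); an object-level classifier could rescue nearly whole cells.
* The watershed baseline assumes non-touching, roughly convex cells;
  dense or clumped fields need imported masks.
* One drug channel per run; multi-channel fusion is out of scope.
* The viability rule requires a detected nucleus and a meaningful
  cytoplasmic signal; control wells rely on the background floor.
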