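# radialcell

Single-cell quantification of fluorescently labeled drug uptake and its
radial subcellular distribution from two-channel microscopy images.

The package targets experiments of the following shape: suspension cells
(e.g. primary hepatocytes or macrophage lines) are treated with a
fluorophore-conjugated compound such as an antisense oligonucleotide
(ASO), and each field of view is acquired in two co-registered channels —
a **morphology channel** (lipid CARS contrast or autofluorescence: bright
cytoplasm, dark nuclei) used for segmentation, and a **drug channel**
(compound fluorescence) used for quantification. The questions are *how
much* compound each viable cell has internalized as a function of dose and
time, and *where* in the cell it sits — stuck at the membrane, spread
through the cytoplasm, or trafficked to the perinuclear region.

## Method

For every segmented cell with cell area `Sc` (pixels) and nucleus area
`Sn`, with summed drug-channel intensities `Ic` (whole cell) and `In`
(nucleus), the normalized per-cell uptake is

    Ī = (Ic − In) / (Sc − Sn)        [a.u. per cytoplasmic pixel]

Each cytoplasmic pixel `p` also gets a **radial ratio**

    r(p) = d_cell(p) / (d_cell(p) + d_nuc(p)) ∈ [0, 1]

where `d_cell` and `d_nuc` are Euclidean distances to the cell and nucleus
contours (nearest nucleus, for binucleated cells). `r = 0` on the membrane
and `r = 1` at the nucleus edge, so binning `r` into five equal-width bands
divides each cell into five concentric regions R1 (membrane-adjacent) …
R5 (nucleus-adjacent). Per band:

    Ī_Ri   = I_Ri / S_Ri                 (band mean intensity)
    Perc_Ri = I_Ri / Σ_j I_Rj × 100%     (band share of cytoplasmic signal)

Dead/dying cells lose membrane integrity and fill passively with compound,
nucleus included; they are excluded automatically when the nuclear mean
`In/Sn` reaches θ (default 0.75) times the cytoplasmic mean and clears a
floor above background. Cell viability is reported as
`CV% = viable / total × 100`.

Condition-level aggregation gives dose-response and time-course tables
(mean ± SD of Ī over viable cells), per-region `Perc_Ri` trajectories with
Theil–Sen trend signs, and condition contrasts (fold change of means,
Welch two-sided t-test, with an exact permutation cross-check).

Because raw study images are rarely shareable, the package ships a
**synthetic scene generator** with exact ground truth (cell/nucleus label
maps, per-cell dead flags, uptake densities, distribution profiles:
peripheral, perinuclear, polar-focal, uniform/dead). Every stage is tested
against it.

## Worked example

```python
from dataclasses import replace
import radialcell as rc
from radialcell.synthetic import PRESETS
from radialcell.kinetics import aggregate

params = replace(PRESETS["hepatocyte_galnac"], n_cells=25, seed=1)
morph, drug, truth = rc.generate_scene(params)
drug.treatment, drug.dose_nM, drug.time_min = "galnac_aso", 50.0, 70.0

df, qc = rc.analyze_frame(morph, drug)   # segment -> partition -> quantify
print(qc)
print(aggregate(df).round(2).to_string(index=False))
```

prints

```
{'frame': 0, 'n_cells_segmented': 25, 'n_border_excluded': 0,
 'background_median': 0.0043, 'n_anucleate': 1, 'n_cells_quantified': 25}
 treatment  dose_nM  time_min  n_cells  mean_I_bar  sd_I_bar  mean_Perc_R1  mean_Perc_R2  mean_Perc_R3  mean_Perc_R4  mean_Perc_R5 ...
galnac_aso     50.0      70.0       20        9.28      0.17         63.96         32.66          2.06          0.72          0.59
```

Read: 25 cells were segmented from the morphology channel; 20 entered the
aggregate (dead cells and one cell without a detectable nucleus were
excluded). Mean uptake Ī ≈ 9.3 a.u./px recovers the preset's true density
of 10 (the segmented masks include a thin zero-intensity rim), and ~64% of
the compound sits in the membrane-adjacent band R1 — the peripheral
uptake signature the `hepatocyte_galnac` preset encodes.

The same stages are available from the shell:

```sh
radialcell simulate --preset hepatocyte_galnac --n-cells 25 --seed 1 --out scene/
radialcell segment scene/morphology.tif --out-cells cells.tif --out-nuclei nuclei.tif
radialcell radial --bands 5 --cells cells.tif --nuclei nuclei.tif --out-region regions.tif
radialcell quantify --drug scene/drug.tif --cells cells.tif --nuclei nuclei.tif --out features.csv
radialcell summarize features.csv --out summary/
radialcell run --config run.json    # end-to-end, provenance in qc.json
```

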