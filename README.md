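# cortifilo

Quantification of protein localization at the cell cortex in single-cell
fluorescence micrographs, built for the kind of live-cell imaging used to
study filopodia formation in *Dictyostelium* amoebae: where on the cell
periphery a myosin or actin marker sits, how strongly it is enriched at
the cortex, and how many filopodia each cell extends.

The package implements, as a tested and reusable pipeline:

- **Segmentation** of cells from maximum-intensity projections
  (data-relative thresholding, removal of thin protrusions from the body
  mask, photometric nucleus detection) and the partition of each cell
  into a **cortical band** (default 0.8 µm, by exact sub-pixel Euclidean
  distance to the boundary), the interior **cytoplasm**, and the nucleus.
- The two per-cell headline statistics:
  - **cortex:cytoplasm ratio** `R = ⟨I⟩_band / ⟨I⟩_cyto` — `R ≈ 1` means
    no cortical enrichment, `R ≈ 1.2` means 20 % enrichment;
  - **cortical SD** — the standard deviation of band intensity across
    angular bins around the whole periphery; high values indicate
    polarized (leading-edge) localization. For a cosine-modulated band
    `M·(1 + A·cos(φ − θ₀))` the expected value is `M·A/√2`.
- **Filopodia counting** by radial tip search: rays cast from the cell
  centroid, the outermost intensity peak above the noise floor along each
  ray is a tip candidate, and candidates are merged across adjacent rays;
  per-cell counts feed the summary convention *percent of cells with ≥1
  filopodium* and *mean count among those cells*.
- **Pixel-wise colocalization** (cytofluorograms, Pearson *r* over the
  in-mask pixels of two channels) and **linescan analyses**: arbitrary or
  longest-axis intensity profiles, [0, 1] normalization, and averaging of
  multiple profiles with a restricted cubic spline (SD and SEM bands).
- The **statistics layer**: ROUT outlier exclusion at FDR Q = 0.1 %
  (robust median/RSDR location-scale with a Benjamini–Hochberg step-up),
  one-way ANOVA with Tukey or Dunnett post-hoc comparisons, Student's
  t-test, per-experiment ("superplot") means, and summary-table reports.
- A **synthetic scene generator** that renders amoeba-like cells with
  known ground truth — cortical enrichment factor, angular polarity,
  filopodium tip positions, channel correlation, Poisson + Gaussian
  camera noise over z-slices — so every stage above is validated against
  exact truth without real microscopy data.

## Worked example

Render one synthetic control-like cell (20 % cortical enrichment, three
filopodia), then quantify it with the same pipeline you would run on a
real TIFF stack:

```python
from cortifilo import (SceneParams, make_cell_scene, max_project,
                       segment_cells, partition_cortex, cortex_cyto_ratio,
                       cortical_asymmetry, radial_tip_search)

params = SceneParams(enrichment_factor=1.2, n_filopodia=3,
                     image_shape=(300, 300), seed=7)
stack, truth = make_cell_scene(params)
img = max_project(stack)

cell = segment_cells(img)[0]
part = partition_cortex(cell, band_width_um=0.8)
print(f"cortex:cytoplasm ratio = {cortex_cyto_ratio(img, part):.3f}")
sd, profile = cortical_asymmetry(img, part, cell, n_bins=360)
print(f"cortical SD            = {sd:.2f}")
tips = radial_tip_search(img, cell)
print(f"filopodia detected     = {len(tips)} (truth: {params.n_filopodia})")
```

prints

```
cortex:cytoplasm ratio = 1.185
cortical SD            = 5.56
filopodia detected     = 3 (truth: 3)
```

The ratio recovers the simulated 20 % enrichment (1.185 vs 1.2; the
small shortfall is boundary discretization plus noise), the cortical SD
is low because the band is unpolarized, and all three protrusions are
found.

For batch work there is a CLI: `cortifilo simulate | quantify | coloc |
linescan | stats | all`, driven by a validated TOML/YAML config, e.g.

```sh
cortifilo all --config study.yaml --seed 1
```

which writes `per_cell.csv`, `tips.csv`, `summary.json`, ANOVA and
pairwise-comparison tables, and a run manifest with the config hash.

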