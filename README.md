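# spatialcn

Cellular-neighborhood and proximity analysis for multiplexed tissue-imaging
cell tables.

Multiplexed immunofluorescence (CODEX-style) imaging of tissue microarrays
yields, after segmentation, one row per cell: spot and patient identifiers,
centroid coordinates in µm, and mean intensities for a nuclear counterstain
(DAPI) plus lineage markers (PanCK, CD3, CD4, CD8, CD20, CD31, CD68).
`spatialcn` turns such tables into tissue-architecture statistics and
outcome associations:

1. **Phenotyping** — priority-ordered threshold gating into eight cell
   types: Tumor (PanCK⁺), Endothelial (CD31⁺), CD8 T (CD3⁺CD8⁺), CD4 T
   (CD3⁺CD4⁺), other T (CD3⁺CD8⁻CD4⁻), Macrophage (CD68⁺), B cell (CD20⁺),
   and Stroma (DAPI⁺ only).
2. **Cellular neighborhoods (CNs)** — for every cell, a composition window
   over the cell and its 9 nearest same-spot neighbors; windows pooled
   across all spots are clustered with mini-batch k-means (k = 10), similar
   clusters are merged (average-linkage agglomeration on centroid cosine
   distance, or an explicit map), and each cell inherits the final CN of
   its own window. A per-type z-score of mean composition across CNs (the
   enrichment matrix) labels what each CN is made of, and Voronoi
   tessellations of the spots can be exported as GeoJSON for visual
   alignment with the underlying images.
3. **Proximity** — per-cell nearest-neighbor distances between strata
   (e.g. CD8 T → nearest tumor cell), per-spot means, and the spatial
   score of a center cell,

   `score = d(nearest identity A) / d(nearest identity B)`,

   e.g. with CD8 T centers, A = Tumor and B = CD4 T, a high score reads as
   CD8 T cells sitting near CD4 T cells rather than near tumor.
4. **Outcome statistics** — Kaplan–Meier estimation, two-group log-rank
   tests on median-split (high/low) per-patient covariates, t-tests,
   one-way ANOVA with Bonferroni-adjusted pairwise comparisons, and Pearson
   correlations, assembled into a cohort-level association report.

Because segmented imaging cohorts are rarely public, the package ships a
first-class synthetic-data module: seeded TMA cohorts (default 64 patients,
one 1.5 mm spot each, 1,500–3,000 cells per spot) with spatially contiguous
regions following six planted neighborhood archetypes, a two-channel
log-normal marker-emission model, and exponential survival whose log-hazard
is proportional to each patient's true frequency of a designated risk
archetype. Ground-truth labels make recovery quantifiable (Adjusted Rand
Index against the planted regions).

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from spatialcn import SyntheticConfig
from spatialcn.cli_io import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulate=SyntheticConfig(n_patients=16, cells_per_spot=2000, seed=1),
    seed=1, output_dir="readme_run",
)
out = run_pipeline(cfg)

labeled = pd.read_csv(out / "cells_labeled.csv")
print(round(adjusted_rand_score(labeled.true_cn, labeled.cn_final), 3))
print(pd.read_csv(out / "cn_enrichment.csv", index_col=0).round(2))
```

prints an ARI of `0.87` against the planted regions and the enrichment
matrix

```
          Tumor  Endothelial  CD8_T  CD4_T  Other_T  Macrophage  B_cell  Stroma
cn_final
1         -0.40        -0.42  -0.38  -0.42    -0.45        2.11   -0.44   -0.54
2         -0.50        -0.49   2.23   2.23     2.24       -0.61    0.22   -0.63
3         -0.37        -0.35  -0.32  -0.41    -0.47        0.28    2.13    0.09
4         -0.43         2.23  -0.41  -0.42    -0.48       -0.54   -0.64   -0.43
5         -0.53        -0.50  -0.59  -0.51    -0.40       -0.61   -0.63    2.16
6          2.23        -0.48  -0.53  -0.48    -0.44       -0.65   -0.64   -0.66
```

— read row-wise: CN2 is the lymphocyte-enriched neighborhood (CD8/CD4/other
T high), CN5 pure stroma, CN6 bulk tumor, and so on. At the full default
scale (64 patients, ~140,000 cells, ~11 s on one CPU) the association
report in `association_report.csv` recovers the planted biology: the
lymphocyte CN's frequency predicts shorter survival (log-rank p = 0.010),
correlates positively with the mean CD8 T → tumor distance (r = 0.48,
p = 1e-4) and negatively with the CD8 T → CD4 T distance (r = −0.79), and
patients with high lymphocyte-CN frequency have significantly higher
spatial scores (t = 6.3).

The same pipeline runs from a shell:

```bash
spatialcn simulate --patients 16 --seed 1 --out cohort
spatialcn run --seed 1 --out results_dir
spatialcn neighborhoods cohort/cells.csv --k 10 --seed 1 --voronoi --out cn_out
```

To analyze real exports instead of simulations, point `PipelineConfig`
(or a YAML config passed to `spatialcn run --config`) at a cell-table CSV
with columns `cell_id, patient_id, spot_id, x_um, y_um` plus either the
eight `<marker>_intensity` columns or a pre-assigned `cell_type` column,
and a survival CSV with `patient_id, time_months, event`.

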