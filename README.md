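# slidesample

Tile sampling and cellularity profiling for whole-slide histology images.

A whole-slide image (WSI) is far too large to push through a cell detector
in one piece, so it is tiled into 500 × 500-pixel patches at 20X
(~0.5 µm/pixel) and the detector is run per tile.  A typical colon-cancer
slide holds ~900 tissue-bearing tiles; processing all of them is expensive,
and most of the information about a slide-level summary is already present
in a modest sample.  `slidesample` implements and evaluates that idea:

- **Profiles.**  A cell identifier maps tile *I* to a cell map
  *M(I) = {n_M, ⟨x_i, y_i⟩, c_i}* of nucleus locations typed as epithelial,
  inflammatory, fibroblast or "other".  The tile profile is the per-type
  count *f_j = Σ_i [c_i = j]* normalised to cells per 100-µm square, and the
  slide profile is the mean over the n_T sampled tiles,
  *fw_ij = Σ_t f_tij / n_T* — a four-feature cellularity summary.
- **Sampling policies.**  Random sampling (RS) draws n_T tiles uniformly
  without replacement.  Systematic random sampling (SRS) covers the slide
  with g × g-tile *sample grids* and draws one tile per grid, discarding
  draws that land on background or artifact tiles; the block side is
  *g = ⌊√(γ n_F / n_NOM)⌋* for nominal size n_NOM, foreground tile count
  n_F and non-artifact fraction γ.  Because nearby tissue is alike, SRS
  estimates the slide profile with visibly less variance than RS at the
  same cost.
- **Reproducibility metric.**  Running a policy twice ("batch runs") and
  averaging |fw⁽¹⁾ − fw⁽²⁾| over slides, divided by the cell type's global
  average, gives the *relative batch difference* (RBD) — the scale-free
  number the policies are compared on.
- **Clinical associations.**  Per-slide profiles are tested against binary
  clinical variables (Welch t-tests) or continuous ones (Pearson), with
  Benjamini–Hochberg control of the false discovery rate over the whole
  test family.
- **Synthetic cohorts.**  A generator simulates slides as elliptical tissue
  blobs with per-tile Poisson cell counts driven by a spatially correlated
  log-Gaussian intensity field (cross-type correlation signs included),
  plus an identifier stand-in with a calibrated miss rate (0.35) and label
  confusion (0.76 correct).  Every stage of the pipeline runs with no
  scanner, no slides and no trained network.

The foreground/tiling machinery (local-entropy segmentation, tile
classification, gray-artifact detection, γ estimation) works on real rasters
too; per-tile cell maps can be supplied in a plain CSV interchange format by
any external detector.

## Worked example

`examples/03_batch_difference.py` simulates a 30-slide cohort and runs the
two-batch RS/SRS comparison with the noisy identifier:

```
relative batch difference (%):
              epithelial  inflammatory  fibroblast  other
policy n_nom
SRS    25           6.31          5.87        6.26   5.78
RS     25           9.55         10.31        7.13   7.86
SRS    50           4.39          3.97        3.75   3.71
RS     50           7.69          4.49        4.74   3.91
SRS    100          2.22          2.33        2.46   2.75
RS     100          5.00          4.25        3.79   3.92
```

Each entry is the between-batch disagreement of slide profiles as a
fraction of that cell type's global average: reproducibility improves with
sample size (down each column block) and SRS beats RS at every matched
size.  `examples/04_associations.py` shows the association battery
recovering a simulated fibroblast–metastasis effect (group means 5.22 vs
7.43 cells per 100-µm square, BH-adjusted p = 0.0015) while leaving the
null rows unflagged, and the other examples cover cohort simulation and
single-slide sampling.  A thin CLI (`slidesample simulate | sample |
associate`) wraps the same functions for shell use.

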