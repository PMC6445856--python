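"""Simulate a small synthetic cohort and inspect one slide.

Builds a cohort of 6 slides (small grids for speed), prints each slide's
foreground tile count and its exhaustive ground-truth cellularity profile —
cells per 100-µm square for the four cell types.  The cohort-mean densities
should sit near the configured targets (21.3, 5.52, 5.64, 2.43), while
individual slides scatter around them through slide-level heterogeneity.
"""

import slidesample as ss

config = ss.CohortConfig(n_slides=6, grid_shape=(16, 16), target_foreground_tiles=200)
slides, clinical = ss.generate_clinical_cohort(config, seed=7)

print("slide    n_F  epithelial  inflammatory  fibroblast  other")
for slide in slides:
    p = slide.true_profile()
    e, i, f, o = p.values
    print(f"{slide.slide_id}  {slide.tile_grid.n_F:4d}  {e:10.2f}  {i:12.2f}  {f:10.2f}  {o:6.2f}")

profiles = ss.cohort_profiles(slides)
print("\ncohort mean:", profiles.mean().round(2).to_dict())
print("configured: ", {k: v for k, v in ss.DEFAULT_MEAN_DENSITY.items()})
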