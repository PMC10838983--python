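# perishell

Functional profiling of the gray matter surrounding a cortical lesion from
resting-state fMRI.

Focal cortical dysplasia (FCD) and similar epileptogenic lesions are
surrounded by normal-appearing cortex whose spontaneous activity may
nevertheless be abnormal, and the spatial extent of that abnormality
matters for surgical planning. `perishell` quantifies it layer by layer:
it builds ten concentric 2-mm shells of cortical gray matter (GM) around a
lesion mask ("layer 1" innermost to "layer 10" outermost, a 20-mm band),
mirrors the lesion across the midsagittal plane to obtain contralateral
homotopic control shells, computes voxelwise resting-state metrics, and
tests each layer's ipsilateral mean against its homotopic control.

The package is aimed at imaging researchers who have per-subject inputs
already aligned in a common symmetric space (lesion mask, cortical GM
mask, hemisphere labels, 4D BOLD series, motion parameters, optional
resection mask), and at methodologists who want to study the layer-wise
approach itself on fully synthetic cohorts with known ground truth.

## Metrics and statistics

**ALFF** (amplitude of low-frequency fluctuations) is the band-amplitude
ratio

&nbsp;&nbsp;ALFF(v) = Σ<sub>0.01 ≤ f ≤ 0.1</sub> A<sub>v</sub>(f) / Σ<sub>0 < f ≤ 0.25</sub> A<sub>v</sub>(f),

where A<sub>v</sub>(f) is the discrete Fourier amplitude spectrum of voxel
v's detrended, nuisance-regressed (but not bandpassed) time series; the DC
bin is excluded from both sums, so raw ALFF ∈ [0, 1].

**ReHo** (regional homogeneity) is Kendall's coefficient of concordance of
a voxel with its 26 nearest neighbours over the bandpassed series,

&nbsp;&nbsp;W = 12 S / (K²(t³ − t) − K ΣT<sub>j</sub>),

with S the variance of the per-timepoint rank sums, K ≤ 27 the in-mask
neighbourhood size and T<sub>j</sub> the usual tie correction.

Both maps are standardized by their global in-mask mean. Per layer k the
package runs a two-sided paired t-test of ipsilateral vs contralateral
layer means across subjects at the Bonferroni-corrected threshold
α = 0.05/10 = 0.005, plus two-sample group comparisons, Pearson
correlation of layer means with log-normalized lesion volume
(v<sub>norm</sub> = lesion volume × 10⁶ / intracranial volume), and a
resection-completeness classification (complete iff lesion ∪ layers 1..L
lies inside the resection mask, L being the outermost contiguous
significant layer) tested against seizure outcome with a 2×2 chi-square.

## Worked example

```python
import numpy as np
from perishell import CohortSpec, make_anatomy, build_layers
from perishell import PerilesionalLayerModel
from perishell.pipeline import simulate_group_profiles

# a 15-subject synthetic group: 40% ALFF deficit extending 12 mm
spec = CohortSpec(n_subjects=15, grid_shape=(40, 40, 28), n_timepoints=100,
                  deficit_extent_mm=12.0, alff_deficit_fraction=0.4, seed=100)
anatomy = make_anatomy(spec)
layers = build_layers(anatomy.lesion, anatomy.gm, anatomy.hemis)
profiles = simulate_group_profiles(spec, group="IIa", anatomy=anatomy,
                                   layers=layers)
results = PerilesionalLayerModel(profiles).fit()
print(results.summary())
```

prints

```
Perilesional layer-wise statistics
  layers: 10, family alpha 0.05, per-layer alpha 0.005

ALFF | group IIa | abnormal extent: layers 1-6
  layer     n        t        p   sig
      1    15   -9.119  0.00000   *
      2    15  -13.012  0.00000   *
      3    15  -14.828  0.00000   *
      4    15  -13.833  0.00000   *
      5    15  -13.629  0.00000   *
      6    15   -7.333  0.00000   *
      7    15   -2.581  0.02175
      8    15   -0.211  0.83569
      9    15   -0.889  0.38923
     10    15   -1.106  0.28736
```

Layers 1–6 (0–12 mm) show the injected ipsilateral ALFF reduction at
p < 0.005; layer 7 feels the 6-mm smoothing kernel's spillover but stays
above the corrected threshold, and the abnormal extent is recovered as 6
layers = 12 mm, matching the ground truth. The same objects drive the
between-group tests (`results.between_frame()`), the extent summary
(`results.extent_summary()`) and the layer-profile plot
(`results.plot_profiles("ALFF", "IIa")`).

A shell interface wraps the same pipeline:

```bash
perishell simulate --spec cohort.yaml --out cohort/
perishell cohort --data cohort/ --out cohort/group/
```

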