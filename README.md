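# starchmorph

Quantitative analysis of starch granule populations, built around the way
potato tuber starch is characterized in practice: imaging flow cytometry for
per-granule shape, conventional flow cytometry with bead calibration for
number-weighted size, and Coulter-counter-style volume-weighted size
distributions. The package targets researchers studying granule
morphogenesis — for example the contrast between wild-type ovoid granules
(which become less round as they grow), near-spherical granule mutants, and
lines whose granules fuse from multiple initiation points (hila).

Because such datasets are instrument measurements with no deposited raw
images, the package ships a first-class synthetic-population generator with
embedded ground truth, so every stage of the analysis is testable end to
end.

## What it computes

**Shape.** For a single-granule binary mask with boundary pixels at
distances `r_1 … r_m` from the centroid,

- circularity = `mean(r) / sd(r)` (population SD; scale-invariant, capped
  for vanishing variation),
- aspect ratio = `minor / major` of the second-central-moment ellipse,
  with `major = 4 sqrt(lambda_1)`, `minor = 4 sqrt(lambda_2)` from the
  eigenvalues of the mask covariance — 1 for a perfect disc,
- hilum count = number of prominent, well-separated local intensity minima
  inside the granule (>= 1 by convention).

**Single-object QC.** Frames pass three filters before measurement: spot
count 1 under a broad intensity mask (instrument window 0–600), spot count
1 under a stringent window (0–13) that resolves the bright cores of
attached granules, and a configurable shape gate. Measurement always uses
the broad mask.

**Size.** A forward-scatter model
`signal = k d_eq^p (1 + beta (1 − AR)) (1 + eta)` with piecewise-linear
log-log calibration against PMMA beads (1, 8, 30, 60 µm); number-weighted
gate fractions over `<2, 2–7, 7–15, 15–50, >50` µm; volume-weighted
histograms of the equivalent spherical diameter on linear bins.

**Composition and expression.** Iodine-ratio amylose
(`% = 100 (3.5 − 5.1R)/(10.4R − 19.9)` for the blank-corrected absorbance
ratio `R`), gravimetric moisture, glucose-based starch content with a
162/180 anhydroglucose correction, and Pfaffl efficiency-corrected relative
expression `E_ref^Ct_ref / E_target^Ct_target`.

**Statistics.** One-way ANOVA (raw values or mean ± SEM ± n summaries, the
latter exact), Tukey HSD with an insert-and-absorb compact letter display,
and Pearson correlation for expression-phenotype relationships.

## Worked example

```python
import numpy as np
from starchmorph import PopulationSpec, run_population
from starchmorph.sizing import (
    FscModel, bead_signal, fit_bead_calibration, fsc_signal, gate_fractions,
)

spec = PopulationSpec(
    n=500, shape_coupling=0.12, fused_fraction=0.02,
    doublet_rate=0.16, debris_rate=0.06, seed=42,
)
out = run_population(spec, pixel_size=0.5)
shapes = out["shapes"]
print(f"QC retention:          {out['qc'].retention:.3f}")
print(f"median aspect ratio:   {shapes.aspect_ratio.median():.3f}")
print(f"multi-hilum frequency: {100 * (shapes.n_hila >= 2).mean():.2f}%")

cal = fit_bead_calibration([(d, float(bead_signal(d))) for d in (1, 8, 30, 60)])
signals = fsc_signal(out["truths"], FscModel(beta=0.3, noise_sd=0.05, seed=42))
print(gate_fractions(cal.diameter(np.asarray(signals))))
```

prints

```
QC retention:          0.772
median aspect ratio:   0.868
multi-hilum frequency: 1.30%
{'<2': 0.0, '2-7': 0.336, '7-15': 0.266, '15-50': 0.398, '>50': 0.0}
```

The retention of 0.772 reflects the injected doublet/debris contamination
(the filter keeps almost exactly the true single-granule frames); the
median aspect ratio below 1 reflects the wild-type-like size-shape
coupling (`shape_coupling=0.12`); the multi-hilum frequency recovers the 2%
fused fraction among surviving frames; and the gate fractions summarize the
bead-calibrated size view of the same population.

A `starchmorph` console command exposes the same stages
(`simulate`, `qc`, `measure`, `density`, `size`, `assay`, `stats`,
`report`) for file-based workflows; see `starchmorph --help`.

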