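# Methods

## The measurement problem

Potato tuber starch granules are large (roughly 2–60 µm) ellipsoidal
particles. Three instrument views are commonly combined to characterize a
population: an imaging flow cytometer takes one grayscale image per event
and yields per-granule shape parameters after aggressive single-object
filtering; a conventional flow cytometer gives a number-weighted size
distribution through the forward-scatter (FSC) channel calibrated against
beads; and a Coulter counter gives a volume-weighted distribution that is
insensitive to shape. The package reimplements the computations behind all
three views plus the composition assays and the group statistics used to
report them, and pairs them with a synthetic granule generator so the whole
chain can be validated against ground truth.

## Synthetic populations

Granules are prolate spheroids `a >= b = c` whose major axis lies in the
image plane, so the true aspect ratio `b/a` equals the projected
minor/major ratio — the minimal 3-D model with a single shape parameter.
The sampled size is the projected-area-equivalent diameter `d`, drawn from
a lognormal mixture whose default modes sit at 4, 11, 23 and 40 µm
(sd_log 0.13; weights 0.32/0.30/0.24/0.14, smaller granules more numerous).
These defaults make the number-weighted density show four distinct local
maxima, the qualitative structure a tuber starch FSC trace exhibits.

Shape couples to size through
`AR_i = clip(1 − s·ln(d_i/d_0) + eps_i, 0.2, 1)` with `d_0` the smallest
mode mean, noise `eps ~ N(0, 0.04^2)` and default slope `s = 0.12`, which
puts a 40 µm granule near AR 0.72 — wild-type-like behaviour where only
small granules are round. `s = 0` with zero noise produces the decoupled,
perfectly spherical population used to emulate sphere-forming mutants. The
floor of 0.2 avoids degenerate needles.

A configurable fraction of granules is *fused*: two equal spherical lobes
(radius `0.75 d/2`, centre separation `max(6 µm, 0.9 r_lobe)`) with one
hilum per lobe, drawn from the upper size mixture (>= 18 µm) because fused
granules arise from multiple initiations that have grown into one large
particle. The size floor also guarantees that a fused granule presents a
single merged bright core to the stringent QC window (it must survive QC to
be counted), whereas two *touching separate* granules present two cores and
are rejected.

### Rendering

Each granule is rasterized as a filled lobe union: intensity at a plateau
of 613 units inside half the lobe radius, falling linearly to 50 at the
boundary, background at 5, additive pixel noise (SD 2). The boundary is
perturbed multiplicatively by a random low-order Fourier series in polar
angle with fractional SD `boundary_noise` (default 2%). Hila are Gaussian
intensity depressions (depth 80 units, width 12% of the lobe semi-minor
axis, floored at 0.4 µm) whose depth scales down linearly for lobes under
4 µm semi-minor — small granules show shallow hila, which both matches
optics and keeps their bright cores intact. Growth-ring modulation is
available but off by default (cosmetic; nothing measures it). Rendering is
bit-deterministic given the per-granule seed recorded in the truth table.

Contamination operates at the frame level: a `doublet_rate` fraction of
frames gains a second granule (half barely touching at 98% of the summed
support radii, half disjoint), and a `debris_rate` fraction is replaced by
a dim irregular speck (intensity 20–40, no bright core). Neither rate has a
published value; the defaults used in the study-like configuration
(0.16/0.06) were chosen once so that QC retention lands in the mid-70s to
low-80s percent band reported for real acquisitions, and are free
parameters everywhere.

### What the generator does not emulate

No optics: no birefringence (the maltese cross is replaced by a plain
intensity depression at the hilum), no refraction, no point-spread
function, no 3-D stacks, no camera gain artefacts. Real granule boundaries
are also rougher than a 5-harmonic Fourier perturbation. Consequently,
passing tests demonstrate that the *computations* recover known structure
from images with this statistical shape; they do not validate instrument
physics or absolute commercial-software feature values, for which only
orderings and distribution shapes are meaningful.

## Single-object QC

The instrument windows are kept verbatim (broad 0–600, stringent 0–13,
both inclusive) and interpreted on a declared brightfield-complement
channel `c = clip(613 − I, 0)`: background maps above 600 (excluded),
foreground maps inside the broad window, and only plateau pixels
(I >= 600) reach the stringent window. Components are 8-connected with a
4 px minimum area (suppresses single-pixel noise). Pass 1 requires exactly
one broad-window spot; pass 2 exactly one stringent-window core (this is
what separates attached granules that pass 1 merged); pass 3 applies
permissive, configurable area and aspect-ratio gates. Measurement reverts
to the broad mask. Retention on a contaminated synthetic set tracks the
true singlet-frame fraction to within 2 percentage points, with rare
(<1%) touching-doublet leakage, which mirrors the "predominantly single
granules" character of the real filtered datasets.

## Shape statistics

*Circularity* is `mean/SD` of centroid-to-boundary distances, boundary
pixels being foreground pixels with a 4-neighbour background. SD (not
variance) is used so the score is scale-invariant, which is what makes
granules of different sizes comparable; the source descriptions waver
between "variance" and "variation", and SD is the choice documented here.
Absolute circularity of near-perfect discs is resolution-limited (the
variation left is pixelation), hence the cap (default 1000) and the
contract that only orderings are meaningful for very round objects.

*Aspect ratio* comes from the eigenvalues of the mask's second central
moment matrix (`major = 4 sqrt(lambda_1)`), computed directly from pixel
coordinates; it is rotation-invariant and equals `b/a` exactly for ideal
ellipses. The centroid is the binary centroid, not intensity-weighted, so
hilum depressions do not bias it.

*Hilum counting* smooths the image (Gaussian, sigma 0.6 µm), finds strict
local minima at least 1 µm inside the mask, requires prominence >= 30
intensity units against the local surround within the 3 µm exclusion
radius, and suppresses minima closer than 3 µm (deepest first). Granules
with no detected minimum count as one hilum, since every granule has one.
At the default rendering parameters this recovers a 5% fused fraction
within binomial error at n = 2000 and produces no false positives on
singlets; small singlets' shallow hila are simply counted as 1.

The joint size-shape summary is a mass-normalized 2-D histogram of
(area, aspect ratio) with contour levels at mass quantiles, plus the
median aspect ratio per size decile — the curve used to decide whether a
population keeps roundness across sizes (spherical populations stay above
0.9 in every decile) or declines (coupled populations).

## Sizing

The FSC forward model is declared phenomenology, not optics: signal
`k d_eq^p (1 + beta (1 − AR)) (1 + eta)` with `d_eq` the volume-equivalent
sphere diameter, `p = 2` (scattering cross-section grows roughly with
projected area at these sizes), `beta = 0.3` (shape sensitivity: FSC
responds to major shape change), multiplicative Gaussian noise. Bead
calibration interpolates piecewise-linearly in (log d, log signal), exact
for a pure power law; queries outside the bead hull use end-segment
extrapolation and are flagged rather than refused. The Coulter emulation
weights each granule by its true (or spheroid-estimated) volume and bins
equivalent spherical diameter linearly. Together these reproduce the
two-instrument contrast the analysis leans on: spherizing a population at
fixed volume distribution moves the FSC-derived gate fractions but leaves
the volume histogram exactly unchanged.

## Assays

The composition formulas are implemented exactly as printed. The amylose
ratio domain is `[3.5/5.1, 19.9/10.4)`; outside it the formula is negative
or singular and the functions raise naming the violated bound. Within the
domain the estimate is continuous and strictly increasing but exceeds 100%
close to the singularity — such values are returned with a warning rather
than clipped, since the formula itself is the contract. The 620/535 nm vs
618/550 nm wavelength labels are treated as interchangeable names for the
long/short pair; only the blank-corrected ratio enters the formula. The
starch assay's anhydroglucose factor defaults to 162/180 (glucosyl residue
over free glucose mass). Pfaffl expression uses the within-sample form
`E_ref^Ct_ref / E_target^Ct_target` (values "relative to the reference
gene"); a two-sample calibrator mode is provided for the classic ratio
form. Genomic interval lengths use the 1-based inclusive convention
(`end − start + 1`).

## Group statistics

One-way ANOVA accepts raw values or (mean, SEM, n) summaries; the summary
path reconstructs within-group sums of squares from `SD = SEM sqrt(n)`,
which is algebraically identical to the raw computation — this exists so
published tables can be re-analysed. The post-hoc procedure behind
published letter annotations is rarely stated; Tukey HSD on the pooled
variance with an insert-and-absorb compact letter display is the standard
realization and is what is implemented (alpha configurable, default 0.05).
Letters are assigned in descending order of group mean, and the letter
relation is by construction the exact complement of the pairwise
significance relation. Pearson correlations use the t-transform p-value
with n − 2 degrees of freedom.

## Numerical choices and problem sizes

Tie-breaks and degenerate inputs: zero-variation circularity returns the
cap; hilum suppression keeps the deeper minimum; half-open gates put a
boundary diameter in the upper gate; duplicate bead diameters are errors
while unordered beads are sorted. Seeds propagate from a single population
seed through per-granule render seeds (all below 2^31), making truth
tables, images and reports byte-reproducible.

Test and acceptance runs use populations of 300–5000 granules rendered at
0.25–0.5 µm/px — large enough for binomial/multinomial checks at 3-sigma
tolerances and for stable medians, and small enough that the full suite
runs in well under a minute on one CPU. The headline acceptance quantities
use n = 1000 rendered granules each.

## Known limitations

- Absolute circularity values are not comparable to commercial-software
  features; only orderings and distributions are.
- The projection model puts the major axis in-plane; real granules tumble,
  so measured aspect ratios on real data are biased upward relative to the
  3-D truth in a way the generator does not emulate.
- Fused granules are modelled with exactly two lobes; higher-order fusions
  occur in strongly overexpressing lines and would be undercounted by the
  two-minimum geometry only insofar as hila sit closer than 3 µm.
- The FSC model is phenomenological; it is calibrated to be invertible and
  shape-sensitive, not to predict instrument voltages.
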