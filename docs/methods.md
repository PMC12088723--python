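# Methods

## Problem

Machine-learning classifiers on intravascular imaging — NIRS–IVUS
(near-infrared spectroscopy + ultrasound) and OCT (optical coherence
tomography) — segment coronary plaque into fibrotic (FT), calcific (Ca)
and necrotic-core (NC) tissue. Validating them against histology requires
putting a depressurized, shrunken, differently-sampled histology section
into pixel-wise correspondence with the pressurized in vivo frame, and
then quantifying agreement of plaque size and composition. `plaqueval`
implements that validation pipeline: co-registration by lumen-anchored
band warping, quantitative agreement statistics, region- and area-level
confusion analysis, macrophage comparison, and a synthetic matched-pair
generator that supplies ground truth for end-to-end verification.

## Co-registration model

Every plaque point is addressed in *band coordinates* anchored to the
lumen border: the normalized arc-length position `s ∈ [0,1)` of its
nearest lumen-contour point, and its outward physical depth `d` in mm.
Expert landmark pairs on the two lumen contours define a circular,
strictly monotone, piecewise-linear map between the two arc-length
parameterizations (validated at construction: crossing pairs are
rejected with the offending pair named). Depth is transferred unchanged
— radial scaling happens purely through the two pixel sizes — which is
the incompressibility assumption: plaque tissue is neither compressed
nor elongated between acquisitions. Under that assumption the warp
conserves each tissue class's physical area whenever the two frames
depict the same physical cross-section, whatever the resolutions; the
conservation tests exercise pixel-size ratios from 0.25 to 4 (pixel-space
lumen dilations 0.25–4) and lumen-collapse factors 0.7–1.0.

The warp is evaluated *inversely*: for every imaging-frame pixel within
the strip (depth 0 to `strip_depth_mm`, default the maximum outward EEM
depth of the imaging frame plus 0.5 mm, so the whole plaque is covered),
the source histology sample at `(map(s), d)` is pulled. Forward "strips"
pasted outward from the lumen would overlap or gap at concave segments;
the inverse form computes the same correspondence gap-free. Label
transfer is nearest-neighbour — labels are categorical, interpolation
would invent classes — implemented as a KD-tree lookup over histology
band pixels keyed by their own `(s, d)` coordinates. This single rule is
total and deterministic, degrades gracefully where lumen concavity makes
the normal field fold (the nearest band-coordinate key is still unique),
and is exact on the identity pair. A 2×2 subpixel supersample with
majority vote (ties to the smallest label code) halves quantisation bias
at class boundaries. Queries farther than 3 histology pixels from any
source key (off the histology image) are marked invalid; sources beyond
the histology EEM keep the background label and never enter plaque
tallies.

## Quantitative agreement

Per frame and source: EEM and lumen areas by the shoelace formula on the
annotated contours, plaque area = EEM − lumen, plaque burden =
plaque/EEM × 100, and per-class tissue areas by pixel count ×
pixel-size². Lumen areas are computed but never compared across sources:
a decompressed histology lumen is not commensurable with a pressurized
in vivo lumen. The agreement battery per quantity: Mann–Whitney U (exact
enumeration when both samples are ≤ 8 without ties, tie-corrected normal
approximation otherwise), Bland–Altman bias ± 1.96·SD (sample SD),
Lin's concordance correlation coefficient with population (1/n) moments
and a Fisher-z asymptotic 95% CI, Kolmogorov–Smirnov screening against a
fitted normal choosing between Student's t and the rank test, and
Pearson correlation for error-versus-burden relations. Differences are
histology − classifier, so negative bias = classifier overestimates.
α = 0.05 throughout; no multiplicity correction is applied.

## Qualitative agreement

Plaque-footprint overlap is reported in both directions (hist-only and
classifier-only, each as a share of its own total). Connected components
of one class in the warped histology form ROIs (8-connectivity by
default; components under 0.01 mm² are dropped as warp speckle — both
defaults are package choices, with 4-connectivity and other floors
available). Region level: each ROI contributes one count at (histology
class, classifier's predominant class inside it), ties broken by the
fixed priority Ca > NC > FT, mirroring the histology precedence rule
that overlapping Ca/NC is annotated Ca. Area level: per-pixel mm²
cross-tabulation. Histology tissue outside the classifier's EEM border
is invisible to the classifier and goes to a separate "missed" column;
classifier-unlabeled plaque inside the EEM goes to an "unclassified"
column — both excluded from the 3×3 metrics and reported separately, so
total tallied mass equals the warped histology plaque area exactly.
Metrics: sensitivity = diag/row, precision = diag/column, F = harmonic
mean, accuracy = 100 × trace/total; overall values are row-sum-weighted
averages, which makes overall weighted sensitivity ≡ accuracy/100
algebraically. Classifier "lipid" output is remapped to NC at load.

Frames entering a cohort analysis must be ≥ 0.4 mm apart along the
pullback; the filter is greedy from the most proximal frame (the
selection order is a package choice; only the spacing criterion itself
is inherited from the validation protocol).

## Macrophage analysis

A plaque pixel is macrophage-rich when the CD68-positive fraction within
a circular window, clipped to the plaque region, reaches 40%. The
neighbourhood underlying the published 40% concentration rule is not
specified anywhere we could find; the circular sliding window with a
0.1 mm default radius is this package's declared operationalisation (a
one-pixel window degenerates to the raw positive mask). Analysis covers
the entire plaque, not only fibrous caps. Histology and classifier
macrophage areas are compared per frame and in total, with Lin's CCC and
a count of frames where histology found macrophages but the classifier
none.

## Synthetic matched pairs

The generator stands in for cadaveric data and *defines the study
conditions*; defaults describe a mid-sized diseased coronary
cross-section: lumen radius 1.4 ± 0.15 mm with low-order harmonics
(orders 2–4, relative amplitudes 6/4/2%), wall thickness 0.45–0.75 mm
with a ±0.08 mm first-harmonic asymmetry (EEM area ≈ 12 mm², plaque
burden ≈ 50%), three Ca and three NC elliptical inclusions of
0.10–0.30 mm² each (total Ca ≈ 0.6 mm² per frame, matching reported
cohort means), imaged at 20 µm (catheter frame, 384² grid) and 8 µm
(histology). Inclusions are ellipses in (θ, depth) band coordinates, so
their physical areas follow from 1-D quadrature of ∬(r(θ)+d) dθ dd —
closed-form oracles independent of any rasterisation.

Histology degradation collapses the lumen radially by factor 0.8
(linear), optionally asymmetrically (±5%), while tissue keeps its
physical outward depth — precisely the incompressibility assumption the
warp makes, so the warp can in principle invert the degradation exactly
and recovery tests measure implementation error, not model mismatch. An
optional global scale < 1 shrinks tissue depths too, deliberately
violating the assumption for sensitivity studies. True landmark pairs
are emitted at equally spaced polar angles (16 by default).

The simulated classifier relabels tissue through a row-stochastic 3×3
misclassification matrix realized as a spatially correlated random field
(Gaussian-smoothed white noise, probability-integral-transformed): each
pixel's marginal relabeling law equals the configured row exactly, while
errors remain patchy with a configurable 1/e correlation length
(0.08 mm default). This generalizes wholesale per-region relabeling —
recovered as the correlation length grows — and keeps a 50-frame cohort
statistically capable of recovering each matrix cell to ±0.03, which
whole-region draws at realistic inclusion counts cannot do. Boundary
jitter is a smooth random displacement field (σ default 0.03 mm);
recovery experiments switch it off to isolate the relabeling channel. A
radial EEM bias emulates ultrasound over- or light-based
under-estimation of the vessel wall; OCT mode truncates the EEM at a
penetration depth and relabels tissue beyond an attenuation depth as NC
(signal-attenuation artefact), which populates the missed-outside-EEM
accounting. Frame i of a cohort draws from `SeedSequence((seed, i))`, so
any subset is reproducible regardless of generation order.

What the generator does *not* emulate: ultrasound/OCT texture, NIRS
chemograms, sectioning artefacts (tears, folds), non-radial tissue
deformation, and annotation error in the landmarks themselves. Passing
tests therefore demonstrate correctness of the analysis machinery under
the method's own assumptions, not robustness of the clinical
co-registration protocol to their violation.

## Numerical choices

* Contours are simple polygons, orientation normalized counter-clockwise
  at construction with the start vertex preserved (landmark arc lengths
  refer to it); degenerate or self-intersecting polygons are rejected.
* Nearest-point queries refine a dense (≥1024-sample) arc-length
  resampling by exact projection onto adjacent segments; equidistant
  ties break toward smaller arc length.
* Mask-counted tissue may exceed polygon plaque area by a rasterisation
  margin; records enforce consistency with tolerance
  (lumen+EEM perimeter) × pixel size rather than machine epsilon.
* CCC of two constant, equal vectors is reported as 1 in cohort tables
  (0 if unequal); CCC is NaN for cohorts of fewer than 3 frames.
* Degenerate F-scores (sensitivity + precision = 0) are reported as 0.
* Problem sizes in the shipped tests and the acceptance script — 384²
  imaging grids, 4-frame identity cohorts, a 50-frame recovery cohort —
  were chosen so each experiment's sampling error sits well inside the
  property bounds it checks.

## Known limitations

* The band-coordinate inverse warp is nearest-neighbour; sub-pixel
  anti-aliasing of class boundaries is out of scope, and double warps
  (there-and-back) lose ~2–5% of boundary labels at realistic pixel
  sizes.
* Histology tissue shrinkage is inverted only insofar as the
  incompressibility assumption holds; no elastic or diffeomorphic
  refinement is attempted.
* The two modalities' metrics are never statistically compared against
  each other; the datasets differ and the design does not support a
  head-to-head test.
* Landmark quality is taken as given; there is no automatic landmark
  detection or consistency optimisation beyond the monotonicity check.
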