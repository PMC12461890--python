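# Methods

## The quantification problem

In fly models of neurodegeneration, dying neurons leave empty cavities
(vacuoles) in the brain. On an H&E-stained paraffin section a vacuole appears
as an unstained white region enclosed by pink tissue; the background around
the section is also white. The measurement of interest is the vacuolated
share of the brain:

    percent vacuolation = 100 · V / (T + V)

where V and T are vacuole and tissue pixel counts. Background pixels are
deliberately excluded from the denominator so the number does not depend on
framing or cropping. The package solves the measurement as a three-class
pixel classification (background / tissue / vacuole) learned from sparse user
annotations, followed by a batch loop that classifies whole folders of
sections and tabulates the counts.

## Feature stack

Every pixel is described by a vector of filter responses computed on the
luminance channel (Rec. 601 weights), plus the raw R, G, B values which
retain hue. Per Gaussian scale σ the stack holds the Gaussian blur, the Sobel
gradient magnitude after pre-smoothing at σ, and both eigenvalues of the
scale-σ Hessian; all ordered pairs of scales contribute a difference of
Gaussians; six "membrane projection" planes aggregate line-kernel
convolutions over 30 rotations (sum, mean, sd, median, max, min). All filters
use reflect boundary handling, so constant images produce constant (or zero)
responses with no border artefacts.

Default scales are σ ∈ {1, 2, 4, 8, 16, 32} px (49 features in total). The
top scale is chosen to exceed the largest expected vacuole radius (20 px at
the default section geometry): a pixel deep inside a large cavity and a
background pixel beside the convex tissue edge are locally identical at small
scales — both white with pink somewhere nearby — and only a filter whose
support spans the whole cavity can see that one is enclosed and the other is
not. With the top scale at 16 px this ambiguity made segmentation quality
unstable from one training draw to the next; at 32 px it is resolved.

Membrane kernels are drawn analytically at each rotation angle: a centred
line segment with a Gaussian perpendicular profile (σ = 1.1 px) and
trapezoidal end caps, normalised to total mass = kernel size. Rasterising a
binary line and resampling it would make grid-aligned angles crisp and
oblique angles blurred, so the response to a thin border would depend on its
orientation; the analytic construction treats every angle identically, and
the ~1 px profile width sets the angular selectivity so that 30 rotations
cover orientation space with under 2% ripple in the max projection. Each
kernel therefore responds to a uniform field with exactly kernel_size × the
field value, at every angle.

## Classifier

A random forest (scikit-learn, 200 trees, √F features per split, fixed seed)
is trained on the feature vectors of annotated pixels. Classes are weighted
inversely to their training frequency: with scribble annotation the per-class
pixel counts reflect stroke lengths, not prior probabilities, and unweighted
training systematically under-votes the minority vacuole class. Prediction
averages the trees' class probabilities and takes the argmax, which breaks
ties toward the lowest class index — a fixed, documented rule. Pixels
excluded by a mask are forced to class 0 and never reach the forest.

Models persist as a joblib archive embedding the feature configuration, the
ordered feature names, the forest configuration and per-class training
counts; loading verifies the names against the embedded configuration and
classification refuses a stack whose feature names differ from the model's.

## Exclusion masks

Stained non-brain structures (eyes, gut) and tears reaching the tissue edge
confound the classifier — a rip is white and locally indistinguishable from
a vacuole. Instead of destructively cropping images, the pipeline accepts a
binary inclusion mask per image. The synthetic ground truth provides the mask
a careful user would draw: the tissue region plus a ~3 px margin, with any
rip cut out generously (6 px dilation). A thin sliver mask around the
artefacts alone is not enough: filters with large support still see the
artefact from beyond a few pixels, and white pixels near an isolated stained
blob imitate vacuole rims.

## Synthetic sections

Real stained sections are not distributable, so the generator renders the
structure the classifier must cope with: an elliptical tissue region
(~25–40% of a 192×256 canvas, jittered ellipse) rendered via per-channel
stain absorbances (eosin pink, with 2% of tissue pixels carrying darker
hematoxylin nuclei speckle), multiplicative stain-texture noise (sd 0.05),
additive sensor noise, and a 0.5 px optical blur; a near-white background;
non-overlapping elliptical vacuoles (radii 3–20 px, log-uniform with a
mixture knob between many-small and few-large regimes) carved out of the
tissue until a target area fraction is reached (rejection-sampled to ±20%
relative); optionally a white rip entering from the tissue edge and stained
distractor blobs outside the tissue. Ground truth is exact because vacuoles
are placed as analytic ellipses before rendering. Everything is bit-exact
reproducible under the section's seed parameter.

Cohorts draw a per-fly mean vacuole fraction from a Beta distribution
(genotype mean and concentration), then per-section fractions from a tighter
Beta (concentration 300) around the fly mean — several sections per fly from
several flies per genotype, matching how such experiments are sampled.

What the generator does **not** emulate: real staining variability between
batches, tissue-fold and knife artefacts, out-of-focus regions, anisotropic
textures, and vacuoles with partially stained content. Passing tests
therefore demonstrate that the pipeline recovers known truth under the
modelled contrast structure, not that any particular accuracy will hold on a
given real dataset — the intended workflow (retrain on a sample of your own
images whenever staining changes) carries over, the numbers do not.

## Annotation emulation

The scribble sampler reproduces the documented annotation behaviour (six
annotations per image, one or two per class) and was designed around the
failure modes observed during development:

* background: one closed trace hugging the **outside** of the section
  outline at ~3 px, plus one long stroke wandering the open background —
  near-boundary white is the region most easily confused with a vacuole, and
  omitting it produces a halo of false vacuoles around the section;
* tissue: one closed trace ringing a vacuole at ~3 px plus one interior
  stroke;
* vacuole: fills of individual cavities — a 12-vertex polygon kept 2 px off
  the rim for large vacuoles, a row-by-row brush stroke of the eroded
  interior for small ones; the component is chosen half the time
  proportionally to area (the obvious large cavities) and half uniformly
  (small ones).

Vacuole labels closer than ~1 px to the rim were found to cause systematic
over-detection (the transitional blur zone is claimed for the vacuole class)
and are deliberately avoided. With this protocol, ten training sections and
twenty held-out sections at planted fractions of 2–20%, the vacuole-class
Jaccard index across twelve independent seed sets ranged 0.84–0.98 (median
0.95, eleven of twelve ≥ 0.91), with mean absolute percent error ≤ 1.4
points and true-vs-estimated correlation ≥ 0.99 in every run.

## Validation statistics

The rater table is long-format (section, genotype, rater, percent). The
analysis chain follows the standard recipe for rater-agreement validation of
such classifiers: a square-root transform to normalise right-skewed
percentages; a balanced fixed-effects two-way ANOVA (genotype × rater, with
interaction) via an OLS fit, where balance makes type-I and type-III sums of
squares coincide — unbalanced tables are rejected rather than silently
reinterpreted; effect sizes as η² = SS_effect/SS_total; pairwise Pearson
correlation matrices over sections, plus the correlation of the classifier
against the arithmetic mean of the human raters; and critical correlation
thresholds r_crit = t/√(t² + df) from the Student-t quantile (two-tailed by
default; at 28 df this gives 0.361 and 0.463 for α = 0.05 and 0.01). A
degenerate table with zero total variance returns all-zero effects rather
than numerical noise. Tukey HSD for one-way genotype comparisons wraps the
standard studentized-range procedure.

The simulated raters used in tests score the true percent plus a per-rater
additive bias (drawn once per rater) plus independent Gaussian noise, clipped
to [0, 100]. For type-I calibration of the rater effect the bias is zero and
the ANOVA is run on the raw (untransformed) tables, where the F test is exact
under the null; the empirical rejection rate at α = 0.05 over 1000 tables is
within 5% ± 2%.

## Numerical and design choices

* Coordinates are 0-based, row-major, origin top-left; class maps save with
  the fixed palette purple/red/green for background/tissue/vacuole, and the
  palette inversion recovers the label array bit-exactly.
* Batch processing is sequential in lexicographic filename order; a failing
  image is logged and flagged in the results CSV, never fatal.
* An empty section (no tissue and no vacuole pixels after masking) is an
  error and a flagged row — reporting 0% would silently hide a failed
  classification.
* No minimum-vacuole-size filter is applied: detecting small disperse
  vacuoles that human raters miss is part of the method's point; a size
  floor would bias exactly the phenotype of interest.
* Membrane convolutions use FFT with explicit symmetric padding; all filter
  implementations agree with naive double-loop convolution oracles to
  better than 1e-6 relative error.
* Problem sizes in the test-suite and acceptance script (192×256 canvas,
  ten training and twenty held-out sections, 1000 simulated rater tables)
  are the package's chosen desk-scale defaults; they exercise every code
  path at full fidelity while keeping a complete run in the order of a
  minute.

## Known limitations

* The background/vacuole distinction ultimately rests on enclosure, which is
  only visible to filters whose support exceeds the cavity; vacuoles larger
  than the top Gaussian scale would need the scale list extended.
* Pixel-level Jaccard on thin rims is sensitive to the training draw; the
  percent-vacuolation estimate (the quantity of scientific interest) is much
  more stable because rim errors largely cancel between missed and gained
  pixels.
* The two-way ANOVA treats sections as independent units; fly-level
  clustering is not modelled (no mixed-effects option).
* The generator's Beta-based cohort model is a convenience, not a fitted
  biological model.
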