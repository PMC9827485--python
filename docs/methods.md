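# Methods

## Scope

`hemoscore` implements the desk-scale analysis of semi-quantitative
hemosiderophage scoring for equine EIPH: the total hemosiderin score (THS),
rater agreement and its decomposition, grade standardization against a
reference annotation set, diagnostic uncertainty around the THS ≥ 75
cut-off, and correlations with bronchoalveolar-lavage (BALF) chemistry.
Because the real 52-slide, 10-rater dataset is not bundled, a synthetic
study generator reproduces its *structure*; every statistical routine is
data-agnostic and accepts real annotation CSVs with the same schema.

## Scoring

A slide's THS is `100 * mean(grade)` over all annotated macrophages
(grades 0–4), range 0–400.  Conventions:

- **All annotated cells count.**  Raters label *at least* 300 cells; the
  score uses all of them, not a truncation to the first 300.
- **Minimum cell count.**  Fewer than 300 cells raises
  `InsufficientCellsError` unless `allow_fewer=True` (used for reference
  sets, standardized subsets and sparse images) — mirroring the protocol
  rule that excludes slides with < 300 scorable macrophages.
- **Cut-off tie.**  THS exactly 75 is EIPH-positive ("< or ≥ 75"); the
  cut-off is configurable.
- **Grades are integers.**  Fractional grades are rejected, not rounded.
- **Content thresholds.**  The grading literature defines a verbal continuum
  from "no hemosiderin" to "filled"; the package fixes one canonical mapping
  from continuous pigment-area fraction *p* ∈ [0,1] to grades: bin edges
  (0.02, 0.25, 0.50, 0.75), lower-inclusive (grade = number of edges ≤ *p*).
  These edges are an artifact convention shared by the generator and the
  image grader, and are config-exposed everywhere.

## Annotation matching and grade standardization

Two annotation sets of one slide are paired by centre distance with a 50 px
radius (12.5 µm at the 0.25 µm/px scan scale — about one macrophage
diameter).  The assignment is **one-to-one, maximum cardinality, minimum
total Euclidean distance**, solved per connected component of the candidate
graph with the Hungarian algorithm; nearest-neighbour matching without the
one-to-one constraint would let one reference cell absorb several rater
annotations.  Numerical conventions:

- the radius test compares squared distances, so behaviour at exactly 50 px
  is not subject to square-root rounding;
- exact ties between optimal assignments are broken towards lower input
  indices by an infinitesimal index-ordered cost perturbation (scaled far
  below any representable distance gap within a component), which also makes
  the matched set order-independent in the generic distinct-distance case.

`standardize_grades` keeps the rater's matched annotations (their
coordinates and identity) but substitutes the matched reference grade;
unmatched annotations are dropped.  This isolates *cell-selection*
disagreement from *grading* disagreement.  Grade confusion (5×5 matrix,
accuracy, one-off fraction, which-side-is-higher fraction) is tabulated over
matched pairs only.

## Agreement model

The design is fully crossed with a single measurement per cell of the
design: every rater scores every slide once.  The model is

    y_sa = mu + slide_s + annotator_a + e_sa,

with independent random effects.  The reference estimator is ANOVA
method-of-moments from the balanced design's expected mean squares
(σ̂²_e = MSE, σ̂²_a = (MSA − MSE)/S, σ̂²_s = (MSS − MSE)/A); negative
solutions are truncated to zero with a warning.  An optional REML estimator
maximises the exact three-strata restricted likelihood of the balanced
crossed design (slide contrasts, annotator contrasts, interaction) and is
cross-checked against the MoM path in the tests.

Two ratio summaries are reported, because the field's usage of "ICC" is
ambiguous for this design:

- `icc_agreement` = σ²_s / (σ²_s + σ²_a + σ²_e) — the conventional
  single-measure agreement ICC;
- `error_partition` = σ²_a / (σ²_a + σ²_e) — the share of *measurement
  error* that is systematic (between raters) rather than random.

Both are always computed and labelled; neither is asserted to equal any
externally reported value.

**Error reduction** from grade standardization fits the decomposition to the
raw and the standardized THS tables and reports
`1 − component_std / component_raw` (overall error σ²_a + σ²_e, between-rater
σ²_a, residual σ²_e) in percent; a reduction over a zero raw component is
undefined and reported as `None`.

**Measurement errors** are `e_sa = y_sa − mean_a(y_s·)` (deviation from the
slide's mean rater score); they sum to zero within each slide.  The **80%
uncertainty interval** takes their 10% and 90% quantiles — linear
interpolation of order statistics, the numpy default convention, chosen
because the published bounds depend on an unstated convention; the
convention is config-exposed via `coverage` and the quantile code — and maps
them around the cut-off: `[75 + q10, 75 + q90]`.  By default errors from all
slides (both stains) are pooled.

## Synthetic study generator

The generator states one explicit world and keeps it fixed:

- **Design**: 26 BALF samples × 2 stains (Prussian blue, Turnbull blue);
  per-slide macrophage counts uniform on [596, 8954]; paired slides share
  the sample's severity.
- **Severity and content**: per-sample severity ~ U(0,1).  Cell pigment
  content is a two-component Beta mixture indexed by severity σ: with
  probability σ the cell draws from Beta(1+4σ, 5−3σ) (high content, mean
  rising with severity), otherwise from 0.02·Beta(1,3) (bounded below the
  grade-1 edge, so a severity-0 slide is uniformly grade 0 and scores THS
  0).  No distributional form is published for real slides; this shape is a
  package choice that spans the full 0–400 score range with roughly half the
  slides EIPH-positive.
- **Geometry**: cells sit on a jittered square grid (pitch 140 px, jitter
  ±15 px), guaranteeing centre spacing ≥ 110 px > 2 × the 50 px matching
  radius, so matching is geometrically unambiguous at defaults.  0-based
  pixel coordinates, x rightward, y downward, 0.25 µm/px.
- **Distractors**: 35% additional non-macrophage leukocytes (near-zero
  pigment) interleaved on the same grid; they are excluded from the
  ground-truth annotation set and serve as targets for misidentified rater
  annotations.  (BALF contains abundant non-macrophage cells; 35% also keeps
  the binomial tail of the misidentification draw below the supply on
  300-cell slides.)
- **Raters**: each profile has a signed `threshold_shift` added to all grade
  edges (negative ⇒ lower thresholds ⇒ higher grades — the dominant
  systematic error of human experts), Gaussian per-cell perception noise
  (default sd 0.05), a selection pattern (uniform random, clustered fields,
  or meander — the three styles observed among experts), coordinate jitter
  (sd 10 px, truncated just inside the matching radius; the true magnitude
  of human placement error is not published, so this default is ours), and a
  misidentification rate (default 0.23, calibrated to the reported ~77%
  matched fraction).  The default ten-rater cohort uses shifts evenly spaced
  from −0.09 to +0.01: mostly negative, reproducing the experts' tendency to
  over-grade relative to the reference.
- **Chemistry**: iron = baseline + slope·(THS/400)·density^0.25 ·
  LogNormal(0, 0.6), censored below the 0.4 µmol/L detection limit (a
  censored slide carries the limit value plus a flag, and enters rank
  correlations as a tie at the limit).  The noise multiplies the
  THS-dependent term so that a zero-signal slide is always censored.  RBC
  count and hemoglobin are lognormal draws independent of the THS: they mark
  acute bleeding, not the chronic hemorrhage the THS measures, and their
  near-zero correlation is itself a property under test.
- **Determinism**: all randomness flows through `numpy.random.SeedSequence`
  substreams keyed by (stage, slide, rater); one master seed reproduces
  every output byte-for-byte.

## Image rendering and the rule-based grader

Rendered slides are a *stand-in* for scanned cytology, not a photorealistic
model: macrophages are rotated ellipses (axes ~30–38 × 24–32 px) of pale
cytoplasm with an offset Nuclear-Fast-Red nucleus; hemosiderin is painted as
blue pixels (hue shifted slightly for the Turnbull variant) covering an
exact pixel count equal to content × cell area, cytoplasm first, always
sparing a small nucleus core (4% of axes squared) so even grade-4 cells
retain a detectable nucleus — hence the rendered pigment fraction can fall
short of the requested content by at most ~0.04.  Distractors render smaller
and anucleate.  Additive Gaussian noise (sd 2.5 counts) finishes the image.

The grader classifies pixels by HSV windows (blue pigment, red nucleus,
near-white background, cytoplasm as remainder), takes connected components
of cell pixels after morphological closing, splits oversized components by
watershed on the distance transform, **rejects components without a
nucleus** (the stand-in for the experts' difficulty distinguishing
macrophages from other cell types), filters by area (1200–6500 px²), and
grades each detection by its pigment pixel fraction through the canonical
thresholds.  Its output is an ordinary annotation set under the reserved
rater id `"algorithm"`.

A green image-round-trip test therefore establishes that detection, nucleus
gating, pigment quantification and grading are mutually consistent with the
renderer — it says nothing about performance on real scanned slides, whose
colour variation, focus artefacts, overlapping cells and debris are outside
this model.

## What a green run does not establish

- No claim is made about the real study's numerical results (ICC, accuracy
  percentages, uncertainty bounds); those require the real slides and
  raters.  The synthetic world reproduces structure and directionality, and
  its parameters are fixed a priori, not fitted to published values (except
  where the published value *is* the parameter: study dimensions, cell-count
  range, misidentification rate, detection limit, cut-off, radius).
- The diagnostic-accuracy pooling ("all raters combined") is the
  observation-level mean over rater × slide calls, which equals the mean of
  per-rater accuracies in a complete design; the mean-annotators reference
  includes the evaluated rater (leave-one-out is available but off by
  default).
- Unbalanced designs, ICC confidence intervals, ROC sweeps of the cut-off
  and real-WSI ingestion are out of scope.

## Numerical edge cases

- Constant THS tables: all components zero; ratio summaries reported as 0
  with a `degenerate` flag.
- Negative MoM variance estimates: truncated to zero with a warning.
- Spearman correlation of a constant vector: NaN (undefined flag); pipeline
  runs with < 3 slides report NaN correlations.
- Grade confusion with no divergent pairs: divergent-pair fractions reported
  as 0 with a `no_divergent` flag.
- Rater jitter is radially truncated at 0.98 × the matching radius, and
  misidentified annotations sit on distractor cells ≥ 110 − 49 px from any
  true macrophage, so by construction genuine annotations stay matchable and
  misidentified ones never match.
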