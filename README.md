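# hemoscore

Cytologic scoring of exercise-induced pulmonary hemorrhage (EIPH) in horses,
as a tested, reusable pipeline: the **total hemosiderin score (THS)**,
annotation matching and grade standardization, interobserver variance
decomposition, diagnostic uncertainty intervals — plus a synthetic study
generator (slides, biased raters, BALF chemistry, rendered iron-stained
images) and a rule-based image grader, so the whole analysis is exercisable
at desk scale with a known ground truth.

## The score

EIPH leaves its trace as hemosiderin inside alveolar macrophages
(hemosiderophages) recovered by bronchoalveolar lavage.  Under an iron stain
(Prussian blue or Turnbull's blue), each of *n* ≥ 300 enumerated macrophages
receives a discrete grade *g<sub>i</sub>* ∈ {0,…,4} for its
intracytoplasmic hemosiderin content, and

> THS = 100 · (Σ *g<sub>i</sub>*) / *n* ∈ [0, 400],  EIPH-positive ⇔ THS ≥ 75.

Human raters apply the verbal grade definitions with personal thresholds, so
the THS carries a large *systematic* between-rater error on top of random
error.  The package quantifies this with a fully crossed two-way
random-effects decomposition

> y<sub>sa</sub> = μ + slide<sub>s</sub> + annotator<sub>a</sub> + ε<sub>sa</sub>

reporting σ²-components, the agreement ICC σ²<sub>s</sub>/(σ²<sub>s</sub>+σ²<sub>a</sub>+σ²<sub>e</sub>),
the error partition σ²<sub>a</sub>/(σ²<sub>a</sub>+σ²<sub>e</sub>), the
error reduction achieved by exchanging rater grades for reference grades of
cell-matched annotations (≤ 50 px centre distance, optimal one-to-one
assignment), and an 80% uncertainty interval — the 10%/90% quantiles of the
rater measurement errors mapped around the 75-point cut-off, inside which a
single rater's diagnosis is not reproducible.

## Worked example

Simulate the default study — 26 slide pairs in two stains with 596–8954
macrophages per slide, ten raters each labelling 300 cells with systematic
grade-threshold bias, perception noise and 23% misidentified cells, iron
chemistry censored below 0.4 µmol/L:

```python
from hemoscore import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7), "out/")
print(report["agreement"]["raw"]["error_partition"])
print(report["agreement"]["error_reduction"]["between_annotator_pct"])
print(report["agreement"]["uncertainty_interval"])
print(report["matched_fraction_mean"])
```

which prints (runs in ~15 s; rendering of images is off by default at this
slide size):

```
0.6399...            # 64% of the measurement error is systematic between raters
99.33...             # grade standardization removes ~99% of it
{'q_low': -16.0, 'q_high': 12.2, 'lower': 59.0, 'upper': 87.2, ...}
0.7704...            # 77% of rater annotations match a ground-truth cell
```

So for this simulated cohort, a single rater's THS between ≈59 and ≈87 does
not reproducibly decide the EIPH diagnosis, most of the disagreement is
reproducible rater bias, and swapping rater grades for the matched reference
grades removes nearly all of it — the qualitative behaviour expected of
semi-quantitative hemosiderin grading.

The same pipeline is available from the shell:

```bash
hemoscore run --config config.yaml --seed 7 --out out/
hemoscore simulate --out study/          # manifests, ground truth, annotations
hemoscore ths --annotations study/annotations.csv --out ths.csv
hemoscore match --set-a a.csv --set-b b.csv --out match.json
hemoscore agree --table out/ths_raw.csv --out agree.json
hemoscore score-image --image slide.png --slide-id S1 --out algo.csv
```

Small configs (set `render_images: true`) also render each slide to an RGB
image — elliptical macrophages with a Nuclear-Fast-Red nucleus and blue
pigment granules covering a pixel fraction equal to the cell's hemosiderin
content — and score it with the rule-based detector under the rater id
`"algorithm"`, which flows through matching, agreement and diagnostics
exactly like a human rater.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly constructed annotation sets, the THS of a slide
whose 300 enumerated macrophages all carry the maximum grade 4 and of one
whose 300 macrophages all carry grade 1, and writes the scores as JSON.

See `docs/methods.md` for the statistical model, generator assumptions,
numerical conventions and known limitations.
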