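# slofgrade

Automated grading of hull biofouling severity in underwater inspection
images, with statistically principled benchmarking of any grader — human
or model — against a group of experts.

## The problem

Biofouling (organisms accumulating on immersed surfaces) on ship hulls is
a biosecurity pathway for marine non-indigenous species, and regulators
increasingly require in-water inspections.  Reviewing the imagery is
expensive expert work.  `slofgrade` implements a pipeline that:

1. grades each image on the 3-class **SLoF** (Simplified Level of
   Fouling) scale — 0: no fouling organisms (biofilm/slime allowed);
   1: patchy macrofouling (1–15% of the surface covered); 2: heavy
   macrofouling (16–100% covered);
2. trains an **ordinal-regression CNN** that emits one raw score per
   image, with per-sample loss weights w_c = N/(K·n_c) that undo the
   heavy class imbalance of survey data, under vessel-grouped 5-fold
   cross-validation;
3. turns scores into classifiers by **precision–recall thresholding**:
   two binary tasks (fouling: SLoF > 0, heavy: SLoF = 2), with per-task
   cutoffs chosen on the combined out-of-fold PR curve at 50/80/95%
   recall floors, and model quality summarised by mean average precision
   (AP = Σᵢ (Rᵢ − Rᵢ₋₁)·Pᵢ, averaged over the two tasks);
4. benchmarks a grader against an expert group via **ordered label
   pairs** (k experts on n images give n·k·(k−1) within-group pairs and
   n·k candidate-vs-group pairs), comparing precision/recall with
   two-sided Fisher exact tests and agreement with a one-sided
   two-proportion **non-inferiority z-test** at a 5-percentage-point
   margin (H0: the expert group is at least 5 points better; reject at
   α = 0.05 to conclude non-inferiority).

Real hull-inspection datasets are held by biosecurity agencies and are
not public, so the package ships a first-class **synthetic data module**:
procedural hull images with an exact macrofouling mask (hence exact
coverage and SLoF grade), vessel-grouped styles, manifests reproducing
the published survey structure (10,263 images at a ≈76/17/7% class mix;
an 841-image test split containing a 120-image expert-group subset), and
simulated expert raters whose agreement is high on clean and heavily
fouled hulls and lower on patchy fouling.

## Worked example

```bash
slofgrade demo --out demo_run --seed 0
```

generates 600 images (300/180/120 per grade) over 30 vessels, trains the
tiny CNN out-of-fold, thresholds, and benchmarks against three simulated
experts.  It prints

```
oof mean AP 0.944, test mean AP 0.895; report in demo_run/report
```

i.e. the scorer nearly separates both binary tasks on held-out vessels.
`demo_run/report/thresholds_table.csv` starts

```
split,task,recall_target,threshold,precision,recall
validation,fouling,0.5,0.961573,1.0,0.5022
validation,heavy,0.5,1.818209,1.0,0.5
validation,fouling,0.8,0.462966,0.8293,0.9067
```

— at the 50%-recall (high-precision) policy every flagged image truly has
fouling, at the cost of missing half of them; the 80% policy trades some
precision for recall.  `label_pairs_table.csv` mirrors the expert
benchmark: for example the simulated expert group agrees with itself on
85.6% of fouling-task pairs (Wilson 95% CI 0.816–0.888), and each
candidate row carries its Fisher p-values and non-inferiority p-value
against that reference.

The same stages are available individually (`slofgrade generate`,
`rate`, `score`, `train`, `thresholds`, `run --config cfg.yaml`), and as
library functions (`slofgrade.generate_dataset`, `pr_curve`,
`select_threshold`, `tost_noninferiority_prop`, ...).

## Layout

- `src/slofgrade/synthetic.py` — procedural images, manifests, simulated
  raters and scores
- `src/slofgrade/model.py` — ordinal-regression scorer (numpy CNN),
  class weights, losses, grouped CV, ensembling, Sobol candidates
- `src/slofgrade/classifier.py` — PR curves, average precision,
  thresholding, evaluation
- `src/slofgrade/agreement.py` — label-pair constructions and agreement
  statistics
- `src/slofgrade/stats.py` — Fisher exact, non-inferiority z-test,
  Wilson intervals
- `src/slofgrade/pipeline.py`, `cli.py` — orchestration and the
  `slofgrade` command
- `docs/methods.md` — modelling assumptions, parameter choices and
  limitations
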