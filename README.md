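# frontgait

Front-view video gait analysis for scoring the severity of Parkinsonian gait
impairment (UPDRS part-III gait item, levels 0/1/2).

A subject walking toward a front-facing camera grows in apparent pixel
height and shrinks while walking away.  `frontgait` turns that observation
into a severity score:

1. **Tracking** — a pluggable person detector yields a per-frame silhouette
   bounding box (height *Sh*, width *Sw*) and a face detector yields the
   face height *fh*.
2. **Height signal** — *Sh* is divided by *fh* (removing stature
   differences), min-max normalized to [0, 1] (removing camera distance),
   smoothed with a 5-frame moving average, quantized into 5-frame partition
   means, and split into forward/backward walks at the height maximum.
3. **Gait features** — gait events are the points of amplitude increase in
   the quantized forward walk; consecutive inter-event intervals alternate
   as stance/swing and pair into strides.  Five features are extracted:

   | feature | meaning |
   |---|---|
   | `S_avg` | mean stride time (s) — short steps give low values |
   | `alpha` | DFA scaling exponent — irregular, shuffling progression |
   | `E` | amplitude entropy −Σ x·log₂x of the normalized walk |
   | `A_delta_C` | mean difference of consecutive 5-sample spectral centroids (Hz) — festination proxy |
   | `T` | valley-to-peak time (s) — walking-speed proxy |

4. **Classification** — a one-vs-all soft-margin SVM with the Pearson-VII
   universal kernel

   k(Vᵢ, Vⱼ) = 1 / [1 + (2‖Vᵢ−Vⱼ‖·√(2^(1/ω)−1) / σ)²]^ω,  ω = 0.2, σ = 1.0

   on standardized features, evaluated with stratified 10-fold
   cross-validation (per-fold accuracy, pooled confusion matrix, per-class
   ROC/AUC), plus a Kruskal-Wallis rank screen of each feature.

Because no clinical recordings are publicly available, the package ships a
first-class simulator (`frontgait.synthetic`) that generates labelled height
signals — staircase ascent with two plateau-and-rise steps per stride, turn
dwell, mirrored descent, class-dependent cadence/amplitude/irregularity,
festination bursts, detection noise — and can render them as silhouette
videos for end-to-end tests of the tracking stage.

## Worked example

```bash
frontgait simulate --out-dir sims --n-per-class 15 --seed 1
frontgait features sims/sim-*.csv --labels sims/labels.csv --out features.csv
frontgait evaluate features.csv --out report.json --rank-out ranks.json --seed 1
```

The feature table starts like

```
recording_id,S_avg,alpha,E,A_delta_C,T,label
sim-0-000,0.942857142857143,1.8263830450347847,141.55927816895309,0.010443864201348756,7.8,0
sim-0-001,0.8857142857142856,1.830274685562912,130.3962213038631,0.007223577716106522,7.24,0
```

— a healthy walk with ~0.9 s strides and a ~7–8 s approach.  The evaluation
report for this run contains

```
mean_accuracy 0.95        macro_auc 0.9963
confusion    [[15, 0, 0], [0, 13, 2], [0, 0, 15]]
per-class TPR 0: 1.00  1: 0.87  2: 1.00
```

i.e. 45 walks each tested exactly once across the 10 folds, with only two
level-1 walks confused with level 2.  The rank test (`ranks.json`) shows
`S_avg`, `E` and `T` increasing monotonically with severity (p < 1e-7) and
`alpha` decreasing, while the signed `A_delta_C` is not discriminative on
simulated walks (p = 0.24); see `docs/methods.md` for why.

The same machinery is available as a library — `GaitFeatureExtractor`
(detection series → feature table) and `PukSvc` (an sklearn-style
classifier) compose with scikit-learn pipelines and model selection.

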