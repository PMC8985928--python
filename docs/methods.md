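# Methods

## Problem and pipeline

E-scooter injuries carry no dedicated diagnosis code, so they can only be
found by reading free text. At health-system scale (tens of millions of
notes) reading everything is impossible; reading only keyword matches is
still expensive because "scooter" and the brand eponyms collide with
unrelated clinical language. The pipeline therefore has three statistical
layers, each implemented as its own module:

1. a **keyword prefilter** that reduces the corpus to candidates;
2. a **classifier** that concentrates human review on probable injuries;
3. a **two-phase verification design** that converts the review into
   unbiased estimates of what the classifier missed, and hence honest test
   characteristics, followed by patient-level epidemiology.

## The RMDL classifier

The ensemble follows the random-multimodel-deep-learning idea: rather than
tuning one architecture, draw several small architectures at random and
average their probabilities (soft voting, unweighted mean). Members come in
two families bound to two text representations:

* **Feedforward networks on TF-IDF vectors.** Smoothed idf
  (`log((1+n)/(1+df)) + 1`) with L2-normalized rows, vocabulary capped at
  2,000 stems with `min_df = 2`; hidden depth drawn from 1–3 layers and
  width from 32–128 units.
* **1-D convolutional networks on embedding sequences.** Embeddings are
  trained locally from the training corpus: symmetric 5-token window with
  1/distance weights, positive pointwise mutual information, truncated SVD
  to 50 dimensions, vectors `U·sqrt(S)` with a deterministic sign
  convention. Notes are padded/truncated to 60 tokens; unknown and padding
  positions share a zero vector. Conv stacks draw 1–2 layers, 16–48 filters,
  kernels 3–5, valid convolutions with ReLU, global max pooling, sigmoid
  head. Embeddings are frozen during training. A loader accepts external
  whitespace-delimited word-vector files when pretrained vectors are
  preferred.

Defaults are 3 + 3 members, dropout 0.2, 8 epochs, batch 64, Adam at 1e-3,
binary cross-entropy. The nets are plain numpy (forward, backprop, Adam):
at these sizes a framework adds nothing, and bitwise reproducibility under a
single spec seed is easier to guarantee. Architecture sampling and each
member's initialization/shuffling stream derive from that seed via
`numpy.random.SeedSequence` spawning, so a spec pins the whole ensemble.

Preprocessing is lowercase alphabetic tokenization, a frozen English
stop list, and the classic Porter stemmer iterated to a fixed point (plain
Porter is not idempotent — `glucose → glucos → gluco`; the fixed point makes
preprocessing a projection, which the test suite checks). Stop words are
filtered before and after stemming.

Labeled corpora grow over three cycles against a note pool, as in staged
model development on real EHR data: cycle 1 adds "scooter"-keyword notes,
cycle 2 adds brand/misspelling-keyword notes, cycle 3 tops up with randomly
sampled keyword-free negatives until the negative:positive ratio reaches
1,613:1,036 — the composition of the published final labeled corpus. Splits
are 70/30, label-stratified, seeded. "Possible" injuries count as negatives
for training and tallies (the conservative reviewer rule); an
`possible_as_positive` flag flips that downstream for sensitivity analysis.

## Triage and two-phase verification

A note is predicted positive iff its ensemble probability is **at or above
0.90** (boundary inclusive). All predicted positives are reviewed. Predicted
negatives are sampled uniformly without replacement per stratum — the design
that produced the published counts reviews every ED negative (f = 1.0) and a
10% outpatient sample — with sample size round-half-up of f·N (so 12,460
negatives at f = 0.10 give exactly 1,246). Sampling is seeded and drawn once
per stratum overall, not per month.

The sampled-negative arm is scaled by 1/f (Horvitz–Thompson): observed
false negatives FN and true negatives TN become FN/f and TN/f, which sum
back to the stratum's predicted-negative count up to rounding. Extrapolated
counts stay real-valued internally; rounding happens only at display.
Characteristics use the starred counts: sensitivity TP/(TP+FN\*),
specificity TN\*/(TN\*+FP), PPV, NPV, accuracy (TP+TN\*)/N,
LR+ = sensitivity/(1 − specificity) (NaN when specificity = 1), prevalence
(TP+FN\*)/N. Zero denominators yield NaN flags, not exceptions. Wilson 95%
intervals accompany each proportion.

Adjusted prevalence among keyword notes is reported in two modes:
**observed** (TP + observed FN over all keyword notes — the mode consistent
with the published 4.1% figure) and **extrapolated** (TP + FN/f). The
keyword-only workload counterfactual is confirmed positives divided by the
observed-mode prevalence.

## Epidemiology

Confirmed notes collapse to one case per `patient_id` (training and testing
patients deduplicate against each other). Confirmed notes more than 30 days
apart mark distinct accidents; 30 days matches the resource-abstraction
window and is configurable. A patient's index month is the earliest
encounter. Rates restrict to months where injury and trip series overlap:
the headline rate is the ratio of monthly means × 1e6 (equal to the ratio
of totals on a complete window — asserted to 1e-12 in tests); fatalities are
total deaths × 1e8 / total trips, counting only deaths from trauma at the
index visit. Months with zero trips get NaN per-month rates rather than
errors. Group comparisons use chi-squared on contingency tables **without
continuity correction** (so the 2×2 statistic equals the closed-form
Σ(O−E)²/E), ANOVA or Kruskal–Wallis for continuous variables; all two-sided.

## Synthetic data: what it emulates and what it does not

The generator produces the lexical collision structure the classifier must
resolve, with template sentences and slot-filled mechanism/device/anatomy
phrases plus shared clinical filler:

* **Classes.** Confirmed injuries (riders 93%, non-riders 7%), ambiguous
  "possible" notes (young patient, device type undocumented), confusers
  (push scooter 30%, knee scooter 20%, power wheelchair 10%, lime fruit 15%,
  Lyme disease 15%, Byrd 10%), and keyword-free negatives. Defaults: 5%
  injuries, 1% possible, 20% confusers.
* **Strata.** Injuries present mostly to the ED (82%), confusers mostly to
  outpatient clinics, reproducing the prevalence contrast that drives the
  published ED-vs-outpatient PPV gap (~50% of ED keyword notes are injuries,
  ~5–8% of outpatient keyword notes).
* **Patients.** 8% of injury notes are follow-ups of an existing patient
  (3–21 days later); ~1% of injury notes are second, distinct accidents
  (45–150 days later), exercising the gap rule. Patient-level resource use
  is drawn from the published cohort's marginal frequencies; the
  multiple-settings indicator is drawn directly at its 30% probability so
  patient-level aggregation is testable against a known target.
* **Seasonality.** Injury dates and trip counts follow a sinusoid peaking in
  July; trip series are rescaled so the total equals `round(mean × months)`
  exactly, with jitter that scales with the amplitude (amplitude 0 is exactly
  flat).

Deliberate simplifications: resource indicators are drawn independently, so
unions of overlapping indicators (e.g. "substantial resource use") run
higher than in the real cohort, where inpatient stays, major procedures and
multi-setting care concentrate in the same patients; template text is far
more separable than real clinical prose, so held-out AUC sits at ceiling and
says nothing about real-data accuracy; and there is no reviewer
disagreement, misspelling noise, or de-identification artifact. Passing
tests therefore validate the *pipeline arithmetic and estimators*, not
clinical performance — which is why the published review counts are packaged
as fixtures and every printed figure derived from them (PPV 91%/49%,
negative-arm positivity 27%/4%, ~500 extrapolated missed injuries, accuracy
92%, LR+ 12.2, adjusted prevalence 4.1%, workload 12,276, 115 injuries per
million trips, 19 fatalities per 100 million, 1,354 patients) is
regression-tested.

## Numerical and design choices

* Hyphens and apostrophes are word boundaries for whole-word keyword terms;
  "scooter" is substring-within-word so e-scooter/escooter/scooters match.
  Age exclusion precedes keyword exclusion in the tally (eligibility is the
  conjunction either way).
* AUC is the Mann–Whitney concordance with ties counted half (computed via
  scikit-learn, checked against exhaustive pairwise counting).
* Sample-size rounding is round-half-up; negative-sample draws sort ids
  first so plans are stable across dict orderings.
* The end-to-end suite runs at 5,000 generated notes with the default
  ensemble; unit-level training checks use 1 DNN + 1 CNN members on a
  ~1,500-note labeled corpus. Both corpora are regenerated at test time;
  no data files ship with the package.
* Model persistence is a directory bundle (JSON manifest + npz weights);
  the library API plus the `examples/` scripts are the intended interface —
  there is no shell CLI.

## Known limitations

* Extrapolated-count variance is validated by replicate simulation, not by
  closed-form variance estimators; no finite-population correction.
* The generator's taxonomy covers the documented confuser families only.
* Training determinism is exact under a fixed seed on a given platform;
  across BLAS builds results can differ at floating-point tolerance.
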