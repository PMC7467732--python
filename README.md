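# advagree

Tools for measuring — and stress-testing — the agreement between human
observers and deep image classifiers on *fooling adversarial images*: images
synthesised so that a classifier assigns them a confident label although they
look like noise or abstract patterns to people.

Claims that humans can "decipher" such images rest on forced-choice
experiments: on each trial a participant sees an adversarial image and must
pick one of *m* candidate labels (an *m*-alternative forced choice, or mAFC),
one of which is the classifier's label. How that agreement is *scored*, and how
the stimuli and response alternatives are *chosen*, turn out to drive the
conclusion. This package implements the full analysis pipeline around that
question for researchers in visual psychophysics and computational cognitive
science:

- **Simulated observer cohorts** (`advagree.cohort`) — nAFC response tables
  generated under parameterised strategies: uniform guessing ("blindfolded"),
  similarity-driven educated guessing over superficial image features, and
  machine mimicry; lognormal response times; per-participant randomisation of
  trial and label order; the sub-500 ms random-clicker exclusion rule.
- **Agreement metrics** (`advagree.agreement`) — the two competing summaries:

  *mean agreement*, the mean over participants of the per-participant
  percentage of trials matching the classifier; and the *counting metric*,
  the percentage of participants credited as "agreeing" (full credit above the
  chance count c = n·p, half credit at exactly c). For a blindfolded observer
  the agreement count is K ~ Binomial(n, p) with p = 1/m; with n = 48 trials
  at p = 1/48 the counting metric credits ≈45 % of pure guessers while mean
  agreement sits at the 2.08 % chance level — the package computes both the
  analytic null and Monte-Carlo cohorts. Per-image exact binomial tests,
  machine-label ranks, and pairwise network/human agreement probabilities
  round out the module.
- **Desk-scale attacks** (`advagree.attacks`) — a synthetic labelled shape
  dataset, a softmax classifier exposing class probabilities and exact input
  gradients, an iterative gradient-sign attack (step ε·sign(∇ₓ log p(t|x)) to
  a ≥0.99-confidence criterion), a direct-encoding evolutionary attack whose
  genome is the raw pixel grid, an ensemble transferability filter (keep
  images fooling ≥ k of K independently trained classifiers), and the standard
  224×224 centre-crop / per-channel normalisation contract.
- **Experiment designs** (`advagree.design`) — random vs *competitive* foil
  selection (foils sharing superficial features with the image), best/worst
  case stimulus selection from pre-study counts, 2×2 within-participant
  crossings, and pick-the-matching-image identification trials.
- **Inference** (`advagree.stats`) — one/two-sample t-tests with Cohen's d,
  two-way repeated-measures ANOVA with partial η², minimal-detectable-effect
  computation on the noncentral t distribution, and report assembly.

The main analysis surface is a model/results pair:
`AgreementModel(table).fit()` returns an `AgreementResults` with estimates,
confidence intervals, the test against chance and a `summary()` table.

## Worked example

Simulate 100 educated guessers on ten 4AFC trials whose foils were chosen
*competitively* (sharing 90 % of the image's superficial features), then score
them:

```python
import numpy as np
import advagree as ag
from advagree.design import ExperimentDesign, build_trials

rng = np.random.default_rng(0)
labels = tuple(f"lab{j:02d}" for j in range(12))
space = ag.make_feature_space(10, labels, overlap=0.9, rng=rng)
design = ExperimentDesign("competitive_foils", n_alternatives=4, label_pool=labels)
trials = build_trials(dict(space.target_labels), design, space, rng)
cohort = ag.simulate_cohort(trials, 100, ag.ObserverStrategy("feature_guesser"),
                            space, rng)
print(ag.AgreementModel(cohort).fit().summary())
```

```
Agreement analysis
==========================================================
participants                   100
trials per participant          10
chance                      25.00%
mean agreement              27.60%  (2.76/10 images)
  95% CI               [24.72%, 30.48%]
counting metric             47.00%
  blindfolded expects       47.44%
t vs chance             t(99) = 1.79, p = 0.0761, d = 0.18
==========================================================
```

The two metrics tell opposite stories about the same cohort: mean agreement is
statistically indistinguishable from the 25 % chance level, yet the counting
metric credits 47 % of participants — almost exactly what it would credit a
cohort of blindfolded guessers (47.44 %). The analytic null behind that
expectation is one call:

```python
pmf, expected = ag.blindfolded_null(ag.BinomialNull(48, 1/48))
# P(K=1) = 37.2%, P(K=2) = 18.6%, expected counting metric = 45.0%
```

A command-line surface wraps the same pipeline
(`advagree simulate-cohort | build-experiment | generate-attacks |
score-agreement | blindfolded-null | report`); every run writes a manifest
with its seed and config hash.

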