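# Methods

This note documents the models implemented in `advagree`, the defaults and
numerical choices, and what the synthetic-data generators do and do not
emulate.

## The agreement problem

A participant completes n forced-choice trials; on each trial they pick one of
m labels, one of which is a classifier's label for the displayed adversarial
image. Two summaries of the resulting response table are in competition:

- **Mean agreement.** Per participant, the percentage of trials on which the
  chosen label equals the machine label; report the mean over participants
  (and, for interpretability, the equivalent mean count of agreeing images,
  count = pct/100 × n). Chance is 100/m %.
- **Counting metric.** Let c = n·p be the expected agreement count under
  chance (p = 1/m). A participant is credited 1 if their agreement count
  exceeds c, ½ if it equals c, 0 otherwise; report the percentage of credited
  participants. When c = 1 (48 trials of 48AFC) this is exactly the rule
  "count everyone at 2+ agreements plus half of those at exactly 1".

**Generalised crediting.** When c is not an integer no participant can land
exactly on chance, so half credit cannot occur; the rule reduces to full
credit strictly above c. This generalisation is the package's own and is
needed for designs such as 2AFC over 48 trials (c = 24) or 10 trials of 4AFC
(c = 2.5).

**The blindfolded null.** For an observer guessing uniformly, the agreement
count is K ~ Binomial(n, p). `blindfolded_null` returns the exact pmf
(via `scipy.stats.binom`) and the expected counting metric
Σₖ pmf(k)·credit(k, c). For n = 48, p = 1/48: P(K=1) ≈ 37.2 %,
P(K=2) ≈ 18.6 %, P(K=3) ≈ 6.1 %, expected counting metric ≈ 45 % — the sense
in which the counting metric certifies "agreement" for observers who cannot
see the stimulus at all, while mean agreement correctly sits at 2.08 %.

**Per-image analysis.** For each image, an exact one-sided (greater) binomial
test of the number of machine-label choices against p. One-sided is a
deliberate choice — the scientific question is above-chance agreement — and is
flagged here because the convention is not universal. Raw p-values are
reported; a Bonferroni flag at α/(number of images) accompanies them, since no
particular multiplicity correction is canonical for this design. The machine
label's *rank* is its competition rank (ties share the minimum rank) in the
descending frequency order of chosen labels; a machine label never chosen
ranks one past the number of distinct chosen labels. Modal-label frequency
ties break lexicographically so results are deterministic.

**Pairwise agreement.** Network-network agreement is the fraction of
(image, unordered network pair) comparisons with equal labels — for K networks
and I images, I·K(K−1)/2 comparisons (10 networks, 20 images → 900).
Network-human uses (image, network, participant response) triples;
human-human, unordered participant pairs per image. Participants contribute
comparisons only for images they saw.

## Simulated cohorts

`simulate_cohort` draws one strategy per participant from a weighted mixture
(participants, not trials, are the natural unit of strategy variation), then
samples every response. Three strategies:

- *blindfolded*: uniform over the m alternatives;
- *feature_guesser*: softmax over similarity(image, label)/τ, default τ = 1 —
  the "educated guessing from superficial features" hypothesis;
- *machine_mimic*: the machine label with probability q, the remaining m−1
  labels uniformly otherwise — an upper-bound observer who has internalised
  the classifier.

Trial order and on-screen label order are randomised independently per
participant and stored in the table. Response times are lognormal,
rt = median·exp(σZ), default median 1500 ms, σ = 0.4 — the experimental
literature this emulates reports only a 500 ms exclusion rule, so these are
explicit stand-ins, and nothing downstream depends on them except the
exclusion logic. `exclude_fast_responders` removes whole participants whose
*mean* RT falls strictly below the threshold (a mean exactly at the threshold
is retained, matching the "below 500 ms" phrasing).

**Feature space.** `make_feature_space` gives every label a one-hot identity
feature (plus `dim` label-irrelevant nuisance dimensions drawn once per image
in [0,1]). An image loads 1.0 on its target label's identity feature and
`overlap` ∈ [0,1] on the identity features of a per-image designated foil set
(default 3 labels, drawn at random). Dot-product similarity then satisfies,
by construction: at overlap 0 the target strictly dominates every label; at
overlap 1 the target and its designated foils are indistinguishable; and a
feature-guesser's probability of choosing the target among competitive foils,
1/(1 + f·e^{(overlap−1)/τ}), decreases monotonically in overlap. This is the
minimal geometry that realises the "superficial commonality" account;
real images, of course, do not have orthogonal identity features.

**What the generator does not emulate:** learning or fatigue across trials,
perceptual noise, confidence, eye movements, or any image-computable notion of
similarity. Passing tests therefore certify the *analysis machinery* and the
*direction* of design effects (competitive < random foils, etc.), not human
behaviour on real stimuli — published human agreement percentages cannot be
reproduced without the human data.

## Desk-scale attacks

`make_shape_dataset` builds grayscale images (default 32×32) from up to 12
parametric pattern classes (bars, disk, ring, cross, diagonals, checkerboard,
gratings, frame, square) plus iid Gaussian pixel noise (default SD 0.15),
clipped to [0,1]. At zero noise the classes are their templates and are
separable by a nearest-centroid rule.

`train_classifier` fits a multinomial logistic (softmax) model on flattened
pixels with scikit-learn. Probabilities are softmax(Wx+b); the input gradient
of log p(t|x) is computed analytically as w_t − Σ_c p_c w_c, so the
`ClassifierHandle` gradient contract is exact (verified against finite
differences in the tests). Optimiser non-convergence is flagged in
`metadata["converged"]`, never silently ignored. The handle abstraction admits
wrapped pretrained deep networks — the `PreprocessSpec` retains the standard
224×224 centre crop with mean [0.485, 0.456, 0.406] and
std [0.229, 0.224, 0.225] for that use — but the test surface is the
desk-scale classifier.

**Iterative gradient attack.** Start from iid Uniform[0,1] pixels (the
distribution is a package choice; "independently sampled" admits several).
Each iteration steps by step_size·sign(∇ₓ log p(t|x)), default 1/255, clipped
to [0,1]; stop at confidence ≥ 0.99 (the customary fooling-image criterion) or
after max_iterations (default 500). The objective is the log-probability
rather than the raw logit — stabler near softmax saturation — while the stop
criterion is checked on the probability. No momentum or step schedule is used;
the method is the plain iterated fast-gradient-sign attack. The returned
confidence is always a fresh forward pass on the returned image. On a linear
softmax model the step direction reduces to sign(w_target − Σp·w), which the
tests exploit as a closed-form oracle.

**Direct-encoding evolutionary attack.** Genome = raw pixel grid; per-pixel
Bernoulli(0.01) Gaussian mutation (SD 0.1), population 20, elitism 1, parents
drawn from the top half. Elitism makes the best-of-generation confidence
non-decreasing, which is asserted. The hyperparameters are package defaults
(the classic fooling-image EA's exact settings are not public in this form);
direct encoding characteristically produces noise-like images, and a test
checks that EA images correlate less with the class templates than real class
members do.

**Ensemble transferability filter.** A candidate is retained when at least
k_min of the ensemble's classifiers "agree": argmax equals the target class
and (optionally) target-class confidence ≥ conf_min; conf_min defaults to 0,
reducing agreement to the pure argmax rule. The reported median confidence is
taken over agreeing (classifier, image) pairs of retained candidates only —
whether such medians are over networks, images or pairs is ambiguous in the
wild, so the convention is fixed and documented here.

**Centre crop.** For odd margins the window rounds toward the top-left
((H−c)//2), a tie-break that must be fixed for reproducibility.

## Experiment designs

*Random foils*: m−1 labels uniformly without replacement from the pool minus
the target minus its exclusion partners. *Competitive foils*: the m−1
non-excluded labels most similar to the image in the feature space —
an operational stand-in for the human experimenters' subjective selection —
deterministic given the space (stable sort; ties keep pool order), so foil
composition is seed-invariant while presentation order is not. Exclusion
pairs (semantically overlapping labels such as baseball/basketball) are an
explicit input list; such judgments cannot be derived. *Identification
trials* present one target-class fooling image among foil-class fooling
images; chance is 1/(foils+1). Best/worst-case stimulus selection takes the
argmax of most-like/least-like pre-study counts with lowest-index tie-break
(determinism for tests); best and worst may coincide and are then flagged.

## Inference

t-tests are two-tailed; Cohen's d = (mean − μ₀)/SD for one sample and mean
difference over pooled SD for two samples. The two-sample test pools variances
by default — matching the t(n₁+n₂−2) degrees-of-freedom convention of the
analyses this layer reproduces — with Welch as an option. The identities
t = d·√n (one-sample) and t = d·√(n/2) (equal-n two-sample) hold to 1e-9 and
are property-tested. The two-way repeated-measures ANOVA (both factors within
participant) is computed by pingouin behind the module's `AnovaResult`
surface, with partial η² = SS_effect/(SS_effect+SS_error); an incomplete
participant×cell crossing is rejected rather than imputed, and with 2-level
factors no sphericity correction applies. The independent check in the tests
is a hand SS decomposition on a 4-participant fixture.

`detectable_effect` solves power(d) = target by Brent's method on the
noncentral t distribution: paired/within designs use dof n−1 and
noncentrality d√n; between designs (n per group) dof 2n−2 and d√(n/2). For
very large noncentrality, where scipy's noncentral t returns NaN, a normal
approximation is substituted (power is ~1 there). For n = 200 within at
α = .05 and power .80 this yields d ≈ 0.199, and d ≈ 0.398 for 100 per group
between. Published power analyses for this design quote 0.18 (within) and
0.35 (between) without stating their assumptions (one- vs two-tailed,
correlation between repeated measures); the package reports its computed
values alongside and does not assert equality.

## Problem sizes and numerical choices

The Monte-Carlo cross-check of the blindfolded null uses 10,000 participants ×
48 trials (sampling is vectorised; ~15 s), with agreement within 3 Monte-Carlo
standard errors of the analytic values. Attack harnesses use 10 target classes
on the 32×32 shape classifier; direction-of-effect simulations use 250–300
participants per condition, sizes at which the simulated effects are far
larger than Monte-Carlo noise. Choice sampling uses inverse-CDF draws with the
final cumulative mass pinned to 1 to avoid edge leakage; softmax computations
subtract the maximum before exponentiation. All simulation entry points
require an explicit seeded `numpy.random.Generator`; identical seed and
configuration reproduce byte-identical tables.

## Known limitations

- The similarity space is a geometric idealisation; it supports ordering and
  calibration claims, not quantitative predictions about human observers.
- The desk-scale classifier is linear in pixels; attack dynamics against deep
  nonlinear networks (plateaus, gradient masking) are out of scope, though the
  handle contract admits them.
- The indirect-encoding (CPPN) evolutionary image family is not implemented;
  only the direct encoding is.
- The importer for deposited response data is configuration-driven (column
  map); it validates structure, not provenance.
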