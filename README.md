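# parentese

Computational analysis of early caregiver–infant interaction: an acoustic
detector of *parentese* (infant-directed emotional prosody), extraction of
caregiver→infant response bi-grams from coded behavioral event logs, and
binomial mixed-effects models of infant response probability.

## Who this is for

Researchers in developmental psychology and social signal processing who
study dyadic interaction in naturalistic recordings — e.g. retrospective
home-movie corpora of infants later diagnosed with autistic disorder (AD)
versus typically developing (TD) controls.  The package provides the full
analysis chain over (a) segmented caregiver speech and (b) time-stamped
behavioral codings, and ships a synthetic-data generator with recorded
ground truth so every stage is testable without any recorded corpus.

## The methods

**Parentese detector.**  Parentese is infant-directed speech with higher
pitch, slower tempo and exaggerated intonation contours.  Each utterance is
described by two feature streams: *segmental* — per-frame Mel-frequency
cepstral coefficients (25 ms frames, 10 ms hop, c1–c13 + log-energy) — and
*supra-segmental* — utterance-level statistics of the fundamental-frequency
contour (mean, sd, min, max, range, slope), the frame energy in dB, the
duration, and the voiced fraction, with F0 estimated by short-time
autocorrelation (75–600 Hz band, parabolic interpolation).  One
diagonal-covariance Gaussian mixture is trained per class and stream
(M = 12 segmental, M = 15 supra-segmental); the per-stream class scores
(mean per-frame log-likelihood for the segmental stream) are softmax-
normalised into posteriors and fused convexly,

```
P(c | x) = λ · P_seg(c | x) + (1 − λ) · P_supra(c | x),        λ = 0.4,
```

with the label taken as the argmax (ties → other speech).  Evaluation
reports accuracy, PPV and NPV with two-sided exact (Clopper–Pearson)
binomial 95% confidence intervals.

**Interaction database.**  Behavioral event logs (tab-delimited text; point
events plus regulation-up/down states; caregiver vocal events carry speaker
and speech type) are mined for *bi-grams*: every caregiver event followed
by an infant event within the 3-second window, lag ∈ [0, 3] s inclusive,
all pairs.  Infant items are grouped into six meta-behaviors (behavior with
object, plus receptive, expressive, active, exploratory and inter-subjective
behaviors toward people); counts satisfy the margin identities
`toward_people = Σ(5 subtypes)` and `total = toward_object + toward_people`.

**Response model.**  One record per caregiver vocalisation with a binary
indicator per response subtype, modelled as a logit GLMM

```
logit P(y_ij = 1) = x_ij'β + b_i,   b_i ~ N(0, σ²)
```

with child random intercept b_i; fixed effects are semester (successive-
difference contrasts: S2 vs S1, S3 vs S2), group (AD vs TD), speaker
(mother vs father) and speech type (parentese vs other speech).  The
marginal likelihood is maximised by adaptive Gauss–Hermite quadrature;
inference is Wald, two-tailed, α = 0.05.  Stratified post-hoc suites (per
group; per group × semester) and a parentese-use trend model are included.

## Worked example

```python
from parentese.synth import synth_corpus
from parentese.detector import ParenteseDetector, evaluate

train = synth_corpus(100, seed=1)      # 100 parentese + 100 other speech
test  = synth_corpus(50,  seed=2)
det   = ParenteseDetector().fit(train, seed=1)
rep   = evaluate([u.label for u in test], det.predict(test))
print(rep.summary())
```

prints

```
n = 100  (TP=50 FN=0 FP=0 TN=50)
 accuracy = 100.00%  (95% CI 96.38-100.00%)
      ppv = 100.00%  (95% CI 92.89-100.00%)
      npv = 100.00%  (95% CI 92.89-100.00%)
```

i.e. on clean synthetic speech with the default prosodic profiles (350 vs
210 Hz mean F0) the fused detector separates the classes completely; the
interval widths show the n = 100 evaluation uncertainty.  The same
arithmetic applied to a published-scale father-set confusion matrix
(TP=40, FN=10, FP=16, TN=34) gives accuracy 74.00% (95% CI 64.27–82.26%),
PPV 71.43% (57.79–82.70%), NPV 77.27% (62.16–88.53%).

The `analysis/` drivers run the full chain on a simulated study
(28 children, 3 scenes per semester, ~5000 vocalisations):

```
python analysis/01_train_detector.py       # detector training + evaluation
python analysis/02_simulate_study.py       # writes scene logs to scratch/
python analysis/03_extract_interactions.py # bi-grams, count table, proportions
python analysis/04_fit_response_models.py  # GLMMs, post-hoc suites, trend
```

Outputs land in `results/` (count table with margins, parentese
proportions by speaker/semester/context, GLMM coefficient tables).  On the
default design the models recover the planted structure: e.g. a group
deficit of −0.52 (SE 0.06) on any response, the strongest parentese
facilitation on receptive responses (+0.80, SE 0.08), and declining
parentese use across semesters (−0.46 and −0.31 for the successive
contrasts).

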