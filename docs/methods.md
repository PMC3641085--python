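# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Acoustic front-end

Audio is mono PCM, resampled to 16 kHz before framing (polyphase
resampling). Two feature streams are extracted.

**Segmental (MFCC).** Pre-emphasis 0.97; 25 ms Hamming frames at a 10 ms
hop with no padding, so a signal of `N` samples yields
`floor((N − 400)/160) + 1` frames; 512-point FFT power spectrum; 26
triangular Mel filters spanning 0–8 kHz; DCT-II (orthonormal) cepstrum
keeping c1–c13 (c0 excluded) with per-frame log-energy appended — a 14-dim
vector per frame. These are standard speech-recognition settings; the
choice of 13 coefficients + log-energy balances spectral-envelope detail
against the modest training-corpus sizes the detector is used with.

**Fundamental frequency.** Short-time autocorrelation on 40 ms frames
(10 ms hop), search band 75–600 Hz (configurable; must fit the frame).
The normalised autocorrelation is maximised over local peaks in the band;
to avoid octave-down errors on harmonically rich voices the *shortest* lag
whose peak is within 15% of the global maximum is selected, then refined
by parabolic interpolation. A frame is voiced when the selected peak
exceeds 0.45 and the frame RMS exceeds 2% of the loudest frame's RMS; both
thresholds were chosen so that pure noise is nearly entirely unvoiced
while fully voiced synthetic syllables are retained. On clean harmonic
signals in the 100–500 Hz speech range the estimator is well inside 2%
relative error (asserted in the suite).

**Supra-segmental vector** (11 dims): F0 mean/sd/min/max/range over voiced
frames and the least-squares slope of (time, F0); frame-energy mean/sd/
range in dB; total duration in seconds; voiced fraction. An utterance with
zero voiced frames carries NaN in the F0 fields and is flagged; such
utterances train and score only the segmental stream, the supra-segmental
stream contributing the class prior at fusion.

## The detector

Per class (parentese / other speech) and per stream, a diagonal-covariance
Gaussian mixture is fitted by EM with k-means initialisation
(`sklearn.mixture.GaussianMixture`, variance floor `reg_covar = 1e-6`,
relative tolerance 1e-4, at most 200 iterations), M = 12 components for
the segmental stream and M = 15 for the supra-segmental stream. The fit is
stepped one EM iteration at a time so the training log-likelihood trace is
recorded on the model. Exact EM never decreases the likelihood; because
the variance floor is re-added at every M-step, the recorded mean
per-sample trace can dip by up to roughly the floor's scale, so
monotonicity is asserted with an absolute tolerance of 1e-5
(`GmmModel.is_loglik_monotone`).

Scoring: the segmental utterance score is the *mean* per-frame
log-likelihood — the mean rather than the sum removes the duration
dependence, without which the fusion weight would implicitly vary with
utterance length. The supra-segmental score is the log-density of the
single statistics vector. The two streams' raw log-likelihoods differ by
orders of magnitude (hundreds of frames vs one vector), so fusion operates
on posteriors: each stream's two class scores are softmax-normalised
(uniform priors; the evaluation corpora are balanced) and combined
convexly with weight λ = 0.4 on the segmental stream. λ = 1 and λ = 0
reduce exactly to the single-stream classifiers. An exact posterior tie
resolves to the negative class (other speech).

Evaluation reports accuracy, PPV and NPV as percentages with two-sided
exact (Clopper–Pearson) 95% binomial intervals on each metric's own
numerator/denominator; a metric with an empty denominator is omitted
rather than reported as 0. The exact method is used because it reproduces
published father-set interval bounds to two decimals where normal
approximations do not.

## Event logs and the interaction database

Logs are tab-delimited UTF-8 with `#`-metadata comments (child, group,
semester, scene, duration) and columns
`time_s, actor, code, kind, end_time_s, speaker, speech_type`. Point
events take an instant; regulation-up/down are states with start and end.
Scenes shorter than 40 s — the corpus inclusion rule — are rejected at
load unless explicitly overridden. Ages bin into semesters as S1: ≤ 6
months, S2: 6–12 (12 inclusive, mirroring the inclusive lower bin), S3:
> 12.

The item→meta-behavior map (5 caregiver, 6 infant categories) ships as an
editable JSON resource; the item codes in it are package-defined
placeholders for a coding grid whose full item list is site-specific.
Reporting aliases (vocalizations↔expressive, seeking-people↔active,
orienting↔exploratory) are resolved by the map.

Bi-gram extraction emits **all pairs** (caregiver event, infant event)
with lag in [0, 3] s, both ends inclusive: "within the same second"
forces lag 0; the upper bound is taken inclusive on the integer-second
export granularity. One infant behavior may thus answer several caregiver
behaviors; nearest-only pairing is available as an option. State-type
caregiver events anchor the window at their start time. The
implementation is continually checked against a brute-force double loop
over all pairs (property-based and bulk random-log tests).

Counts aggregate by (group, semester, speaker, speech type, subtype) with
vocalisation denominators counted from the logs independently of
responses. Two views exist deliberately: raw bi-gram counts (the count
table) and a binary per-vocalisation indicator (the modelling unit) —
whether a vocalisation received ≥ 1 response of a subtype — because the
response-probability models need one Bernoulli trial per vocalisation.

Parentese proportions are computed per (group, semester, speaker) over all
tagged vocal events and, separately, over vocal events overlapping a
regulation-up state interval; an empty cell is missing, not zero.

Cohen's kappa is computed from the marginal formula
κ = (p_o − p_e)/(1 − p_e); with chance agreement 1 the only realisable
case is two identical constant raters, which returns 1. The
implementation is cross-checked against scikit-learn's in the suite.

## Response models

The GLMM is a Bernoulli-logit model with a child-level random intercept.
The marginal likelihood integrates the intercept by **adaptive
Gauss–Hermite quadrature** (default 15 nodes): per child, a Newton inner
loop finds the mode of the joint log-density in b, and Hermite nodes are
centred and scaled by the mode curvature; log-sum-exp is used throughout.
Optimisation is L-BFGS-B over (β, log σ) with log σ bounded in [−8, 3];
standard errors come from the inverse central-difference Hessian at the
optimum; Wald z and two-tailed p follow. The implementation agrees with
`lme4::glmer(..., nAGQ = 15)` on estimates, standard errors and the
random-intercept sd in a cross-check test.

Codings: semester uses successive-difference (backward) contrasts so the
two coefficients are the S2 − S1 and S3 − S2 log-odds changes; group is
AD vs TD (TD reference), speaker mother vs father (father reference),
speech type parentese vs other speech (other-speech reference). A factor
with a single observed level raises "contrast inestimable" (e.g. a
single-semester dataset). A constant response or a single subject is an
error; non-convergence and coefficients at the ±15 bound (suspected
complete separation) are flagged on the returned fit. With the
random-intercept variance driven to ~0 the fit reduces to ordinary
logistic regression (asserted against statsmodels GLM). No
multiple-testing correction is applied by default (per-coefficient
two-tailed tests at α = 0.05); the main four-factor model fits main
effects only, interactions being left to explicit configuration.

Post-hoc suites stratify (a) by group (semester + speaker + speech type)
and (b) by group × semester (speaker + speech type); degenerate strata are
reported as skipped with the reason rather than fitted.

## Synthetic-data generator

**Speech.** An utterance is a sum of harmonics (partials below 4 kHz,
1/h amplitudes) driven by a phase-continuous F0 contour — a sinusoidal
intonation contour with per-utterance random rate and phase around a
log-normally jittered mean (5% log-sd, a speaker-variability stand-in) —
gated into raised-cosine syllable bursts, with white noise at 25 dB SNR to
emulate the adverse acoustics of amateur recordings. Default profiles:
parentese 350 Hz mean F0, 200 Hz excursion, 2.5 syll/s; adult-directed
210 Hz, 60 Hz, 4.5 syll/s. The values realise the qualitative parentese
contrast (higher pitch, wider excursion, slower tempo) at a separation
typical of reported infant- vs adult-directed speech differences; they are
configurable. Each utterance stores its generating contour and voicing
mask, which downstream tests use as ground truth. Durations default to
2 s (within the 0.5–10 s validity range); sample format 16 kHz mono,
16-bit PCM on export.

**Interaction studies.** Defaults mirror the emulated corpus: 14 children
per group, 3 scenes per semester, 20 vocalisations per scene at 5-second
spacing (scene length 106 s, above the 40 s inclusion rule). Speakers are
drawn mother/father/other at 0.6/0.3/0.1. Mother parentese proportions
decline 0.60/0.45/0.35 over semesters, fathers 0.20/0.15/0.12 (the
published proportions are 40–60% for mothers and 15–20% for fathers);
a vocalisation falls inside a regulation-up state with probability 0.25,
which multiplies its parentese odds by 3.5 — reproducing the
"regulation-up is full of parentese" pattern. Response probabilities are
built on the logit scale with the signs the emulated study reports (S1→S2
rise, AD deficit, parentese facilitation concentrated on receptive
responses). Each vocalisation triggers at most one response per subtype
(a Bernoulli draw each; multi-response bursts off), at a lag uniform on
{0, 1, 2, 3} s. The 5 s spacing exceeds the 3 s window, so planted
responses are uniquely attributable — the extraction-exactness tests rely
on this. A child-level random intercept on the response logit is
available (sd 0 by default so empirical frequencies converge exactly to
the design probabilities; recovery tests use sd 0.5).

`simulate_records` generates response datasets directly from the GLMM
(covariates balanced at random within child, truth expressed in the same
contrast parametrisation the fitter reports), which is the
parameter-recovery surface: bias and type-I behavior are measured against
it at n = 2000 observations / 20 children scale.

**What the generator does not emulate** — and hence what passing tests do
not show about real corpora: natural speech (no formant structure,
lexical content, speaker identity or channel variability beyond additive
noise), camera/microphone artefacts, overlapping speakers, continuous
audio requiring segmentation (utterances arrive pre-segmented, as in the
emulated workflow's manual segmentation step), behavioral codings with
rater noise, and non-stationary response dynamics within a scene. The
synthetic detector accuracies (near-perfect on clean, well-separated
profiles) are an artifact property; published real-corpus accuracies
(74–87.5%) reflect a much harder signal and are not reproducible without
the original recordings, whose coefficients this package therefore does
not target.

## Problem sizes

The shipped tests and the acceptance script run the detector at train
100+100 / test 50+50 utterances of 2 s, the bi-gram oracle at 500–1000
random logs, and the mixed models at up to 100 replicates of n = 1000–2000
observations with 20 subjects — sizes chosen to give stable Monte-Carlo
margins (3-SE binomial bounds on every stochastic assertion) on a single
CPU in minutes.
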