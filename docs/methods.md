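# Methods

`edasleep` re-implements, as a fully tested pipeline, an analysis that
classifies sleep stages and obstructive sleep apnoea (OSA) severity
from a single peripheral signal: overnight electrodermal activity
(EDA). Because real full-night EDA recordings with expert hypnograms
are not shareable, the package pairs the analysis chain with a
synthetic-data generator that emulates the statistical structure the
features respond to. This note records the model choices, the defaults
and their rationale, and what the synthetic experiments do and do not
demonstrate.

## The processing chain

**Epochs.** All classification is per 30 s epoch, matching the scoring
grid of clinical sleep studies (1050 samples at the 35 Hz working
rate).

**Conditioning.** The raw 200 Hz trace is anti-alias resampled to
35 Hz (polyphase, 7/40; the signal mean is removed before resampling
and restored afterwards because the polyphase branches of the
anti-alias FIR carry ~1e-5 DC ripple). From the 35 Hz trace five
derived signals are built:

* `detEDA` — the trace minus its whole-night least-squares quadratic
  (computed on an abscissa scaled to [-1, 1] for conditioning).
  Detrending over the full night, rather than per epoch, is the
  deliberate reading of "the raw signal": the quadratic captures the
  subject-specific tonic drift that makes individuals incomparable.
* `sgEDA` — seventh-order Savitzky-Golay smoothing. The window length
  is a free parameter; the default 127 samples (~3.6 s) must exceed the
  polynomial order and is chosen to suppress content above the 3 Hz
  event band without flattening events. The filter weights are
  computed from the local least-squares problem on a scaled abscissa:
  the textbook unscaled normal equations lose ~6 digits at this order
  and window, and the package's exactness tests (degree-7 polynomials
  pass unchanged to 1e-8) require the well-conditioned form.
* `dwtEDA` — 4-level discrete wavelet transform (Daubechies-4 default;
  the family is not dictated by anything in the problem) with soft
  thresholding of the detail coefficients at the universal threshold
  sigma*sqrt(2 ln n), sigma estimated as MAD/0.6745 of the finest
  detail level. A zero threshold reproduces the input to 1e-10
  (perfect reconstruction), which the tests pin. The thresholded
  detail coefficients DL1-DL4 are kept: they feed the time-frequency
  features directly.
* `diffEDA` — `dwtEDA − sgEDA`, the band of activity that wavelet
  denoising retains but polynomial smoothing removes.
* Derivatives — first and second time derivatives of `eda` and
  `detEDA` via a linear-phase order-50 FIR differentiator (passband
  10 Hz, stopband 12.5 Hz, gain 2*pi*f in-band; designed with
  `firwin2`, antisymmetric). One pass per derivative order; the first
  50 output samples of each pass are discarded as start-up transient
  and the remaining samples carry an explicit offset (discard minus
  the 25-sample group delay) so epoch windows stay time-aligned.
  Derivatives are computed for `eda` and `detEDA` only — the feature
  table defines derivative features for exactly those four signals,
  and no diffEDA derivative appears anywhere downstream.

All conditioning stages are linear and deterministic; the test suite
asserts linearity to 1e-8 on random inputs.

## Events and storms

An EDA *event* is a band-limited (0.25-3 Hz) oscillation classified by
its phase count: positive/negative monophasic, biphasic, triphasic.
An EDA *storm* is a timespan of at least one minute containing at
least two events.

Detection is two-stage, and the reason is worth recording. A
monophasic deflection is one-signed, so its spectrum extends to DC;
after the 0.25 Hz high-pass edge of the detection band the filtered
excursion is necessarily zero-mean, with ringing side-lobes that reach
25-45% of the main peak for slow events. Counting lobes at a 25%
threshold on the band-passed trace therefore misreads slow monophasic
events as triphasic and shifts their onsets by more than a second.
The detector consequently:

1. finds candidate spans on the zero-phase band-passed trace (seed
   lobes at the amplitude threshold, default 0.5 signal units; span
   growth over neighbouring lobes above 0.5 of the peak; ring lobes
   above 0.1 of the peak consumed so they cannot seed duplicates; a
   2 s guard at the trace edges absorbs filtfilt start-up transients);
2. re-derives morphology and boundaries on the *raw* trace after
   subtracting a local linear baseline (interpolated between the trace
   medians flanking the span). There is no filter ringing in that
   domain, so the 25% lobe rule is applied there as intended, and the
   boundary lobes are trimmed at their 10%-of-peak crossings.

On traces with 50 well-separated planted events at high SNR the
detector recovers every event (F1 = 1.0 at ±1 s onset tolerance) with
full morphology agreement across seeds.

Storm semantics follow the sliding-window reading: every 60 s window
position containing at least two event onsets qualifies, and the union
of qualifying windows (clamped to the recording) forms the storm
spans. Two onsets more than 60 s apart never share a window and so
never form a storm by themselves. The per-epoch event/storm features
are the fraction of epoch samples inside an event (storm) and the
Euclidean norm of the raw 35 Hz epoch trace restricted to those
samples; using the raw rather than band-passed trace for the energy is
a configuration choice, documented here because either reading is
defensible.

A practical limitation, measured during development: the
two-events-per-minute storm criterion *saturates* once background
event rates approach 2/min — nearly every window qualifies and the
storm fraction stops carrying information. Storm-oriented analyses
therefore use the sparse-background scenario (below).

## The 77-variable feature set

Per epoch: 9 time-domain statistics for `eda` and `detEDA` (18); mean,
population variance, median and positive count for the four derivative
signals (16); maximum periodogram ordinate, its frequency and Fisher's
g for `eda` and `detEDA` (6); six statistics of each wavelet detail
level DL1-DL4 restricted to the epoch (24); Lyapunov exponent and
envelope extrema for `eda` and `detEDA` (6); autocorrelation sum and
maximum self-convolution of `diffEDA` (2); the four event/storm
features (4); and sex as a categorical column (1). Column order is
frozen and guarded by a schema test.

Conventions chosen where the quantities are underdetermined:

* **Mode / Shannon entropy** of a real-valued trace use a
  Freedman-Diaconis histogram (capped at 512 bins); the mode is the
  modal-bin midpoint; a single-bin (constant) distribution has entropy
  0.
* **SVD entropy**: Shannon entropy (nats) of the normalised singular
  values of the delay-embedded trajectory matrix, delay 1, dimension
  10; 0 for rank-one (constant) input.
* **Non-linear energy**: the Teager-Kaiser operator
  x[n]^2 − x[n−1]x[n+1], averaged over the epoch.
* **Fisher's g**: maximum periodogram ordinate over the sum of
  ordinates, zero frequency excluded; 0 for an all-zero epoch.
* **Variance** of derivative traces is the population variance
  (ddof = 0), stated here because either convention is common.
* **Lyapunov exponent**: Rosenstein-style — embed (dimension 5, delay
  4), pair every third point with its nearest neighbour outside a
  35-sample Theiler window, regress the mean log divergence over 30
  steps; units nats/sample; 0 for near-constant traces. The estimator
  is validated on a regular orbit (non-positive) and the fully chaotic
  logistic map (positive).
* **Envelopes** are peak-based: maximum of the local maxima and
  minimum of the local minima (falling back to the global extrema when
  a trace has no interior peaks).
* **diffEDA partners**: the feature table names only one signal for
  the cross-correlation/convolution pair, so both are taken against
  the signal itself. The autocorrelation sum then equals (sum d)^2,
  an algebraic identity the tests exploit.

**Normalisation** is column-wise z-scoring fitted on training epochs
only and applied frozen to test epochs — deliberately stricter than
pooled normalisation, which would leak test-subject statistics into
training. Zero-variance columns are left unscaled with a warning; sex
is excluded.

## Feature reduction

Pairwise Pearson correlations (zero-variance columns report r = 0 with
a warning) feed a greedy scan: anchors in ascending index order,
skipping eliminated anchors; each surviving anchor i eliminates every
later j with |r_ij| > r_th (default 0.8). Absolute correlation is the
default because an anticorrelated duplicate is as redundant as a
correlated one; `signed=True` restores the literal one-sided reading.
The scan is verified against an independently written brute-force
implementation on random correlation structures, and retained counts
are monotone in r_th. Sex never enters the scan. By default the
reduction is refit inside each training fold (no leakage); a pooled
whole-cohort mode reproduces the single-fit protocol.

## Classification and validation

Tasks: 5-stage (W, N1, N2, N3, REM), 4-stage (N1+N2 merged to light
sleep, N3 relabelled deep sleep), and OSA severity from AHI or ODI
(non-OSA < 5, mild 5-15, moderate-severe >= 15 events/hour; every
epoch inherits its subject's class), plus the binary OSA collapse.

Training balances classes with SMOTE: synthetic minority rows are
convex combinations of a seed row and one of its k = 5 nearest
same-class neighbours in numeric feature space; the categorical sex
column is copied from the seed row (interpolating a categorical code
would be meaningless). The classifier is an XGBoost gradient-boosted
tree ensemble; the hyperparameters are not dictated by the problem, so
defaults (300 trees, depth 6, learning rate 0.1, hist method, single
thread) are exposed in the configuration and logged with each model.

Validation is leave-one-subject-out (LOSO) — one fold per subject,
with normalisation, reduction, SMOTE and training all fitted inside
the fold's training portion — or *personalized*: a seeded random 25%
of the held-out subject's epochs joins the training set before SMOTE
and the remaining 75% is tested. Per-subject selection seeds derive
deterministically from the master seed. Macro F1 and macro recall
average per-class scores over the full task vocabulary (an absent
class contributes 0 — this depresses scores when a fold lacks a class
and is the intended behaviour under imbalance); fold-averaged scores
are the default, with epoch-pooled scoring available. The *adjusted
accuracy* of the 3-class OSA task collapses both OSA grades before
computing binary accuracy. All metric implementations are checked
against scikit-learn on random label vectors.

SHAP attribution uses exact TreeSHAP through XGBoost's native
`pred_contribs` path; per-sample additivity against the margin output
is asserted at 1e-3 every time values are computed. Importance is the
mean absolute SHAP value over epochs, summed across class outputs for
multiclass models (an aggregation choice; per-class tables are
recoverable from the raw contributions).

## The synthetic generator

A night is: tonic baseline + second-order polynomial drift + smoothed
random walk, plus planted events (flat-top-tapered half-cycle lobes of
a 0.25-3 Hz carrier: 1 lobe mono±, 2 bi, 3 tri; amplitudes log-uniform
in 1.5-6 signal units against a default detection threshold of 0.5),
plus storm episodes (60-120 s spans with >= 2 events at 6 events/min)
whose nightly rate is 0.5 + 0.25*min(AHI, 30) per hour — a linear
rendering of the qualitative association between apnoea severity and
sweating episodes — plus rectangular movement artifacts (0.5-2 s,
>= 5x the tonic level, 2/hour) and white noise (sd 0.1). Hypnograms
come from a first-order Markov chain that persists in the current
stage (p = 0.85) and otherwise resamples from a cyclically modulated
stage distribution (period 90 min; deep sleep favoured early in a
cycle, REM late). The modulation is zero-mean over a cycle, so the
long-run stage proportions converge to the requested mix; with the
clinical stage mix (12.2/16.5/32.5/18.2/20.6%) simulated proportions
agree within ±2 percentage points at 1e5 epochs.

Scenarios: the **strong-signal** staging scenario gives stages
distinct event rates (0.2-12/min), carrier bands (slow 0.25-0.7 Hz
events in N3, fast 1.8-3 Hz in REM) and amplitudes (largest in N3) —
the physiologically expected pattern, exaggerated so that the pipeline
power check has signal to find; the **null** scenario removes all
stage dependence (the chance-level control); the **OSA** scenario
keeps background events sparse (<= 0.8/min) so the storm statistic
reflects the planted AHI-coupled storm episodes rather than saturating
(see above). Cohorts draw per-subject AHI from three severity strata,
ODI as AHI with multiplicative jitter, and vary tonic level, event
amplitude scale and noise across subjects — the inter-individual
variability that makes personalization genuinely informative.

Problem sizes used by the tests and the acceptance script: 10 subjects
x 120 epochs (1 h nights) for the staging and null cohorts, 20
subjects for the OSA analyses. These are the package's simulation-size
choices; nothing in the code depends on them.

**What the synthetic experiments show — and don't.** They demonstrate
that the chain is implemented correctly end to end: exact filters,
perfect planted-event recovery, a reduction scan equal to brute force,
metrics equal to the reference implementation, chance-level scores
when no stage signal exists and strong scores when it does, a
personalization benefit under inter-subject variability, and storm
exposure that rises with planted AHI. They do *not* calibrate
real-data performance: real EDA has non-stationary tonic dynamics,
artifact structure, and stage-EDA coupling far weaker and more
idiosyncratic than the strong scenario plants. In particular, the
per-epoch OSA tasks sit near chance under LOSO at this synthetic
scale — the label is subject-level while storm exposure is episodic,
so most epochs of a severe subject are locally indistinguishable from
a healthy subject's epochs; the informative signal is the night-level
storm fraction, which is where the monotone AHI association is tested.

## Degenerate inputs and numerical edges

Constant epochs are valid everywhere (entropies and the Lyapunov
estimate defined as 0; histogram statistics collapse to the single
value). All-zero epochs give zero spectral features by convention.
The wavelet soft threshold skips shrinking when the estimated
threshold is 0 (avoiding 0/0 in the shrinkage formula). EDF
round-trips are exact to the 16-bit quantisation step of the channel's
physical range. Classifier determinism holds for a fixed seed and
single-threaded training.

## Known limitations

* The event detector's amplitude threshold and lobe rules are design
  choices calibrated on the generator's waveform family, not on real
  endosomatic recordings; the original detection algorithm this stands
  in for is not public.
* The storm definition saturates under dense event activity; analyses
  that rely on storm exposure must keep background rates sparse or use
  a rate-normalised statistic.
* Events are planted additively on the tonic trace; real skin
  potential responses have asymmetric rise/recovery shapes that the
  flat-top lobe family only approximates.
* No artifact-removal stage is implemented (none is specified);
  movement spikes flow into the features, and robustness to them is
  only probed, not guaranteed.
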