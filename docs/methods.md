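# Methods

`somnoscore` implements an epoch-based automated sleep-stage scorer and the
agreement statistics used to validate such scorers against human experts.
This note records the models, the defaults and why they were chosen, and
what the synthetic test bed does and does not demonstrate.

## Problem setting

Polysomnography is scored on 30-second epochs, each labelled with one of the
five AASM stages W, N1, N2, N3, R (this order is fixed throughout for every
matrix and vector). The scorer sees six mastoid-referenced EEG derivations
(F3-M2, F4-M1, C3-M2, C4-M1, O1-M2, O2-M1), two EOG channels, and a chin
EMG. The package splits the task into feature extraction, sequence
classification, and agreement evaluation, plus a synthetic generator so the
whole chain can be exercised and tested without clinical recordings.

## Feature extraction

Each 30-s epoch is divided into 29 sub-epochs of 2 s stepping by 1 s — short
enough that a sleep spindle (~0.5–1.5 s, ~13 Hz) or a K-complex dominates at
least one window. Per sub-epoch and EEG channel we estimate the power
spectral density with the multitaper (DPSS) method, time-bandwidth product
`nw = 2` and `k = 3` tapers: at 2-s windows this gives ±1 Hz spectral
concentration, a standard resolution/variance compromise. Sub-epochs are
mean-removed first (DC offsets are amplifier artifacts, not physiology).

Band powers use the conventional edges delta 0.5–4 Hz, theta 4–7 Hz, alpha
8–13 Hz, beta 13–30 Hz, integrated by the rectangle rule on the rfft grid.
Each band power is divided by the *epoch total power*, defined as the
0.5–30 Hz integral averaged over the epoch's 29 sub-epochs for that channel
pair; this keeps fractions scale-free (amplitude calibration and skull
impedance drop out) and bounded by the analysed range. PSDs from
contralateral channels (frontal, central, occipital pairs) are averaged to
reduce noise before any fraction is formed. From the fractions we derive
delta–theta, theta–alpha and delta–alpha ratios with an `eps = 1e-12`
denominator guard. Line length (sum of absolute first differences) and
Pearson kurtosis (m4/m2², undefined on zero variance) are computed per
sub-epoch per channel and contralaterally averaged; kurtosis flags
transient-rich windows (K-complexes), line length tracks amplitude and
waveform complexity.

Every sub-epoch track is summarized by four scalars — the linearly
interpolated 95th percentile, minimum, mean, and sample (n−1) standard
deviation — chosen so that both sustained content (mean) and transient
events (p95, sd) survive the pooling. EOG channels contribute the 0.3–5 Hz
spectral energy per sub-epoch (covers both slow rolling movements at
~0.25–1 Hz leakage and rapid eye movements), averaged over the two eyes;
the chin EMG contributes the mean-square of the mean-removed sub-epoch.
Both are summarized the same way. The layout is therefore
3 sites × 9 features × 4 summaries + 4 EOG + 4 EMG = 116 named columns,
exported with a machine-readable manifest; a fingerprint of the layout is
embedded in every trained model and checked at prediction time.

Degenerate epochs (EEG pair with vanishing total power, i.e. a dead
channel) are flagged and zero-filled rather than dropped, keeping the epoch
grid aligned with the reference hypnogram.

Open design points resolved here: the EOG "energy band" is a fixed-band
spectral energy with a configurable band defaulting to 0.3–5 Hz; line
length and kurtosis are computed per sub-epoch and summarized (an
epoch-level value is recoverable from the mean track if needed).

## Classifiers

Three variants share one contract (features in, one stage per epoch out,
deterministic for a fixed seed):

* **conv** — a 1-D convolution (16 filters, kernel 9) sliding along the
  feature axis within each epoch, ReLU, global mean+max pooling, then a
  32-unit dense layer; epochs are classified independently.
* **recurrent** — an Elman recurrent network (hidden 32) over the epoch
  sequence, carrying state across the night.
* **conv_recurrent** — the conv encoder's pooled output concatenated with
  the raw feature vector (a skip connection, so pooling does not bottleneck
  the epoch) feeding the recurrent network.

All are compact numpy networks (manual gradients, Adam at lr 0.01, seeded
initialisation, ≤ ~10⁴ parameters) — sized to train in minutes on one CPU.
The loss is cross-entropy with inverse-frequency class weights, because
stage prevalence is heavily skewed (N3 is only a few percent of epochs in
typical adult cohorts and would otherwise be ignored). Recurrent variants
train on chunks of `context_len = 9` epochs (4.5 min of context) and
predict on the full sequence. Features are standardized with training-set
statistics stored in the model.

Model selection uses Cohen's κ pooled over validation subjects — the same
chance-corrected metric used for final evaluation, which accuracy is not,
given the imbalance. Ties go to the smaller model, then registration order.
Splits are always by subject; epochs within a night are strongly dependent
and subject leakage would inflate every estimate. Predicted labels come
from an argmax whose ties break by the fixed stage order, and models
serialize to a single JSON bundle (text, byte-stable, reload-exact).

An optional post-processor relabels isolated single-epoch N1 intrusions
flanked on both sides by the same stage S ∈ {N2, R} to S, mirroring the
scoring-manual continuity convention that a lone low-amplitude
mixed-frequency epoch inside an established N2/REM run keeps the
surrounding stage. It is idempotent and off by default. No other
stage-transition rules are implemented.

## Agreement statistics

For two hypnograms of equal length we form the 5×5 confusion matrix (rows =
reference scorer). Cohen's κ = (p_o − p_e)/(1 − p_e) with the usual
marginal-product chance term; κ is undefined (reported as NaN) when both
scorers are constant on the same stage. The qualitative scale is the
conventional Landis–Koch one (breakpoints 0, 0.20, 0.40, 0.60, 0.80;
intervals closed on the right), implemented as a generic breakpoint/label
structure so alternative scales can be supplied.

Per-stage agreement collapses the matrix to a 2×2 table (a, b, c, d) and
reports Cicchetti–Feinstein specific agreement: PA = 2a/(2a+b+c),
NA = 2d/(2d+b+c), OA = (a+d)/n, as percentages. The "total" row pools a, b,
c, d over the five collapses (pooled PA then equals the raw percent
concordance — an identity asserted in the tests) and reports OA as the mean
of the per-stage OAs. Undefined ratios are NaN markers, never silently
dropped.

Uncertainty comes from a subject-level bootstrap: R = 1000 resamples by
default, each drawing subjects with replacement, pooling their confusion
matrices, and recomputing every metric; the report carries the median and
the 2.5/97.5 percentiles. Subjects — not epochs — are the exchangeable unit.
A metric undefined in more than half the resamples is reported undefined
with a diagnostic. Reports keep full precision; printed-style output rounds
half away from zero. A per-subject κ distribution summary
(median/mean/SD/min/max) is also available, and hypnogram overlays are
plotted on the conventional depth axis (W, R, N1, N2, N3 top to bottom).

## Synthetic polysomnography

Stage sequences come from a sticky Markov chain, `P = s·I + (1−s)·1πᵀ`,
whose stationary law is exactly the target stage mix π for any stickiness
s; the default mix (W 16.5%, N1 15.2%, N2 50.2%, N3 2.7%, R 15.4%) matches
adult clinical cohorts, and s = 0.9 gives mean stage bouts of roughly
5 minutes, qualitatively matching human sleep-bout structure. Chains start
in W, the natural beginning of a recording; at full-night length the
resulting transient bias on occupancy is a fraction of a percentage point.

Signals are rendered per epoch from per-stage recipes: Butterworth
band-limited noise components with site-specific gains (alpha ~10 Hz
occipitally dominant in W; low-amplitude mixed-frequency theta in N1/R;
high-amplitude frontal delta in N3), plus transient templates — spindles as
13 Hz Hann-windowed bursts (Poisson rate 2/epoch in N2) and K-complexes as
biphasic slow waves (rate 1/epoch in N2) — conjugate EOG deflections (blinks
in W, slow rolls in N1, rapid bursts in R) and stage-dependent EMG tone
with REM atonia. Default sampling rate 200 Hz, EDF physical range ±500 µV.
An alpha-deficient wake recipe (alpha amplitude suppressed, theta raised)
models the sizeable minority of people without a posterior alpha rhythm;
by default 10% of cohort subjects use it. Between-subject variability
jitters each subject's stage mix by a Dirichlet draw with concentration 13,
chosen to reproduce a realistic between-subject SD (~13 percentage points
for the N2 fraction). One RNG stream per subject is split by purpose
(hypnogram / signal / noise-scorer) through fixed sub-seed derivation, so
adding a feature never perturbs unrelated draws.

Synthetic "second scorers" resample each true label from a row-stochastic
confusion model, enabling exact expectations for every agreement statistic.

**What the generator does not emulate:** arousals and artifacts, realistic
EEG microstructure, respiratory events, drifting stage architecture across
the night, scorer errors that correlate in time, or the contextual AASM
re-scoring rules. Consequently, a high synthetic κ demonstrates that the
pipeline is wired correctly and that the classifiers can exploit the
constructed spectral separability — it is *not* evidence of clinical-grade
performance, which can only be established on real recordings.

## Problem sizes and numerical choices

The default synthetic cohort is 30 subjects × 120 epochs (1 h) at 200 Hz —
large enough for subject-level 80/10/10 splits and stable κ estimates,
small enough that the full chain (synthesis, extraction, training of all
three variants, bootstrap evaluation) runs in a few minutes on one CPU.
Statistics that need no signals use full-night hypnograms (960 epochs) and
larger cohorts. EDF quantization uses a symmetric 16-bit digital range so
that 0 µV is exactly representable; writing is lossy only at the
quantization step (~0.015 µV at ±500 µV range). Percentiles interpolate
linearly; standard deviations use n−1; band integrals use the rectangle
rule; all tie-breaks (argmax, model selection) are fixed and documented.

## Known limitations

* The classifiers are deliberately small; no claim is made that these
  architectures match production deep-learning stagers.
* Hypnogram-level post-processing implements only the single N1-continuity
  rule; full AASM transition logic is out of scope.
* The EDF layer covers continuous uniform recordings (EDF and EDF+C
  payloads); discontinuous EDF+D files and annotation streams are not
  parsed.
* Specific-agreement CIs use the percentile bootstrap; with very few
  subjects (< ~10) its coverage runs below nominal, as percentile
  bootstraps do.
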