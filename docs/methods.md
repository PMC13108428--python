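# Methods

## The model

`painecg` treats objective pain assessment as two linked problems. A binary
classifier decides whether pain is present, defined on subjective ground
truth (*no pain* iff the continuous 0–100 CoVAS rating is 0, *pain* iff it
is positive), and a regressor estimates intensity on the CoVAS scale — but
only for rows the classifier calls painful; everything else is reported as
intensity 0 exactly. Both stages are random forests: tree ensembles keep the
attribution methods exact (see below), handle the mixed scales and
collinearity of HRV features, and are cheap at inference time. The cascade
mirrors clinical reasoning (detect first, quantify second) and keeps the
regression conditioned on a physiologically meaningful regime, at the cost
that intensity errors inherit classification errors at the pain boundary.

Hyperparameters are deliberately ordinary: 100 trees, unlimited depth,
√p feature subsampling, decision threshold 0.5 (probability ties count as
pain), all seeded. Every choice the underlying study design leaves open —
window mode, label reduction, number of retained features, split grouping,
threshold — is a named config key so alternative readings are one-line
changes.

## Synthetic study conditions

The generator emulates a tonic heat-pain protocol: 5 temperature levels ×
8 repetitions × 10 s stimuli, rests drawn uniformly from 20–30 s, randomized
stimulus order, continuous CoVAS sampled on the ECG clock at 250 Hz. CoVAS
is exactly 0 at rest. During a stimulus it sits on a level-dependent plateau
with targets (0, 15, 35, 60, 85) — spanning the mild (1–30), moderate
(31–70) and severe (71–100) strata, with the lowest level warm but
non-painful — plus truncated Gaussian noise (SD 3 CoVAS units) on painful
levels. Zero-target plateaus stay exactly 0 so the label rule
(no pain ⇔ CoVAS = 0) is never blurred by rating noise.

Autonomic ground truth is parametric and explicit. Defaults: baseline
70 bpm, +0.15 bpm per CoVAS unit (≈ +13 bpm at CoVAS 85); baseline SDNN
50 ms suppressed by up to 50% at maximal pain; ECG amplitude raised by up to
30%; LF/HF 1.5 at rest rising by 2.0 at maximal pain; ECG measurement noise
0.02 mV. These magnitudes are in the range reported for strong acute
sympathetic activation and produce a *strongly separable* study: the default
conditions are a power check for the pipeline, not a difficulty benchmark,
and the held-out classes separate completely. The null-effect generator
(all gains zero) is the matching negative control: CoVAS labels exist but
the ECG carries no signal, and the fitted cascade must classify at chance.

RR tachograms come from spectral synthesis: two Gaussian spectral lobes
(LF 0.10 ± 0.015 Hz, HF 0.25 ± 0.030 Hz) with band powers in the prescribed
LF/HF ratio, inverse-FFT with random phases, variance scaled so the RR
standard deviation hits the SDNN target, then cumulative summation to beat
times (0.25 s floor per interval). An incomplete final beat is dropped
rather than truncated — a clipped last interval would be a gross outlier
that inflates SDNN. Beats are rendered as sums of Gaussian bumps
(P, Q, R, S, T); the whole template scales with the amplitude factor, so
peak-to-peak amplitude is exactly linear in it. What the generator does
*not* emulate: realistic 12-lead morphology, ectopy and artifact, motion
noise, respiration coupling, habituation/sensitization across repetitions,
or between-subject variability. Passing tests therefore demonstrate correct
method implementation and parameter recovery under clean conditions, not
clinical performance.

All randomness flows from one seed through counter-based splitting
(CRC-derived child seeds per named stage), so sessions, splits, fits,
bootstrap and permutation draws are individually reproducible and adding a
stage never perturbs another.

## Preprocessing and features

Channels are cropped to their overlapping interval and polyphase-resampled
to 250 Hz. The default analysis unit is the stimulus-aligned 10-s window
plus a 10-s baseline ending at each onset (stimuli closer than one window
length to the record start lose their baseline, with a warning); a
fixed-length mode (1000 samples, configurable stride) is available. Window
labels use the mean CoVAS by default (max is available) — the mean is the
least surprising reduction of a continuous rating and is what the tolerance
strata are defined on.

R-peaks: 5–30 Hz bandpass, squared gradient, 150 ms moving-average envelope,
peaks above 20% of the envelope maximum with a 250 ms refractory period,
refined to the raw R apex within ±60 ms. On noiseless synthetic ECG the
detector is within ±20 ms of the true beat (tests assert ≤ 4 ms typical).
Windows with fewer than two detected beats get NaN HRV cells — missing,
never zero.

Conventions in the battery: moments are uncorrected population estimators;
SDNN uses the n−1 sample SD; pNN50 counts strictly greater than 50 ms; the
RR histogram uses the standard 1000/128 ≈ 7.8125 ms bin; TINN is the base
width of the least-squares triangle (feet grid-searched over bin centers);
the tachogram is cubic-interpolated to 4 Hz before Welch (Hann, 60-s
segments, 50% overlap, shrunk with a warning on short records); band powers
are trapezoidal PSD integrals. Frequency-domain values on 10-s windows are
computed for battery completeness but are low-confidence by construction —
a VLF period exceeds the window itself — and routinely come out as
zero-variance columns that standardization flags and passes through. Both
`rr_std`/`sdnn` and `rr_mean`/`ibi_mean` are kept as duplicate columns for
battery fidelity; `hr_mean · ibi_mean = 60000` exactly.

## Explainability

Shapley values are computed two independent ways. The oracle enumerates all
feature subsets (≤ 12 features), evaluating f(S) as the model on the
explained row with out-of-coalition features replaced by background rows.
The production path exploits tree structure: against one background row, a
leaf is reachable under coalition S iff every path feature on which the
explained row and the background row diverge takes the explained row's
branch (set U) or the background row's branch (set V) according to
membership in S; such an AND-game has closed-form Shapley values
(|U|−1)!|V|!/(|U|+|V|)! per U-feature. Summing over leaves, trees and
background rows gives attributions identical to the oracle (tested to 1e−4,
observed at machine precision) in one pass per leaf. The same leaf
decomposition yields pairwise interaction values (half the change in φᵢ
when j is forced present versus absent); the diagonal is defined as the
remainder so rows sum exactly to φ. The background set is a seeded subsample
of training rows (default cap 64 in the pipeline): the interventional
reference distribution is a design choice, and training data is the least
surprising one.

Permutation importance shuffles one column at a time within the evaluation
split (baseline minus permuted accuracy or R², mean ± SD over repeats,
default 100 in the library, 50 in the orchestrated run). A caveat the test
suite documents deliberately: with duplicated or near-duplicate features —
which this battery contains by construction — single-feature permutation
importance is degenerate (shuffling one of a redundant pair costs nothing),
so cross-method rank-agreement checks are run on de-duplicated or
constructed graded-signal data, while modulated-feature top-rank checks run
on the ECG study itself.

PD/ICE marginalizes the partial-dependence expectation empirically over the
observed rows; PD is asserted to be the exact columnwise ICE mean. ICE
phenotype clustering centers each curve at its leftmost grid value (shape,
not offset) and applies seeded k-means with k = 3 by default; this is a
declared reconstruction of response-phenotype discovery, not a prescribed
procedure. The global surrogate is a depth-5 decision tree fit to the
model's own predictions, scored by held-out agreement and exported as
IF/AND/THEN rules.

## Evaluation

Pain is the positive class everywhere. Undefined ratios (no predicted
positives, zero variance) are NaN, never 0. AUC confidence intervals use a
stratified percentile bootstrap (2000 resamples by default) since no
analytic method is prescribed. Bland–Altman uses differences
predicted − actual, the n−1 sample SD, and the fixed 1.96 multiplier;
points on the limits count as within. Stratum scores bin *actual* CoVAS
into no-pain/mild/moderate/severe; pain strata are scored one-vs-rest on
the stratum membership of the predicted intensity, and the no-pain row
reports the specificity of the binary label. The pipeline evaluates the
regressor on held-out rows that are both truly painful and called painful —
the cascade's operating regime — so regression metrics are conditional on
detection.

## Problem sizes and numerical choices

The orchestrated run defaults to 4 sessions (320 windows, 80 per session),
80–100 trees, 12 explained rows against a 48–64-row background, 50
permutation repeats; the test suite uses 2–3 session studies. These sizes
give stable estimates for every statistic the suite asserts while keeping a
full run in tens of seconds. Degenerate inputs are defined rather than
accidental: empty RR lists produce empty signals, flat-line ECG produces
missing HRV, constant tachograms produce zero band power, single-bin RR
histograms produce triangular index 1 and TINN of one bin width,
zero-variance features stand out of correlation matrices as NaN.

## Known limitations

Synthetic validation only — no claim transfers to clinical ECG without
external data. The regressor never sees no-pain rows, so intensity is
unconditionally 0 below the detection threshold. Permutation importance on
the full battery is structurally degenerate under redundancy (documented
above). Frequency-domain HRV on 10-s windows is reported but physically
marginal; sessions long enough for 60-s Welch segments are needed for
meaningful band powers. The surrogate tree explains the classifier's
decisions, not the physiology.
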