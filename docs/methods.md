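# Methods

## Signal model and segmentation

The input is a subject's skin-conductance series (microsiemens) at a
fixed rate `fs` (4 Hz for wrist devices) with one affective-state label
per sample from {baseline, stress, amusement, other}; `other` absorbs
everything to be excluded (transients, meditation blocks, mixed label
regions). Candidate windows of `t_length` samples start on the fixed grid
0, t_step, 2·t_step, … over the whole signal (t_step = t_length −
t_overlap). A window is emitted only when every label inside it is
identical and not `other`; windows straddling a state transition are
rejected rather than relabelled, so a segment's class is always
unambiguous. The grid is anchored at sample 0 of the signal, not restarted
per label run: the purity test already handles run boundaries, and a
single grid keeps the emitted starts a strict subset of one deterministic
enumeration.

WESAD records label at 700 Hz against 4 Hz wrist EDA (ratio 175). Label
alignment reduces each 175-sample block to its label when uniform, else to
`other` — a conservative rule (a majority vote could smuggle transition
samples into "pure" segments). The alignment is the package's own choice;
nothing downstream depends on it beyond the four-code label contract.

## Preprocessing and spectra

Default preprocessing is per-segment mean removal. Raw conductance sits on
a tonic offset of several µS; without DC removal the 0 Hz bin dominates
every energy-based quantity and the half-energy frequency degenerates to
the lowest bin. Mean removal zeroes exactly the DC bin of the segment's
DFT and nothing else; it can be disabled (`preprocess="none"`) for
sensitivity analysis.

Spectra use the unnormalized forward DFT, kept one-sided over bins
0..N/2 with resolution fs/N. Two redundant controls over the DC/scale
question are exposed rather than one guessed intent: time-domain mean
removal (above) and an optional per-segment energy normalization of the
spectrum (`normalize="energy"`, dividing |X| by √Σ|X|²). The band features
are scale-covariant, so features default to raw (unnormalized) spectra;
normalization matters only for cross-segment spectral comparisons.

## Features

Per band [f_low, f_high): the arithmetic mean, the sample standard
deviation (divisor N_b − 1) and the maximum of the in-band magnitudes.
N_b is the *count of in-band bins* at the actual resolution — for 12 s
segments at 4 Hz a 1 Hz band holds 12 bins. Band edges are half-open by
default so a shared edge (1.0 Hz for the default bands) belongs to exactly
one band; a closed-interval rule is available (`edge_rule="closed"`) but
double-counts shared edges.

The half-energy frequency f_P/2 is the smallest bin frequency whose
normalized cumulative energy reaches 0.5, computed over the full spectrum
with the DC bin excluded by default (`include_dc` restores it). The
discrete first-bin rule is used deliberately: interpolation would invent
precision the 1/12 Hz grid does not have, and the discrete rule is
monotone, reproducible, and invariant under positive rescaling of the
signal. Segments whose retained bins carry no energy raise a typed error;
the pipeline drops such segments with a logged count (real conductance
never produces them).

Sequence analysis augments each base feature with its mean and variance
over the w most recent segments, using exactly w terms with divisor w for
the mean and the population normalizer 1/w for the variance (the two
windowed statistics intentionally share one window; the per-band standard
deviation above keeps the sample convention — each statistic follows its
own stated definition). Windows never span a subject or label boundary —
a mixed window would have no defined class — and the first w − 1 segments
of each uniform run yield no row (dropping beats padding: padded rows
would mix a fictitious steady state into V_w). With m = 2 bands: 7 base
features, 21 columns after expansion.

## Evaluation

LOSO: for J subjects, J models; each trained on J − 1 subjects' rows and
scored on the held-out subject; accuracy and F1 averaged unweighted over
subjects (never pooled over rows, so heavy recorders don't dominate).
Binary F1 takes stress as the positive class; the three-class task uses
macro averaging (the unweighted mean of one-vs-rest F1), with a class
absent from both truth and prediction contributing 0 under a logged
warning. The classifier roster is fixed and untuned: decision tree
(depth 10), 1-NN, 10-NN, random forests of 10/100 trees (depth 10,
balanced class weights), RBF SVM (balanced), bagged SVM (10 bootstrap
replicates of the RBF SVM, majority vote — the smallest standard bagging
construction), and AdaBoost over 10 random forests of 100 trees.
Features are standardized with train-fold statistics for the distance-
and kernel-based learners (kNN, SVM variants) and left raw for trees,
which are scale-invariant; the choice is config-exposed. All stochastic
learners take one top-level seed.

Time to detection: TTD = t_length + (w − 1)·t_step in seconds — the span
between the first and last raw sample one decision consumes. The
fixed-TTD grid iterates (t_length, t_overlap) with t_overlap < t_length,
keeps cells where w = (TTD − t_length)/t_step + 1 is a positive integer,
and LOSO-evaluates each kept cell; default ranges cover 16–240-sample
windows. The window sweep holds (48, 20) fixed and evaluates a list of w
values with 10-NN, pairing each score with its TTD.

## The synthetic cohort generator

Each subject is a tonic level (uniform in [2, 20] µS, with a Gaussian
random-walk drift of 0.005 µS per step) plus skin-conductance responses
(SCRs) arriving as a Poisson process and shaped as bi-exponential pulses
h(t) ∝ e^(−t/τ_d) − e^(−t/τ_r) with τ_r = 0.75 s, τ_d = 3 s, scaled so
the sampled peak equals the drawn amplitude, plus white Gaussian sensor
noise; the sum is clipped to stay above 0.05 µS. The default block plan
is baseline 600 s, amusement 300 s, stress 600 s per subject, six
subjects.

Class structure (defaults, per state — rate events/min, log-normal
amplitude median µS / log-SD, noise SD µS):

| state     | rate | amplitude       | noise | character |
|-----------|------|-----------------|-------|-----------|
| baseline  | 2    | 0.3 / 0.5       | 0.12  | sparse small SCRs, noisiest |
| amusement | 4    | 0.7 / 0.5       | 0.04  | bursty: rate redrawn every 60 s (log-normal, log-SD 2.0) |
| stress    | 8    | 0.8 / 0.3       | 0.02  | frequent large SCRs, stationary, quiet |

These choices realize the three contrasts the features exploit: stress
concentrates energy below 1 Hz (high band-[0,1) mean, low half-energy
frequency), baseline's noise floor pushes relative energy upward in
frequency (high f_P/2), and amusement's rate resampling creates
segment-to-segment variability that dominates the windowed variance. The
amusement burst dispersion and amplitude were set large enough that its
between-segment variance exceeds stress's even though stress SCRs are
individually larger — with weak burstiness, stress's Poisson count
fluctuations win on absolute scale and the variance contrast inverts.
The generator emulates event statistics and spectra only; it has no
motion artifacts, sensor dropout, posture effects, demographic variation
or label noise, so a passing end-to-end test demonstrates correct
pipeline wiring and feature-direction signs, not expected performance on
real recordings.

## Problem sizes and numerical choices

The default cohort (6 subjects × 1500 s at 4 Hz) yields ~1260 base
segments and 1152 sequence rows at the default segmentation — enough for
stable LOSO scores while the full suite runs in seconds. Statistical
gates run over seeds 1–10 and require 9/10 agreement, which tolerates one
unlucky draw without weakening the direction claim. Tolerances: DFT
against the direct-summation oracle at 1e−9 absolute; Parseval at 1e−6
relative; cumulative energy terminal value at 1e−9; exact-arithmetic
identities at 1e−12. Half-energy threshold comparison uses ≥ 0.5 − 1e−12
so a cumulative sum hitting 0.5 exactly (equal-energy split) selects the
lower bin. Ties in band maxima need no rule (max over reals); windowed
statistics use vectorized sliding views with no padding.

## Known limitations

* The WESAD adapter is exercised against synthetic records with the same
  key layout; behaviour on the real download (e.g. unexpected extra keys)
  is untested here.
* Band features assume the band lies within [0, fs/2]; no anti-aliasing
  or resampling is provided for other rates.
* The three-class macro-F1 convention and the feature-scaling policy are
  this package's choices where the field reports scores without stating
  either; both are configurable.
* No hyperparameter tuning, tonic/phasic decomposition, artifact
  rejection, or competing feature sets — deliberately out of scope.
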