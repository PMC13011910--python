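# Methods

`alphadrift` is an in-silico reconstruction of a covert alpha neurofeedback
study: participants passively watch a circle whose size is (in the
experimental conditions) driven by their own parietal alpha power in real
time, while the quantity of scientific interest — a spontaneous,
time-on-task increase of alpha band power — is independent of the feedback.
Because no human data ship with the package, every stage is validated on
synthetic sessions with known ground truth: the generator injects a
specified alpha drift, and the analysis chain is required to recover it (and
to recover *nothing* when nothing was injected).

## 1. Synthetic EEG generator

Each trial is the sum of three parts, per channel, in microvolts:

* **Broadband background** — Gaussian noise with a `1/f^gamma` amplitude
  spectrum (`background_exponent`, default `gamma = 1`, flattened below
  0.5 Hz, zero DC), independent per channel, scaled to
  `background_rms` (default 5 μV RMS). This reproduces the aperiodic EEG
  spectrum without biophysical modelling.
* **Four band-limited oscillators** — theta, alpha, SMR and beta, each a
  unit-RMS narrowband noise source (white noise, 3rd-order Butterworth
  band-pass, forward-backward) multiplied by a fixed spatial weight vector
  and a band amplitude. One source per band is mixed rank-1 across
  channels, which keeps the 6-channel ICA decomposition well-posed. Source
  bands are *inset* within the analysis bands (theta 4.5–7.5, alpha 9–11,
  SMR 12.5–14.5, beta 16–28 Hz): real rhythms are spectrally peaked (the
  individual alpha peak sits near 10 Hz), and a flat source occupying the
  full analysis band would place power exactly on the shared edge bins
  (8, 12, 15 Hz), leaking any alpha drift into the neighbouring bands'
  measurements. Analysis bands are unchanged (see §3).
* **Eye blinks** — raised-cosine transients of 100–400 ms at a Poisson rate
  (`blink_rate`, default 15/min) and amplitude `blink_amplitude` (default
  80 μV), mixed with the frontal-dominant weights
  (1.0, 1.0, 1.0, 0.5, 0.2, 0.05) over (Fp1, Fpz, Fp2, Fz, Cz, Pz). Each
  event is annotated, giving the ICA stage known targets.

Default band amplitudes (theta 2.0, alpha 4.0, SMR 1.5, beta 1.5 μV RMS at
the strongest channel) were chosen once so that the resulting band powers
fall in a plausible −10..30 dB(μV²/Hz) range; they are module constants,
not empirical claims.

**Time-on-task drift.** The alpha source amplitude for subject *i* at
session trial *t* is governed by a per-subject intercept and slope drawn
from normal population distributions (`alpha_trial_slope`,
`subject_sd_intercept`, `subject_sd_slope`). Two parametrizations exist:

* `drift_unit="uv"` (default): amplitude = intercept + slope·(t−1), linear
  in microvolts;
* `drift_unit="db"`: amplitude = intercept·10^(slope·(t−1)/20), so the
  alpha *band power in dB* rises linearly by `slope` dB per trial.

The μV-linear form is the plainer physical statement; the dB-linear form is
what the downstream linear model (fit on dB → z-scored power) estimates
without approximation, so the recovery harness (§5) uses it — with μV-linear
drift the dB trend is mildly concave and the estimand would need a
linearization constant.

Other bands are stationary, no feedback is ever coupled back into the EEG
(the study's null mechanism is encoded by construction, with the online vs
offline source arm changing only the display path), and trials are
generated contiguously through the 3-s preroll so there is no discontinuity
at trial onset.

**Counterbalancing.** Condition orders come from the four rotated
quadruplets (1342, 2413, 3124, 4231); each aligned block of four
participants receives a seeded permutation of the four, so any 4k aligned
participants use each quadruplet exactly k times.

**Seeding.** One master seed; per-subject and per-trial streams are derived
by counter-based `numpy` seed sequences, so any trial is reproducible in
isolation and every output is a pure function of (config, seed).

## 2. Online feedback engine

At each update instant (hop = sampling_rate/update_rate; rates 1, 5, 10 Hz;
first update at trial onset, enabled by the 3-s preroll) the engine:

1. zero-phase filters the trailing Pz buffer with the 1–20 Hz 4th-order
   Butterworth band-pass (forward–backward). The buffer is the preroll plus
   elapsed samples, capped at 10 s — this honours per-step zero-phase
   filtering while keeping the loop causal at the trace level (the emitted
   radius at update k depends only on samples up to that instant);
2. tapers the last 500 processed samples (2 s) with a *symmetric* Hann
   window and computes a single periodogram (no sub-segmentation — the most
   parsimonious reading of a 2-s window with a stated symmetric taper);
3. averages the spectral density at bins with 8 ≤ f ≤ 12 Hz inclusive and
   converts to dB re 1 μV²/Hz (all-zero windows report a −120 dB floor);
4. maps dB to a circle radius by a clamped affine map between two
   calibration anchors (defaults −6/+6 dB → 50/200 px; control radius
   100 px). The map is non-decreasing by construction.

Consecutive analysis windows therefore share
`window − sampling_rate/update_rate` samples: 250, 450, 475 (50%, 90%, 95%)
at 1, 5, 10 Hz.

Sham ("offline alpha") feedback replays per-step alpha increments drawn at
random from a library of previously recorded traces, making the displayed
radius statistically independent of the concurrent recording.

## 3. Offline spectral pipeline

Per channel and trial: zero-phase 0.5 Hz high-pass (6th-order Butterworth)
then a 50 Hz notch (2nd-order IIR, Q = 35). Preroll samples are excluded
from offline spectra (trial onset to offset only).

**Ocular ICA.** Extended-Infomax ICA (via `mne.preprocessing.infomax`) is
fit per subject on the PCA-whitened concatenation of the preprocessed
trials. A component is rejected as ocular when |correlation of its time
series with the mean of the Fp channels| > 0.7 **and** more than 0.6 of its
power lies below 4 Hz; at most three components are removed (strongest
frontal correlation first). Rejected components are zeroed and the data
back-projected. The deterministic two-criterion rule replaces the visual
component selection a human operator would do, so tests are reproducible;
both thresholds are arguments.

**Band powers.** Welch's method with the segment length chosen as
`L = floor(2N/9)` so that eight 50%-overlapping segments tile the trial,
each tapered with a symmetric Hamming window; no detrending (the high-pass
already removed DC). Band power is the mean spectral density over bins with
`low ≤ f ≤ high` — edge bins (8, 12, 15 Hz) count in both adjacent bands —
converted to 10·log10. Analyses use Fz, Cz, Pz only.

**Standardization.** Each of the 12 variables (4 bands × 3 channels) is
z-scored across all subject-trials within each experiment separately.

## 4. Bayesian multilevel models

Two Gaussian models on z-scored power:

* **Equation 1** (condition structure):
  `power ~ 1 + Trial×Condition×Source` with by-subject
  `1 + Trial×Condition` varying effects; Trial is the within-condition
  index 1..8 minus 1 (the intercept is the first-trial expectation).
* **Equation 2** (whole session): `power ~ 1 + Trial×Source` with
  by-subject `1 + Trial` varying effects; Trial is the session index 1..32
  minus 1.

Condition and Source enter through generalized-inverse contrast coding: the
contrast matrix is the Moore–Penrose inverse of a hypothesis matrix whose
rows are (intercept; experimental-vs-control; 5 Hz−1 Hz; 10 Hz−5 Hz) and
(intercept; online−offline), so each regression coefficient estimates the
named hypothesis and `H·C = I` exactly. Source terms are dropped when a
table holds a single experiment.

Priors: N(0, 1) on every population-level coefficient; half-Normal(0, 1) on
the residual SD and each varying-effect SD. Varying effects are independent
across coefficients (diagonal covariance) — a simplification relative to a
full covariance with an LKJ prior; none of the shipped checks involve
random-effect correlations.

**Sampler.** A blocked Gibbs sampler: fixed and varying coefficients have
conjugate Gaussian full conditionals; the SD parameters are updated by
univariate slice sampling on the log scale. Because a fixed effect and the
(per-group) mean of its matching varying effects are only identified
through the priors, the naive blocks mix poorly along those directions; the
sampler detects every such likelihood-invariant direction (a fixed column
equal to per-subject constants times a varying column, which covers the
intercept, the between-subject Source codes, and all their Trial/Condition
interactions) and adds an exact Gibbs step on the joint shift
(an interweaving / ancillarity move). Defaults: 4 chains, 500 warmup +
1000 retained draws (scaled-down profiles use 2 chains and fewer draws);
R-hat ≥ 1.05 on any fixed effect raises an error with full diagnostics
(R-hat and ESS are computed with `arviz`).

**Bayes factors.** BF10 for each point null via the Savage–Dickey density
ratio: N(0, 1) prior density at zero over a Gaussian-KDE (Silverman
bandwidth) estimate of the posterior density at zero. When the null lies
more than five robust SDs (median/MAD) into the tail, or the KDE value
underflows the cap, BF10 is reported as ">100" with a flag — a KDE value
that far into a tail is dominated by stray draws. The one-sided
BF10+ = BF10 · 2 · Pr(coefficient > 0 | data). Evidence labels follow the
substantial-evidence convention: BF10 > 3 for the effect, < 1/3 for the
null, otherwise insensitive. The stability protocol repeats the whole fit
with three distinct seeds and reports the mean posterior mean, the
element-wise widest 95% credible-interval bounds, and the mean BF10.

The KDE-based ratio is validated against the conjugate normal-normal
closed form (`BF10 = (n+1)^(-1/2) exp(mu_n^2 (n+1)/2)`) over a 20-cell
grid; with 1e5 posterior draws the worst relative deviation is below 5%
(Silverman smoothing bias plus Monte-Carlo noise).

## 5. Validation harnesses and problem sizes

The recovery and null harnesses run the full chain (generate → preprocess →
Welch → z-score → equation-2 fit) at a deliberately reduced profile chosen
so a replicate costs seconds: 12 subjects × 32 trials of 10 s, blink-free
(ICA is exercised by its own fixtures), `background_rms` 2 μV so the
parietal alpha peak dominates its band the way a posterior rhythm does,
dB-linear drift of 0.06 dB/trial with subject slope SD 0.01 dB/trial.
The injected slope is several times the design's Monte-Carlo standard
error (the criterion asks for at least three).

The true z-scale slope per replicate is the injected dB slope attenuated by
the alpha share of in-band power — the measured band also contains
background and neighbouring-band leakage — divided by the empirical SD used
in standardization. The attenuation is evaluated at run time from two short
single-component calibration simulations (mean in-band power per unit alpha
variance, and of everything else); only their ratio enters, so the
calibration's Monte-Carlo error is second order.

Across 20 replicates the 95% CrI covers the true slope in ≥ 16, the alpha
trial effect earns `evidence_for_effect`, and theta/SMR/beta do not; with
zero injected drift, essentially no variable earns an effect label across
20 seeds × 12 variables (BF10 ≈ 0.01 is typical). The full-size study
profile (32+32 subjects, 60-s trials, 4 chains) is the documented
long-running mode; the smoke profile (6 subjects, 10-s trials, 2 chains)
runs the complete two-experiment orchestration in minutes.

## 6. What the synthetic data does and does not establish

The generator reproduces the statistical structure the analysis consumes:
1/f background, peaked band-limited rhythms with a posterior-dominant
alpha, frontal blinks, per-subject heterogeneity, and a linear trial drift
confined to alpha. It does **not** model volume conduction (mixing is
rank-1 per source), saccades or lateral eye movements, electrode impedance
or drift, non-stationary 1/f, inter-trial rest periods (trials are
generated back-to-back with independent noise), or any coupling of the
displayed feedback back into the brain. Passing tests therefore show that
the *pipeline* is correct and calibrated — that a time-on-task alpha drift
of the assumed form is recovered faithfully and that no effect is invented
where none exists — not that real recordings contain such a drift.

## 7. Numerical conventions and degenerate inputs

* dB values are referenced to 1 μV²/Hz; all-zero online windows return the
  −120 dB floor.
* Band-edge bins belong to both adjacent bands (documented inclusive rule,
  consistent online and offline).
* Welch segmentation uses `L = floor(2N/9)`; the exact spectral resolution
  of the original tooling is not a conformance target.
* z-scoring raises on zero-variance cells; model fitting requires ≥ 2
  subjects; ICA requires a session much longer than channels².
* Update rates must divide the sampling rate into an integer hop.
* All randomness flows from explicit seeds; identical configs give
  byte-identical tables and reports.
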