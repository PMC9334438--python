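# Methods

## The synthetic voice corpus

The synthesizer is a source–filter model chosen so that every measure in the
feature battery has an analytic injected truth. The glottal source is a
pulse train whose period interpolates linearly between 1/f0_start and
1/f0_end over the sentence (a declination of 15% is the profile default);
each period is multiplied by an i.i.d. uniform(−j, +j) factor, j being the
`jitter_frac` parameter. Pulses are placed with fractional-delay (two-sample
linear) interpolation — integer-sample rounding would inject ≈ 1/(T·fs) of
spurious period perturbation, comparable to small genuine jitter levels.
Note that for this perturbation model the expected local jitter (mean
absolute consecutive-period difference over mean period) is 2j/3, and all
recovery checks compare measurements against the *realized pulse times*
(`ground_truth_pulses`), not against j.

The source is shaped by one real pole (−6 dB/oct) and filtered through a
cascade of five two-pole resonators (center frequencies and bandwidths from
the sentence's `VoiceSpec`). The rendered signal is therefore exactly
all-pole, which is what makes linear-prediction formant recovery
well-conditioned. Aspiration noise is Gaussian noise passed through the same
resonator cascade and mixed at `noise_db` relative to the harmonic part, so
−noise_db is the injected harmonics-to-noise target. Lip-radiation
differencing is deliberately omitted: its zero breaks the all-pole structure
and adds nothing the analyses need.

Sampling rate defaults to 16 kHz, a standard wideband-speech rate: the 6 kHz
band edge used by the spectral measures sits well below Nyquist, and the
five-formant region (≤ 5.5 kHz) occupies most of the band, keeping F4/F5 at
realistic levels relative to F1. At much higher rates the cascade's skirt
decay pushes F5 tens of dB further down and five-formant LPC becomes
ill-conditioned.

Speaker profiles place between-speaker variation where human voices have it:
female f0 ≈ 205 ± 30 Hz, male ≈ 125 ± 22 Hz; per-speaker jitter means
0.8–3.5%; vocal-tract length (formant scale) SD 5% around gender-specific
formant patterns; per-speaker noisiness −35…−18 dB. Within-speaker
(sentence-to-sentence) SDs default to 25% of the corresponding
between-speaker spread — the regime in which speakers are highly
discriminable, as the choice task assumes. The default corpus is one owner
plus 14 gender-balanced controls, 28 sentences each.

What the generator does **not** emulate: phonemes, syllable structure,
amplitude envelopes of words, prosodic emotion, recording-channel effects.
Passing tests therefore show that the *estimators and models* behave
correctly on signals with known truth, not that the pipeline's numerical
outputs would match any particular real recording set.

## The feature battery

All measures operate on the whole sentence and are invariant to amplitude
scaling (a property test enforces this), matching stimuli normalized to a
common volume.

* **Pitch** — frame-wise normalized autocorrelation (40 ms Hann window,
  10 ms hop, floor 75 Hz, ceiling 500 Hz), with the window's own
  autocorrelation divided out so a perfectly periodic frame scores r ≈ 1.
  Voicing requires corrected peak strength ≥ 0.45 plus a relative energy
  gate; a small octave cost (0.05 per octave of lag) and a median-based
  repair pass suppress halving/doubling errors. These are conventional
  speech defaults; the upstream study does not report its analysis settings,
  so exact numerical agreement with any external tool is not a target.
* **f0 statistics** — mean/SD/min/max over voiced frames, range = max − min,
  start/end at the first/last voiced frame, slope = end − start, and the
  relative times of the extrema (earliest frame on ties) divided by call
  length.
* **Pulses and jitter** — one epoch per glottal cycle: the first epoch of a
  voiced run is the strongest amplitude peak within one period; subsequent
  epochs come from cross-correlating the current cycle with the signal one
  period ahead (lag search 0.7–1.3 T, parabolic refinement). Matching whole
  cycle shapes keeps period estimates robust to additive noise, where
  single-peak picking degrades badly. ppj is local jitter
  (mean |T_i − T_{i−1}| / mean T) over in-range periods, with periods > 30%
  away from the local median excluded (missed/doubled epochs); ppp is the
  epoch count and ppm the count per voiced second — the most standard
  readings of "number of voice cycles" and "mean number of voice cycles".
* **Harmonicity** — per voiced frame, HNR = 10·log10(r/(1−r)) at the f0 lag
  of the corrected autocorrelation, capped at +40 dB; the sentence carries
  the mean, SD and max. HNR responds to *total* aperiodicity: additive noise
  and period jitter both depress it, which matters when interpreting
  recovery tests (the injected noise level is only the full truth at zero
  jitter).
* **Spectral measures** — a Welch-averaged power spectrum (Blackman–Harris
  window, 4096-point segments, 10 ms hop) is treated as a distribution over
  frequency: CG is its mean, DevFreq its SD, Sk/Kr the standardized third
  and fourth (excess) moments, cmoment the un-normalized third moment.
  Wiener entropy is log(geometric/arithmetic mean) of the same averaged
  spectrum with bins floored at 10⁻¹² of the peak. Averaging the spectrum
  *before* taking the ratio keeps the flat-spectrum limit near 0 (per-frame
  periodogram bias would put white noise at ≈ −0.58), and the low-sidelobe
  window keeps leakage from inflating DevFreq for near-line spectra.
  EnergyDiff is the dB log-ratio of 0–2 kHz to 2–6 kHz energy and BEn the
  2–4 kHz proportion of total energy — scale-invariant readings of "energy
  difference" and "band density".
* **Formants** — the signal is decimated to twice the gender ceiling
  (5.5 kHz female / 5.0 kHz male) with a sharp custom FIR (the default
  polyphase anti-alias filter's wide transition band attenuates F5),
  pre-emphasized above 50 Hz, and an order-14 autocorrelation LPC polynomial
  is fitted per voiced 30 ms frame. Pole angles give candidate formants;
  poles with bandwidth > 400 Hz or outside (90 Hz, ceiling − 50 Hz) are
  discarded; frames contributing fewer than five survivors are skipped, and
  the per-formant medians over frames yield F1…F5 and
  dF = (F5 − F1)/4. Order 14 rather than the textbook 10–12: at f0 ≈ 280 Hz
  in very clean conditions order 12 occasionally fails to separate F5 from
  the harmonic comb, while order 14 recovers dF within 2% across a
  7-pattern × 24-condition sweep.

Missing values propagate as NaN (silent input → all-NaN with a warning;
unvoiced input → f0/jitter/HNR/dF missing, purely spectral measures intact);
sentences with missing features are dropped listwise before LDA, which
requires complete vectors.

## Speaker space

The collinearity filter greedily removes features until no retained pair has
|Pearson r| ≥ 0.8 (the conventional cutoff; the criterion itself is stated
upstream without a value). Within the worst pair it drops the feature with
the larger mean absolute correlation to the other retained features, ties
going against the later feature in battery order. On corpora with derived
features (range = max − min) this guarantees the collinear triple is never
retained intact. Note the "hub" member of a family (e.g. f0 mean) can be the
one dropped — the rule is symmetric and data-driven.

`SpeakerLDA` solves the generalized eigenproblem of between- vs pooled
within-group covariance. Numerically it standardizes by within-group SDs
first (making the solve exactly invariant to unit changes such as Hz → kHz),
orders discriminant functions by decreasing between/within variance ratio,
and normalizes scores to unit pooled within-group variance — the same
convention as classical implementations, under which "loadings" are
standardized discriminant coefficients (raw coefficient × within-group SD).
Standardized *coefficients* (not structure correlations, which are bounded
by 1) are the only scale on which a selection threshold of 1.3 in absolute
value is meaningful; features exceeding it on at least one function are the
identity markers, ordered by their maximum absolute loading. Classification
uses the nearest class mean in discriminant space with equal priors
(speakers are design groups, not a population sample); the default success
measure is leave-one-out (refit without the held-out sentence), with
resubstitution as an option. A relative ridge (10⁻⁸) guards singular
within-group covariance.

Acoustic distance for a trial is |owner − control| on a marker, computed
from speaker-level mean features, then z-scored across the trial table. The
behavioral models use the six markers implicated in voice identity
(f0 mean, f0 SD, dF, HNR, entropy, ppj) as the distance dimensions.

## Trial simulation and behavioral models

The design generator reproduces the experiment's constraints per dog: 10
test trials with hiding sides balanced 5/5 and no more than 3 consecutive
trials on one side, last speakers balanced, control speakers drawn without
replacement; 2 olfaction-control trials for 23 of the 28 dogs (scoring
follows the voice). Outcomes come from the generative truth in
`EffectConfig`, whose defaults are the fitted values of the original
analyses: choice log-odds intercept 1.601, owner-left effect 0.688,
owner-last effect 0.630; looking-time effects gender-difference −1.107,
f0-distance slope 5.613 (same-gender), ppj slope 4.010, f0 × gender
interaction −8.956 (so the different-gender slope is −3.343). Quantities the
original work does not report are set once to plausible values: dog
random-intercept SD 1.0 on the logit scale and residual looking-time SD 25
percentage points (chosen so simulated success proportions and looking-time
dispersion resemble the published summaries), looking baseline 55%, dog
looking SD 5. Looking time is truncated to [0, 100], which mildly attenuates
recovered slopes — visible in the acceptance script's averaged estimates.
Latency is generated weakly anti-correlated with looking time and carries no
true covariate effect, mirroring the null latency finding; olfaction trials
use the same choice model as test trials (no phase difference).

The mixed-model engine is written in-package because no installed Python
library fits frequentist binomial mixed models or provides Satterthwaite
degrees of freedom:

* **Gaussian** (`LinearMixedModel`) — independent random-intercept variance
  components, profiled REML (ML available for likelihood-ratio work)
  optimized over log variance ratios; Wald t statistics with
  Satterthwaite-style df obtained by the delta method on the variance
  parameters (numerical gradient of each coefficient's variance and the
  inverse numerical Hessian of the restricted likelihood), clipped to
  [1, n − p]. The same machinery serves linear contrasts, which is how
  simple slopes get their df. Estimates, likelihoods and variance components
  agree with statsmodels MixedLM to ≈ 10⁻⁴ in the tests.
* **Binomial logit** (`BinomialMixedModel`) — a single random factor is
  integrated by adaptive Gauss–Hermite quadrature (15 nodes around each
  group's Laplace mode); crossed factors use the Laplace approximation with
  a penalized Newton inner loop. Wald z and odds ratios (exp of the
  estimate, an exact identity in the result object). The AGQ path matches a
  brute-force 80-node fixed-grid likelihood optimized independently to
  ≈ 10⁻³ in the tests. A factor whose variance estimate collapses to the
  boundary is dropped and the model refitted (logged in the result), the
  standard treatment for "explained no variance".

Backwards elimination refits after removing the highest-p fixed term with
p ≥ 0.1 — the conventional reading of "tendency level", consistent with a
published table retaining a p = 0.059 term — never removing a main effect
while an interaction containing it survives. With few distinct control
speakers the six distance columns can be linearly aliased; aliased terms are
dropped up front (as fixed-effect pivoting would) with a warning.

The phase comparison is a signed-rank test on per-dog success proportions
with zero differences dropped and a tie-corrected normal approximation; the
all-zero-difference case returns exactly Z = 0, p = 1. Owner-vs-control
voice comparisons aggregate features to speaker level (speaker is then the
experimental unit, so no random effect is needed): an exact F test for the
speaker-type term on f0 mean (Gaussian, identity link, controlling gender)
and a likelihood-ratio χ² on jitter (Gaussian, log link), plus an LR test of
the type × gender interaction.

## Numerical and design choices

* All randomness flows through named integer seeds; identical configurations
  give byte-identical reports (tested).
* Optimizers: L-BFGS-B with tight tolerances, with a deterministic
  Nelder-Mead polish accepted only if it does not worsen the objective —
  line searches at machine precision otherwise abort spuriously.
* Variance parameters live on the log scale with bounds wide enough that a
  zero-variance fit reproduces the closed-form intercept-only logit to
  10⁻⁶.
* Degenerate inputs: < 2 voiced frames → missing f0 set with a warning;
  < 3 pulses → missing ppj; zero-energy signals are rejected by the
  spectral measures; single-gender speaker tables drop the gender term with
  a warning.
* Problem sizes in the tests and the acceptance script — 15 × 28 corpus,
  1 s sweep sentences, 200 recovery replicates (60 in the script, where the
  replicate average rather than coverage is reported) — were chosen as
  desk-scale analogues of the study; the published headline numbers derive
  from unreleased recordings and trial data and are approached qualitatively
  (e.g. LOO discrimination ≥ 80% rather than exactly 88.2%).

## Known limitations

* The synthesizer's sentences are stationary-vowel-like; features tied to
  phonetic content (and the entropy/CG values of real speech) will differ in
  absolute terms from any real corpus.
* HNR recovery is confounded with jitter by construction — both are real
  aperiodicity. Recovery tests stratify accordingly.
* Laplace/AGQ binomial estimates carry the usual small attenuation for
  binary data with ~10 observations per group; looking-time truncation
  attenuates simulated slopes by ~10–15%. Both effects are visible in, and
  absorbed by, the ±2 SE coverage criteria.
* Satterthwaite df rely on numerical second derivatives and can be rough
  when a variance component sits near its boundary (the df then falls back
  to the residual value).
* The collinearity filter's retained set on synthetic corpora differs from
  the set reported for the real recordings; only the rule, not the outcome,
  transfers across corpora.
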