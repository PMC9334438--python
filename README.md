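# vocalid

Which acoustic cues let a listener tell one human voice from another? In
dog–human interaction research this question is studied with a two-way choice
task: a dog hears its owner's voice from one hiding place and an unfamiliar
control voice from the other, and the analysis asks which acoustic
differences between the two speakers predict the dog's behavior. `vocalid`
implements that entire analysis chain as a tested, seeded pipeline for
researchers in bioacoustics and comparative cognition:

1. **Voice synthesis** (`vocalid.synth`) — a Klatt-style source–filter
   synthesizer (glottal pulse train with period jitter, five-formant
   resonator cascade, calibrated aspiration noise) that generates a corpus of
   sentence-like recordings with *known* acoustic ground truth, emulating one
   owner and 14 gender-balanced control speakers × 28 sentences.
2. **Acoustic feature battery** (`vocalid.features`) — 25 sentence-level
   measures: ten fundamental-frequency statistics (f0 mean/SD/min/max/range,
   start/end/slope, relative extremum positions), seven noisiness measures
   (local jitter *ppj*, voice-cycle counts *ppp*/*ppm*, Wiener entropy,
   HNR mean/SD/max), and eight spectral-energy measures (formant dispersion
   *dF*, spectral center of gravity and its moments, band-energy ratios).
3. **Speaker space** (`vocalid.speaker_space`) — Pearson-correlation
   collinearity filtering, linear discriminant analysis with speakers as
   groups (`SpeakerLDA`, a scikit-learn-style classifier), leave-one-out
   discrimination success, identity-marker selection by the
   |standardized loading| > 1.3 rule, and per-trial acoustic distances
   |owner − control| on each marker (z-scored across trials).
4. **Trial simulation** (`vocalid.trials`) — the experiment's design
   (28 dogs × 10 test trials + 23 dogs × 2 olfaction-control trials, sides
   and last speakers balanced, ≤ 3 consecutive same-side trials, control
   speakers drawn without replacement) with behavioral outcomes generated
   from a configurable truth: a binomial choice model and a Gaussian
   looking-time model with distance × gender-match structure.
5. **Behavioral models** (`vocalid.behavior`, engine in `vocalid.mixed`) —
   binomial mixed models (adaptive Gauss–Hermite / Laplace), Gaussian mixed
   models (REML with Satterthwaite degrees of freedom), backwards
   elimination at the tendency level (p < 0.1), simple-slope post hocs,
   a tie-corrected Wilcoxon signed-rank phase comparison, and
   owner-vs-control voice comparisons by F and likelihood-ratio tests.

The statistical core, for choice on trial *t* of dog *i*:

    logit P(choice_it = 1) = β0 + β_side·left_it + β_last·ownerlast_it + u_i,
    u_i ~ N(0, σ²_dog)

and for looking time (percent of the stimulus window toward the owner's
side), with z-scored acoustic distances *d* and a gender-difference
indicator *g*:

    look_it = γ0 + γ_g·g_it + Σ_m γ_m·d_mit + Σ_m γ_mg·d_mit·g_it + v_i + ε_it

## Worked example

```python
from vocalid import (default_profiles, sample_corpus, extract_features_table,
                     collinearity_filter, classification_success)
from vocalid.features import FEATURE_NAMES

profiles = default_profiles(n_speakers=15, seed=101)   # owner + 14 controls
corpus   = sample_corpus(profiles, n_sentences=28, seed=202)
features = extract_features_table(corpus).dropna(subset=FEATURE_NAMES)
retained = collinearity_filter(features, r_max=0.8)
success  = classification_success(features[retained],
                                  features["speaker_id"].to_numpy(), mode="loo")
print(f"{len(retained)} features retained; LOO discrimination {success:.1f}%")
```

prints (420 sentences, a few seconds of compute):

```
12 features retained; LOO discrimination 96.4%
```

i.e. after removing collinear measures, the discriminant space classifies
96.4% of held-out sentences to the correct speaker — voices synthesized with
within-speaker variation at 25% of the between-speaker spread are highly
individually discriminable, the regime the choice task assumes.

The full pipeline, end to end, with a report bundle:

```bash
vocalid -v run --outdir runs/demo      # report.json, model tables, CSVs
vocalid verify                         # quick self-checks, PASS/FAIL
```

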