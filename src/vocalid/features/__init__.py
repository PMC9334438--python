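"""The acoustic feature battery: one vector of 25 sentence-level measures.

Ten fundamental-frequency statistics, seven noisiness measures (jitter,
cycle counts, Wiener entropy, HNR family), and eight spectral-energy measures
(formant dispersion, spectral moments, band energies).  All measures are
ratios, frequencies or normalized moments, so the vector is invariant to
amplitude scaling of the waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..synth import Waveform
from .pitch import (
    F0_FIELDS,
    PitchSettings,
    PitchTrack,
    PulseSequence,
    extract_pulses,
    f0_statistics,
    harmonicity,
    jitter_features,
    track_pitch,
)
from .spectral import SPECTRAL_FIELDS, long_term_spectrum, spectral_shape, wiener_entropy
from .formants import estimate_formants, formant_dispersion

__all__ = [
    "FEATURE_NAMES",
    "FeatureSettings",
    "extract_features",
    "extract_features_table",
    "AcousticFeatureExtractor",
    "PitchSettings",
    "PitchTrack",
    "PulseSequence",
    "track_pitch",
    "f0_statistics",
    "extract_pulses",
    "jitter_features",
    "harmonicity",
    "wiener_entropy",
    "spectral_shape",
    "long_term_spectrum",
    "estimate_formants",
    "formant_dispersion",
]

#: canonical order of the feature battery (used for tie-breaks downstream)
FEATURE_NAMES = F0_FIELDS + [
    "ppj",
    "ppp",
    "ppm",
    "ent",
    "HNR",
    "HNR_SD",
    "HNR_max",
    "dF",
    "CG",
    "DevFreq",
    "EnergyDiff",
    "Sk",
    "Kr",
    "cmoment",
    "BEn",
]


@dataclass(frozen=True)
class FeatureSettings:
    """Analysis settings; conventional speech defaults."""

    pitch: PitchSettings = PitchSettings()
    formant_ceiling_female_hz: float = 5500.0
    formant_ceiling_male_hz: float = 5000.0
    lpc_order: int = 14
    max_formant_bandwidth_hz: float = 400.0
    spectrum_nperseg: int = 4096

    def formant_ceiling(self, gender: str | None) -> float:
        if gender == "male":
            return self.formant_ceiling_male_hz
        return self.formant_ceiling_female_hz

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["pitch"] = dict(self.pitch.__dict__)
        return d


def extract_features(
    w: Waveform,
    gender: str | None = None,
    settings: FeatureSettings | None = None,
) -> dict:
    """All sentence-level acoustic measures for one waveform.

    Missing components (e.g. unvoiced input) propagate as NaN; a fully silent
    signal yields an all-NaN vector with a warning.
    """
    st = settings or FeatureSettings()
    out = {k: np.nan for k in FEATURE_NAMES}
    if not np.any(np.asarray(w.samples)):
        warnings.warn("silent waveform: all features missing")
        return out

    track = track_pitch(w, settings=st.pitch)
    out.update(f0_statistics(track))

    if track.n_voiced >= 2:
        pulses = extract_pulses(w, track)
        out.update(jitter_features(pulses, track))
        out.update(harmonicity(w, track))
        out["dF"] = formant_dispersion(
            w,
            track,
            ceiling_hz=st.formant_ceiling(gender),
            order=st.lpc_order,
            max_bandwidth_hz=st.max_formant_bandwidth_hz,
        )
    else:
        warnings.warn("no voiced region: periodicity features missing")

    out["ent"] = wiener_entropy(w, nperseg=st.spectrum_nperseg)
    out.update(spectral_shape(w, nperseg=st.spectrum_nperseg))
    return out


def extract_features_table(
    items, settings: FeatureSettings | None = None
) -> pd.DataFrame:
    """Feature table for a corpus: one row per (speaker, sentence).

    ``items`` is an iterable of CorpusItem or of (speaker_id, gender,
    sentence_id, Waveform) tuples.
    """
    rows = []
    for it in items:
        if hasattr(it, "waveform"):
            sid, gender, sent, wav = it.speaker_id, it.gender, it.sentence_id, it.waveform
        else:
            sid, gender, sent, wav = it
        row = {"speaker_id": sid, "gender": gender, "sentence_id": sent}
        row.update(extract_features(wav, gender=gender, settings=settings))
        rows.append(row)
    return pd.DataFrame(rows, columns=["speaker_id", "gender", "sentence_id"] + FEATURE_NAMES)


class AcousticFeatureExtractor:
    """sklearn-style transformer: list of waveforms -> feature DataFrame.

    Stateless (fit is a no-op); exists so the battery composes with sklearn
    pipelines.  ``transform`` accepts Waveforms or (speaker, gender,
    sentence, Waveform) tuples / CorpusItems.
    """

    def __init__(self, settings: FeatureSettings | None = None, gender: str | None = None):
        self.settings = settings
        self.gender = gender

    def get_params(self, deep: bool = True) -> dict:
        return {"settings": self.settings, "gender": self.gender}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        if len(X) and isinstance(X[0], Waveform):
            rows = [
                extract_features(w, gender=self.gender, settings=self.settings)
                for w in X
            ]
            return pd.DataFrame(rows, columns=FEATURE_NAMES)
        return extract_features_table(X, settings=self.settings)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
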