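"""Seeded source-filter voice synthesizer with analytic ground truth.

The generator stands in for a corpus of recorded spoken sentences: a glottal
pulse train (linearly interpolated period, optional multiplicative jitter) is
shaped by a -12 dB/oct glottal rolloff, passed through a cascade of five
second-order formant resonators, and mixed with vocal-tract-shaped broadband
noise at a configurable level.  Every acoustic parameter measured downstream
(f0 contour, cycle-to-cycle jitter, formant positions, harmonics-to-noise
ratio) therefore has a known injected value, which is what the feature
extractor is validated against.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "VoiceSpec",
    "SpeakerProfile",
    "Waveform",
    "CorpusItem",
    "synthesize_voice",
    "ground_truth_pulses",
    "sample_corpus",
    "default_profiles",
    "write_corpus",
    "read_wav",
]

#: canonical neutral formant pattern (Hz); speaker profiles scale it
BASE_FORMANTS_FEMALE = (520.0, 1560.0, 2600.0, 3640.0, 4680.0)
BASE_FORMANTS_MALE = (470.0, 1400.0, 2350.0, 3300.0, 4250.0)
DEFAULT_BANDWIDTHS = (90.0, 110.0, 140.0, 180.0, 220.0)


@dataclass(frozen=True)
class VoiceSpec:
    """Ground-truth parameters of one synthesized sentence."""

    duration_s: float
    f0_start_hz: float
    f0_end_hz: float
    jitter_frac: float = 0.0
    formants_hz: tuple = BASE_FORMANTS_FEMALE
    bandwidths_hz: tuple = DEFAULT_BANDWIDTHS
    noise_db: float = -30.0
    sample_rate_hz: int = 16000

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        for name in ("f0_start_hz", "f0_end_hz"):
            v = getattr(self, name)
            if not 0 < v < self.sample_rate_hz / 2:
                raise ValueError(f"{name} must lie in (0, Nyquist), got {v}")
        if not 0 <= self.jitter_frac < 0.2:
            raise ValueError(
                f"jitter_frac must lie in [0, 0.2), got {self.jitter_frac}"
            )
        if len(self.formants_hz) != 5 or len(self.bandwidths_hz) != 5:
            raise ValueError("formants_hz and bandwidths_hz must have 5 entries")
        f = np.asarray(self.formants_hz, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError(f"formants_hz must be strictly ascending, got {tuple(f)}")
        if np.any(f >= self.sample_rate_hz / 2):
            raise ValueError("formants_hz must all be below Nyquist")
        if np.any(np.asarray(self.bandwidths_hz) <= 0):
            raise ValueError("bandwidths_hz must be positive")
        if not np.isfinite(self.noise_db):
            raise ValueError("noise_db must be finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass
class Waveform:
    """Mono audio signal, amplitudes normalized to [-1, 1]."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.samples)


def _period_at(spec: VoiceSpec, t: float) -> float:
    frac = min(max(t / spec.duration_s, 0.0), 1.0)
    t0, t1 = 1.0 / spec.f0_start_hz, 1.0 / spec.f0_end_hz
    return t0 + (t1 - t0) * frac


def _pulse_times(spec: VoiceSpec, rng: np.random.Generator) -> np.ndarray:
    times = []
    t = _period_at(spec, 0.0) * 0.5  # first closure mid-way into the first cycle
    while t < spec.duration_s:
        times.append(t)
        period = _period_at(spec, t)
        if spec.jitter_frac > 0:
            period *= 1.0 + rng.uniform(-spec.jitter_frac, spec.jitter_frac)
        else:
            rng.uniform(-1, 1)  # keep the stream position independent of jitter
        t += period
    return np.asarray(times)


def ground_truth_pulses(spec: VoiceSpec, seed: int) -> np.ndarray:
    """Glottal closure instants the synthesizer will emit for (spec, seed).

    This is the independent oracle for jitter/cycle-count measures: it replays
    the same random stream used by :func:`synthesize_voice`.
    """
    spec.validate()
    return _pulse_times(spec, np.random.default_rng(seed))


def _resonator_sos(f: float, bw: float, fs: float) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * f / fs
    # Klatt-style unit-DC-gain two-pole section: the cascade is exactly all-pole
    a = [1.0, -2 * r * np.cos(theta), r * r]
    g = 1 - 2 * r * np.cos(theta) + r * r
    return np.array([[g, 0.0, 0.0, *a]])


def _vocal_tract(x: np.ndarray, spec: VoiceSpec) -> np.ndarray:
    sos = np.vstack(
        [
            _resonator_sos(f, b, spec.sample_rate_hz)
            for f, b in zip(spec.formants_hz, spec.bandwidths_hz)
        ]
    )
    return signal.sosfilt(sos, x)


def synthesize_voice(spec: VoiceSpec, seed: int) -> Waveform:
    """Render one sentence-like waveform; identical (spec, seed) -> identical samples."""
    spec.validate()
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    n = spec.n_samples

    pulses = _pulse_times(spec, rng)
    # fractional-delay impulse placement: splitting each pulse across the two
    # neighbouring samples keeps sub-sample timing (integer rounding would
    # inject ~1/(T*fs) of spurious period jitter)
    excitation = np.zeros(n + 1)
    pos = pulses * fs
    idx = np.floor(pos).astype(int)
    frac = pos - idx
    keep = idx < n
    np.add.at(excitation, idx[keep], 1.0 - frac[keep])
    np.add.at(excitation, idx[keep] + 1, frac[keep])
    excitation = excitation[:n]

    # glottal rolloff: one real pole (-6 dB/oct).  The rendered signal stays
    # all-pole (source pole + resonator cascade), which keeps every formant
    # recoverable by linear prediction at realistic relative levels.
    rolloff = 0.98
    source = signal.lfilter([1.0], [1.0, -rolloff], excitation)

    harmonic = _vocal_tract(source, spec)
    noise = _vocal_tract(rng.standard_normal(n), spec)

    h_rms = np.sqrt(np.mean(harmonic**2))
    n_rms = np.sqrt(np.mean(noise**2))
    gain = h_rms / n_rms * 10 ** (spec.noise_db / 20) if n_rms > 0 else 0.0
    y = harmonic + gain * noise

    # short raised-cosine fades avoid clicks at the edges
    edge = min(int(0.005 * fs), n // 4)
    if edge > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
        y[:edge] *= ramp
        y[-edge:] *= ramp[::-1]

    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    return Waveform(y, fs)


# ---------------------------------------------------------------------------
# speaker profiles and corpus sampling


@dataclass
class SpeakerProfile:
    """Per-speaker distribution over sentence-level VoiceSpec parameters.

    Each sentence draws its parameters from independent normals (clipped into
    the valid range), so within-speaker variation is controlled by the *_sd
    fields and between-speaker variation by differences in the means.
    """

    speaker_id: str
    gender: str  # "female" | "male"
    f0_hz: float
    f0_sd_hz: float
    jitter: float
    jitter_sd: float
    formant_scale: float
    formant_scale_sd: float
    noise_db: float
    noise_db_sd: float
    duration_s: float = 1.3
    duration_sd: float = 0.15
    declination: float = 0.15  # relative f0 fall from start to end of sentence

    def __post_init__(self):
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be 'female' or 'male', got {self.gender!r}")
        for name in (
            "f0_sd_hz",
            "jitter_sd",
            "formant_scale_sd",
            "noise_db_sd",
            "duration_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def base_formants(self) -> tuple:
        return BASE_FORMANTS_FEMALE if self.gender == "female" else BASE_FORMANTS_MALE

    def draw_spec(self, rng: np.random.Generator) -> VoiceSpec:
        f0c = max(75.0, rng.normal(self.f0_hz, self.f0_sd_hz))
        jit = float(np.clip(rng.normal(self.jitter, self.jitter_sd), 0.0, 0.19))
        scale = max(0.7, rng.normal(self.formant_scale, self.formant_scale_sd))
        noise = float(np.clip(rng.normal(self.noise_db, self.noise_db_sd), -60.0, -6.0))
        dur = max(0.6, rng.normal(self.duration_s, self.duration_sd))
        d = self.declination
        return VoiceSpec(
            duration_s=dur,
            f0_start_hz=f0c * (1 + d / 2),
            f0_end_hz=f0c * (1 - d / 2),
            jitter_frac=jit,
            formants_hz=tuple(f * scale for f in self.base_formants),
            bandwidths_hz=DEFAULT_BANDWIDTHS,
            noise_db=noise,
        )


@dataclass
class CorpusItem:
    speaker_id: str
    gender: str
    sentence_id: str
    spec: VoiceSpec
    waveform: Waveform
    synth_seed: int


def default_profiles(
    n_speakers: int = 15,
    seed: int = 0,
    within_sd_frac: float = 0.25,
    owner_gender: str = "female",
    duration_s: float = 1.3,
) -> list:
    """One owner plus (n_speakers - 1) gender-balanced control speakers.

    Between-speaker spreads emulate adult speech: female f0 around 205 Hz,
    male around 125 Hz, jitter 0.8-3.5%, mild formant-scale (vocal-tract
    length) variation, and per-speaker noisiness.  Within-speaker SDs are
    ``within_sd_frac`` of the corresponding between-speaker spread.
    """
    if n_speakers < 2:
        raise ValueError("need at least 2 speakers (owner + 1 control)")
    rng = np.random.default_rng(seed)
    n_controls = n_speakers - 1
    genders = ["female", "male"] * (n_controls // 2 + 1)
    control_genders = genders[:n_controls]

    between = {
        "f0_female": 30.0,
        "f0_male": 22.0,
        "jitter": (0.035 - 0.008) / np.sqrt(12),
        "formant_scale": 0.05,
        "noise_db": (35.0 - 18.0) / np.sqrt(12),
    }

    def make(speaker_id: str, gender: str) -> SpeakerProfile:
        if gender == "female":
            f0 = rng.normal(205.0, between["f0_female"])
            f0_b = between["f0_female"]
        else:
            f0 = rng.normal(125.0, between["f0_male"])
            f0_b = between["f0_male"]
        return SpeakerProfile(
            speaker_id=speaker_id,
            gender=gender,
            f0_hz=float(np.clip(f0, 85.0, 320.0)),
            f0_sd_hz=within_sd_frac * f0_b,
            jitter=float(rng.uniform(0.008, 0.035)),
            jitter_sd=within_sd_frac * between["jitter"],
            formant_scale=float(rng.normal(1.0, between["formant_scale"])),
            formant_scale_sd=within_sd_frac * between["formant_scale"],
            noise_db=float(rng.uniform(-35.0, -18.0)),
            noise_db_sd=within_sd_frac * between["noise_db"],
            duration_s=duration_s,
        )

    profiles = [make("owner", owner_gender)]
    for i, g in enumerate(control_genders):
        profiles.append(make(f"control_{i + 1:02d}", g))
    return profiles


def sample_corpus(profiles: list, n_sentences: int, seed: int) -> list:
    """Draw and synthesize ``n_sentences`` sentences per speaker.

    Returns a list of :class:`CorpusItem`, fully determined by
    (profiles, n_sentences, seed).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 speaker profiles")
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    items = []
    for prof in profiles:
        for j in range(n_sentences):
            spec = prof.draw_spec(rng)
            synth_seed = int(rng.integers(0, 2**31 - 1))
            wav = synthesize_voice(spec, synth_seed)
            items.append(
                CorpusItem(
                    speaker_id=prof.speaker_id,
                    gender=prof.gender,
                    sentence_id=f"s{j + 1:02d}",
                    spec=spec,
                    waveform=wav,
                    synth_seed=synth_seed,
                )
            )
    return items


# ---------------------------------------------------------------------------
# WAV + manifest I/O


def write_wav(path, w: Waveform) -> None:
    data = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), w.sample_rate_hz, (data * 32767).astype(np.int16))


def read_wav(path) -> Waveform:
    sr, data = wavfile.read(str(path))
    if data.ndim == 2:  # stereo: downmix
        import warnings

        warnings.warn(f"{path}: stereo input downmixed to mono")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return Waveform(np.asarray(data, dtype=np.float64), int(sr))


def write_corpus(items: list, outdir, config: dict | None = None) -> Path:
    """Write per-sentence WAVs plus a ground-truth manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    wav_dir = outdir / "wav"
    wav_dir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    cols = [
        "speaker_id",
        "gender",
        "sentence_id",
        "path",
        "synth_seed",
        "duration_s",
        "f0_start_hz",
        "f0_end_hz",
        "jitter_frac",
        "noise_db",
        "sample_rate_hz",
    ] + [f"formant{i + 1}_hz" for i in range(5)]
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(cols)
        for it in items:
            fname = f"{it.speaker_id}_{it.sentence_id}.wav"
            write_wav(wav_dir / fname, it.waveform)
            s = it.spec
            wr.writerow(
                [
                    it.speaker_id,
                    it.gender,
                    it.sentence_id,
                    str(Path("wav") / fname),
                    it.synth_seed,
                    s.duration_s,
                    s.f0_start_hz,
                    s.f0_end_hz,
                    s.jitter_frac,
                    s.noise_db,
                    s.sample_rate_hz,
                    *s.formants_hz,
                ]
            )
    if config is not None:
        (outdir / "corpus_config.json").write_text(json.dumps(config, indent=2))
    return manifest
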