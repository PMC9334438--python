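"""Autocorrelation pitch tracking, glottal pulse extraction, and f0 statistics.

Frame-wise normalized autocorrelation with a window-ACF correction (so a
perfectly periodic signal scores r ~= 1 regardless of the analysis taper), a
voicing decision on corrected peak strength plus a relative silence gate, and
a small octave penalty so the fundamental beats its subharmonics when both
score near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import next_fast_len, rfft, irfft

from ..synth import Waveform

__all__ = [
    "PitchSettings",
    "PitchTrack",
    "PulseSequence",
    "track_pitch",
    "f0_statistics",
    "extract_pulses",
    "jitter_features",
    "harmonicity",
]

F0_FIELDS = [
    "f0_mean",
    "f0_range",
    "f0_change",
    "f0_sd",
    "f0_max",
    "f0_min",
    "f0_mnpozr",
    "f0_mxpozr",
    "f0_end",
    "f0_st",
]


@dataclass(frozen=True)
class PitchSettings:
    floor_hz: float = 75.0
    ceiling_hz: float = 500.0
    frame_s: float = 0.040
    hop_s: float = 0.010
    voicing_threshold: float = 0.45
    silence_rel: float = 0.05  # frame RMS gate, relative to the loudest frame
    octave_cost: float = 0.05  # per octave of lag, favors the shortest strong lag


@dataclass
class PitchTrack:
    frame_times: np.ndarray  # frame centers, s
    f0_hz: np.ndarray  # nan where unvoiced
    voiced: np.ndarray  # bool per frame
    strength: np.ndarray  # corrected autocorrelation at the chosen lag
    call_length: float  # total waveform duration, s
    settings: PitchSettings

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    @property
    def voiced_duration(self) -> float:
        return self.n_voiced * self.settings.hop_s


@dataclass
class PulseSequence:
    pulse_times: np.ndarray  # strictly increasing glottal epochs, s

    def periods(self) -> np.ndarray:
        return np.diff(self.pulse_times)


def _frames_and_acf(x: np.ndarray, fs: float, st: PitchSettings):
    """Window-corrected normalized autocorrelation per frame.

    Returns (frame_times, corrected_acf[n_frames, max_lag+1], frame_rms).
    """
    win = int(round(st.frame_s * fs))
    hop = int(round(st.hop_s * fs))
    if len(x) < win:
        # pad very short signals to one frame
        x = np.pad(x, (0, win - len(x)))
    frames = sliding_window_view(x, win)[::hop]
    times = (np.arange(frames.shape[0]) * hop + win / 2) / fs
    window = np.hanning(win)
    fw = frames * window
    rms = np.sqrt(np.mean(frames**2, axis=1))

    max_lag = int(np.ceil(fs / st.floor_hz)) + 2
    nfft = next_fast_len(win + max_lag + 1)
    spec = rfft(fw, nfft, axis=1)
    ac = irfft(np.abs(spec) ** 2, nfft, axis=1)[:, : max_lag + 1]
    wac = irfft(np.abs(rfft(window, nfft)) ** 2, nfft)[: max_lag + 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        r = ac / ac[:, :1]
        r = r / (wac / wac[0])[None, :]
    r[~np.isfinite(r)] = 0.0
    return times, r, rms


def _parabolic(r_row: np.ndarray, k: int):
    """Refine a peak at integer lag k; returns (delta, value)."""
    if k <= 0 or k >= len(r_row) - 1:
        return 0.0, r_row[k]
    a, b, c = r_row[k - 1], r_row[k], r_row[k + 1]
    denom = a - 2 * b + c
    if denom >= -1e-12:
        return 0.0, b
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return d, b - 0.25 * (a - c) * d


def track_pitch(
    w: Waveform,
    floor_hz: float = 75.0,
    ceiling_hz: float = 500.0,
    settings: PitchSettings | None = None,
) -> PitchTrack:
    """Frame-wise autocorrelation pitch with a voicing decision."""
    fs = w.sample_rate_hz
    if settings is None:
        settings = PitchSettings(floor_hz=floor_hz, ceiling_hz=ceiling_hz)
    st = settings
    if not st.floor_hz < st.ceiling_hz < fs / 2:
        raise ValueError("need floor < ceiling < Nyquist")
    x = w.samples - np.mean(w.samples)
    times, r, rms = _frames_and_acf(x, fs, st)

    lmin = max(2, int(np.floor(fs / st.ceiling_hz)))
    lmax = min(int(np.ceil(fs / st.floor_hz)), r.shape[1] - 2)
    lags = np.arange(lmin, lmax + 1)
    penalty = st.octave_cost * np.log2(lags / lmin)
    score = r[:, lmin : lmax + 1] - penalty[None, :]

    best = np.argmax(score, axis=1) + lmin
    n = r.shape[0]
    f0 = np.full(n, np.nan)
    strength = np.zeros(n)
    loud = np.max(rms) if len(rms) else 0.0
    for i in range(n):
        d, val = _parabolic(r[i], best[i])
        strength[i] = val
        lag = best[i] + d
        if lag > 0:
            f0[i] = fs / lag
    voiced = (
        (strength >= st.voicing_threshold)
        & (rms > st.silence_rel * loud)
        & (f0 >= st.floor_hz)
        & (f0 <= st.ceiling_hz)
    )

    # octave-error repair: isolated halving/doubling against the local median
    # track is re-searched among the other autocorrelation peaks
    vi = np.flatnonzero(voiced)
    if len(vi) >= 5:
        from scipy.signal import medfilt

        med = medfilt(f0[vi], kernel_size=5)
        for j, i in enumerate(vi):
            if med[j] > 0 and abs(f0[i] - med[j]) / med[j] > 0.25:
                seg = r[i, lmin : lmax + 1]
                peaks = np.flatnonzero(
                    (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
                ) + 1 + lmin
                if len(peaks) == 0:
                    continue
                cand_f0 = []
                for k in peaks:
                    dlt, val = _parabolic(r[i], k)
                    if val >= 0.5 * st.voicing_threshold:
                        cand_f0.append(fs / (k + dlt))
                if cand_f0:
                    cand_f0 = np.asarray(cand_f0)
                    best_c = cand_f0[np.argmin(np.abs(cand_f0 - med[j]))]
                    if abs(best_c - med[j]) / med[j] < 0.25:
                        f0[i] = best_c

    f0[~voiced] = np.nan
    return PitchTrack(times, f0, voiced, strength, w.duration_s, st)


def f0_statistics(p: PitchTrack) -> dict:
    """The ten fundamental-frequency summary measures of a pitch track.

    Start/end are the first/last voiced frames; the relative positions divide
    the time of the extremum (earliest if tied) by total call length.
    """
    out = {k: np.nan for k in F0_FIELDS}
    v = p.voiced
    if v.sum() < 2:
        warnings.warn("fewer than 2 voiced frames; f0 statistics are missing")
        return out
    f0 = p.f0_hz[v]
    t = p.frame_times[v]
    out["f0_mean"] = float(np.mean(f0))
    out["f0_sd"] = float(np.std(f0, ddof=1))
    out["f0_max"] = float(np.max(f0))
    out["f0_min"] = float(np.min(f0))
    out["f0_range"] = out["f0_max"] - out["f0_min"]
    out["f0_st"] = float(f0[0])
    out["f0_end"] = float(f0[-1])
    out["f0_change"] = out["f0_end"] - out["f0_st"]
    out["f0_mnpozr"] = float(t[np.argmin(f0)] / p.call_length)
    out["f0_mxpozr"] = float(t[np.argmax(f0)] / p.call_length)
    return out


def _voiced_runs(p: PitchTrack):
    """Contiguous voiced frame index runs as (start, stop) inclusive pairs."""
    idx = np.flatnonzero(p.voiced)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [len(idx) - 1]))
    return [(idx[a], idx[b]) for a, b in zip(starts, stops)]


def extract_pulses(w: Waveform, p: PitchTrack) -> PulseSequence:
    """Mark one epoch per glottal cycle in voiced regions.

    The first epoch of each voiced run is the strongest amplitude peak within
    one period; every following epoch is located by cross-correlating the
    current cycle with the signal one period ahead (lag search 0.7-1.3 T,
    parabolic refinement).  Matching whole cycle shapes instead of single
    peaks keeps the period estimates robust to additive noise.
    """
    fs = w.sample_rate_hz
    x = np.asarray(w.samples, float)
    xa = np.abs(x)
    hop = p.settings.hop_s
    times = []
    for a, b in _voiced_runs(p):
        t0 = max(p.frame_times[a] - hop, 0.0)
        t1 = min(p.frame_times[b] + hop, w.duration_s)
        ft = p.frame_times[a : b + 1]
        ff = p.f0_hz[a : b + 1]

        def f0_at(t):
            return float(np.interp(t, ft, ff))

        # first pulse: strongest peak within one period of the run start
        T = 1.0 / f0_at(t0)
        i0, i1 = int(t0 * fs), min(int((t0 + T) * fs) + 1, len(x))
        if i1 <= i0 + 1:
            continue
        t = (i0 + int(np.argmax(xa[i0:i1]))) / fs
        times.append(t)
        while True:
            T = 1.0 / f0_at(t)
            if t + 1.3 * T > t1 + 0.5 * T:
                break
            it = int(round(t * fs))
            wlen = max(int(0.8 * T * fs), 8)
            l0, l1 = int(0.7 * T * fs), int(np.ceil(1.3 * T * fs))
            if it + l1 + wlen > len(x) or it + wlen > len(x):
                break
            seg = x[it : it + wlen]
            c = np.correlate(x[it + l0 : it + l1 + wlen], seg, mode="valid")
            j = int(np.argmax(c))
            if 0 < j < len(c) - 1:
                aa, bb, cc = c[j - 1], c[j], c[j + 1]
                den = aa - 2 * bb + cc
                d = 0.5 * (aa - cc) / den if den < -1e-30 else 0.0
                d = float(np.clip(d, -0.5, 0.5))
            else:
                d = 0.0
            t = t + (l0 + j + d) / fs
            times.append(t)
    times = np.asarray(times)
    if len(times) > 1:
        times = times[np.concatenate(([True], np.diff(times) > 0))]
    return PulseSequence(times)


def jitter_features(s: PulseSequence, p: PitchTrack) -> dict:
    """Local jitter (ppj), cycle count (ppp) and cycles per voiced second (ppm).

    ppj = mean |T_i - T_{i-1}| / mean T over consecutive in-range periods;
    periods spanning voicing gaps are excluded.
    """
    st = p.settings
    periods = s.periods()
    lo, hi = 0.7 / st.ceiling_hz, 1.3 / st.floor_hz
    valid = (periods >= lo) & (periods <= hi)
    if np.any(valid):
        # a missed or doubled pulse yields a period far from the local norm;
        # exclude those from the perturbation statistics
        med = np.median(periods[valid])
        valid &= np.abs(periods / med - 1.0) < 0.3
    out = {"ppj": np.nan, "ppp": float(len(s.pulse_times)), "ppm": np.nan}
    if p.voiced_duration > 0:
        out["ppm"] = out["ppp"] / p.voiced_duration
    good = periods[valid]
    if len(s.pulse_times) < 3 or len(good) < 2:
        return out
    pair_ok = valid[:-1] & valid[1:]
    if not np.any(pair_ok):
        return out
    diffs = np.abs(np.diff(periods))[pair_ok]
    out["ppj"] = float(np.mean(diffs) / np.mean(good))
    return out


def harmonicity(w: Waveform, p: PitchTrack, cap_db: float = 40.0) -> dict:
    """Per-frame HNR = 10 log10(r / (1 - r)) at the tracked f0 lag, capped.

    r is the window-corrected normalized autocorrelation evaluated (with
    parabolic refinement) at the lag of the frame's f0 estimate.
    """
    out = {"HNR": np.nan, "HNR_SD": np.nan, "HNR_max": np.nan}
    if p.n_voiced == 0:
        return out
    fs = w.sample_rate_hz
    x = w.samples - np.mean(w.samples)
    _, r, _ = _frames_and_acf(x, fs, p.settings)
    vals = []
    for i in np.flatnonzero(p.voiced):
        lag = int(round(fs / p.f0_hz[i]))
        if lag < 1 or lag >= r.shape[1] - 1:
            continue
        # local refinement: the integer lag may sit off the true peak
        k = lag - 1 + int(np.argmax(r[i, lag - 1 : lag + 2]))
        _, rv = _parabolic(r[i], k)
        rv = float(np.clip(rv, 1e-6, 1 - 1e-6))
        hnr = 10 * np.log10(rv / (1 - rv))
        vals.append(min(hnr, cap_db))
    if not vals:
        return out
    vals = np.asarray(vals)
    out["HNR"] = float(np.mean(vals))
    out["HNR_SD"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    out["HNR_max"] = float(np.max(vals))
    return out
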