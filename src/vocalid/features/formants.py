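"""Formant estimation by linear prediction and formant dispersion (dF).

The signal is decimated to twice the gender-dependent formant ceiling,
pre-emphasized, and an autocorrelation LPC polynomial is fit per voiced
frame.  Pole angles give candidate formants; wide-bandwidth poles are
discarded.  Median per-formant frequencies over frames yield the first five
formants and dF = (F5 - F1) / 4, the mean spacing of five consecutive
formants (a vocal-tract length correlate).
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.linalg import solve_toeplitz

from ..synth import Waveform
from .pitch import PitchTrack

__all__ = ["estimate_formants", "formant_dispersion"]


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC; returns polynomial [1, a1..ap] or None."""
    n = len(frame)
    if n <= order + 1:
        return None
    ac = signal.fftconvolve(frame, frame[::-1])[n - 1 : n + order]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    ac[0] *= 1.000001  # tiny ridge keeps the Toeplitz solve stable
    try:
        a = solve_toeplitz((ac[:order], ac[:order]), -ac[1 : order + 1])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate(([1.0], a))


def estimate_formants(
    w: Waveform,
    p: PitchTrack,
    ceiling_hz: float = 5500.0,
    order: int = 14,
    max_bandwidth_hz: float = 400.0,
    frame_s: float = 0.030,
    n_formants: int = 5,
) -> np.ndarray:
    """Median frequencies of the first ``n_formants`` formants over voiced frames.

    Returns an array of length ``n_formants`` (nan-filled if too few frames
    yield enough resolvable formants).
    """
    fs = w.sample_rate_hz
    down = max(int(fs // (2 * ceiling_hz)), 1)
    if down > 1:
        # sharp anti-alias FIR: the default short filter would eat F5
        h = signal.firwin(64 * down + 1, 0.98 / down)
        x = signal.resample_poly(w.samples, 1, down, window=h)
    else:
        x = np.asarray(w.samples, dtype=float)
    fs2 = fs / down

    alpha = np.exp(-2 * np.pi * 50.0 / fs2)
    x = np.append(x[0], x[1:] - alpha * x[:-1])

    win = int(round(frame_s * fs2))
    if len(x) < win or p.n_voiced == 0:
        return np.full(n_formants, np.nan)
    window = np.hamming(win)

    rows = []
    for t in p.frame_times[p.voiced]:
        c = int(round(t * fs2))
        a, b = c - win // 2, c - win // 2 + win
        if a < 0 or b > len(x):
            continue
        poly = _lpc(x[a:b] * window, order)
        if poly is None:
            continue
        roots = np.roots(poly)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs2 / (2 * np.pi)
        bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs2 / np.pi
        keep = (freqs > 90) & (freqs < ceiling_hz - 50) & (bws < max_bandwidth_hz)
        freqs = np.sort(freqs[keep])
        if len(freqs) >= n_formants:
            rows.append(freqs[:n_formants])
    if len(rows) < 3:
        warnings.warn("too few frames with resolvable formants; dF missing")
        return np.full(n_formants, np.nan)
    return np.median(np.asarray(rows), axis=0)


def formant_dispersion(
    w: Waveform, p: PitchTrack, ceiling_hz: float = 5500.0, **kwargs
) -> float:
    """dF: mean difference of five consecutive formants = (F5 - F1) / 4."""
    f = estimate_formants(w, p, ceiling_hz=ceiling_hz, **kwargs)
    if np.any(np.isnan(f)):
        return np.nan
    return float((f[-1] - f[0]) / (len(f) - 1))
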