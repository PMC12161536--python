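"""Signal-similarity metrics for validating simulated surface EMG.

Per repetition two scalar features are extracted — the root mean square and
the median frequency (the frequency that splits the FFT power spectrum into
equal halves) — plus two envelopes: the rectified signal smoothed with a
0.5 s moving average (temporal) and the FFT magnitude spectrum smoothed
with a 10 Hz moving average (spectral).

Feature distributions are compared with
``FeatSimi = 1 - (avgSimi + stdSimi) / 2`` where each term is the absolute
difference of the statistics normalised by their sum; envelopes are
compared with Pearson correlation clamped at zero.  The General Similarity
Index is the mean of the four indices; everything lives in [0, 1], 1 being
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureDistribution",
    "Envelope",
    "compute_features",
    "compute_envelopes",
    "feat_simi",
    "envelope_cc",
    "similarity_indices",
]


@dataclass
class FeatureDistribution:
    """One feature value per repetition (RMS in signal units or MF in Hz)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("feature distribution must be non-empty")


@dataclass
class Envelope:
    """Non-negative envelope vector in the time or frequency domain."""

    domain: str  # "time" | "frequency"
    x: np.ndarray


def compute_features(signal: np.ndarray, fs: float) -> tuple[float, float]:
    """(RMS, median frequency in Hz) of one repetition.

    The median frequency is the smallest frequency at which the cumulative
    one-sided FFT power reaches half the total; an all-zero signal has no
    spectrum and raises.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.size == 0:
        raise ValueError("empty signal")
    rms = float(np.sqrt(np.mean(sig**2)))
    power = np.abs(np.fft.rfft(sig)) ** 2
    total = power.sum()
    if total <= 0:
        raise ValueError("median frequency undefined for an all-zero signal")
    freqs = np.fft.rfftfreq(sig.size, d=1.0 / fs)
    cum = np.cumsum(power)
    mf = float(freqs[np.searchsorted(cum, 0.5 * total)])
    return rms, mf


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Centred moving average with edge truncation (partial windows)."""
    if win <= 1:
        return x.copy()
    kernel = np.ones(win)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def compute_envelopes(
    signal: np.ndarray,
    fs: float,
    time_window_s: float = 0.5,
    freq_window_hz: float = 10.0,
) -> tuple[Envelope, Envelope]:
    """Temporal and spectral envelopes of one repetition.

    Temporal: moving average of the rectified signal over ``time_window_s``.
    Spectral: moving average of the one-sided FFT magnitude over
    ``freq_window_hz`` worth of bins.  The signal must be longer than the
    temporal window.
    """
    sig = np.asarray(signal, dtype=float)
    win_t = int(round(time_window_s * fs))
    if sig.size <= win_t:
        raise ValueError("signal shorter than the temporal window")
    temporal = _moving_average(np.abs(sig), max(win_t, 1))
    mag = np.abs(np.fft.rfft(sig))
    df = fs / sig.size
    win_f = max(int(round(freq_window_hz / df)), 1)
    spectral = _moving_average(mag, win_f)
    return Envelope("time", temporal), Envelope("frequency", spectral)


def feat_simi(
    real: FeatureDistribution, sim: FeatureDistribution
) -> float:
    """``1 - (avgSimi + stdSimi)/2`` with sum-normalised differences.

    Undefined (NaN) when both means or both stds are zero, since the
    normalising sum vanishes.
    """
    ra, sa = float(np.mean(real.values)), float(np.mean(sim.values))
    rs, ss = float(np.std(real.values)), float(np.std(sim.values))
    if ra + sa == 0 or (rs + ss == 0 and (rs != 0 or ss != 0)):
        return float("nan")
    avg_simi = abs(ra - sa) / (ra + sa)
    std_simi = 0.0 if rs + ss == 0 else abs(rs - ss) / (rs + ss)
    return 1.0 - 0.5 * (avg_simi + std_simi)


def envelope_cc(real: Envelope, sim: Envelope) -> float:
    """Pearson correlation of two envelopes, clamped at zero.

    Envelopes of differing length are linearly resampled to the shorter
    one before correlating.
    """
    a, b = np.asarray(real.x, float), np.asarray(sim.x, float)
    n = min(len(a), len(b))
    if len(a) != n:
        a = np.interp(np.linspace(0, len(a) - 1, n), np.arange(len(a)), a)
    if len(b) != n:
        b = np.interp(np.linspace(0, len(b) - 1, n), np.arange(len(b)), b)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    cc = float(np.corrcoef(a, b)[0, 1])
    return max(cc, 0.0)


def similarity_indices(
    real_rms: FeatureDistribution,
    sim_rms: FeatureDistribution,
    real_mf: FeatureDistribution,
    sim_mf: FeatureDistribution,
    real_time_env: Envelope,
    sim_time_env: Envelope,
    real_freq_env: Envelope,
    sim_freq_env: Envelope,
) -> dict:
    """All four indices plus their mean, the General Similarity Index."""
    rms_simi = feat_simi(real_rms, sim_rms)
    mf_simi = feat_simi(real_mf, sim_mf)
    time_cc = envelope_cc(real_time_env, sim_time_env)
    freq_cc = envelope_cc(real_freq_env, sim_freq_env)
    gsi = float(np.mean([rms_simi, mf_simi, time_cc, freq_cc]))
    return {
        "rms_simi": rms_simi,
        "mf_simi": mf_simi,
        "time_cc": time_cc,
        "freq_cc": freq_cc,
        "gsi": gsi,
    }
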