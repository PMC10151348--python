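"""Spectro-acoustic measurement of syllables: 21 features per clip.

The registry covers three families used throughout the analyses:

* **frequency** — statistics of the mean power spectrum treated as a
  probability mass function over frequency (mean, sd, median, quartiles, IQR),
  the fundamental-frequency track (mean/min/max, nullable when no frame passes
  the voicing threshold), and the dominant (peak-power) frequency track
  (mean/min/max);
* **power distribution** — shape of the spectrum: skew, kurtosis, spectral
  entropy, spectral flatness, time entropy, overall entropy;
* **spectrotemporal** — syllable duration, dominant frequency slope, and the
  modulation index (dominant-track path length over its range).

All frequencies are in Hz, durations in seconds, entropies/flatness in [0, 1].
Every measure is invariant to global amplitude scaling of the clip.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import SyllableClip

__all__ = [
    "FEATURE_NAMES",
    "FUND_FEATURES",
    "FREQ_FEATURES",
    "POWER_FEATURES",
    "SPECTROTEMPORAL_FEATURES",
    "ID_COLUMNS",
    "mean_spectrum",
    "spectral_shape_stats",
    "entropy_measures",
    "dominant_track",
    "fundamental_track",
    "extract_features",
    "extract_table",
    "validate_feature_table",
]

ID_COLUMNS = ["species", "bird", "motif", "syllable"]

#: The 21 per-syllable acoustic features, in canonical column order.
FEATURE_NAMES = [
    "duration",
    "mean_freq",
    "sd_freq",
    "median_freq",
    "q25",
    "q75",
    "iqr",
    "skew",
    "kurtosis",
    "spectral_entropy",
    "spectral_flatness",
    "time_entropy",
    "overall_entropy",
    "fund_mean",
    "fund_min",
    "fund_max",
    "dom_mean",
    "dom_min",
    "dom_max",
    "modulation_index",
    "dom_slope",
]

#: The three fundamental-frequency features; the only columns allowed to be
#: missing (noisy syllables can fail the voicing threshold on every frame).
FUND_FEATURES = ["fund_mean", "fund_min", "fund_max"]

# family grouping: singular frequency measures vs. spectrum-shape (power
# distribution) measures vs. temporal/spectrotemporal measures
FREQ_FEATURES = [
    "mean_freq", "median_freq", "q25", "q75",
    "fund_mean", "fund_min", "fund_max", "dom_mean", "dom_min", "dom_max",
]
POWER_FEATURES = [
    "sd_freq", "iqr", "skew", "kurtosis", "spectral_entropy",
    "spectral_flatness", "time_entropy", "overall_entropy",
]
SPECTROTEMPORAL_FEATURES = ["duration", "modulation_index", "dom_slope"]

BAND = (250.0, 8000.0)  # analysis band, Hz
DEFAULT_WINDOW = 512
DEFAULT_OVERLAP = 0.5


def _frames(x: np.ndarray, window: int, overlap: float) -> np.ndarray:
    """Hann-windowed frames (n_frames x window); pads a short clip to one frame."""
    hop = max(1, int(round(window * (1.0 - overlap))))
    if x.size < window:
        x = np.pad(x, (0, window - x.size))
    n = 1 + (x.size - window) // hop
    idx = np.arange(window)[None, :] + hop * np.arange(n)[:, None]
    return x[idx] * np.hanning(window)[None, :]


def mean_spectrum(
    clip: SyllableClip, window: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP
) -> tuple[np.ndarray, np.ndarray]:
    """Mean power spectrum restricted to the 250-8000 Hz band, normalized to
    sum to 1. Returns ``(freqs_hz, power)``.

    Clips shorter than one window are zero-padded to a single frame (warned).
    """
    x = np.asarray(clip.samples, dtype=float)
    if x.size < window:
        warnings.warn("clip shorter than one analysis window; padded to a single frame")
    frames = _frames(x, window, overlap)
    psd = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(window, d=1.0 / clip.sample_rate)
    mean_psd = psd.mean(axis=0)
    mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    freqs, mean_psd = freqs[mask], mean_psd[mask]
    total = mean_psd.sum()
    if total <= 0:
        raise ValueError("zero power in the analysis band")
    return freqs, mean_psd / total


def spectral_shape_stats(freqs: np.ndarray, spectrum: np.ndarray) -> dict:
    """Moments and quantiles of frequency under the spectrum-as-pmf view.

    Quantile convention: the lowest frequency whose cumulative mass reaches the
    requested probability (inverse-CDF on the discrete mass function).
    """
    p = np.asarray(spectrum, dtype=float)
    f = np.asarray(freqs, dtype=float)
    mean = float(np.sum(p * f))
    var = float(np.sum(p * (f - mean) ** 2))
    sd = np.sqrt(var)
    cdf = np.cumsum(p)

    def quantile(q):
        return float(f[np.searchsorted(cdf, q)])

    if sd > 0:
        skew = float(np.sum(p * (f - mean) ** 3) / sd**3)
        kurt = float(np.sum(p * (f - mean) ** 4) / sd**4)
    else:
        warnings.warn("degenerate one-bin spectrum: skew/kurtosis undefined")
        skew = kurt = float("nan")
    q25, med, q75 = quantile(0.25), quantile(0.5), quantile(0.75)
    return {
        "mean_freq": mean,
        "sd_freq": sd,
        "median_freq": med,
        "q25": q25,
        "q75": q75,
        "iqr": q75 - q25,
        "skew": skew,
        "kurtosis": kurt,
    }


def entropy_measures(
    clip: SyllableClip, freqs: np.ndarray, spectrum: np.ndarray, smooth_s: float = 0.005
) -> dict:
    """Spectral entropy, spectral flatness, time entropy, overall entropy.

    Spectral entropy is Shannon entropy of the normalized spectrum divided by
    log(#bins); flatness is the geometric/arithmetic mean ratio of power; time
    entropy applies the entropy formula to the normalized amplitude envelope;
    overall entropy is their product.
    """
    p = np.asarray(spectrum, dtype=float)
    nz = p[p > 0]
    # a one-bin spectrum carries no frequency uncertainty: entropy 0
    spec_ent = float(-(nz * np.log(nz)).sum() / np.log(p.size)) if p.size > 1 else 0.0
    flatness = float(np.exp(np.mean(np.log(p + 1e-300))) / np.mean(p))
    win = max(1, int(round(smooth_s * clip.sample_rate)))
    env = np.convolve(np.abs(clip.samples), np.ones(win) / win, mode="same")
    if env.sum() <= 0:
        raise ValueError("zero-power clip")
    env = env / env.sum()
    env_nz = env[env > 0]
    time_ent = float(-(env_nz * np.log(env_nz)).sum() / np.log(env.size))
    return {
        "spectral_entropy": spec_ent,
        "spectral_flatness": flatness,
        "time_entropy": time_ent,
        "overall_entropy": spec_ent * time_ent,
    }


def dominant_track(
    clip: SyllableClip, window: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP
) -> dict:
    """Per-frame peak-power frequency and its summary statistics.

    ``dom_slope = (dom_end - dom_start) / track span`` (Hz/s, signed), where
    the span is the time between the first and last frame centers (using the
    full clip duration instead would bias the slope low by the half-window
    margins at each end);
    ``modulation_index = sum(|delta dom|) / (dom_max - dom_min)``, defined as 1
    for a flat track (one traversal of a zero range).
    """
    x = np.asarray(clip.samples, dtype=float)
    frames = _frames(x, window, overlap)
    psd = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(window, d=1.0 / clip.sample_rate)
    mask = (freqs >= BAND[0]) & (freqs <= BAND[1])
    psd = psd[:, mask]
    freqs = freqs[mask]
    power = psd.sum(axis=1)
    voiced = power > 1e-12 * power.max() if power.max() > 0 else np.zeros_like(power, bool)
    if not voiced.any():
        raise ValueError("all frames silent; no dominant track")
    track = freqs[np.argmax(psd[voiced], axis=1)]
    hop = max(1, int(round(window * (1.0 - overlap))))
    span = (track.size - 1) * hop / clip.sample_rate
    duration = span if span > 0 else clip.duration
    dom_range = float(track.max() - track.min())
    path = float(np.abs(np.diff(track)).sum())
    return {
        "dom_start": float(track[0]),
        "dom_end": float(track[-1]),
        "dom_mean": float(track.mean()),
        "dom_min": float(track.min()),
        "dom_max": float(track.max()),
        "dom_slope": (float(track[-1]) - float(track[0])) / duration,
        "modulation_index": path / dom_range if dom_range > 0 else 1.0,
    }


def fundamental_track(
    clip: SyllableClip,
    window: int = 1024,
    overlap: float = DEFAULT_OVERLAP,
    fmin: float = BAND[0],
    fmax: float = 3500.0,
    voicing_threshold: float = 0.5,
) -> dict:
    """Frame-wise fundamental frequency by normalized autocorrelation.

    Frames whose autocorrelation peak (within the lag range implied by
    [fmin, fmax]) falls below ``voicing_threshold`` are treated as unvoiced.
    When every frame is unvoiced, all three statistics are missing (NaN) —
    missingness is data, not an error.
    """
    sr = clip.sample_rate
    x = np.asarray(clip.samples, dtype=float)
    frames = _frames(x, window, overlap)
    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(window - 2, int(np.ceil(sr / fmin)))
    f0s = []
    for frame in frames:
        frame = frame - frame.mean()
        r0 = float(np.dot(frame, frame))
        if r0 <= 0:
            continue
        spec = np.fft.rfft(frame, n=2 * window)
        ac = np.fft.irfft(spec * np.conj(spec))[: window]
        ac = ac / r0
        if lag_max <= lag_min:
            continue
        seg = ac[lag_min : lag_max + 1]
        if seg.max() < voicing_threshold:
            continue
        # the true period is the shortest lag whose autocorrelation peak
        # clears the voicing threshold: peaks at period multiples are equally
        # high (global argmax would halve the f0), while peaks at fractions of
        # the period are weak or negative for natural harmonic rolloffs
        interior = np.flatnonzero(
            (seg[1:-1] >= voicing_threshold)
            & (seg[1:-1] >= seg[:-2])
            & (seg[1:-1] >= seg[2:])
        ) + 1
        if interior.size == 0:
            # threshold is only reached at a search-range boundary: no
            # trustworthy period peak, treat the frame as unvoiced
            continue
        k = int(interior[0])
        lag = lag_min + k
        # parabolic interpolation around the peak for sub-sample lag accuracy
        if 0 < lag < window - 1:
            y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                lag = lag + 0.5 * (y0 - y2) / denom
        f0s.append(sr / lag)
    if not f0s:
        return {"fund_mean": float("nan"), "fund_min": float("nan"), "fund_max": float("nan")}
    f0s = np.asarray(f0s)
    return {
        "fund_mean": float(f0s.mean()),
        "fund_min": float(f0s.min()),
        "fund_max": float(f0s.max()),
    }


def extract_features(clip: SyllableClip, window: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP) -> dict:
    """All 21 features for one clip (plus dom_start/dom_end as extras)."""
    freqs, spec = mean_spectrum(clip, window, overlap)
    out = {"duration": clip.duration}
    out.update(spectral_shape_stats(freqs, spec))
    out.update(entropy_measures(clip, freqs, spec))
    out.update(dominant_track(clip, window, overlap))
    out.update(fundamental_track(clip))
    return out


def extract_table(clips: list[SyllableClip], window: int = DEFAULT_WINDOW, overlap: float = DEFAULT_OVERLAP) -> pd.DataFrame:
    """Feature table: one row per clip, ID columns plus the 21 features.

    Per-clip failures are aggregated into rows flagged NaN across all feature
    columns rather than aborting the batch.
    """
    rows = []
    n_failed = 0
    for clip in clips:
        ids = {
            "species": clip.species,
            "bird": clip.bird,
            "motif": clip.motif,
            "syllable": clip.syllable,
        }
        try:
            feats = extract_features(clip, window, overlap)
        except ValueError:
            n_failed += 1
            feats = {name: float("nan") for name in FEATURE_NAMES}
        rows.append({**ids, **{k: feats[k] for k in FEATURE_NAMES}})
    if n_failed:
        warnings.warn(f"{n_failed} clip(s) failed feature extraction; rows flagged NaN")
    table = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_NAMES)
    for col in FUND_FEATURES:
        frac = table[col].isna().mean()
        if frac > 0:
            warnings.warn(f"{col}: {frac:.2%} missing")
    return table


def validate_feature_table(table: pd.DataFrame) -> None:
    """Schema check: ID columns present, exactly the 21 feature columns, and
    missingness confined to the fundamental-frequency features."""
    missing_cols = [c for c in ID_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    non_fund = [c for c in FEATURE_NAMES if c not in FUND_FEATURES]
    bad = [c for c in non_fund if table[c].isna().any()]
    if bad:
        raise ValueError(f"missing values outside fundamental-frequency columns: {bad}")
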