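"""Recording preprocessing: band-limiting, RMS power matching, and syllable
segmentation.

The pipeline order is bandpass -> rms_match -> segment_syllables. Filtering is
zero-phase (forward-backward 4th-order Butterworth) so syllable onsets are not
shifted by group delay. RMS matching is to a dB level re. unity full scale;
absolute calibration is irrelevant because every downstream feature is
amplitude-scale invariant after matching.

Time convention: seconds, half-open intervals [onset, offset), 0-based sample
indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "Motif",
    "SyllableClip",
    "bandpass",
    "rms_match",
    "segment_syllables",
    "group_bouts",
    "read_wav",
    "write_wav",
]

DEFAULT_BAND = (250.0, 8000.0)  # Hz
DEFAULT_TARGET_DB = 65.0  # dB re unity full scale


@dataclass
class Motif:
    """One song motif (or GW-style bout treated as a motif)."""

    samples: np.ndarray
    sample_rate: float
    species: str = ""
    bird: str = ""
    motif: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("motif waveform is empty")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class SyllableClip:
    """One segmented syllable with provenance and time bounds."""

    samples: np.ndarray
    sample_rate: float
    onset: float
    offset: float
    species: str = ""
    bird: str = ""
    motif: str = ""
    syllable: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not (0 <= self.onset < self.offset):
            raise ValueError("require 0 <= onset < offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def read_wav(path, **meta) -> Motif:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data, dtype=float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    # integer PCM scale is irrelevant downstream; RMS matching normalizes it
    return Motif(samples=data, sample_rate=float(rate), **meta)


def write_wav(path, samples: np.ndarray, sample_rate: float) -> None:
    wavfile.write(str(path), int(sample_rate), np.asarray(samples, dtype=np.float32))


def bandpass(motif: Motif, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]) -> Motif:
    """Zero-phase Butterworth bandpass; default passband 250-8000 Hz."""
    nyq = motif.sample_rate / 2.0
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=motif.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, motif.samples)
    return replace(motif, samples=filtered)


def rms_match(motif: Motif, target_db: float = DEFAULT_TARGET_DB) -> Motif:
    """Scale the waveform so 20*log10(RMS) equals ``target_db`` exactly.

    Idempotent and invariant to the input's own scale. Raises on silent input.
    """
    rms = float(np.sqrt(np.mean(motif.samples**2)))
    if rms == 0.0:
        raise ValueError("cannot RMS-match an all-zero motif")
    target_rms = 10.0 ** (target_db / 20.0)
    return replace(motif, samples=motif.samples * (target_rms / rms))


def _envelope(samples: np.ndarray, sample_rate: float, smooth_s: float) -> np.ndarray:
    win = max(1, int(round(smooth_s * sample_rate)))
    kernel = np.ones(win) / win
    return np.convolve(np.abs(samples), kernel, mode="same")


def segment_syllables(
    motif: Motif,
    threshold: float = 0.10,
    min_duration: float = 0.010,
    min_gap: float = 0.010,
    smooth_s: float = 0.005,
) -> list[SyllableClip]:
    """Envelope-threshold segmentation into syllables.

    Maximal runs where the smoothed rectified envelope is >= ``threshold`` x
    its peak; gaps shorter than ``min_gap`` are merged, then runs shorter than
    ``min_duration`` dropped. Returns clips sorted by onset, non-overlapping.
    Silence yields an empty list.
    """
    env = _envelope(motif.samples, motif.sample_rate, smooth_s)
    peak = env.max()
    if peak <= 0:
        return []
    above = env >= threshold * peak
    if not above.any():
        return []
    # run boundaries
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + [e + 1 for e in edges if not above[e]]
    ends = [e + 1 for e in edges if above[e]] + ([above.size] if above[-1] else [])
    runs = list(zip(starts, ends))
    # merge gaps shorter than min_gap
    gap_n = int(round(min_gap * motif.sample_rate))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    # drop runs shorter than min_duration
    min_n = int(round(min_duration * motif.sample_rate))
    clips = []
    idx = 0
    for s, e in merged:
        if e - s < min_n:
            continue
        clips.append(
            SyllableClip(
                samples=motif.samples[s:e],
                sample_rate=motif.sample_rate,
                onset=s / motif.sample_rate,
                offset=e / motif.sample_rate,
                species=motif.species,
                bird=motif.bird,
                motif=motif.motif,
                syllable=idx,
            )
        )
        idx += 1
    return clips


def group_bouts(clips: list[SyllableClip], max_isi: float = 2.5) -> list[int]:
    """Assign bout ids: consecutive clips with inter-syllable interval (onset
    minus previous offset) below ``max_isi`` seconds share a bout.

    Default 2.5 s (2500 ms). Input must be sorted by onset.
    """
    onsets = [c.onset for c in clips]
    if onsets != sorted(onsets):
        raise ValueError("clips must be sorted by onset")
    bouts = []
    current = 0
    for i, clip in enumerate(clips):
        if i > 0 and clip.onset - clips[i - 1].offset >= max_isi:
            current += 1
        bouts.append(current)
    return bouts
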