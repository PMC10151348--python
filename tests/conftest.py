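"""Shared fixtures: the bundled 7-species tree, small synthetic tables, and
constructed waveforms with known ground truth."""

import numpy as np
import pytest

from songphylo.preprocess import Motif, SyllableClip
from songphylo.synth import SynthSpec, synth_feature_table
from songphylo.trees import example_tree


@pytest.fixture(scope="session")
def tree7():
    return example_tree()


@pytest.fixture(scope="session")
def small_spec():
    """Small, complete (no missingness) feature-table design for fast tests."""
    return SynthSpec(
        syllables_per_species={s: 40 for s in "ZF LF DF RF CB GW BF".split()},
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_table(tree7, small_spec):
    return synth_feature_table(small_spec, tree7)


def tone_clip(freq=3000.0, duration=0.2, sr=44100.0, **ids):
    t = np.arange(int(round(duration * sr))) / sr
    return SyllableClip(
        samples=np.sin(2 * np.pi * freq * t), sample_rate=sr,
        onset=0.0, offset=duration, **ids,
    )


def noise_clip(duration=0.2, sr=44100.0, seed=0, **ids):
    rng = np.random.default_rng(seed)
    return SyllableClip(
        samples=rng.standard_normal(int(round(duration * sr))), sample_rate=sr,
        onset=0.0, offset=duration, **ids,
    )


def tone_motif(freq=3000.0, duration=0.5, sr=44100.0, **ids):
    t = np.arange(int(round(duration * sr))) / sr
    return Motif(samples=np.sin(2 * np.pi * freq * t), sample_rate=sr, **ids)
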