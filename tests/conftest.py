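"""Shared fixtures: small synthetic sessions generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from prpkit import preprocess, prp, synthetic
from prpkit.types import EpochSet


@pytest.fixture(scope="session")
def inventory():
    return synthetic.default_inventory()


@pytest.fixture(scope="session")
def speakers():
    return synthetic.default_speakers()


@pytest.fixture(scope="session")
def alignment_30s(inventory, speakers):
    return synthetic.gen_phoneme_sequence(inventory, 30.0, 6, speakers, seed=11)


@pytest.fixture(scope="session")
def kernels8():
    return synthetic.default_kernels(8)


@pytest.fixture(scope="session")
def clean_session(inventory, speakers, alignment_30s, kernels8):
    """Noise- and artifact-free EEG for oracle comparisons."""
    rec, truth = synthetic.gen_eeg(
        alignment_30s,
        kernels8,
        inventory,
        speakers,
        n_electrodes=8,
        fs=500.0,
        noise_snr_db=None,
        artifact_rate_per_min=0.0,
        seed=5,
    )
    return rec, truth


@pytest.fixture(scope="session")
def noisy_session(inventory, speakers, alignment_30s, kernels8):
    rec, truth = synthetic.gen_eeg(
        alignment_30s,
        kernels8,
        inventory,
        speakers,
        n_electrodes=8,
        fs=500.0,
        noise_snr_db=0.0,
        artifact_rate_per_min=0.0,
        seed=5,
    )
    return rec, truth


def decimate_epochs(epochs: EpochSet, step: int) -> EpochSet:
    return EpochSet(
        epochs.epochs[:, :, ::step],
        epochs.lags_ms[::step],
        epochs.labels,
        epochs.speakers,
        epochs.utterances,
        epochs.onsets,
    )


def paired_epochs(inventory, speakers, seed, duration=60.0, n_utt=12, snr=0.0,
                  duration_means=None, fs=500.0, step=1, n_electrodes=8):
    """EEG + ideal-spectrogram epoch sets over the same kept tokens."""
    alignment = synthetic.gen_phoneme_sequence(
        inventory, duration, n_utt, speakers, seed=seed, duration_means=duration_means
    )
    kernels = synthetic.default_kernels(n_electrodes)
    rec, _ = synthetic.gen_eeg(
        alignment, kernels, inventory, speakers,
        n_electrodes=n_electrodes, fs=fs, noise_snr_db=snr,
        artifact_rate_per_min=0.0, seed=seed + 1,
    )
    rec = preprocess.zscore_channels(preprocess.bandpass_filter(rec))
    spec = synthetic.gen_ideal_spectrogram(alignment, inventory, speakers, frame_rate=fs)
    kept = preprocess.exclude_utterance_onset_tokens(alignment)
    ep = prp.extract_epochs(rec, kept, (-100.0, 600.0))
    sp = prp.extract_spectrogram_epochs(spec, kept, (-100.0, 600.0))
    common = sorted(set(np.round(ep.onsets, 9)) & set(np.round(sp.onsets, 9)))
    ep = ep.subset(np.isin(np.round(ep.onsets, 9), common))
    sp = sp.subset(np.isin(np.round(sp.onsets, 9), common))
    if step > 1:
        ep, sp = decimate_epochs(ep, step), decimate_epochs(sp, step)
    return ep, sp
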