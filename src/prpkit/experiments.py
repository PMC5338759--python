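"""Canned parameter-recovery experiments on synthetic sessions.

Each function runs one complete verification study at desk scale -- from
generation through analysis -- and returns plain-number summaries. They
exist so the same study conditions back both the test suite and the
reproduction script. Problem sizes (session length, electrode count,
sampling rate, cohort size) are fixed here as the package's reference
conditions; docs/methods.md motivates them.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, prp, rsa, speaker as spkm, stats, synthetic
from .types import EpochSet, PRPSet

__all__ = [
    "EQUAL_DURATIONS",
    "paired_session_epochs",
    "prp_oracle_error",
    "latency_recovery",
    "recurrent_structure",
    "speaker_identity_null",
    "vowel_speaker_recovery",
    "null_calibration",
]

COMPONENTS_MS = (50.0, 120.0, 230.0, 400.0)
EQUAL_DURATIONS = {m: 0.09 for m in ("plosive", "fricative", "nasal", "vowel")}


def _decimate(epochs: EpochSet, step: int) -> EpochSet:
    if step <= 1:
        return epochs
    return EpochSet(
        epochs.epochs[:, :, ::step], epochs.lags_ms[::step], epochs.labels,
        epochs.speakers, epochs.utterances, epochs.onsets,
    )


def paired_session_epochs(
    seed: int,
    duration_s: float = 60.0,
    n_utterances: int = 12,
    snr_db: float | None = 0.0,
    duration_means: dict | None = None,
    fs: float = 500.0,
    n_electrodes: int = 8,
    step: int = 1,
    artifact_rate: float = 0.0,
) -> tuple[EpochSet, EpochSet]:
    """One synthetic subject: preprocessed EEG epochs and the matching
    auditory-spectrogram epochs over the same kept tokens."""
    inv = synthetic.default_inventory()
    spk = synthetic.default_speakers()
    alignment = synthetic.gen_phoneme_sequence(
        inv, duration_s, n_utterances, spk, seed=seed, duration_means=duration_means
    )
    kernels = synthetic.default_kernels(n_electrodes)
    rec, _ = synthetic.gen_eeg(
        alignment, kernels, inv, spk, n_electrodes=n_electrodes, fs=fs,
        noise_snr_db=snr_db, artifact_rate_per_min=artifact_rate, seed=seed + 1,
    )
    rec = preprocess.zscore_channels(preprocess.bandpass_filter(rec))
    spec = synthetic.gen_ideal_spectrogram(alignment, inv, spk, frame_rate=fs)
    kept = preprocess.exclude_utterance_onset_tokens(alignment)
    ep = prp.extract_epochs(rec, kept, (-100.0, 600.0))
    sp = prp.extract_spectrogram_epochs(spec, kept, (-100.0, 600.0))
    common = sorted(set(np.round(ep.onsets, 9)) & set(np.round(sp.onsets, 9)))
    ep = ep.subset(np.isin(np.round(ep.onsets, 9), common))
    sp = sp.subset(np.isin(np.round(sp.onsets, 9), common))
    return _decimate(ep, step), _decimate(sp, step)


def prp_oracle_error(seed: int, duration_s: float = 300.0) -> dict:
    """Max deviation of the category averaging from literal brute-force loops
    on a five-minute session (both neural and acoustic pathways)."""
    ep, sp = paired_session_epochs(seed, duration_s=duration_s,
                                   n_utterances=int(duration_s / 5), snr_db=0.0)
    worst = 0.0
    for epochs, compute in ((ep, prp.compute_prp), (sp, prp.compute_avg_spectrograms)):
        out = compute(epochs)
        for k, cat in enumerate(out.categories):
            acc = np.zeros(epochs.epochs.shape[1:])
            n = 0
            for i, lab in enumerate(epochs.labels):
                if lab == cat:
                    acc += epochs.epochs[i]
                    n += 1
            worst = max(worst, float(np.max(np.abs(out.values[k] - acc / n))))
            assert n == out.counts[k]
    return {"max_abs_error": worst, "n_tokens": len(ep)}


def latency_recovery(seed: int, n_runs: int = 20, duration_s: float = 120.0) -> dict:
    """Recover the four planted component latencies from the manner F series.

    One synthetic subject per seeded run at 0 dB SNR; a component counts as
    recovered when the F argmax within +/-25 ms of the planted latency lies
    within +/-10 ms of it and is FDR-significant at q = 0.05.
    """
    inv = synthetic.default_inventory()
    partition = stats.MannerPartition({l: inv.manner(l) for l in inv.labels})
    good_runs = 0
    peaks = {L: [] for L in COMPONENTS_MS}
    for r in range(n_runs):
        ep, _ = paired_session_epochs(seed + 1000 * r, duration_s=duration_s,
                                      n_utterances=int(duration_s / 5), snr_db=0.0)
        values, groups, lags = stats.units_from_epochs(ep, partition, electrode=0)
        fs = stats.manner_f_series(values, groups, lags, q=0.05)
        ok = True
        for latency in COMPONENTS_MS:
            peak = fs.peak_lag((latency - 25.0, latency + 25.0))
            peaks[latency].append(peak)
            significant = bool(fs.mask[int(np.argmin(np.abs(lags - peak)))])
            if abs(peak - latency) > 10.0 or not significant:
                ok = False
        good_runs += ok
    return {
        "runs_recovered": good_runs,
        "n_runs": n_runs,
        "median_peaks_ms": {L: float(np.median(peaks[L])) for L in COMPONENTS_MS},
    }


def recurrent_structure(seed: int, duration_s: float = 240.0) -> dict:
    """Bootstrap covariance map between neural and acoustic distance series.

    Durations are equalized across manners so token timing carries no manner
    information and the only planted neural-acoustic link is the kernel
    coupling. Counts significant cells at each late component (acoustic lag
    in-phone) and cells outside every planted component region.
    """
    ep, sp = paired_session_epochs(
        seed, duration_s=duration_s, n_utterances=int(duration_s / 5),
        snr_db=0.0, duration_means=EQUAL_DURATIONS, step=4,
    )
    cross = rsa.bootstrap_significance(ep, sp, n=20, q=0.0001, seed=seed)
    rows, cols = np.nonzero(cross.mask)
    ln = cross.lags_a_ms[rows]
    la = cross.lags_b_ms[cols]
    cells = {}
    for latency in (120.0, 230.0, 400.0):
        cells[latency] = int(
            np.sum((np.abs(ln - latency) <= 30.0) & (la >= 0.0) & (la <= 100.0))
        )
    in_any_component = np.zeros(ln.size, dtype=bool)
    for latency in COMPONENTS_MS:
        in_any_component |= np.abs(ln - latency) <= 40.0
    outside = int(np.sum(~(in_any_component & (la >= -40.0) & (la <= 160.0))))
    return {
        "cells_r2": cells[120.0],
        "cells_r3": cells[230.0],
        "cells_r4": cells[400.0],
        "cells_outside": outside,
        "n_cells_total": int(cross.mask.size),
    }


def speaker_identity_null(n_steps: int = 5) -> dict:
    """Exact zero of the speaker index and SE under speaker identity, and
    monotone growth of the vowel SE over a separation sweep (noise-free
    kernel-level responses)."""
    inv = synthetic.default_inventory()
    kernels0 = synthetic.default_kernels(8, speaker_separation=0.0)
    pa = synthetic.kernel_prps(kernels0, inv, 0)
    pb = synthetic.kernel_prps(kernels0, inv, 1)
    sdm = spkm.speaker_distance_matrix(pa, pb, lag_ms=230.0)
    idx0 = spkm.speaker_index(sdm)
    se0 = spkm.se_index(pa, pb)
    sweep = []
    for sep in np.linspace(0.0, 0.8, n_steps):
        k = synthetic.default_kernels(8, speaker_separation=float(sep))
        a = synthetic.kernel_prps(k, inv, 0)
        b = synthetic.kernel_prps(k, inv, 1)
        se = spkm.se_index(a, b)
        sweep.append(
            float(np.mean([s for c, s in zip(a.categories, se)
                           if inv.manner(c) == "vowel"]))
        )
    violations = int(np.sum(np.diff(sweep) <= 0))
    return {
        "speaker_index_identity": float(idx0),
        "se_identity_max_abs": float(np.max(np.abs(se0))),
        "sweep_monotone_violations": violations,
        "sweep_values": sweep,
    }


def _restrict(p: PRPSet, shared: list[str]) -> PRPSet:
    idx = [p.category_index(c) for c in shared]
    return type(p)(p.values[idx], shared, p.counts[idx], p.lags_ms, p.subject)


def vowel_speaker_recovery(
    seed: int, n_runs: int = 20, n_subjects: int = 6, duration_s: float = 150.0
) -> dict:
    """Recover the vowel-specific speaker effect planted on the 230 ms
    component.

    Each run is a small cohort; per-speaker PRPs are grand-averaged across
    subjects. Success per run: (a) the median neural lag of significant
    positive cells (acoustic lag in-phone) in the speaker-dependent
    neural-acoustic correlation map falls within 230 +/- 25 ms, and (b) the
    mean vowel SE exceeds the mean consonant SE.
    """
    inv = synthetic.default_inventory()
    se_ok = map_ok = 0
    for run in range(n_runs):
        per_speaker_prp = {"S1": [], "S2": []}
        per_speaker_spec = {"S1": [], "S2": []}
        for subj in range(n_subjects):
            ep, sp = paired_session_epochs(
                seed + 9973 * run + 97 * subj, duration_s=duration_s,
                n_utterances=int(duration_s / 5), snr_db=10.0,
                duration_means=EQUAL_DURATIONS, step=5,
            )
            for sid in ("S1", "S2"):
                sel = np.array([s == sid for s in ep.speakers])
                per_speaker_prp[sid].append(prp.compute_prp(ep.subset(sel)))
                per_speaker_spec[sid].append(
                    prp.compute_avg_spectrograms(sp.subset(sel))
                )
        ga = {s: prp.grand_average(per_speaker_prp[s]) for s in per_speaker_prp}
        gs = {s: prp.grand_average(per_speaker_spec[s]) for s in per_speaker_spec}
        shared = sorted(
            set.intersection(*[set(x.categories) for x in [*ga.values(), *gs.values()]])
        )
        pa, pb = _restrict(ga["S1"], shared), _restrict(ga["S2"], shared)
        sa, sb = _restrict(gs["S1"], shared), _restrict(gs["S2"], shared)
        se = spkm.se_index(pa, pb)
        vowel = np.mean([s for c, s in zip(shared, se) if inv.manner(c) == "vowel"])
        consonant = np.mean([s for c, s in zip(shared, se) if inv.manner(c) != "vowel"])
        se_ok += vowel > consonant
        r, mask, ln, la = spkm.speaker_neural_acoustic_map((pa, pb), (sa, sb), q=0.05)
        in_phone = (la >= 0.0) & (la <= 120.0)
        rows, cols = np.nonzero(mask & in_phone[None, :] & (r > 0))
        if rows.size:
            median_lag = float(np.median(ln[rows]))
            map_ok += abs(median_lag - 230.0) <= 25.0
    return {"se_runs_ok": se_ok, "map_runs_ok": map_ok, "n_runs": n_runs}


def null_calibration(seed: int, n_f_sims: int = 200, n_boot_sims: int = 60) -> dict:
    """Type-I control with nothing planted.

    F series: iid normal units, four balanced groups, BH-FDR at q = 0.05.
    Bootstrap covariance: independent noise in both spaces, n = 20 resamples,
    q = 1e-4. Reports the significant fraction in each family.
    """
    rng = np.random.default_rng(seed)
    sig_f = tot_f = 0
    for _ in range(n_f_sims):
        values = rng.standard_normal((40, 30))
        groups = np.array(["a", "b", "c", "d"] * 10)
        fs = stats.manner_f_series(values, groups, np.arange(30.0), q=0.05)
        sig_f += int(fs.mask.sum())
        tot_f += fs.mask.size
    sig_b = tot_b = 0
    for s in range(n_boot_sims):
        n_tok, n_feat, n_lag = 120, 4, 12
        labels = [str(i % 6) for i in range(n_tok)]
        mk = lambda: EpochSet(
            rng.standard_normal((n_tok, n_feat, n_lag)), np.arange(n_lag, dtype=float),
            labels, ["S1"] * n_tok, [0] * n_tok, np.arange(n_tok, dtype=float),
        )
        out = rsa.bootstrap_significance(mk(), mk(), n=20, q=0.0001, seed=seed + s)
        sig_b += int(out.mask.sum())
        tot_b += out.mask.size
    return {
        "f_significant_fraction": sig_f / tot_f,
        "f_cells": tot_f,
        "bootstrap_significant_fraction": sig_b / tot_b,
        "bootstrap_cells": tot_b,
    }
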