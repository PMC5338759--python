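"""Umbrella pipeline: simulate -> spectrogram -> preprocess -> PRP ->
representational analysis -> group statistics -> speaker encoding.

The configuration's analysis defaults are the study parameters (2-15 Hz
band, +/-10 z rejection, 500 ms utterance-onset exclusion, 0.01% category
floor, 0-400 ms clustering window, bootstrap n = 20, q levels 0.01 / 0.05 /
0.001 / 1e-4); the simulation defaults are desk-scale (two minutes, eight
electrodes, 500 Hz) so the full bundle runs in seconds to minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from . import preprocess, prp, rsa, speaker, stats, synthetic
from .types import EpochSet, PRPSet

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # simulation
    duration_s: float = 120.0
    n_utterances: int = 24
    n_electrodes: int = 8
    eeg_fs: float = 500.0
    frame_rate: float = 500.0
    noise_snr_db: float | None = 0.0
    artifact_rate_per_min: float = 0.5
    speaker_separation: float = 0.4
    seed: int = 0
    # analysis (study defaults)
    filter_low_hz: float = 2.0
    filter_high_hz: float = 15.0
    rejection_threshold_z: float = 10.0
    onset_exclusion_s: float = 0.5
    rare_category_floor: float = 0.0001
    window_ms: tuple[float, float] = (-100.0, 600.0)
    cluster_window_ms: tuple[float, float] = (0.0, 400.0)
    bootstrap_n: int = 20
    q_baseline: float = 0.01
    q_fstat: float = 0.05
    q_electrode: float = 0.001
    q_bootstrap: float = 0.0001
    covariance_lag_step: int = 4
    classifier_holdout: float = 0.10

    def __post_init__(self) -> None:
        for name in ("q_baseline", "q_fstat", "q_electrode", "q_bootstrap"):
            q = getattr(self, name)
            if not 0 < q < 1:
                raise ValueError(f"{name} = {q} must lie in (0, 1)")
        if not 0 < self.classifier_holdout < 1:
            raise ValueError("classifier_holdout must lie in (0, 1)")
        if self.duration_s <= 0 or self.n_electrodes < 1:
            raise ValueError("invalid simulation geometry")
        if not self.filter_low_hz < self.filter_high_hz:
            raise ValueError("invalid filter band")

    def to_json(self) -> str:
        d = asdict(self)
        d["window_ms"] = list(d["window_ms"])
        d["cluster_window_ms"] = list(d["cluster_window_ms"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["window_ms"] = tuple(d["window_ms"])
        d["cluster_window_ms"] = tuple(d["cluster_window_ms"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _decimate_lags(epochs: EpochSet, step: int) -> EpochSet:
    if step <= 1:
        return epochs
    return EpochSet(
        epochs.epochs[:, :, ::step],
        epochs.lags_ms[::step],
        epochs.labels,
        epochs.speakers,
        epochs.utterances,
        epochs.onsets,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on a synthetic session; returns the result bundle.

    Outputs (when ``out_dir`` is given) carry provenance metadata: the config
    hash, the seed, and the package version. Any stage failure aborts with
    the stage named.
    """
    from . import __version__

    bundle: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    }
    stage = "simulate"
    try:
        inventory = synthetic.default_inventory()
        speakers = synthetic.default_speakers()
        kernels = synthetic.default_kernels(
            config.n_electrodes, speaker_separation=config.speaker_separation
        )
        alignment = synthetic.gen_phoneme_sequence(
            inventory, config.duration_s, config.n_utterances, speakers, config.seed
        )
        rec, truth = synthetic.gen_eeg(
            alignment,
            kernels,
            inventory,
            speakers,
            n_electrodes=config.n_electrodes,
            fs=config.eeg_fs,
            noise_snr_db=config.noise_snr_db,
            artifact_rate_per_min=config.artifact_rate_per_min,
            seed=config.seed,
        )

        stage = "spectrogram"
        spec = synthetic.gen_ideal_spectrogram(
            alignment, inventory, speakers, frame_rate=config.frame_rate
        )

        stage = "preprocess"
        rec = preprocess.bandpass_filter(rec, config.filter_low_hz, config.filter_high_hz)
        rec = preprocess.zscore_channels(rec)
        kept_alignment = preprocess.exclude_utterance_onset_tokens(
            alignment, config.onset_exclusion_s
        )

        stage = "prp"
        epochs = prp.extract_epochs(rec, kept_alignment, config.window_ms)
        spec_epochs = prp.extract_spectrogram_epochs(spec, kept_alignment, config.window_ms)
        # edge tokens can survive in one space only; keep the intersection
        common = sorted(set(np.round(epochs.onsets, 9)) & set(np.round(spec_epochs.onsets, 9)))
        epochs = epochs.subset(np.isin(np.round(epochs.onsets, 9), common))
        spec_epochs = spec_epochs.subset(np.isin(np.round(spec_epochs.onsets, 9), common))
        mask = preprocess.reject_artifact_epochs(epochs, config.rejection_threshold_z)
        epochs_kept = epochs.subset(mask.keep)
        spec_epochs_kept = spec_epochs.subset(mask.keep)
        prpset = prp.filter_rare_categories(
            prp.compute_prp(epochs_kept), config.rare_category_floor
        )
        avgspec = prp.compute_avg_spectrograms(spec_epochs_kept)

        stage = "rsa"
        epochs_dec = _decimate_lags(epochs_kept, config.covariance_lag_step)
        spec_dec = _decimate_lags(spec_epochs_kept, config.covariance_lag_step)
        cross = rsa.bootstrap_significance(
            epochs_dec, spec_dec, n=config.bootstrap_n, q=config.q_bootstrap, seed=config.seed
        )
        tree = rsa.upgma_cluster(prpset, config.cluster_window_ms)
        neural_d = rsa.pairwise_distance_series(prpset)

        stage = "stats"
        partition = stats.MannerPartition(
            {l: inventory.manner(l) for l in prpset.categories}
        )
        values, groups, lags = stats.units_from_epochs(epochs_kept, partition, electrode=0)
        fseries = stats.manner_f_series(values, groups, lags, q=config.q_fstat)
        manners = partition.groups_for(epochs_dec.labels)
        _, confusion_neural = stats.rls_classifier(
            epochs_dec, manners, holdout=config.classifier_holdout, seed=config.seed
        )
        _, confusion_acoustic = stats.rls_classifier(
            spec_dec, manners, holdout=config.classifier_holdout, seed=config.seed
        )
        conf_r, conf_p = stats.confusion_correlation(confusion_neural, confusion_acoustic)

        stage = "speaker"
        ids = [s.speaker_id for s in speakers]
        prp_by_speaker = []
        spec_by_speaker = []
        for sid in ids:
            sel = np.array([s == sid for s in epochs_kept.speakers])
            prp_by_speaker.append(prp.compute_prp(epochs_kept.subset(sel), subject=sid))
            spec_by_speaker.append(
                prp.compute_avg_spectrograms(spec_epochs_kept.subset(sel), subject=sid)
            )
        shared = sorted(
            set(prp_by_speaker[0].categories)
            & set(prp_by_speaker[1].categories)
            & set(spec_by_speaker[0].categories)
            & set(spec_by_speaker[1].categories)
        )

        def restrict(p: PRPSet) -> PRPSet:
            idx = [p.category_index(c) for c in shared]
            return type(p)(p.values[idx], shared, p.counts[idx], p.lags_ms, p.subject)

        prp_a, prp_b = (restrict(p) for p in prp_by_speaker)
        spec_a, spec_b = (restrict(p) for p in spec_by_speaker)
        se_neural = speaker.se_index(prp_a, prp_b, config.cluster_window_ms)
        se_acoustic = speaker.se_index(spec_a, spec_b, config.cluster_window_ms)
        se_r, se_p = speaker.se_correlation(se_neural, se_acoustic)
        sdm = speaker.speaker_distance_matrix(prp_a, prp_b, lag_ms=230.0, speakers=tuple(ids))
        spk_index = speaker.speaker_index(sdm)

        bundle.update(
            {
                "alignment": kept_alignment,
                "recording_truth": truth,
                "prp": prpset,
                "avg_spectrograms": avgspec,
                "rejection_fraction": mask.fraction_rejected,
                "fseries": fseries,
                "cross_covariance": cross,
                "dendrogram_newick": rsa.to_newick(tree),
                "neural_distances": neural_d,
                "confusion_neural": confusion_neural,
                "confusion_acoustic": confusion_acoustic,
                "confusion_correlation": (conf_r, conf_p),
                "se_neural": se_neural,
                "se_acoustic": se_acoustic,
                "se_correlation": (se_r, se_p),
                "speaker_index": spk_index,
                "categories": shared,
            }
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prov = bundle["provenance"]
        (out / "config.json").write_text(config.to_json())
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        pio.write_alignment(bundle["alignment"], out / "alignment.tsv")
        (out / "ground_truth.json").write_text(bundle["recording_truth"].to_json())
        pio.write_prpset(bundle["prp"], out / "prp.tsv")
        pio.write_prpset(bundle["avg_spectrograms"], out / "avg_spectrograms.tsv")
        (out / "dendrogram.nwk").write_text(bundle["dendrogram_newick"] + "\n")
        np.savetxt(out / "fseries.tsv", np.column_stack(
            [bundle["fseries"].lags_ms, bundle["fseries"].f, bundle["fseries"].p]
        ), delimiter="\t", header="lag_ms\tF\tp", comments="")
        summary = {
            "rejection_fraction": bundle["rejection_fraction"],
            "confusion_correlation_r": bundle["confusion_correlation"][0],
            "confusion_correlation_p": bundle["confusion_correlation"][1],
            "se_correlation_r": bundle["se_correlation"][0],
            "se_correlation_p": bundle["se_correlation"][1],
            "speaker_index": bundle["speaker_index"],
            "se_neural": {c: float(v) for c, v in zip(bundle["categories"], bundle["se_neural"])},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return bundle
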