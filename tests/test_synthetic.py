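"""Generator properties: determinism, tiling, superposition, planted truth."""

import json

import numpy as np
import pytest

from prpkit import synthetic


def _tokens_tuple(alignment):
    return [(t.label, t.onset, t.offset, t.speaker, t.utterance) for t in alignment]


class TestPhonemeSequence:
    def test_same_seed_reproduces_alignment_exactly(self, inventory, speakers):
        a = synthetic.gen_phoneme_sequence(inventory, 20.0, 4, speakers, seed=1)
        b = synthetic.gen_phoneme_sequence(inventory, 20.0, 4, speakers, seed=1)
        assert _tokens_tuple(a) == _tokens_tuple(b)

    def test_utterances_alternate_speakers(self, inventory, speakers):
        a = synthetic.gen_phoneme_sequence(inventory, 20.0, 4, speakers, seed=2)
        order = []
        for tok in a:
            if not order or order[-1][0] != tok.utterance:
                order.append((tok.utterance, tok.speaker))
        assert [s for _, s in order] == ["S1", "S2", "S1", "S2"]

    def test_tokens_tile_utterances_without_gaps(self, inventory, speakers):
        a = synthetic.gen_phoneme_sequence(inventory, 60.0, 6, speakers, seed=3)
        utt_dur = 10.0
        by_utt = {}
        for tok in a:
            by_utt.setdefault(tok.utterance, []).append(tok)
        for u, toks in by_utt.items():
            assert toks[0].onset == pytest.approx(u * utt_dur, abs=1e-9)
            assert toks[-1].offset == pytest.approx((u + 1) * utt_dur, abs=1e-9)
            total = sum(t.duration for t in toks)
            assert total == pytest.approx(utt_dur, abs=1e-6)
            for prev, cur in zip(toks, toks[1:]):
                assert cur.onset == pytest.approx(prev.offset, abs=1e-12)

    def test_vowels_longer_than_plosives_on_average(self, inventory, speakers):
        a = synthetic.gen_phoneme_sequence(inventory, 300.0, 10, speakers, seed=4)
        durs = {"plosive": [], "vowel": []}
        for tok in a:
            m = inventory.manner(tok.label)
            if m in durs:
                durs[m].append(tok.duration)
        assert np.mean(durs["vowel"]) > np.mean(durs["plosive"])

    @pytest.mark.parametrize("bad", [dict(total_duration=0.0), dict(n_utterances=0)])
    def test_invalid_arguments_rejected(self, inventory, speakers, bad):
        kwargs = dict(total_duration=10.0, n_utterances=2, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            synthetic.gen_phoneme_sequence(
                inventory, kwargs["total_duration"], kwargs["n_utterances"],
                speakers, kwargs["seed"],
            )


class TestStimulusAudio:
    def test_empty_alignment_yields_empty_waveform(self, inventory, speakers):
        from prpkit.types import PhonemeAlignment

        wave = synthetic.gen_stimulus_audio(
            PhonemeAlignment([]), inventory, speakers, fs=16000.0
        )
        assert wave.size == 0

    def test_sustained_vowel_peaks_at_profile_frequency(self, inventory, speakers):
        from prpkit.types import PhonemeAlignment, PhoneToken

        tok = PhoneToken("AA", 0.0, 0.5, "S1", 0)
        wave = synthetic.gen_stimulus_audio(
            PhonemeAlignment([tok]), inventory, speakers, fs=16000.0, seed=0
        )
        spec = np.abs(np.fft.rfft(wave)) ** 2
        freqs = np.fft.rfftfreq(wave.size, 1 / 16000.0)
        # smooth over ~the profile bandwidth, then locate the peak
        cf = inventory.acoustic_profile["AA"][0]
        bw = inventory.acoustic_profile["AA"][1]
        peak = freqs[np.argmax(spec)]
        assert abs(peak - cf) < bw

    def test_formant_scale_shifts_spectral_peak(self, inventory, speakers):
        from prpkit.types import PhonemeAlignment, PhoneToken

        def peak_for(speaker_id):
            tok = PhoneToken("AA", 0.0, 0.5, speaker_id, 0)
            wave = synthetic.gen_stimulus_audio(
                PhonemeAlignment([tok]), inventory, speakers, fs=16000.0, seed=0
            )
            spec = np.abs(np.fft.rfft(wave)) ** 2
            freqs = np.fft.rfftfreq(wave.size, 1 / 16000.0)
            return freqs[np.argmax(spec)]

        ratio = peak_for("S2") / peak_for("S1")
        # speaker 2 has formant_scale 1.2; harmonic quantization adds slack
        assert 1.05 < ratio < 1.4

    def test_low_sampling_rate_rejected(self, inventory, speakers, alignment_30s):
        with pytest.raises(ValueError, match="fs"):
            synthetic.gen_stimulus_audio(alignment_30s, inventory, speakers, fs=4000.0)

    def test_same_seed_reproduces_waveform(self, inventory, speakers, alignment_30s):
        a = synthetic.gen_stimulus_audio(alignment_30s, inventory, speakers, fs=16000.0, seed=9)
        b = synthetic.gen_stimulus_audio(alignment_30s, inventory, speakers, fs=16000.0, seed=9)
        np.testing.assert_array_equal(a, b)


class TestEEGForwardModel:
    def test_superposition_equals_bruteforce_kernel_sum(
        self, inventory, speakers, alignment_30s, kernels8, clean_session
    ):
        rec, _ = clean_session
        fs = rec.fs
        expected = np.zeros_like(rec.values)
        order = {s.speaker_id: i for i, s in enumerate(speakers)}
        for tok in alignment_30s:
            si = order[tok.speaker]
            ker = kernels8.waveform(tok.label, si, inventory, fs, 8, speakers[si])
            i0 = int(np.ceil(tok.onset * fs - 1e-9))
            i1 = min(i0 + ker.shape[1], expected.shape[1])
            expected[:, i0:i1] += ker[:, : i1 - i0]
        peak = np.max(np.abs(expected))
        assert np.max(np.abs(rec.values - expected)) < 1e-10 * peak

    def test_single_token_energy_confined_to_kernel_support(self, inventory, speakers):
        from prpkit.types import PhonemeAlignment, PhoneToken

        kernels = synthetic.default_kernels(4)
        tok = PhoneToken("S", 1.0, 1.1, "S1", 0)
        rec, _ = synthetic.gen_eeg(
            PhonemeAlignment([tok]), kernels, inventory, speakers,
            n_electrodes=4, fs=500.0, noise_snr_db=None, seed=0,
        )
        lo_ms, hi_ms = kernels.support_ms()
        lo = int((1.0 + lo_ms / 1000.0) * 500)
        hi = int(np.ceil((1.0 + hi_ms / 1000.0) * 500)) + 1
        outside = np.concatenate([rec.values[:, :lo].ravel(), rec.values[:, hi:].ravel()])
        assert np.all(outside == 0.0)
        assert np.max(np.abs(rec.values)) > 0

    def test_two_identical_tokens_average_to_single_kernel(self, inventory, speakers):
        from prpkit import prp
        from prpkit.types import PhonemeAlignment, PhoneToken

        kernels = synthetic.default_kernels(4)
        toks = [PhoneToken("M", 1.0, 1.1, "S1", 0), PhoneToken("M", 4.0, 4.1, "S1", 0)]
        rec, _ = synthetic.gen_eeg(
            PhonemeAlignment(toks), kernels, inventory, speakers,
            n_electrodes=4, fs=500.0, noise_snr_db=None, seed=0,
        )
        epochs = prp.extract_epochs(rec, PhonemeAlignment(toks), (0.0, 600.0))
        avg = epochs.epochs.mean(axis=0)
        ker = kernels.waveform("M", 0, inventory, 500.0, 4, speakers[0])
        m = min(avg.shape[1], ker.shape[1])
        assert np.max(np.abs(avg[:, :m] - ker[:, :m])) < 1e-10

    def test_artifact_count_poisson_consistent_and_recorded(self, inventory, speakers):
        alignment = synthetic.gen_phoneme_sequence(inventory, 600.0, 10, speakers, seed=1)
        kernels = synthetic.default_kernels(2)
        # at this rate 15 z-unit transients are infeasible (they would
        # dominate the variance); only the planted count is under test
        with pytest.warns(UserWarning, match="artifact rate"):
            _, truth = synthetic.gen_eeg(
                alignment, kernels, inventory, speakers,
                n_electrodes=2, fs=200.0, noise_snr_db=0.0,
                artifact_rate_per_min=6.0, seed=1,
            )
        n = len(truth.artifact_times)
        # Poisson(60): 60 +/- 4 sd
        assert 30 <= n <= 95
        assert truth.artifact_times == sorted(truth.artifact_times)

    def test_planted_artifacts_exceed_rejection_threshold(self, inventory, speakers):
        alignment = synthetic.gen_phoneme_sequence(inventory, 240.0, 8, speakers, seed=2)
        kernels = synthetic.default_kernels(2)
        rec, truth = synthetic.gen_eeg(
            alignment, kernels, inventory, speakers,
            n_electrodes=2, fs=200.0, noise_snr_db=0.0,
            artifact_rate_per_min=1.0, seed=2,
        )
        assert truth.artifact_times
        sd = np.std(rec.values)  # includes the artifacts' own contribution
        for t0 in truth.artifact_times:
            i0 = int(t0 * rec.fs)
            i1 = i0 + int(truth.artifact_duration * rec.fs)
            assert np.max(np.abs(rec.values[:, i0:i1])) > 10 * sd

    def test_zero_separation_makes_speaker_kernels_identical(self, inventory):
        kernels = synthetic.default_kernels(4, speaker_separation=0.0)
        for lab in inventory.labels:
            a = kernels.waveform(lab, 0, inventory, 500.0, 4)
            b = kernels.waveform(lab, 1, inventory, 500.0, 4)
            np.testing.assert_array_equal(a, b)

    def test_same_seed_reproduces_recording(self, inventory, speakers, alignment_30s, kernels8):
        a, _ = synthetic.gen_eeg(
            alignment_30s, kernels8, inventory, speakers,
            n_electrodes=8, fs=500.0, noise_snr_db=0.0, seed=7,
        )
        b, _ = synthetic.gen_eeg(
            alignment_30s, kernels8, inventory, speakers,
            n_electrodes=8, fs=500.0, noise_snr_db=0.0, seed=7,
        )
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_arguments_rejected(self, inventory, speakers, alignment_30s, kernels8):
        with pytest.raises(ValueError):
            synthetic.gen_eeg(
                alignment_30s, kernels8, inventory, speakers, n_electrodes=0, seed=0
            )
        with pytest.raises(ValueError):
            synthetic.gen_eeg(
                alignment_30s, kernels8, inventory, speakers,
                n_electrodes=2, artifact_rate_per_min=-1.0, seed=0,
            )


class TestGroundTruth:
    def test_json_roundtrip_is_bit_exact(self, inventory, speakers, alignment_30s):
        kernels = synthetic.default_kernels(4)
        _, truth = synthetic.gen_eeg(
            alignment_30s, kernels, inventory, speakers,
            n_electrodes=4, fs=500.0, noise_snr_db=3.0, artifact_rate_per_min=0.0, seed=3,
        )
        text = truth.to_json()
        back = synthetic.GroundTruth.from_json(text)
        assert back.to_json() == text
        np.testing.assert_array_equal(back.kernels.topography, truth.kernels.topography)
        assert back.artifact_times == truth.artifact_times

    def test_inventory_profiles_valid(self, inventory):
        assert len(inventory.labels) == 30
        for lab in inventory.labels:
            assert inventory.manner(lab) in synthetic.MANNERS
            cf, bw, g = inventory.acoustic_profile[lab]
            assert cf > 0 and bw > 0 and g >= 0

    def test_kernel_spec_invariants(self):
        with pytest.raises(ValueError):
            synthetic.KernelSpec(component_latencies_ms=(50.0, 40.0))
        with pytest.raises(ValueError):
            synthetic.KernelSpec(component_widths_ms=(0.0, 1.0, 1.0, 1.0))
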