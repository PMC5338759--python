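"""Forward-modelled speech/EEG sessions with known ground truth.

The generator emulates the study design that the analysis modules target:
short stories of alternating sentences from two speakers, a 30-category
American English phone inventory, and scalp EEG formed by superposing
category- and speaker-dependent response kernels at the four canonical
component latencies (~50, 120, 230, 400 ms) on top of 1/f background noise
and sparse high-amplitude artifacts.

Everything planted is recorded in a :class:`GroundTruth` sidecar so each
downstream stage has a parameter-recovery test surface. The generator is a
study simulator, not a speech synthesizer: stimulus tokens are spectrally
shaped noise or harmonic complexes matching each category's manner profile,
and the EEG forward model is a per-category kernel sum, not a head model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import EEGRecording, PhonemeAlignment, PhoneToken, AuditorySpectrogram

__all__ = [
    "PhonemeInventory",
    "SpeakerProfile",
    "KernelSpec",
    "GroundTruth",
    "default_inventory",
    "default_speakers",
    "default_kernels",
    "electrode_names",
    "gen_phoneme_sequence",
    "gen_stimulus_audio",
    "gen_eeg",
    "gen_ideal_spectrogram",
]

MANNERS = ("plosive", "fricative", "nasal", "vowel")

# label -> (manner, center frequency Hz, bandwidth Hz, gain)
_DEFAULT_PHONES: dict[str, tuple[str, float, float, float]] = {
    # plosives: sudden, spectrally broad onsets
    "P": ("plosive", 1200.0, 2400.0, 0.9),
    "B": ("plosive", 900.0, 2200.0, 0.9),
    "T": ("plosive", 3200.0, 2800.0, 0.9),
    "D": ("plosive", 2800.0, 2600.0, 0.9),
    "K": ("plosive", 1900.0, 2500.0, 0.9),
    "G": ("plosive", 1600.0, 2400.0, 0.9),
    # fricatives: energy peak in higher frequencies
    "F": ("fricative", 4200.0, 2000.0, 0.7),
    "V": ("fricative", 3600.0, 1800.0, 0.7),
    "TH": ("fricative", 4800.0, 2200.0, 0.6),
    "DH": ("fricative", 3900.0, 1900.0, 0.6),
    "S": ("fricative", 6200.0, 1800.0, 0.8),
    "Z": ("fricative", 5800.0, 1800.0, 0.8),
    "SH": ("fricative", 3400.0, 1600.0, 0.8),
    "HH": ("fricative", 2400.0, 2400.0, 0.5),
    # nasals: spectrally suppressed, low-frequency murmur
    "M": ("nasal", 280.0, 260.0, 0.5),
    "N": ("nasal", 320.0, 280.0, 0.5),
    "NG": ("nasal", 350.0, 300.0, 0.5),
    # vowels: centred low-to-mid frequency activity (first-formant region)
    "IY": ("vowel", 280.0, 260.0, 1.0),
    "IH": ("vowel", 400.0, 300.0, 1.0),
    "EH": ("vowel", 550.0, 320.0, 1.0),
    "AE": ("vowel", 690.0, 340.0, 1.0),
    "AA": ("vowel", 850.0, 360.0, 1.0),
    "AH": ("vowel", 640.0, 330.0, 1.0),
    "AO": ("vowel", 590.0, 330.0, 1.0),
    "UH": ("vowel", 450.0, 300.0, 1.0),
    "UW": ("vowel", 310.0, 270.0, 1.0),
    "ER": ("vowel", 490.0, 310.0, 1.0),
    "AY": ("vowel", 750.0, 380.0, 1.0),
    "EY": ("vowel", 480.0, 320.0, 1.0),
    "OW": ("vowel", 520.0, 330.0, 1.0),
}

# token duration log-normal means per manner (seconds); plausible speech scale
_DURATION_MEANS = {"plosive": 0.060, "fricative": 0.090, "nasal": 0.090, "vowel": 0.120}
_DURATION_LOG_SD = 0.25
_MIN_TOKEN_DURATION = 0.020

_ELECTRODE_62 = [
    "FCz", "Cz", "Fz", "Pz", "Oz", "FC1", "FC2", "C3", "C4", "F3",
    "F4", "P3", "P4", "T7", "T8", "CP1", "CP2", "F7", "F8", "O1",
    "O2", "FC5", "FC6", "CP5", "CP6", "P7", "P8", "AF3", "AF4", "PO3",
    "PO4", "F1", "F2", "C1", "C2", "P1", "P2", "FT7", "FT8", "TP7",
    "TP8", "CPz", "POz", "AF7", "AF8", "PO7", "PO8", "C5", "C6", "F5",
    "F6", "P5", "P6", "FC3", "FC4", "CP3", "CP4", "AFz", "FT9", "FT10",
    "TP9", "TP10",
]


def electrode_names(n: int) -> list[str]:
    """First ``n`` labels of a 62-electrode extended 10-20 montage."""
    if n <= len(_ELECTRODE_62):
        return _ELECTRODE_62[:n]
    return _ELECTRODE_62 + [f"E{i}" for i in range(len(_ELECTRODE_62), n)]


@dataclass(frozen=True)
class PhonemeInventory:
    """ARPAbet phone set with manner partition and spectral profiles."""

    labels: tuple[str, ...]
    manner_map: dict[str, str]
    acoustic_profile: dict[str, tuple[float, float, float]]  # (center Hz, bandwidth Hz, gain)

    def __post_init__(self) -> None:
        for lab in self.labels:
            if self.manner_map.get(lab) not in MANNERS:
                raise ValueError(f"phone {lab!r} lacks a valid manner")
            cf, bw, g = self.acoustic_profile[lab]
            if cf <= 0 or bw <= 0 or g < 0:
                raise ValueError(f"phone {lab!r}: profile must be non-negative")

    def manner(self, label: str) -> str:
        return self.manner_map[label]

    def scaled_center(self, label: str, speaker: "SpeakerProfile") -> float:
        """Profile center frequency for a speaker.

        Formant scaling models vocal-tract length, so it shifts the resonances
        of voiced sonorants (vowels, nasals); fricative/plosive noise spectra
        are articulation-driven and stay unscaled.
        """
        cf = self.acoustic_profile[label][0]
        if self.manner(label) in ("vowel", "nasal"):
            cf = cf * speaker.formant_scale
        return cf

    def max_frequency(self, speakers: "tuple[SpeakerProfile, ...]" = ()) -> float:
        tops = []
        for label, (cf, bw, _) in self.acoustic_profile.items():
            scales = [1.0]
            if speakers and self.manner(label) in ("vowel", "nasal"):
                scales = [s.formant_scale for s in speakers]
            tops.append(max(scales) * cf + bw / 2)
        return max(tops)

    def log_cf_z(self, label: str) -> float:
        """Standardized log center frequency of ``label`` across the inventory.

        Used to couple neural kernel amplitudes to the acoustic ordering of
        categories, so acoustic distance structure re-appears in the EEG.
        """
        logs = np.log([self.acoustic_profile[l][0] for l in self.labels])
        z = (np.log(self.acoustic_profile[label][0]) - logs.mean()) / logs.std()
        return float(z)


@dataclass(frozen=True)
class SpeakerProfile:
    speaker_id: str
    f0: float  # fundamental frequency, Hz
    formant_scale: float = 1.0  # multiplies profile center frequencies
    amplitude_map: dict[str, float] = field(default_factory=dict)  # per-phone EEG gain

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.formant_scale <= 0:
            raise ValueError("f0 and formant_scale must be positive")


def default_inventory() -> PhonemeInventory:
    labels = tuple(_DEFAULT_PHONES)
    return PhonemeInventory(
        labels=labels,
        manner_map={k: v[0] for k, v in _DEFAULT_PHONES.items()},
        acoustic_profile={k: (v[1], v[2], v[3]) for k, v in _DEFAULT_PHONES.items()},
    )


def default_speakers() -> tuple[SpeakerProfile, SpeakerProfile]:
    """A male-like (f0 110 Hz) and female-like (f0 220 Hz, shorter vocal tract
    i.e. formants scaled up 20%) speaker pair."""
    return (
        SpeakerProfile("S1", f0=110.0, formant_scale=1.0),
        SpeakerProfile("S2", f0=220.0, formant_scale=1.2),
    )


@dataclass
class KernelSpec:
    """Parametric evoked-response kernel: four Gaussian components.

    The amplitude of component ``c`` for phone category ``k`` of speaker ``s``
    at electrode ``e`` factorizes as::

        polarity[c] * base_amplitude[manner(k)][c]
                    * (1 + acoustic_coupling * z_k)      (components >= 1)
                    * speaker_gain(s, k, c)
                    * topography[c, e]

    where ``z_k`` is the standardized log center frequency of the category, so
    later components inherit the acoustic ordering of phones, and
    ``speaker_gain`` applies ``1 + speaker_separation`` to the third component
    (230 ms) of vowels for the second speaker only. ``speaker_separation = 0``
    therefore makes the two speakers' kernels identical.
    """

    component_latencies_ms: tuple[float, ...] = (50.0, 120.0, 230.0, 400.0)
    # Gaussian sigmas chosen so each component is effectively band-limited
    # inside the 2-15 Hz analysis band (sigma_f = 1/(2 pi sigma_t) <= ~9 Hz)
    component_widths_ms: tuple[float, ...] = (18.0, 20.0, 24.0, 32.0)
    polarity: tuple[int, ...] = (1, 1, 1, 1)
    # Signed per-manner amplitudes (deflection signs live here, not in
    # `polarity`): the first component is positive everywhere, largest for
    # obstruents; the second is positive for plosives but negative for
    # vowels; the fourth has signs that cancel in the grand average.
    # Obstruents (plosive, fricative) and sonorants (nasal, vowel) form
    # tight amplitude pairs, so the top hierarchical split of the evoked
    # responses is the obstruent/sonorant tier. Near-zero means of the
    # later components across manners keep the mean evoked response of a
    # random phone from leaking manner-dependent structure at
    # neighboring-token lags.
    base_amplitude: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "plosive": (1.45, 0.80, 0.30, 0.50),
            "fricative": (0.95, 0.50, 0.45, 0.35),
            "nasal": (0.70, -0.60, 0.95, -0.40),
            "vowel": (1.20, -0.90, 1.15, -0.45),
        }
    )
    topography: np.ndarray | None = None  # component x electrode, set by default_kernels
    acoustic_coupling: float = 0.5
    speaker_separation: float = 0.4
    speaker_component: int = 2  # index of the 230 ms component
    support_sigma: float = 3.0  # kernel truncated at latency +/- 3 sigma

    def __post_init__(self) -> None:
        lats = np.asarray(self.component_latencies_ms)
        if np.any(np.diff(lats) <= 0):
            raise ValueError("component latencies must be strictly increasing")
        if np.any(np.asarray(self.component_widths_ms) <= 0):
            raise ValueError("component widths must be positive")

    @property
    def n_components(self) -> int:
        return len(self.component_latencies_ms)

    def support_ms(self) -> tuple[float, float]:
        lo = self.component_latencies_ms[0] - self.support_sigma * self.component_widths_ms[0]
        hi = self.component_latencies_ms[-1] + self.support_sigma * self.component_widths_ms[-1]
        return lo, hi

    def component_amplitudes(
        self,
        label: str,
        speaker_index: int,
        inventory: PhonemeInventory,
        speaker: SpeakerProfile | None = None,
    ) -> np.ndarray:
        manner = inventory.manner(label)
        base = np.asarray(self.base_amplitude[manner], dtype=float).copy()
        z = inventory.log_cf_z(label)
        amps = base * np.asarray(self.polarity, dtype=float)
        amps[1:] *= 1.0 + self.acoustic_coupling * np.tanh(z)
        if speaker_index == 1 and manner == "vowel":
            amps[self.speaker_component] *= 1.0 + self.speaker_separation
        if speaker is not None:
            amps *= speaker.amplitude_map.get(label, 1.0)
        return amps

    def waveform(
        self,
        label: str,
        speaker_index: int,
        inventory: PhonemeInventory,
        fs: float,
        n_electrodes: int,
        speaker: SpeakerProfile | None = None,
    ) -> np.ndarray:
        """Electrode x time kernel sampled at ``fs``, hard-truncated outside
        the +/- ``support_sigma`` envelope of the outermost components."""
        topo = self.topography
        if topo is None:
            topo = _default_topography(self.n_components, n_electrodes)
        if topo.shape[1] != n_electrodes:
            raise ValueError("topography electrode count mismatch")
        lo, hi = self.support_ms()
        n = int(np.ceil(hi / 1000.0 * fs)) + 1
        t_ms = np.arange(n) / fs * 1000.0
        amps = self.component_amplitudes(label, speaker_index, inventory, speaker)
        out = np.zeros((n_electrodes, n))
        for c in range(self.n_components):
            lat, sig = self.component_latencies_ms[c], self.component_widths_ms[c]
            bump = amps[c] * np.exp(-0.5 * ((t_ms - lat) / sig) ** 2)
            out += topo[c][:, None] * bump[None, :]
        out[:, (t_ms < lo) | (t_ms > hi)] = 0.0
        return out


def _default_topography(n_components: int, n_electrodes: int) -> np.ndarray:
    """Smooth frontocentral-like electrode weighting, distinct per component."""
    e = np.arange(n_electrodes)
    centers = np.linspace(0, max(n_electrodes - 1, 1) * 0.6, n_components)
    width = max(n_electrodes * 0.45, 1.0)
    topo = 0.35 + 0.65 * np.exp(-0.5 * ((e[None, :] - centers[:, None]) / width) ** 2)
    return topo


def default_kernels(
    n_electrodes: int,
    speaker_separation: float = 0.4,
    acoustic_coupling: float = 0.5,
) -> KernelSpec:
    spec = KernelSpec(
        speaker_separation=speaker_separation,
        acoustic_coupling=acoustic_coupling,
    )
    spec.topography = _default_topography(spec.n_components, n_electrodes)
    return spec


@dataclass
class GroundTruth:
    """Everything the generator planted, serializable bit-exactly to JSON."""

    kernels: KernelSpec
    n_electrodes: int
    fs: float
    noise_snr_db: float | None
    artifact_rate_per_min: float
    artifact_times: list[float]
    artifact_duration: float
    artifact_amplitude_z: float
    speaker_separation: float
    seed: int

    def to_json(self) -> str:
        d = {
            "kernels": {
                "component_latencies_ms": list(self.kernels.component_latencies_ms),
                "component_widths_ms": list(self.kernels.component_widths_ms),
                "polarity": list(self.kernels.polarity),
                "base_amplitude": {k: list(v) for k, v in self.kernels.base_amplitude.items()},
                "topography": None
                if self.kernels.topography is None
                else self.kernels.topography.tolist(),
                "acoustic_coupling": self.kernels.acoustic_coupling,
                "speaker_separation": self.kernels.speaker_separation,
                "speaker_component": self.kernels.speaker_component,
                "support_sigma": self.kernels.support_sigma,
            },
            "n_electrodes": self.n_electrodes,
            "fs": self.fs,
            "noise_snr_db": self.noise_snr_db,
            "artifact_rate_per_min": self.artifact_rate_per_min,
            "artifact_times": self.artifact_times,
            "artifact_duration": self.artifact_duration,
            "artifact_amplitude_z": self.artifact_amplitude_z,
            "speaker_separation": self.speaker_separation,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        kd = d["kernels"]
        kernels = KernelSpec(
            component_latencies_ms=tuple(kd["component_latencies_ms"]),
            component_widths_ms=tuple(kd["component_widths_ms"]),
            polarity=tuple(kd["polarity"]),
            base_amplitude={k: tuple(v) for k, v in kd["base_amplitude"].items()},
            topography=None if kd["topography"] is None else np.asarray(kd["topography"]),
            acoustic_coupling=kd["acoustic_coupling"],
            speaker_separation=kd["speaker_separation"],
            speaker_component=kd["speaker_component"],
            support_sigma=kd["support_sigma"],
        )
        return cls(
            kernels=kernels,
            n_electrodes=d["n_electrodes"],
            fs=d["fs"],
            noise_snr_db=d["noise_snr_db"],
            artifact_rate_per_min=d["artifact_rate_per_min"],
            artifact_times=list(d["artifact_times"]),
            artifact_duration=d["artifact_duration"],
            artifact_amplitude_z=d["artifact_amplitude_z"],
            speaker_separation=d["speaker_separation"],
            seed=d["seed"],
        )


def gen_phoneme_sequence(
    inventory: PhonemeInventory,
    total_duration: float,
    n_utterances: int,
    speakers: tuple[SpeakerProfile, SpeakerProfile],
    seed: int,
    duration_means: dict[str, float] | None = None,
) -> PhonemeAlignment:
    """Tile ``n_utterances`` equal-length utterances with random phones.

    Utterances alternate between the two speakers (sentence alternation in the
    study design). Category draws are uniform over the inventory; durations are
    log-normal per manner (vowels longest, plosives shortest by default;
    ``duration_means`` overrides the per-manner means, e.g. to make token
    timing independent of manner in controlled experiments). Tokens tile each
    utterance with no gaps or overlaps; the final token of an utterance is
    clipped (or the previous one extended) to land exactly on the boundary.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    if n_utterances < 1:
        raise ValueError("need at least one utterance")
    if not inventory.labels:
        raise ValueError("inventory must be non-empty")
    rng = np.random.default_rng(seed)
    means = dict(_DURATION_MEANS, **(duration_means or {}))
    utt_dur = total_duration / n_utterances
    tokens: list[PhoneToken] = []
    for u in range(n_utterances):
        spk = speakers[u % 2].speaker_id
        start = u * utt_dur
        end = start + utt_dur
        t = start
        while t < end - 1e-9:
            label = str(rng.choice(inventory.labels))
            mean = means[inventory.manner(label)]
            mu = np.log(mean) - 0.5 * _DURATION_LOG_SD**2
            dur = float(np.exp(rng.normal(mu, _DURATION_LOG_SD)))
            dur = max(dur, _MIN_TOKEN_DURATION)
            off = min(t + dur, end)
            if end - off < _MIN_TOKEN_DURATION:  # avoid a sliver token at the boundary
                off = end
            tokens.append(PhoneToken(label, t, off, spk, u))
            t = off
    return PhonemeAlignment(tokens)


def _spectral_shape(freqs: np.ndarray, cf: float, bw: float) -> np.ndarray:
    return np.exp(-0.5 * ((freqs - cf) / (bw / 2.355)) ** 2)  # bw read as FWHM


def gen_stimulus_audio(
    alignment: PhonemeAlignment,
    inventory: PhonemeInventory,
    speakers: tuple[SpeakerProfile, SpeakerProfile],
    fs: float = 16000.0,
    seed: int = 0,
) -> np.ndarray:
    """Render each token as noise or a harmonic complex matching its profile.

    Vowels and nasals are harmonic complexes at the speaker's f0 with a
    spectral envelope centred on the (formant-scaled) profile frequency;
    fricatives and plosives are spectrally shaped noise, plosives with an
    abrupt decaying onset. 5 ms raised-cosine cross-fades avoid clicks.
    """
    spk_by_id = {s.speaker_id: s for s in speakers}
    top = inventory.max_frequency(speakers)
    if fs < 2 * top:
        raise ValueError(f"fs = {fs} Hz below twice the highest profile frequency ({top:.0f} Hz)")
    if not alignment.tokens:
        return np.zeros(0)
    rng = np.random.default_rng(seed)
    total = alignment.tokens[-1].offset
    n = int(np.ceil(total * fs))
    wave = np.zeros(n)
    fade = int(0.005 * fs)
    for tok in alignment:
        spk = spk_by_id[tok.speaker]
        _, bw, gain = inventory.acoustic_profile[tok.label]
        cf = inventory.scaled_center(tok.label, spk)
        i0, i1 = int(round(tok.onset * fs)), int(round(tok.offset * fs))
        i1 = min(i1, n)
        m = i1 - i0
        if m <= 0:
            continue
        manner = inventory.manner(tok.label)
        t = np.arange(m) / fs
        if manner in ("vowel", "nasal"):
            seg = np.zeros(m)
            h = 1
            while h * spk.f0 < min(cf + 2 * bw, fs / 2):
                a = _spectral_shape(np.array([h * spk.f0]), cf, bw)[0]
                if a > 1e-3:
                    seg += a * np.sin(2 * np.pi * h * spk.f0 * t + rng.uniform(0, 2 * np.pi))
                h += 1
        else:
            noise = rng.standard_normal(m)
            spec = np.fft.rfft(noise)
            freqs = np.fft.rfftfreq(m, 1 / fs)
            seg = np.fft.irfft(spec * _spectral_shape(freqs, cf, bw), n=m)
        if manner == "plosive":  # sudden, decaying burst
            seg = seg * np.exp(-t / 0.025)
        rms = np.sqrt(np.mean(seg**2))
        if rms > 0:
            seg = seg / rms * gain
        k = min(fade, m // 2)
        if k > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
            seg[:k] *= ramp
            seg[-k:] *= ramp[::-1]
        wave[i0:i1] += seg
    peak = np.max(np.abs(wave))
    return wave / peak * 0.9 if peak > 0 else wave


def _one_over_f_noise(shape: tuple[int, int], fs: float, rng: np.random.Generator) -> np.ndarray:
    n = shape[1]
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.empty(shape)
    for e in range(shape[0]):
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * scale
        x = np.fft.irfft(spec, n=n)
        out[e] = x / np.std(x)
    return out


def gen_eeg(
    alignment: PhonemeAlignment,
    kernels: KernelSpec,
    inventory: PhonemeInventory,
    speakers: tuple[SpeakerProfile, SpeakerProfile],
    n_electrodes: int = 62,
    fs: float = 2000.0,
    noise_snr_db: float | None = 0.0,
    artifact_rate_per_min: float = 0.0,
    seed: int = 0,
) -> tuple[EEGRecording, GroundTruth]:
    """Superpose per-token response kernels, add 1/f noise and artifacts.

    The clean recording is the exact sum over tokens of the token's category/
    speaker kernel placed at token onset. ``noise_snr_db`` sets the power ratio
    of the clean kernel sum to the 1/f noise (``None`` disables noise).
    Artifacts are 200 ms boxcar transients of 15x the recording's standard
    deviation on all electrodes, at a Poisson rate per minute.
    """
    if n_electrodes < 1:
        raise ValueError("need at least one electrode")
    if artifact_rate_per_min < 0:
        raise ValueError("artifact rate must be non-negative")
    rng = np.random.default_rng(seed)
    speaker_order = {s.speaker_id: i for i, s in enumerate(speakers)}
    _, hi_ms = kernels.support_ms()
    duration = (alignment.tokens[-1].offset if alignment.tokens else 0.0) + hi_ms / 1000.0 + 0.1
    n = int(np.ceil(duration * fs))
    rec = np.zeros((n_electrodes, n))

    cache: dict[tuple[str, int], np.ndarray] = {}
    for tok in alignment:
        si = speaker_order[tok.speaker]
        key = (tok.label, si)
        if key not in cache:
            cache[key] = kernels.waveform(
                tok.label, si, inventory, fs, n_electrodes, speakers[si]
            )
        ker = cache[key]
        i0 = int(np.ceil(tok.onset * fs - 1e-9))
        i1 = min(i0 + ker.shape[1], n)
        rec[:, i0:i1] += ker[:, : i1 - i0]

    if noise_snr_db is not None and np.isfinite(noise_snr_db):
        p_signal = np.mean(rec**2)
        if p_signal > 0:
            p_noise = p_signal / 10.0 ** (noise_snr_db / 10.0)
            rec += np.sqrt(p_noise) * _one_over_f_noise(rec.shape, fs, rng)

    artifact_times: list[float] = []
    art_dur = 0.200
    art_amp_z = 15.0
    if artifact_rate_per_min > 0:
        n_art = int(rng.poisson(artifact_rate_per_min * duration / 60.0))
        sd = np.std(rec) if np.std(rec) > 0 else 1.0
        # "15 z-units" means after downstream per-channel z-scoring, whose
        # standard deviation the artifacts themselves inflate. With covered
        # fraction f, solve amp = z * sqrt(sd^2 + f * amp^2) for amp; the
        # equation is solvable only while z^2 * f < 1 (rare/short artifacts).
        frac = n_art * art_dur / duration
        denom = 1.0 - art_amp_z**2 * frac
        if n_art and denom <= 0.05:
            warnings.warn(
                "artifact rate too high for 15 z-unit transients; they will "
                "fall below the intended magnitude after normalization",
                stacklevel=2,
            )
            denom = 0.05
        amp = art_amp_z * sd / np.sqrt(denom)
        for _ in range(n_art):
            t0 = float(rng.uniform(0, max(duration - art_dur, 0)))
            i0 = int(t0 * fs)
            i1 = min(i0 + int(art_dur * fs), n)
            rec[:, i0:i1] += amp
            artifact_times.append(t0)
        artifact_times.sort()

    recording = EEGRecording(rec, fs, electrode_names(n_electrodes))
    truth = GroundTruth(
        kernels=kernels,
        n_electrodes=n_electrodes,
        fs=fs,
        noise_snr_db=noise_snr_db,
        artifact_rate_per_min=artifact_rate_per_min,
        artifact_times=artifact_times,
        artifact_duration=art_dur,
        artifact_amplitude_z=art_amp_z,
        speaker_separation=kernels.speaker_separation,
        seed=seed,
    )
    return recording, truth


def kernel_prps(
    kernels: KernelSpec,
    inventory: PhonemeInventory,
    speaker_index: int,
    fs: float = 500.0,
    n_electrodes: int = 8,
    window_ms: tuple[float, float] = (-100.0, 600.0),
    speaker: SpeakerProfile | None = None,
):
    """Noise-free PRPs straight from the forward-model kernels.

    The exact evoked response every category would produce for one isolated
    token: the limit of averaging with noise, overlap and artifacts disabled.
    Useful for exact identities (e.g. speaker-separation 0 implies identical
    speaker PRPs).
    """
    from .types import PRPSet

    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    lags_ms = np.arange(lo, hi + 1) / fs * 1000.0
    vals = np.zeros((len(inventory.labels), n_electrodes, lags_ms.size))
    for i, lab in enumerate(inventory.labels):
        ker = kernels.waveform(lab, speaker_index, inventory, fs, n_electrodes, speaker)
        pos = lags_ms >= 0
        m = min(int(pos.sum()), ker.shape[1])
        vals[i, :, np.flatnonzero(pos)[:m]] = ker[:, :m].T
    cats = sorted(inventory.labels)
    order = [list(inventory.labels).index(c) for c in cats]
    return PRPSet(vals[order], cats, np.ones(len(cats), dtype=int), lags_ms,
                  f"kernel-speaker{speaker_index}")


def gen_ideal_spectrogram(
    alignment: PhonemeAlignment,
    inventory: PhonemeInventory,
    speakers: tuple[SpeakerProfile, SpeakerProfile],
    frame_rate: float = 500.0,
    n_channels: int = 32,
    f_min: float = 80.0,
    f_max: float = 8000.0,
    onset_ms: float = 15.0,
    noise_level: float = 0.0,
    seed: int = 0,
) -> AuditorySpectrogram:
    """Model-space auditory spectrogram painted directly from the alignment.

    Each token contributes its (speaker formant-scaled) spectral profile across
    log-spaced channels, with a short onset ramp (plosives decay after the
    burst). This bypasses audio rendering and the cochlear model: it is the
    idealized acoustic representation used when a test needs exact control of
    the acoustic distance structure. It is synthetic by construction, not an
    estimate of any real spectrogram.
    """
    cfs = np.geomspace(f_min, f_max, n_channels)
    spk_by_id = {s.speaker_id: s for s in speakers}
    total = alignment.tokens[-1].offset if alignment.tokens else 0.0
    # trailing margin so epoch windows after the final phone stay in range
    n = int(np.ceil((total + 0.7) * frame_rate)) + 1
    vals = np.zeros((n_channels, n))
    rng = np.random.default_rng(seed)
    for tok in alignment:
        spk = spk_by_id[tok.speaker]
        _, bw, gain = inventory.acoustic_profile[tok.label]
        profile = gain * _spectral_shape(cfs, inventory.scaled_center(tok.label, spk), bw)
        i0 = int(np.ceil(tok.onset * frame_rate - 1e-9))
        i1 = min(int(np.ceil(tok.offset * frame_rate - 1e-9)), n)
        m = i1 - i0
        if m <= 0:
            continue
        t_ms = np.arange(m) / frame_rate * 1000.0
        env = np.minimum(t_ms / onset_ms, 1.0)
        if inventory.manner(tok.label) == "plosive":
            env = env * np.exp(-t_ms / 40.0)
        vals[:, i0:i1] += profile[:, None] * env[None, :]
    if noise_level > 0:
        vals += noise_level * np.abs(rng.standard_normal(vals.shape))
    return AuditorySpectrogram(vals, cfs, frame_rate)
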