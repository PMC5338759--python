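"""Readers and writers for the on-disk formats.

Plain-text formats throughout: WAV for stimuli, Praat TextGrid or TSV for
alignments, tab-delimited matrices with a JSON header line (prefixed ``#``)
for EEG, spectrograms, PRP sets and distance matrices, and JSON for ground
truth. Delimited EEG round-trips bit-exactly (17 significant digits); EDF
can be *read* through mne when it is installed, but the package writes the
delimited format only.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    AuditorySpectrogram,
    AvgSpectrogramSet,
    EEGRecording,
    PhonemeAlignment,
    PhoneToken,
    PRPSet,
)

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_eeg",
    "write_eeg",
    "read_wav",
    "write_wav",
    "read_spectrogram",
    "write_spectrogram",
    "read_prpset",
    "write_prpset",
    "write_labelled_matrix",
    "read_labelled_matrix",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- alignments

def write_alignment(alignment: PhonemeAlignment, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        df = pd.DataFrame(
            {
                "label": [t.label for t in alignment],
                "onset": [t.onset for t in alignment],
                "offset": [t.offset for t in alignment],
                "speaker": [t.speaker for t in alignment],
                "utterance": [t.utterance for t in alignment],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif dialect == "textgrid":
        _write_textgrid(alignment, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_alignment(path: str | Path, dialect: str | None = None) -> PhonemeAlignment:
    """Parse a TSV or Praat TextGrid alignment.

    TextGrid interval labels carry speaker/utterance as ``PHONE|speaker|utt``;
    bare labels default to one speaker/utterance. Overlapping or out-of-order
    intervals are rejected with a diagnostic.
    """
    path = Path(path)
    if dialect is None:
        dialect = "textgrid" if path.suffix.lower() == ".textgrid" else "tsv"
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "onset", "offset"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: TSV alignment needs columns {sorted(required)}")
        tokens = [
            PhoneToken(
                str(r.label),
                float(r.onset),
                float(r.offset),
                str(getattr(r, "speaker", "S1")),
                int(getattr(r, "utterance", 0)),
            )
            for r in df.itertuples()
        ]
        return PhonemeAlignment(tokens)
    if dialect == "textgrid":
        return _read_textgrid(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_textgrid(alignment: PhonemeAlignment, path: Path) -> None:
    toks = alignment.tokens
    xmin = 0.0
    xmax = toks[-1].offset if toks else 0.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin}",
        f"xmax = {xmax}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "phones"',
        f"        xmin = {xmin}",
        f"        xmax = {xmax}",
        f"        intervals: size = {len(toks)}",
    ]
    for i, t in enumerate(toks, 1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {t.onset!r}",
            f"            xmax = {t.offset!r}",
            f'            text = "{t.label}|{t.speaker}|{t.utterance}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n")


_TG_NUM = re.compile(r"=\s*([-+0-9.eE]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"(.*)"')


def _read_textgrid(path: Path) -> PhonemeAlignment:
    lines = Path(path).read_text().splitlines()
    tokens: list[PhoneToken] = []
    xmin = xmax = None
    in_intervals = False
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("intervals: size"):
            in_intervals = True
        elif in_intervals and line.startswith("intervals ["):
            try:
                xmin = float(_TG_NUM.search(lines[i + 1]).group(1))
                xmax = float(_TG_NUM.search(lines[i + 2]).group(1))
                text = _TG_TEXT.search(lines[i + 3]).group(1)
            except (AttributeError, IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed interval near line {i + 1}") from exc
            if text:
                parts = text.split("|")
                label = parts[0]
                speaker = parts[1] if len(parts) > 1 else "S1"
                utt = int(parts[2]) if len(parts) > 2 else 0
                tokens.append(PhoneToken(label, xmin, xmax, speaker, utt))
            i += 3
        i += 1
    if not tokens:
        warnings.warn(f"{path}: empty phone tier", stacklevel=2)
    try:
        return PhonemeAlignment(tokens)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------------- EEG

def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    header = {
        "format": "prpkit-eeg",
        "fs": rec.fs,
        "electrode_labels": rec.electrode_labels,
        "reference": rec.reference,
        "n_samples": rec.n_samples,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, rec.values.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecording:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return EEGRecording(raw.get_data(), raw.info["sfreq"], raw.ch_names, "as recorded")
    if format != "delimited":
        raise ValueError(f"unknown EEG format {format!r}")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[2:])
        for key in ("fs", "electrode_labels", "n_samples"):
            if key not in header:
                raise ValueError(f"{path}: header missing {key!r}")
        values = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    if values.shape[1] != header["n_samples"]:
        raise ValueError(
            f"{path}: truncated file ({values.shape[1]} samples, header says {header['n_samples']})"
        )
    return EEGRecording(
        values, header["fs"], header["electrode_labels"], header.get("reference", "")
    )


# ----------------------------------------------------------------------- WAV

def write_wav(wave: np.ndarray, fs: float, path: str | Path) -> None:
    from scipy.io import wavfile

    wavfile.write(str(path), int(fs), np.asarray(wave, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    fs, data = wavfile.read(str(path))
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:  # fold to mono
        data = data.mean(axis=1)
    if np.issubdtype(np.asarray(wavfile.read(str(path))[1]).dtype, np.integer):
        data = data / np.iinfo(np.int16).max
    return data, float(fs)


# ---------------------------------------------------------------- matrices

def write_spectrogram(spec: AuditorySpectrogram, path: str | Path) -> None:
    header = {
        "format": "prpkit-spectrogram",
        "frame_rate": spec.frame_rate,
        "center_frequencies": spec.center_frequencies.tolist(),
        "n_frames": spec.n_frames,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, spec.values.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_spectrogram(path: str | Path) -> AuditorySpectrogram:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[2:])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return AuditorySpectrogram(
        values, np.asarray(header["center_frequencies"]), header["frame_rate"]
    )


def write_prpset(prp: PRPSet, path: str | Path) -> None:
    k, e, l = prp.values.shape
    header = {
        "format": "prpkit-prpset",
        "kind": type(prp).__name__,
        "categories": prp.categories,
        "counts": prp.counts.tolist(),
        "lags_ms": prp.lags_ms.tolist(),
        "subject": prp.subject,
        "shape": [k, e, l],
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, prp.values.reshape(k * e, l), fmt=_FLOAT_FMT, delimiter="\t")


def read_prpset(path: str | Path) -> PRPSet:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing JSON header line")
        header = json.loads(first[2:])
        flat = np.loadtxt(fh, delimiter="\t", ndmin=2)
    k, e, l = header["shape"]
    cls = AvgSpectrogramSet if header.get("kind") == "AvgSpectrogramSet" else PRPSet
    return cls(
        flat.reshape(k, e, l),
        header["categories"],
        np.asarray(header["counts"]),
        np.asarray(header["lags_ms"]),
        header.get("subject", ""),
    )


def write_labelled_matrix(
    values: np.ndarray, labels: list[str], path: str | Path, meta: dict | None = None
) -> None:
    """Square matrix (e.g. a distance or similarity matrix) with category
    headers and an optional JSON metadata line."""
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta) + "\n")
        df = pd.DataFrame(np.asarray(values), index=labels, columns=labels)
        df.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)


def read_labelled_matrix(path: str | Path) -> tuple[np.ndarray, list[str], dict]:
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("# "):
            meta = json.loads(first[2:])
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return df.to_numpy(), [str(c) for c in df.columns], meta
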