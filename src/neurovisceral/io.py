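"""Readers and writers for the pipeline's standard formats.

Inputs: EDF (via mne) or plain text for ECG and EEG; CSV for pre-extracted
R-R interval series.  Outputs: TSV tables with values fixed to 6 decimals
so reruns are byte-identical, plus JSON sidecar metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import CHANNELS_1020, EEGRecording, normalize_channel_label

__all__ = [
    "read_rr_csv",
    "read_ecg",
    "read_eeg",
    "write_tsv",
    "write_adjacency",
    "write_json",
]


def read_rr_csv(path: str | Path) -> np.ndarray:
    """R-R intervals in ms from a one-column CSV (header optional)."""
    df = pd.read_csv(path)
    col = df.columns[0]
    try:  # headerless file: the "header" is the first value
        float(col)
        df = pd.read_csv(path, header=None)
        col = df.columns[0]
    except ValueError:
        pass
    return df[col].to_numpy(dtype=float)


def _read_edf(path: Path):
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), raw.info["sfreq"], [str(c) for c in raw.ch_names]


def read_ecg(path: str | Path, fs: float | None = None) -> tuple[np.ndarray, float]:
    """Single-channel ECG from EDF or one-column text.

    Text files need ``fs``; EDF carries its own sampling rate.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        data, sf, _ = _read_edf(path)
        return data[0], float(sf)
    if fs is None:
        raise ValueError("sampling rate required for text ECG")
    return np.loadtxt(path, dtype=float).ravel(), float(fs)


def read_eeg(path: str | Path, fs: float | None = None) -> EEGRecording:
    """19-channel EEG from EDF or CSV with channel-name headers.

    Channel labels are normalised to the older 10-20 temporal nomenclature
    (T7/T8/P7/P8 -> T3/T4/T5/T6) and reordered to the canonical montage.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        data, sf, names = _read_edf(path)
        fs = float(sf)
        df = pd.DataFrame(data.T, columns=names)
    else:
        if fs is None:
            raise ValueError("sampling rate required for text EEG")
        df = pd.read_csv(path)
    df.columns = [normalize_channel_label(c) for c in df.columns]
    missing = [c for c in CHANNELS_1020 if c not in df.columns]
    if missing:
        raise ValueError(f"missing channels: {missing}")
    data = df[list(CHANNELS_1020)].to_numpy(dtype=float).T
    return EEGRecording(data=data, fs=float(fs), channels=CHANNELS_1020)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output, floats to 6 decimals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_adjacency(matrix: np.ndarray, channels: tuple, path: str | Path) -> None:
    """Square adjacency matrix TSV with channel labels on both axes."""
    df = pd.DataFrame(matrix, index=channels, columns=channels)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
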