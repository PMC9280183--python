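"""Per-electrode band-power features: FFT and band-wise sum of squared magnitudes.

Each channel's recording is Fourier transformed; for each of the three
canonical bands (theta, alpha, beta) the feature is the sum of squared DFT
magnitudes over the one-sided frequency bins falling inside the band. Bands
are half-open ``[low, high)`` intervals in Hz; bin ``k`` of an ``n``-sample
recording sits at ``k * fs / n`` Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BAND_ORDER",
    "DEFAULT_BANDS",
    "EEGRecording",
    "BandPowerFeatures",
    "SpectralError",
    "fft_band_features",
    "read_long_csv",
    "write_long_csv",
    "read_edf",
]

#: Fixed band/column order of every feature matrix.
BAND_ORDER: tuple[str, ...] = ("theta", "alpha", "beta")

#: Default band edges in Hz, half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


class SpectralError(ValueError):
    """Raised for invalid recordings or band configurations."""


@dataclass(frozen=True)
class EEGRecording:
    """One subject's multichannel recording (microvolts)."""

    subject_id: str
    fs: float
    data: np.ndarray  # channels x samples
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.fs <= 0:
            raise SpectralError(f"sampling rate must be positive, got {self.fs}")
        if data.ndim != 2:
            raise SpectralError(f"data must be channels x samples, got shape {data.shape}")
        if data.shape[0] != len(self.labels):
            raise SpectralError("channel count does not match label count")
        if not np.all(np.isfinite(data)):
            raise SpectralError(f"non-finite samples in recording {self.subject_id!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandPowerFeatures:
    """Electrodes x 3 matrix of band sum-of-squares values (theta, alpha, beta)."""

    values: np.ndarray
    band_edges: tuple[tuple[float, float], ...]
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2 or values.shape[1] != len(BAND_ORDER):
            raise SpectralError(f"values must be electrodes x {len(BAND_ORDER)}")
        if np.any(values < 0):
            raise SpectralError("band power features must be non-negative")

    def subset(self, labels: Sequence[str]) -> "BandPowerFeatures":
        """Rows for ``labels``, in the given order."""
        idx = [self.labels.index(lab) for lab in labels]
        return BandPowerFeatures(self.values[idx], self.band_edges, labels)


def _validate_bands(bands: Mapping[str, tuple[float, float]], fs: float, n: int) -> None:
    edges = [bands[name] for name in BAND_ORDER]
    for name, (lo, hi) in zip(BAND_ORDER, edges):
        if not 0 <= lo < hi:
            raise SpectralError(f"band {name!r} edges must satisfy 0 <= low < high")
        if hi > fs / 2:
            raise SpectralError(
                f"band {name!r} upper edge {hi} Hz exceeds the Nyquist frequency {fs / 2} Hz"
            )
    for (_, hi), (lo2, _) in zip(edges, edges[1:]):
        if lo2 < hi:
            raise SpectralError("bands must be non-overlapping and increasing")
    df = fs / n
    for name, (lo, hi) in zip(BAND_ORDER, edges):
        if not np.any((np.arange(n // 2 + 1) * df >= lo) & (np.arange(n // 2 + 1) * df < hi)):
            raise SpectralError(
                f"band {name!r} contains no DFT bin at fs={fs}, n={n} "
                f"(bin spacing {df:.4g} Hz)"
            )


def fft_band_features(
    rec: EEGRecording,
    bands: Mapping[str, tuple[float, float]] | None = None,
    *,
    demean: bool = False,
    epoch_len: int | None = None,
) -> BandPowerFeatures:
    """Band-wise sums of squared one-sided DFT magnitudes, one row per channel.

    Parameters
    ----------
    rec
        The recording; the whole trace is transformed at once unless
        ``epoch_len`` is given.
    bands
        Band edges; defaults to :data:`DEFAULT_BANDS`. Each band collects
        bins with frequency in ``[low, high)``.
    demean
        Subtract each channel's mean before the transform.
    epoch_len
        Optional epoch length in samples; the recording is cut into
        non-overlapping epochs and per-band sums are averaged over epochs.
    """
    bands = dict(bands) if bands is not None else dict(DEFAULT_BANDS)
    missing = [b for b in BAND_ORDER if b not in bands]
    if missing:
        raise SpectralError(f"missing band edges for {missing}")

    if epoch_len is not None:
        if epoch_len < 2 or epoch_len > rec.n_samples:
            raise SpectralError("epoch_len must be in [2, n_samples]")
        n_ep = rec.n_samples // epoch_len
        chunks = [
            rec.data[:, i * epoch_len : (i + 1) * epoch_len] for i in range(n_ep)
        ]
        feats = [
            fft_band_features(
                EEGRecording(rec.subject_id, rec.fs, c, rec.labels), bands, demean=demean
            ).values
            for c in chunks
        ]
        values = np.mean(feats, axis=0)
        edges = tuple(tuple(bands[b]) for b in BAND_ORDER)
        return BandPowerFeatures(values, edges, rec.labels)

    n = rec.n_samples
    _validate_bands(bands, rec.fs, n)
    data = rec.data - rec.data.mean(axis=1, keepdims=True) if demean else rec.data
    spectrum = np.fft.rfft(data, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    power = np.abs(spectrum) ** 2
    cols = []
    for name in BAND_ORDER:
        lo, hi = bands[name]
        mask = (freqs >= lo) & (freqs < hi)
        cols.append(power[:, mask].sum(axis=1))
    edges = tuple(tuple(bands[b]) for b in BAND_ORDER)
    return BandPowerFeatures(np.column_stack(cols), edges, rec.labels)


# --- I/O -------------------------------------------------------------------

_CSV_COLS = ["subject_id", "channel", "fs", "sample_index", "value"]


def write_long_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as long-format CSV (subject_id, channel, fs, sample_index, value)."""
    n = rec.n_samples
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(rec.subject_id, len(rec.labels) * n),
            "channel": np.repeat(list(rec.labels), n),
            "fs": rec.fs,
            "sample_index": np.tile(np.arange(n), len(rec.labels)),
            "value": rec.data.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_long_csv(path: str | Path) -> EEGRecording:
    """Read one subject's recording from long-format CSV."""
    frame = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in frame.columns]
    if missing:
        raise SpectralError(f"long CSV missing columns {missing}")
    subjects = frame["subject_id"].unique()
    if len(subjects) != 1:
        raise SpectralError(f"expected one subject per file, found {len(subjects)}")
    fs_vals = frame["fs"].unique()
    if len(fs_vals) != 1:
        raise SpectralError("inconsistent sampling rates within file")
    labels = list(dict.fromkeys(frame["channel"]))
    rows = []
    for lab in labels:
        sub = frame[frame["channel"] == lab].sort_values("sample_index")
        rows.append(sub["value"].to_numpy())
    if len({len(r) for r in rows}) != 1:
        raise SpectralError("channels have unequal sample counts")
    return EEGRecording(str(subjects[0]), float(fs_vals[0]), np.vstack(rows), labels)


def read_edf(path: str | Path, subject_id: str | None = None) -> EEGRecording:
    """Read an EDF file (labels and sampling rate from the header)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sid = subject_id if subject_id is not None else Path(path).stem
    # mne returns volts for EEG channels; features downstream are unit-agnostic.
    return EEGRecording(sid, float(raw.info["sfreq"]), raw.get_data(), raw.ch_names)
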