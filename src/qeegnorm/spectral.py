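"""Sensor-level QEEG feature extraction.

Raw multichannel resting EEG -> band-power features: zero-phase band-pass
(default 1-45.5 Hz) and mains notch filtering, common-average re-referencing
(CAR), fixed-length epoching with amplitude-threshold bad-epoch rejection,
Welch power spectral density, trapezoidal band-power integration, and the
natural-log transform that symmetrizes the strongly right-skewed power
distributions before normative fitting.

Amplitude-threshold epoch rejection is a deliberately simple artifact gate:
an epoch is dropped when any channel exceeds the threshold (default
±100 µV).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BANDS, BAND_NAMES, BandDefinition, MONTAGE_1020

__all__ = [
    "EEGRecording",
    "EmptyDataError",
    "read_csv_recording",
    "read_edf_recording",
    "preprocess",
    "epoch_and_reject",
    "welch_psd",
    "band_power",
    "band_power_row",
    "build_band_power_table",
]


class EmptyDataError(RuntimeError):
    """All epochs of a recording were rejected."""


@dataclass(frozen=True)
class EEGRecording:
    """A multichannel EEG segment in µV."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: tuple[str, ...]
    condition: str = "EC"
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError("number of channel labels must match data rows")
        if not np.isfinite(data).all():
            raise ValueError("recording contains non-finite samples")
        unknown = set(self.channel_labels) - set(MONTAGE_1020)
        if unknown:
            raise ValueError(f"labels outside the 10-20 montage: {sorted(unknown)}")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


def read_csv_recording(path, fs: float, condition: str = "EC", subject_id: str = "") -> EEGRecording:
    """Read a CSV matrix (header row of channel labels, one column per channel)."""
    df = pd.read_csv(path, comment="#")
    return EEGRecording(
        data=df.to_numpy().T,
        fs=fs,
        channel_labels=tuple(df.columns),
        condition=condition,
        subject_id=subject_id or Path(path).stem,
    )


def read_edf_recording(path, condition: str = "EC", subject_id: str = "") -> EEGRecording:
    """Read an EDF file via MNE (requires the ``eeg`` extra)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    labels = tuple(ch if ch != "Ñ4" else "C4" for ch in raw.ch_names)
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        condition=condition,
        subject_id=subject_id or Path(path).stem,
    )


def preprocess(
    rec: EEGRecording,
    bandpass: tuple[float, float] = (1.0, 45.5),
    notch: float | None = 60.0,
    notch_q: float = 30.0,
    car: bool = True,
) -> EEGRecording:
    """Zero-phase band-pass + notch filtering, then common-average re-reference.

    The notch default is 60 Hz mains; set ``notch=50.0`` for 50 Hz regions or
    ``None`` to skip.  With ``car=True`` the per-sample mean across channels
    of the output is ~0 by construction.
    """
    low, high = bandpass
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"bandpass ({low}, {high}) Hz invalid for fs={rec.fs} Hz (Nyquist {nyq})"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data, axis=-1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch frequency {notch} Hz at/above Nyquist {nyq} Hz")
        b, a = sps.iirnotch(notch, notch_q, fs=rec.fs)
        data = sps.filtfilt(b, a, data, axis=-1)
    if car:
        data = data - data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def epoch_and_reject(
    rec: EEGRecording, epoch_len: float = 4.0, amp_thresh: float = 100.0
):
    """Cut non-overlapping epochs and drop those exceeding the amplitude threshold.

    Returns ``(epochs, kept_idx)`` with *epochs* of shape
    (n_kept, n_channels, epoch_samples).  Raises :class:`EmptyDataError`
    when no epoch survives.
    """
    samples = int(round(epoch_len * rec.fs))
    if rec.data.shape[1] < samples:
        raise ValueError(
            f"recording shorter ({rec.duration:.1f} s) than one epoch ({epoch_len} s)"
        )
    n_epochs = rec.data.shape[1] // samples
    cut = rec.data[:, : n_epochs * samples]
    epochs = cut.reshape(rec.data.shape[0], n_epochs, samples).transpose(1, 0, 2)
    keep = np.abs(epochs).max(axis=(1, 2)) <= amp_thresh
    if not keep.any():
        raise EmptyDataError(
            f"all {n_epochs} epochs rejected at ±{amp_thresh} µV for subject "
            f"{rec.subject_id or '<unknown>'}"
        )
    return epochs[keep], np.flatnonzero(keep)


def welch_psd(
    epochs: np.ndarray, fs: float, window_len: float = 2.0, overlap: float = 0.5
):
    """Welch PSD averaged over epochs.

    Hann-tapered segments of *window_len* seconds with fractional *overlap*;
    frequency resolution 1/window_len.  Returns ``(freqs, psd)`` with *psd*
    of shape (n_channels, n_freqs) in µV²/Hz.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be (n_epochs, n_channels, n_samples) with >= 1 epoch")
    nperseg = int(round(window_len * fs))
    if nperseg > epochs.shape[2]:
        raise ValueError(
            f"window ({window_len} s) longer than epoch ({epochs.shape[2] / fs} s)"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, psd = sps.welch(
        epochs, fs=fs, nperseg=nperseg, noverlap=noverlap, axis=-1, window="hann"
    )
    return freqs, psd.mean(axis=0)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of the PSD over the band (µV²).

    Grid points with ``band.low <= f <= band.high`` are used, so contiguous
    bands that share an edge point sum exactly to the integral over their
    union.
    """
    if band.low < freqs[0] or band.high > freqs[-1]:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}) Hz outside PSD grid "
            f"[{freqs[0]}, {freqs[-1]}] Hz"
        )
    sel = (freqs >= band.low) & (freqs <= band.high)
    if sel.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 frequency bins")
    return np.trapezoid(psd[..., sel], freqs[sel], axis=-1)


def band_power_row(rec: EEGRecording, bands=None, epoch_len: float = 4.0,
                   amp_thresh: float = 100.0, window_len: float = 2.0,
                   overlap: float = 0.5, preprocessed: bool = False,
                   **preprocess_kw) -> pd.DataFrame:
    """Full single-recording extraction: preprocess -> epoch -> Welch -> band powers.

    Returns a long DataFrame with one row per (channel, band).
    """
    bands = bands or [BANDS[name] for name in BAND_NAMES]
    if not preprocessed:
        rec = preprocess(rec, **preprocess_kw)
    epochs, kept = epoch_and_reject(rec, epoch_len=epoch_len, amp_thresh=amp_thresh)
    freqs, psd = welch_psd(epochs, rec.fs, window_len=window_len, overlap=overlap)
    rows = []
    for band in bands:
        powers = band_power(freqs, psd, band)
        for ch, p in zip(rec.channel_labels, powers):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "channel": ch,
                    "band": band.name,
                    "power_uv2": float(p),
                    "log_power": float(np.log(p)) if p > 0 else np.nan,
                    "n_epochs_used": len(kept),
                }
            )
    return pd.DataFrame(rows)


def build_band_power_table(
    recordings: Iterable[EEGRecording], bands=None, log=None, **kw
) -> pd.DataFrame:
    """Extract band powers for a cohort of recordings into one long table.

    Subjects whose recordings lose every epoch to artifact rejection are
    skipped (and reported through *log*, a callable taking a message);
    duplicate subject ids are an error.
    """
    frames = []
    seen: set[str] = set()
    for rec in recordings:
        if rec.subject_id in seen:
            raise ValueError(f"duplicate subject id {rec.subject_id!r}")
        seen.add(rec.subject_id)
        try:
            frames.append(band_power_row(rec, bands=bands, **kw))
        except EmptyDataError as err:
            if log is not None:
                log(str(err))
    if not frames:
        raise EmptyDataError("no recording yielded any usable epoch")
    return pd.concat(frames, ignore_index=True)
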