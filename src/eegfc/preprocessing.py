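"""Epoching, band-pass filtering, and non-connectivity feature sets.

Two feature families are produced besides connectivity matrices:

* spectral-temporal images: per-channel short-time Fourier spectrograms
  (1 s Hanning window, 50% hop), log-magnitude, cropped to 0.5-45 Hz and
  bilinearly resampled to 224 x 224, min-max scaled to [0, 1];
* conventional per-channel features: energies of the five rhythm bands
  plus eight time-domain statistics (min, max, mean, median, variance,
  standard deviation, Fisher excess kurtosis, skewness).

Filtering is zero-phase (4th-order Butterworth, forward-backward), the
standard EEG choice: no phase distortion, which matters for the phase
synchronization index downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from skimage.transform import resize

from .bands import BandSpec, BROADBAND, RHYTHM_BANDS
from .synth import Recording

SPECTROGRAM_SHAPE = (224, 224)

#: Per-channel statistic names, in flattening order (after band energies).
STAT_NAMES = ("min", "max", "mean", "median", "variance", "std",
              "kurtosis", "skewness")


@dataclass(frozen=True)
class Epoch:
    """One fixed-duration segment of a recording (channels x samples)."""

    data: np.ndarray
    fs: float
    source_subject: str
    index: int
    group_label: str

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Spectrogram:
    """A 224 x 224 log-magnitude time-frequency image in [0, 1].

    Row 0 is the lowest kept frequency ``freq_min_hz``; the last row is
    ``freq_max_hz``; rows are linear in frequency in between.
    """

    image: np.ndarray
    channel: str
    epoch_ref: tuple[str, int]
    freq_min_hz: float = BROADBAND.low_hz
    freq_max_hz: float = BROADBAND.high_hz

    def __post_init__(self) -> None:
        if self.image.shape != SPECTROGRAM_SHAPE:
            raise ValueError(f"spectrogram must be {SPECTROGRAM_SHAPE}")

    def row_to_hz(self, row: int) -> float:
        frac = row / (self.image.shape[0] - 1)
        return self.freq_min_hz + frac * (self.freq_max_hz - self.freq_min_hz)


def epoch_recording(rec: Recording, duration_s: float = 10.0,
                    overlap_s: float = 0.0) -> list[Epoch]:
    """Cut a recording into fixed-length epochs.

    The epoch count is ``floor((L - d) / (d - o)) + 1`` in samples; any
    trailing partial segment is discarded.
    """
    if not (0 <= overlap_s < duration_s):
        raise ValueError("need 0 <= overlap_s < duration_s")
    d = int(round(duration_s * rec.fs))
    o = int(round(overlap_s * rec.fs))
    if d > rec.n_samples:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{duration_s:.1f} s epoch"
        )
    hop = d - o
    n_epochs = (rec.n_samples - d) // hop + 1
    return [
        Epoch(
            data=rec.data[:, k * hop: k * hop + d],
            fs=rec.fs,
            source_subject=rec.subject_id,
            index=k,
            group_label=rec.group_label,
        )
        for k in range(n_epochs)
    ]


def _band_sos(band: BandSpec, fs: float):
    nyq = fs / 2
    if band.high_hz >= nyq:
        raise ValueError(f"band edge {band.high_hz} Hz >= Nyquist {nyq} Hz")
    return signal.butter(4, (band.low_hz, band.high_hz), btype="band",
                         fs=fs, output="sos")


def bandpass_array(data: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase band-pass of a channels x samples array."""
    return signal.sosfiltfilt(_band_sos(band, fs), data, axis=-1)


def bandpass(epoch: Epoch, band: BandSpec) -> Epoch:
    """Zero-phase band-pass filter an epoch (same shape out)."""
    return Epoch(
        data=bandpass_array(epoch.data, band, epoch.fs),
        fs=epoch.fs,
        source_subject=epoch.source_subject,
        index=epoch.index,
        group_label=epoch.group_label,
    )


def spectrogram(epoch: Epoch, channel_index: int = 0,
                window_s: float = 1.0, hop_fraction: float = 0.5) -> Spectrogram:
    """STFT spectrogram image of one channel of an epoch.

    Hanning-tapered Fourier transform (1 s window, 50% hop by default),
    log magnitude, frequency axis cropped to the broadband range, then
    bilinearly resampled to 224 x 224 and min-max scaled to [0, 1].  A
    constant input produces an all-zero image.
    """
    x = np.asarray(epoch.data[channel_index], dtype=float)
    nperseg = int(round(window_s * epoch.fs))
    noverlap = nperseg - int(round(nperseg * hop_fraction))
    if epoch.n_samples < nperseg + (nperseg - noverlap):
        raise ValueError("epoch too short for two STFT windows")
    if np.ptp(x) == 0:  # constant signal: defined all-zero output
        return Spectrogram(image=np.zeros(SPECTROGRAM_SHAPE),
                           channel=str(channel_index),
                           epoch_ref=(epoch.source_subject, epoch.index))
    freqs, _, z = signal.stft(x, fs=epoch.fs, window="hann", nperseg=nperseg,
                              noverlap=noverlap, boundary=None, padded=False)
    keep = (freqs >= BROADBAND.low_hz) & (freqs <= BROADBAND.high_hz)
    kept = freqs[keep]
    mag = np.log(np.abs(z[keep]) + np.finfo(float).eps)
    img = resize(mag, SPECTROGRAM_SHAPE, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        img = np.zeros(SPECTROGRAM_SHAPE)
    else:
        img = (img - lo) / (hi - lo)
    label = (epoch.source_subject, epoch.index)
    return Spectrogram(image=img, channel=str(channel_index), epoch_ref=label,
                       freq_min_hz=float(kept[0]), freq_max_hz=float(kept[-1]))


def feature_names(n_channels: int, labels: tuple[str, ...] | None = None) -> list[str]:
    """Stable flattening order of the conventional feature vector:
    channel-major; per channel the five band energies (delta..low_gamma)
    then the eight statistics."""
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_channels))
    names = []
    for lab in labels:
        for band in RHYTHM_BANDS:
            names.append(f"{lab}_energy_{band.name}")
        for s in STAT_NAMES:
            names.append(f"{lab}_{s}")
    return names


def conventional_features(epoch: Epoch) -> np.ndarray:
    """Flattened conventional time/frequency feature vector of an epoch.

    Band energy is the sum of squared samples of the band-filtered signal
    (time-domain Parseval energy); statistics are computed per channel on
    the unfiltered epoch.  Kurtosis is Fisher excess, skewness the
    biased moment estimator.
    """
    x = np.asarray(epoch.data, dtype=float)
    n_ch = x.shape[0]
    energies = np.empty((n_ch, len(RHYTHM_BANDS)))
    for b, band in enumerate(RHYTHM_BANDS):
        filtered = bandpass_array(x, band, epoch.fs)
        energies[:, b] = np.sum(filtered ** 2, axis=1)
    with np.errstate(invalid="ignore"):
        kurt = stats.kurtosis(x, axis=1, fisher=True, bias=True)
        skew = stats.skew(x, axis=1, bias=True)
    stats_block = np.column_stack([
        x.min(axis=1), x.max(axis=1), x.mean(axis=1), np.median(x, axis=1),
        x.var(axis=1), x.std(axis=1),
        np.nan_to_num(kurt), np.nan_to_num(skew),
    ])
    return np.concatenate([energies, stats_block], axis=1).ravel()
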