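"""Pairwise functional-connectivity measures between EEG channels.

Four measures are implemented, each yielding one channels x channels
matrix per epoch:

* PSI — phase synchronization index: magnitude of the time-averaged unit
  phasor of the instantaneous phase difference, ``|mean exp(j(phi_x -
  phi_y))|``; 1 means strict phase locking, ~0 uniform independent
  phases.  Amplitude-blind.
* ImCoh — imaginary part of coherency: ``|Im(Pxy)| / sqrt(Pxx * Pyy)``
  per frequency bin, averaged over the bins strictly inside the band.
  Insensitive to zero-lag (volume-conducted) coupling.  The square-root
  cross-spectral normalization is the standard coherency denominator and
  keeps the measure in [0, 1]; an alternative normalization without the
  square root is available behind ``sqrt_normalization=False`` but is not
  bounded by 1 in general.
* Corr — Pearson correlation of the two time series.
* AEC — amplitude envelope correlation: Pearson correlation of the
  Hilbert amplitude envelopes of the band-limited signals (no
  orthogonalization; envelope edges trimmed before correlating).

Phase- and envelope-based measures require band-limited input; the
matrix builder band-filters the epoch first (the 0.5-45 Hz broadband
range counts as a band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .bands import BandSpec, BROADBAND
from .preprocessing import Epoch, bandpass_array

METHODS = ("psi", "imcoh", "corr", "aec")

#: Fraction of samples trimmed from each end of an envelope before
#: correlating, to suppress Hilbert edge transients.
ENVELOPE_EDGE_TRIM = 0.05

#: Diagonal value per measure (self-connectivity convention).
DIAGONAL = {"psi": 1.0, "imcoh": 0.0, "corr": 1.0, "aec": 1.0}


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A symmetric channels x channels connectivity matrix with provenance."""

    values: np.ndarray
    method: str
    band: BandSpec
    epoch_ref: tuple[str, int] = ("", -1)
    threshold_provenance: Optional[object] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# phase and envelope primitives

def _check_nonzero(x: np.ndarray) -> None:
    if not np.any(x):
        raise ValueError("all-zero signal has undefined phase")


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) of a band-limited series via the
    analytic signal."""
    x = np.asarray(x, dtype=float)
    _check_nonzero(x)
    return np.angle(signal.hilbert(x))


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: absolute value of the Hilbert analytic signal."""
    x = np.asarray(x, dtype=float)
    return np.abs(signal.hilbert(x))


def psi_from_phases(phi_x: np.ndarray, phi_y: np.ndarray) -> float:
    """Phase synchronization index from two instantaneous-phase series."""
    phi_x = np.asarray(phi_x, dtype=float)
    phi_y = np.asarray(phi_y, dtype=float)
    if phi_x.shape != phi_y.shape:
        raise ValueError("phase series must have equal length")
    if phi_x.size < 2:
        raise ValueError("need at least two samples")
    return float(np.abs(np.mean(np.exp(1j * (phi_x - phi_y)))))


def psi(x: np.ndarray, y: np.ndarray) -> float:
    """PSI between two band-limited series (phases via analytic signal)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    return psi_from_phases(instantaneous_phase(x), instantaneous_phase(y))


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient Cov(x, y) / (sigma_x * sigma_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant series")
    return float(np.corrcoef(x, y)[0, 1])


def _trim(x: np.ndarray, fraction: float) -> np.ndarray:
    k = int(round(x.shape[-1] * fraction))
    return x[..., k: x.shape[-1] - k] if k else x


def aec(x: np.ndarray, y: np.ndarray, band: BandSpec, fs: float,
        edge_trim: float = ENVELOPE_EDGE_TRIM) -> float:
    """Amplitude envelope correlation of two series in a band."""
    filtered = bandpass_array(np.vstack([x, y]).astype(float), band, fs)
    env = np.abs(signal.hilbert(filtered, axis=-1))
    env = _trim(env, edge_trim)
    if np.std(env[0]) == 0 or np.std(env[1]) == 0:
        raise ValueError("correlation undefined for constant envelope")
    return float(np.corrcoef(env[0], env[1])[0, 1])


# ---------------------------------------------------------------------------
# cross-spectra and ImCoh

def _segment_fft(data: np.ndarray, fs: float, window_s: float = 1.0,
                 overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Hanning-windowed segment FFTs of a channels x samples array.

    Returns (freqs, X) with X of shape (segments, channels, freqs).
    """
    nperseg = int(round(window_s * fs))
    step = nperseg - int(round(nperseg * overlap))
    n = data.shape[-1]
    if n < nperseg:
        raise ValueError("epoch too short for one spectral segment")
    win = signal.get_window("hann", nperseg)
    starts = range(0, n - nperseg + 1, step)
    segs = np.stack([data[:, s: s + nperseg] * win for s in starts])
    x = np.fft.rfft(segs, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, d=1 / fs)
    return freqs, x


def cross_spectra(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged cross-spectral density tensor.

    Returns (freqs, S) with S of shape (channels, channels, freqs);
    ``S[i, i]`` is real and nonnegative.  Scaling constants are omitted:
    they cancel in every coherency-type ratio.
    """
    freqs, x = _segment_fft(np.asarray(data, dtype=float), fs)
    s = np.einsum("kif,kjf->ijf", x, np.conj(x)) / x.shape[0]
    return freqs, s

def _band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    keep = (freqs > band.low_hz) & (freqs < band.high_hz)
    if not keep.any():
        raise ValueError(f"no frequency bins strictly inside band {band.name}")
    return keep


def _imcoh_from_spectra(s: np.ndarray, keep: np.ndarray,
                        sqrt_normalization: bool) -> np.ndarray:
    auto = np.real(np.einsum("iif->if", s))[:, keep]
    if np.any(auto <= 0):
        raise ValueError("zero spectral power in band; coherency undefined")
    num = np.abs(np.imag(s[:, :, keep]))
    if sqrt_normalization:
        denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    else:
        denom = auto[:, None, :] * auto[None, :, :]
    return (num / denom).mean(axis=-1)


def imcoh(x: np.ndarray, y: np.ndarray, band: BandSpec, fs: float,
          sqrt_normalization: bool = True) -> float:
    """Band-averaged imaginary part of coherency between two series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    freqs, s = cross_spectra(np.vstack([x, y]), fs)
    m = _imcoh_from_spectra(s, _band_bins(freqs, band), sqrt_normalization)
    return float(m[0, 1])


# ---------------------------------------------------------------------------
# whole-epoch matrices

def _symmetrize(m: np.ndarray, diagonal: float) -> np.ndarray:
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, diagonal)
    return m


def connectivity_matrix(epoch: Epoch, method: str,
                        band: BandSpec = BROADBAND,
                        sqrt_normalization: bool = True) -> ConnectivityMatrix:
    """Connectivity matrix of an epoch for one measure and band.

    All unordered channel pairs are computed at once via vectorized
    equivalents of the pairwise functions; the diagonal is set to the
    measure's self-value (PSI/Corr/AEC 1, ImCoh 0).
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; known: {METHODS}")
    if epoch.n_channels < 2:
        raise ValueError("need at least two channels")
    data = np.asarray(epoch.data, dtype=float)

    if method == "imcoh":
        freqs, s = cross_spectra(data, epoch.fs)
        m = _imcoh_from_spectra(s, _band_bins(freqs, band), sqrt_normalization)
        values = _symmetrize(m, DIAGONAL[method])
    else:
        filtered = bandpass_array(data, band, epoch.fs)
        if method == "psi":
            analytic = signal.hilbert(filtered, axis=-1)
            mags = np.abs(analytic)
            if np.any(mags.max(axis=-1) == 0):
                bad = np.where(mags.max(axis=-1) == 0)[0].tolist()
                raise ValueError(f"all-zero channels {bad}: phase undefined")
            z = analytic / np.maximum(mags, np.finfo(float).tiny)
            m = np.abs(z @ np.conj(z.T)) / filtered.shape[-1]
        elif method == "corr":
            _check_variances(filtered)
            m = np.corrcoef(filtered)
        else:  # aec
            env = _trim(np.abs(signal.hilbert(filtered, axis=-1)),
                        ENVELOPE_EDGE_TRIM)
            _check_variances(env)
            m = np.corrcoef(env)
        values = _symmetrize(m, DIAGONAL[method])

    return ConnectivityMatrix(
        values=values, method=method, band=band,
        epoch_ref=(epoch.source_subject, epoch.index),
    )


def _check_variances(data: np.ndarray) -> None:
    sd = data.std(axis=-1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"zero-variance channels {bad}: correlation undefined")
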