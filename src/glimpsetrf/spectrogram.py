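"""Multiband spectrograms and acoustic-edge features for two-talker audio.

The acoustic front end converts a waveform into a time x frequency-band
magnitude matrix sampled at a fixed frame rate (100 Hz by default), using a
bank of log-spaced bandpass filters followed by Hilbert-envelope extraction.
Acoustic *edges* are the half-wave rectified temporal derivative of such a
spectrogram.  For a talker embedded in a mixture, edges split into

* glimpsed edges: ``min(edge_talker, edge_mixture)`` -- talker edges that
  survive in the mixture, and
* masked edges: ``max(edge_talker - edge_mixture, 0)`` -- talker edges that
  exceed the mixture's and are therefore hidden by the competing talker,

so that glimpsed + masked reconstruct the talker's edges exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class BandSpectrogram:
    """Time x band magnitude matrix at a fixed frame rate.

    Attributes
    ----------
    values : ndarray, shape (n_frames, n_bands)
        Nonnegative band magnitudes.
    band_centers_hz : ndarray, shape (n_bands,)
        Strictly increasing band center frequencies.
    frame_rate_hz : float
        Frames per second (100 by default throughout the package).
    """

    values: np.ndarray
    band_centers_hz: np.ndarray
    frame_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_centers_hz = np.asarray(self.band_centers_hz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x bands)")
        if self.values.shape[1] != self.band_centers_hz.size:
            raise ValueError("band_centers_hz length must match n_bands")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("spectrogram contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("spectrogram magnitudes must be nonnegative")
        if self.band_centers_hz.size > 1 and np.any(np.diff(self.band_centers_hz) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class EdgeSet:
    """Raw, glimpsed, and masked edges of one talker (all time x bands >= 0)."""

    raw: np.ndarray
    glimpsed: np.ndarray
    masked: np.ndarray


def log_band_edges(n_bands: int, fmin_hz: float, fmax_hz: float) -> np.ndarray:
    """Logarithmically spaced band edges (n_bands + 1 values)."""
    return np.geomspace(fmin_hz, fmax_hz, n_bands + 1)


def log_band_centers(n_bands: int, fmin_hz: float, fmax_hz: float) -> np.ndarray:
    """Geometric-mean centers of the log-spaced bands."""
    edges = log_band_edges(n_bands, fmin_hz, fmax_hz)
    return np.sqrt(edges[:-1] * edges[1:])


def compute_band_spectrogram(
    waveform: np.ndarray,
    fs: float,
    n_bands: int = 10,
    fmin_hz: float = 50.0,
    fmax_hz: float = 8000.0,
    frame_rate_hz: float = 100.0,
    filter_order: int = 4,
) -> BandSpectrogram:
    """Bandpass-filterbank spectrogram of a mono waveform.

    Each band is a Butterworth bandpass with log-spaced edges; the band
    magnitude is the Hilbert envelope averaged within each output frame, which
    keeps the representation nonnegative (a linear-magnitude scale -- edge
    extraction relies on min/max algebra over nonnegative values).

    Parameters
    ----------
    waveform : 1-D array of audio samples.
    fs : sampling rate in Hz.
    n_bands : number of bands (10 for TRF regressors, 100 for glimpse ratios).
    fmin_hz, fmax_hz : frequency range of the filterbank; ``fmax`` must not
        exceed the Nyquist frequency.
    frame_rate_hz : output frame rate.

    Returns
    -------
    BandSpectrogram with ``ceil(duration * frame_rate)`` frames.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not (0 < fmin_hz < fmax_hz):
        raise ValueError("need 0 < fmin < fmax")
    if fmax_hz > fs / 2:
        raise ValueError(f"fmax {fmax_hz} Hz exceeds Nyquist {fs / 2} Hz")
    samples_per_frame = fs / frame_rate_hz
    if x.size < samples_per_frame:
        raise ValueError("waveform shorter than one output frame")

    n_frames = int(np.ceil(x.size / fs * frame_rate_hz))
    edges = log_band_edges(n_bands, fmin_hz, fmax_hz)
    centers = log_band_centers(n_bands, fmin_hz, fmax_hz)
    # a top edge exactly at Nyquist is allowed; nudge it inside for the
    # digital filter design
    edges[-1] = min(edges[-1], 0.999999 * fs / 2)

    # frame membership of each sample: sample i -> frame floor(i / fs * rate)
    frame_idx = np.minimum(
        (np.arange(x.size) / fs * frame_rate_hz).astype(int), n_frames - 1
    )
    counts = np.bincount(frame_idx, minlength=n_frames).astype(float)

    out = np.empty((n_frames, n_bands))
    for b in range(n_bands):
        sos = signal.butter(
            filter_order, [edges[b], edges[b + 1]], btype="bandpass", fs=fs, output="sos"
        )
        band = signal.sosfiltfilt(sos, x)
        env = np.abs(signal.hilbert(band))
        out[:, b] = np.bincount(frame_idx, weights=env, minlength=n_frames) / counts
    out = np.maximum(out, 0.0)
    return BandSpectrogram(out, centers, frame_rate_hz)


def compute_edges(spec: BandSpectrogram | np.ndarray) -> np.ndarray:
    """Half-wave rectified temporal derivative of a band spectrogram.

    ``out[t, b] = max(spec[t, b] - spec[t-1, b], 0)`` with the first frame set
    to zero (no predecessor).  Invariant to constant offsets of the input.
    """
    values = spec.values if isinstance(spec, BandSpectrogram) else np.asarray(spec, float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D time x bands matrix")
    out = np.zeros_like(values)
    out[1:] = np.maximum(np.diff(values, axis=0), 0.0)
    return out


def decompose_edges(talker_edges: np.ndarray, mixture_edges: np.ndarray) -> EdgeSet:
    """Split a talker's edges into glimpsed and masked components.

    glimpsed = min(talker, mixture); masked = max(talker - mixture, 0).
    By construction glimpsed + masked == talker exactly.
    """
    t = np.asarray(talker_edges, dtype=float)
    m = np.asarray(mixture_edges, dtype=float)
    if t.shape != m.shape:
        raise ValueError(f"shape mismatch: talker {t.shape} vs mixture {m.shape}")
    if np.any(t < 0) or np.any(m < 0):
        raise ValueError("edges must be nonnegative")
    glimpsed = np.minimum(t, m)
    masked = t - glimpsed  # == max(t - m, 0), and conserves t bit-exactly
    return EdgeSet(raw=t, glimpsed=glimpsed, masked=masked)


def shuffle_local(
    matrix: np.ndarray,
    window_ms: float = 500.0,
    frame_rate_hz: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Shuffle rows within consecutive fixed-duration windows.

    Used as the null transform for acoustic regressors: permuting frames inside
    short (500 ms) windows preserves local and global feature statistics while
    destroying the time-locked stimulus-response relationship.  All columns of
    a row move together; a window longer than the signal degenerates to one
    global permutation.
    """
    x = np.asarray(matrix)
    if x.ndim == 1:
        x = x[:, None]
    rng = np.random.default_rng(seed)
    win = int(round(window_ms / 1000.0 * frame_rate_hz))
    if win < 2:
        raise ValueError("shuffle window must span at least 2 frames")
    out = x.copy()
    for start in range(0, x.shape[0], win):
        stop = min(start + win, x.shape[0])
        perm = rng.permutation(stop - start)
        out[start:stop] = x[start:stop][perm]
    return out
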