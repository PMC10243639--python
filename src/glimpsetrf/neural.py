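"""High-gamma envelope extraction and speech-responsive electrode selection.

Intracranial broadband recordings are cleaned (DC drift removal, line-noise
notches, optional local re-referencing), filtered into eight 10 Hz-wide bands
spanning 70-150 Hz, envelope-extracted with the Hilbert transform, averaged,
and resampled to the 100 Hz analysis rate.  Envelopes are z-scored against a
pre-stimulus silence period, and electrodes are kept when their speech-vs-
silence effect size (Cohen's D) exceeds 0.2.

Synthetic pipelines may enter directly at the envelope stage; the broadband
chain is only needed for raw recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

HG_BAND_EDGES_HZ = [(70 + 10 * i, 80 + 10 * i) for i in range(8)]
D_THRESHOLD = 0.2


@dataclass
class NeuralRecording:
    """Electrode x time envelope matrix with per-electrode metadata.

    coords holds (posterior-anterior coordinate, distance from the pSTG-mSTG
    boundary) per electrode; localization itself happens upstream.
    """

    envelopes: np.ndarray            # electrodes x time, 100 Hz
    subject_ids: np.ndarray          # str or int per electrode
    regions: np.ndarray              # {"HG", "STG", "other"} per electrode
    coords: np.ndarray | None = None  # electrodes x 2
    speech_mask: np.ndarray | None = None
    silence_mask: np.ndarray | None = None
    frame_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.envelopes = np.atleast_2d(np.asarray(self.envelopes, dtype=float))
        self.subject_ids = np.asarray(self.subject_ids)
        self.regions = np.asarray(self.regions)
        n = self.envelopes.shape[0]
        if self.subject_ids.size != n or self.regions.size != n:
            raise ValueError("every electrode needs a subject and region tag")

    @property
    def n_electrodes(self) -> int:
        return self.envelopes.shape[0]

    def select(self, keep: np.ndarray) -> "NeuralRecording":
        return NeuralRecording(
            self.envelopes[keep],
            self.subject_ids[keep],
            self.regions[keep],
            None if self.coords is None else self.coords[keep],
            self.speech_mask,
            self.silence_mask,
            self.frame_rate_hz,
        )


def preprocess_broadband(
    raw: np.ndarray,
    fs: float,
    notch_harmonics_hz: tuple[float, ...] = (60.0, 120.0, 180.0, 240.0),
    notch_bw_hz: float = 1.0,
    neighbor_map: dict[int, list[int]] | None = None,
) -> np.ndarray:
    """Clean broadband recordings: high-pass, re-reference, notch.

    A first-order 1 Hz Butterworth high-pass removes DC drift, each electrode
    is optionally re-referenced against the mean of its nearest neighbors, and
    second-order IIR notches (1 Hz bandwidth) remove line noise harmonics.
    All filtering is zero-phase (forward-backward).  Harmonics above Nyquist
    are skipped with a warning.
    """
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    sos = signal.butter(1, 1.0, btype="highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    if neighbor_map is not None:
        ref = x.copy()
        for e, nbrs in neighbor_map.items():
            x[e] = ref[e] - ref[nbrs].mean(axis=0)
    for f0 in notch_harmonics_hz:
        if f0 >= fs / 2:
            warnings.warn(f"skipping {f0} Hz notch: above Nyquist for fs={fs}")
            continue
        b, a = signal.iirnotch(f0, Q=f0 / notch_bw_hz, fs=fs)
        x = signal.filtfilt(b, a, x, axis=-1)
    return x


def highgamma_envelope(
    cleaned: np.ndarray,
    fs: float,
    target_rate_hz: float = 100.0,
    order: int = 4,
    stopband_db: float = 40.0,
) -> np.ndarray:
    """Average Hilbert envelope of eight 10 Hz bands between 70 and 150 Hz.

    Each band uses a zero-phase Chebyshev type-II bandpass; the eight band
    envelopes are averaged and polyphase-resampled to ``target_rate_hz``.
    Output is clipped at zero (resampling can ring slightly negative).
    """
    if fs < 300:
        raise ValueError("need fs >= 300 Hz to resolve the 70-150 Hz band")
    x = np.atleast_2d(np.asarray(cleaned, dtype=float))
    env = np.zeros_like(x)
    for lo, hi in HG_BAND_EDGES_HZ:
        sos = signal.cheby2(
            order, stopband_db, [lo, hi], btype="bandpass", fs=fs, output="sos"
        )
        band = signal.sosfiltfilt(sos, x, axis=-1)
        env += np.abs(signal.hilbert(band, axis=-1))
    env /= len(HG_BAND_EDGES_HZ)
    up, down = (np.array([target_rate_hz, fs]) / np.gcd(int(target_rate_hz), int(fs))).astype(int)
    out = signal.resample_poly(env, up, down, axis=-1)
    return np.maximum(out, 0.0)


def zscore_to_silence(envelope: np.ndarray, silence_mask: np.ndarray) -> np.ndarray:
    """Standardize each electrode against its pre-stimulus silence period."""
    x = np.atleast_2d(np.asarray(envelope, dtype=float))
    m = np.asarray(silence_mask, dtype=bool)
    if not m.any():
        raise ValueError("silence mask is empty")
    mu = x[:, m].mean(axis=1, keepdims=True)
    sd = x[:, m].std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance silence period; cannot z-score")
    return (x - mu) / sd


def cohens_d(speech: np.ndarray, silence: np.ndarray) -> float:
    """Pooled-SD Cohen's D between speech and silence samples."""
    n1, n2 = speech.size, silence.size
    v1, v2 = speech.var(ddof=1), silence.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        return np.nan
    return (speech.mean() - silence.mean()) / pooled


def speech_responsiveness(
    envelope: np.ndarray,
    speech_mask: np.ndarray,
    silence_mask: np.ndarray,
    d_threshold: float = D_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Cohen's D per electrode and the boolean keep mask (strict ``D > 0.2``).

    Electrodes with a degenerate pooled SD are dropped with a warning.
    """
    x = np.atleast_2d(np.asarray(envelope, dtype=float))
    sp = np.asarray(speech_mask, dtype=bool)
    si = np.asarray(silence_mask, dtype=bool)
    if not sp.any() or not si.any():
        raise ValueError("speech and silence masks must both be nonempty")
    d = np.array([cohens_d(row[sp], row[si]) for row in x])
    if np.any(np.isnan(d)):
        warnings.warn("dropping electrode(s) with degenerate pooled SD")
    keep = np.nan_to_num(d, nan=-np.inf) > d_threshold
    return d, keep
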