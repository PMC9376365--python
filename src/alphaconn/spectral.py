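"""Alpha subband relative power and individual alpha peak frequency (IAPF).

The analysis chain mirrors standard resting-EEG quantitative practice:

1. zero-phase band-limit to 2-35 Hz;
2. cut into consecutive non-overlapping 4-s epochs (0.25 Hz resolution);
3. per epoch and channel, Hann-tapered periodogram; relative power of each
   1-Hz subband of 8-13 Hz as a fraction of total 2-35 Hz power;
4. logit transform ``log[x / (1 - x)]`` (natural log) to correct skewness;
5. average over epochs.

IAPF is the frequency of the maximum of the epoch-averaged spectrum within
8-13 Hz at the native 0.25 Hz bin resolution, ties broken toward the lower
frequency; maxima on the band edge are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from alphaconn.recording import EEGRecording

#: the five 1-Hz alpha subbands, half-open [low, high)
ALPHA_SUBBANDS: list[tuple[float, float]] = [(8, 9), (9, 10), (10, 11), (11, 12), (12, 13)]

#: analysis band; also the denominator of relative power
TOTAL_BAND: tuple[float, float] = (2.0, 35.0)

DEFAULT_EPOCH_S = 4.0
IAPF_BAND = (8.0, 13.0)


@dataclass
class ClampLog:
    """Counter for out-of-domain logit inputs clamped to [eps, 1 - eps]."""

    count: int = 0


@dataclass
class RejectionLog:
    """Bookkeeping for amplitude-threshold epoch rejection."""

    n_total: int = 0
    n_rejected: int = 0
    rejected_indices: list[int] = field(default_factory=list)


def bandlimit(rec: EEGRecording, low: float = 2.0, high: float = 35.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; length-preserving.

    Out-of-band attenuation of the order-4 forward-backward filter exceeds
    40 dB one octave outside the edges.
    """
    nyq = rec.rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges ({low}, {high}) invalid for rate {rec.rate} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return EEGRecording(filtered, rec.rate, list(rec.labels))


def segment_epochs(rec: EEGRecording, epoch_s: float = DEFAULT_EPOCH_S) -> np.ndarray:
    """Split into consecutive non-overlapping epochs.

    Returns an array of shape ``(n_epochs, n_channels, epoch_samples)``; the
    trailing remainder shorter than one epoch is dropped.
    """
    if epoch_s <= 0:
        raise ValueError("epoch length must be positive")
    n_per = int(round(epoch_s * rec.rate))
    n_epochs = rec.n_times // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than one {epoch_s:.0f}-s epoch"
        )
    trimmed = rec.samples[:, : n_epochs * n_per]
    return trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)


def epoch_psd(epoch: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered periodogram of one epoch (channels x samples)."""
    freqs, psd = signal.periodogram(epoch, fs=rate, window="hann", detrend="constant", axis=-1)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Sum of periodogram bins with frequency in ``[band[0], band[1])``."""
    mask = (freqs >= band[0]) & (freqs < band[1])
    return psd[..., mask].sum(axis=-1)


def epoch_relative_power(
    epoch: np.ndarray,
    rate: float,
    band: tuple[float, float],
    total_band: tuple[float, float] = TOTAL_BAND,
) -> np.ndarray:
    """Fraction of total-band power falling in ``band`` for one epoch.

    Bands are half-open, so the 33 one-Hz bins of 2-35 Hz partition the total
    exactly and their fractions sum to one.
    """
    if not (total_band[0] <= band[0] < band[1] <= total_band[1]):
        raise ValueError(f"band {band} not contained in total band {total_band}")
    freqs, psd = epoch_psd(np.asarray(epoch, dtype=float), rate)
    total = band_power(freqs, psd, total_band)
    if np.any(total <= 0):
        raise ValueError("zero total power in analysis band")
    return band_power(freqs, psd, band) / total


def logit_transform(x, eps: float = 1e-6, clamp_log: ClampLog | None = None):
    """Natural-log logit ``log(x / (1 - x))``.

    Inputs outside ``(0, 1)`` are clamped to ``[eps, 1 - eps]`` with a warning;
    pass a :class:`ClampLog` to count clamps.
    """
    arr = np.asarray(x, dtype=float)
    out_of_domain = (arr <= 0) | (arr >= 1)
    if np.any(out_of_domain):
        n_bad = int(out_of_domain.sum())
        warnings.warn(f"clamped {n_bad} relative-power value(s) to [{eps}, {1 - eps}]")
        if clamp_log is not None:
            clamp_log.count += n_bad
        arr = np.clip(arr, eps, 1 - eps)
    result = np.log(arr / (1.0 - arr))
    return float(result) if np.isscalar(x) else result


def _prepare_epochs(
    rec: EEGRecording,
    epoch_s: float,
    reject_uv: float | None,
    rejection_log: RejectionLog | None,
    prefiltered: bool,
) -> np.ndarray:
    if not prefiltered:
        rec = bandlimit(rec, *TOTAL_BAND)
    epochs = segment_epochs(rec, epoch_s)
    if rejection_log is not None:
        rejection_log.n_total = len(epochs)
    if reject_uv is not None:
        peak = np.abs(epochs).max(axis=(1, 2))
        keep = peak <= reject_uv
        if rejection_log is not None:
            rejection_log.n_rejected = int((~keep).sum())
            rejection_log.rejected_indices = list(np.flatnonzero(~keep))
        if not keep.any():
            raise ValueError("all epochs rejected by the amplitude threshold")
        epochs = epochs[keep]
    return epochs


def subject_subband_table(
    rec: EEGRecording,
    epoch_s: float = DEFAULT_EPOCH_S,
    reject_uv: float | None = 100.0,
    clamp_log: ClampLog | None = None,
    rejection_log: RejectionLog | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Mean logit relative power per channel and 1-Hz alpha subband.

    Tidy output: columns ``channel``, ``band`` (e.g. ``"8-9"``), ``value``
    and ``n_epochs``.  ``reject_uv=None`` disables amplitude-based epoch
    rejection (default threshold +/-100 microvolts).
    """
    epochs = _prepare_epochs(rec, epoch_s, reject_uv, rejection_log, prefiltered)
    freqs, psd = epoch_psd(epochs, rec.rate)  # epochs x channels x freqs
    total = band_power(freqs, psd, TOTAL_BAND)
    if np.any(total <= 0):
        raise ValueError("zero total power in analysis band")
    rows = []
    for low, high in ALPHA_SUBBANDS:
        frac = band_power(freqs, psd, (low, high)) / total
        logit = logit_transform(frac, clamp_log=clamp_log)
        mean_logit = logit.mean(axis=0)  # over epochs
        for c, label in enumerate(rec.labels):
            rows.append(
                {
                    "channel": label,
                    "band": f"{int(low)}-{int(high)}",
                    "value": float(mean_logit[c]),
                    "n_epochs": len(epochs),
                }
            )
    return pd.DataFrame(rows)


def mean_spectrum(
    rec: EEGRecording,
    epoch_s: float = DEFAULT_EPOCH_S,
    reject_uv: float | None = 100.0,
    prefiltered: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged Hann periodogram (freqs, channels x freqs)."""
    epochs = _prepare_epochs(rec, epoch_s, reject_uv, None, prefiltered)
    freqs, psd = epoch_psd(epochs, rec.rate)
    return freqs, psd.mean(axis=0)


def argmax_lower_tie(values: np.ndarray) -> int:
    """Index of the maximum; exact ties resolve to the lowest index."""
    return int(np.argmax(values))


def estimate_iapf(
    rec: EEGRecording,
    epoch_s: float = DEFAULT_EPOCH_S,
    band: tuple[float, float] = IAPF_BAND,
    reject_uv: float | None = 100.0,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Per-channel IAPF: argmax of the epoch-averaged spectrum in 8-13 Hz.

    Resolution is the epoch's native bin width (0.25 Hz for 4-s epochs).
    Output columns: ``channel``, ``iapf``, ``at_boundary`` (True when the
    maximum sits on the band edge, i.e. no interior alpha peak).
    """
    freqs, spec = mean_spectrum(rec, epoch_s, reject_uv, prefiltered)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    sub_freqs = freqs[mask]
    sub = spec[:, mask]
    rows = []
    for c, label in enumerate(rec.labels):
        idx = argmax_lower_tie(sub[c])
        f_peak = float(sub_freqs[idx])
        rows.append(
            {
                "channel": label,
                "iapf": f_peak,
                "at_boundary": idx == 0 or idx == len(sub_freqs) - 1,
            }
        )
    return pd.DataFrame(rows)
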