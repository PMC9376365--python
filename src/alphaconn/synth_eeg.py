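"""Synthetic resting EEG with a 1/f background and an alpha peak.

Channels are synthesized in the frequency domain: independent complex Gaussian
coefficients are shaped by a ``f^(-beta/2)`` background amplitude plus a
Gaussian alpha profile centred at the subject's true IAPF.  The inverse FFT of
such coefficients is a stationary Gaussian process whose alpha component has a
Rayleigh-distributed envelope — a waxing-and-waning burst process rather than
a pure sinusoid, which exposes IAPF estimators to realistic spectral leakage.
Alpha amplitude is largest over the occiput and tapers toward frontal sites.
"""

from __future__ import annotations

import numpy as np

from alphaconn.cohort import EEGGenParams, SubjectSpec, subject_rng
from alphaconn.recording import EEGRecording

#: relative alpha amplitude per 10-20 site group (occipital dominance)
_ALPHA_GAIN = {
    "O2": 1.0, "O1": 1.0,
    "P4": 0.9, "P3": 0.9,
    "T6": 0.75, "T5": 0.75,
    "C4": 0.7, "C3": 0.7,
    "T4": 0.6, "T3": 0.6,
    "F4": 0.55, "F3": 0.55,
    "Fp2": 0.5, "Fp1": 0.5,
    "F8": 0.5, "F7": 0.5,
}


def channel_alpha_gain(label: str) -> float:
    """Alpha amplitude gain for a 10-20 channel label (1.0 = occipital)."""
    return _ALPHA_GAIN.get(label, 0.6)


def synth_eeg(subject: SubjectSpec, params: EEGGenParams) -> EEGRecording:
    """Generate one subject's multi-channel resting EEG.

    The power spectrum of each channel is ``noise_sd^2 * f^-beta`` plus an
    alpha peak ``snr_c * noise_sd^2 * iapf^-beta * exp(-(f-iapf)^2/(2 sigma^2))``
    where ``snr_c = alpha_peak_snr * gain_c^2 * true_alpha_power^2`` — i.e.
    ``alpha_peak_snr`` is exactly the peak-bin power SNR of a unit-gain channel
    for a subject with unit alpha amplitude.  Reproducible given
    ``(params.seed, subject.id)``.
    """
    rate, duration = params.sample_rate, params.duration
    if rate <= 0 or duration <= 0:
        raise ValueError("sample rate and duration must be positive")
    n = int(round(rate * duration))
    rng = subject_rng(params.seed, subject.id, "eeg")
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)

    # background amplitude profile (zero at DC)
    bg = np.zeros_like(freqs)
    bg[1:] = params.noise_sd * freqs[1:] ** (-params.one_over_f_exponent / 2.0)

    # alpha amplitude profile; FWHM -> Gaussian sigma of the *power* profile
    sigma = params.alpha_bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    peak_amp = (
        np.sqrt(params.alpha_peak_snr)
        * params.noise_sd
        * subject.true_iapf ** (-params.one_over_f_exponent / 2.0)
        * subject.true_alpha_power
    )
    alpha_profile = np.exp(-((freqs - subject.true_iapf) ** 2) / (4.0 * sigma**2))

    samples = np.empty((len(params.channel_labels), n))
    for c, label in enumerate(params.channel_labels):
        amp = bg + peak_amp * channel_alpha_gain(label) * alpha_profile
        re = rng.standard_normal(len(freqs))
        im = rng.standard_normal(len(freqs))
        coeff = amp * (re + 1j * im) / np.sqrt(2.0)
        coeff[0] = 0.0  # zero mean
        if n % 2 == 0:
            coeff[-1] = coeff[-1].real * np.sqrt(2.0)  # Nyquist bin is real
        # scale so the one-sided PSD follows amp^2 independent of n
        samples[c] = np.fft.irfft(coeff, n=n) * np.sqrt(n * rate / 2.0)
    return EEGRecording(samples, rate, list(params.channel_labels))
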