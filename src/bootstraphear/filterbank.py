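"""Cochlear front end: a 24-channel cosine filterbank on the ERB-rate scale.

The filterbank mimics cochlear frequency selectivity.  Channel centre
frequencies are equally spaced on the ERB-rate (equivalent rectangular
bandwidth) scale of Moore & Glasberg between 20 Hz and 20 kHz.  Each filter
has a cosine magnitude response in ERB-rate coordinates, with half-width
equal to the channel spacing so that adjacent filters overlap at ~0.71 gain.

Band levels are root-mean-square levels expressed in dB SPL re 20 uPa.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

N_CHANNELS = 24
F_LOW = 20.0
F_HIGH = 20_000.0
P_REF = 2e-5  # 20 uPa reference pressure
LEVEL_FLOOR_DB = -100.0  # silent-band floor, see band_levels


def erb_bandwidth(f_hz):
    """Moore & Glasberg equivalent rectangular bandwidth (Hz) at ``f_hz``."""
    return 24.7 * (4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_rate(f_hz):
    """ERB-rate scale value (ERB number) for frequency in Hz."""
    return 21.4 * np.log10(4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


def erb_rate_to_hz(e):
    """Inverse of :func:`erb_rate`."""
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) * 1000.0 / 4.37


@lru_cache(maxsize=None)
def _center_frequencies_cached(n_channels, f_low, f_high):
    e = np.linspace(erb_rate(f_low), erb_rate(f_high), n_channels)
    freqs = erb_rate_to_hz(e)
    freqs.setflags(write=False)
    return freqs


def center_frequencies(n_channels: int = N_CHANNELS,
                       f_low: float = F_LOW,
                       f_high: float = F_HIGH) -> np.ndarray:
    """Channel centre frequencies (Hz), equally spaced on the ERB-rate scale."""
    return _center_frequencies_cached(n_channels, f_low, f_high)


def erb_spacing(n_channels: int = N_CHANNELS,
                f_low: float = F_LOW,
                f_high: float = F_HIGH) -> float:
    """Channel spacing in ERB-rate units."""
    return (erb_rate(f_high) - erb_rate(f_low)) / (n_channels - 1)


def filter_gains(f_hz, n_channels: int = N_CHANNELS,
                 f_low: float = F_LOW, f_high: float = F_HIGH) -> np.ndarray:
    """Magnitude response of every channel at frequencies ``f_hz``.

    Returns an array of shape ``(n_channels, len(f_hz))`` with the cosine
    filter gains.  Gains are zero outside a channel's +-1-spacing support.
    """
    f_hz = np.atleast_1d(np.asarray(f_hz, dtype=float))
    e = erb_rate(np.maximum(f_hz, 1e-6))
    centers_e = np.linspace(erb_rate(f_low), erb_rate(f_high), n_channels)
    width = erb_spacing(n_channels, f_low, f_high)
    d = (e[None, :] - centers_e[:, None]) / width
    gains = np.cos(0.5 * np.pi * d)
    gains[np.abs(d) > 1.0] = 0.0
    return gains


def band_levels(waveform: np.ndarray, sample_rate: float,
                n_channels: int = N_CHANNELS) -> np.ndarray:
    """Per-channel RMS band levels (dB SPL) of a waveform.

    ``waveform`` may be 1-D (mono) or 2-D ``(n_ears, n_samples)``; the result
    has shape ``(n_channels,)`` or ``(n_ears, n_channels)``.  Filtering is
    performed in the frequency domain (the filters are defined by their
    magnitude response).  A silent band would have level -inf; levels are
    clipped at ``LEVEL_FLOOR_DB`` (white-noise stimuli never get near it).
    """
    wave = np.atleast_2d(np.asarray(waveform, dtype=float))
    if wave.shape[-1] == 0:
        raise ValueError("empty waveform")
    n = wave.shape[-1]
    spectrum = np.fft.rfft(wave, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gains = filter_gains(freqs, n_channels)  # (n_channels, n_freqs)
    # Parseval: mean square of the band-filtered signal from the spectrum.
    power = np.abs(spectrum) ** 2
    # rfft double-counts interior bins when reconstructing total power
    weights = np.full(freqs.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    band_ms = (power[:, None, :] * (gains**2 * weights)[None, :, :]).sum(axis=-1) / n**2
    rms = np.sqrt(band_ms)
    with np.errstate(divide="ignore"):
        levels = 20.0 * np.log10(rms / P_REF)
    levels = np.maximum(levels, LEVEL_FLOOR_DB)
    if np.ndim(waveform) == 1:
        return levels[0]
    return levels


def band_power_fractions(sample_rate: float, n_fft: int = 8192,
                         n_channels: int = N_CHANNELS) -> np.ndarray:
    """Fraction of broadband white-noise power captured by each channel.

    Used by the level-domain fast path: a white-noise burst at broadband
    level ``L`` has expected band level ``L + 10*log10(fraction_i)`` before
    any direction-dependent gain is applied.
    """
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    gains = filter_gains(freqs, n_channels)
    total = freqs.size
    return (gains**2).sum(axis=1) / total


def band_level_noise_std(duration_s: float, sample_rate: float,
                         n_channels: int = N_CHANNELS) -> np.ndarray:
    """Std (dB) of the RMS level estimate of a finite white-noise burst.

    The band RMS^2 of a noise token is approximately chi^2 distributed with
    k ~ 2*B*T degrees of freedom (B = effective noise bandwidth of the
    channel, T = duration), giving a level standard deviation of
    (10/ln 10)*sqrt(2/k).  Narrow low-frequency channels therefore fluctuate
    by a few dB from token to token while high channels are nearly stable.
    """
    fc = center_frequencies(n_channels)
    # effective noise bandwidth of the cosine filter: spacing (in ERB units)
    # times the local ERB, times the power-integral of cos^2 (=1/2) * 2 sides
    bw = erb_spacing(n_channels) * erb_bandwidth(fc)
    bw = np.minimum(bw, sample_rate / 2.0)
    k = np.maximum(2.0 * bw * duration_s, 1.0)
    return (10.0 / np.log(10.0)) * np.sqrt(2.0 / k)
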