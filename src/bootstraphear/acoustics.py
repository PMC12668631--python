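"""Acoustic rendering: sources, head poses, HRTF sets and a synthetic head.

A sound source at a head-relative direction is turned into per-ear,
per-frequency-band levels.  Two acoustic models are supported:

* :class:`HRTFSet` — measured head-related impulse responses (e.g. a KEMAR
  set in SOFA format), barycentrically interpolated between the three
  nearest measured positions.
* :class:`SyntheticHeadModel` — a packaged analytic stand-in defined
  directly in the band-level domain.  It emulates the features that make
  the localization task identifiable from 24-band levels alone:
  frequency-dependent interaural level differences that grow with the sine
  of the lateral angle, a monaural level peak near one ear, a small
  high-band attenuation for rear sources (front/back tilt) and an
  antisymmetric spectral ramp across elevation.

All levels are dB SPL; azimuths positive clockwise (listener's right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import clip_elevation, wrap_deg
from . import filterbank as fb


@dataclass
class SoundSource:
    """A sound presentation: direction, fixed 1.4 m distance, level, duration."""

    azimuth: float
    elevation: float = 0.0
    distance: float = 1.4
    level: float = 70.0  # dB SPL
    duration: float = 100.0  # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.azimuth = float(wrap_deg(self.azimuth))
        self.elevation = float(clip_elevation(self.elevation))


@dataclass
class HeadPose:
    """Head orientation; the relative source angle is wrap(source - pose)."""

    azimuth: float = 0.0
    elevation: float = 0.0

    def relative(self, source: SoundSource) -> tuple[float, float]:
        return (
            float(wrap_deg(source.azimuth - self.azimuth)),
            float(np.clip(source.elevation - self.elevation,
                          -130.0, 130.0)),
        )


@dataclass
class DisruptionSpec:
    """A simulated hearing disruption applied to the ANF magnitude vectors.

    ``shift_symmetric``   : L' = L - shift, R' = R - shift (bilateral loss)
    ``scale_symmetric``   : L' = s*L, R' = s*R            (bilateral compression)
    ``scale_asymmetric``  : L' = sL*L, R' = sR*R          (unilateral disruption)
    """

    mode: str = "shift_symmetric"
    shift: float = 20.0
    scale_left: float = 0.5
    scale_right: float = 1.0

    MODES = ("shift_symmetric", "scale_symmetric", "scale_asymmetric")

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValueError(f"unknown disruption mode {self.mode!r}")
        if min(self.scale_left, self.scale_right) <= 0:
            raise ValueError("scale factors must be positive")

    def apply(self, left: np.ndarray, right: np.ndarray):
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if self.mode == "shift_symmetric":
            return left - self.shift, right - self.shift
        if self.mode == "scale_symmetric":
            return self.scale_left * left, self.scale_left * right
        return self.scale_left * left, self.scale_right * right


def apply_disruption(left_mags, right_mags, spec: "DisruptionSpec"):
    """Apply a hearing disruption to an (L, R) magnitude pair."""
    return spec.apply(left_mags, right_mags)


def neural_magnitudes(levels: np.ndarray) -> np.ndarray:
    """ANF transform of band levels; the identity in this model.

    The auditory-nerve-fibre stage preserves the relative magnitude of
    different sound intensities; its absolute scale is arbitrary, so the
    simplest faithful choice is the identity.
    """
    return np.asarray(levels, dtype=float)


def compute_ild(left_mags, right_mags, cf_hz, side: str = "right"):
    """ILD seen by an LSO neuron with characteristic frequency ``cf_hz``.

    The 24-point magnitude spectra are linearly interpolated at the
    neuron's characteristic frequency; interpolation is performed on the
    ERB-rate axis (the axis on which the channels are equally spaced).
    A right-side neuron receives excitation from the right ear, so its
    input is R - L interpolated at cf; a left-side neuron sees L - R.
    Characteristic frequencies outside the channel centre range are refused
    (extrapolation would be meaningless).
    """
    left_mags = np.asarray(left_mags, dtype=float)
    right_mags = np.asarray(right_mags, dtype=float)
    fc = fb.center_frequencies(left_mags.shape[-1])
    cf_hz = np.asarray(cf_hz, dtype=float)
    if np.any(cf_hz < fc[0] - 1e-9) or np.any(cf_hz > fc[-1] + 1e-9):
        raise ValueError("characteristic frequency outside channel centre range")
    x_axis = fb.erb_rate(fc)
    diff = (left_mags - right_mags) if side == "left" else (right_mags - left_mags)
    e_cf = fb.erb_rate(cf_hz)
    if diff.ndim == 1:
        return np.interp(e_cf, x_axis, diff)
    # batched: interpolate each row at (possibly scalar) cf
    idx = np.clip(np.searchsorted(x_axis, e_cf) - 1, 0, len(x_axis) - 2)
    x0, x1 = x_axis[idx], x_axis[idx + 1]
    w = (e_cf - x0) / (x1 - x0)
    return diff[..., idx] * (1.0 - w) + diff[..., idx + 1] * w


@dataclass
class SyntheticHeadModel:
    """Analytic spherical-head-plus-pinna stand-in, in the level domain.

    ``ild_max``  : ILD amplitude (dB) reached at the top channel for a fully
                   lateral source; lower channels scale with their position
                   on the ERB axis, giving ~10 dB at 2 kHz for the default.
    ``tilt_db``  : high-band attenuation applied to rear sources (front/back
                   spectral asymmetry); the transition is a ramp between
                   ``rear_ramp`` degrees around +-90 azimuth.
    ``elevation_droop_db`` : broadband attenuation growing as (1-cos el),
                   giving the monaural response a peak at 0 elevation.
    ``elevation_tilt_db``  : amplitude of an antisymmetric spectral ramp in
                   sin(el) that makes elevation sign decodable from the
                   48-dim input without moving the across-band mean.
    """

    n_channels: int = fb.N_CHANNELS
    ild_max: float = 20.0
    tilt_db: float = 3.0
    rear_ramp: tuple[float, float] = (85.0, 95.0)
    elevation_droop_db: float = 6.0
    elevation_tilt_db: float = 4.0
    ear_azimuths: tuple[float, float] = (-90.0, 90.0)
    head_radius: float = 0.0875  # m, documentation only
    sample_rate: float = 44100.0
    duration_ms: float = 100.0

    fc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.fc = fb.center_frequencies(self.n_channels)
        e = fb.erb_rate(self.fc)
        self._erb_frac = (e - e[0]) / (e[-1] - e[0])
        self._ild_amp = self.ild_max * self._erb_frac
        # high-band weight for the rear tilt: upper-half ramp on the ERB axis
        self._hiband = np.clip(2.0 * self._erb_frac - 1.0, 0.0, 1.0)
        # antisymmetric across-band ramp (zero mean) for the elevation cue
        ramp = np.linspace(-1.0, 1.0, self.n_channels)
        self._el_ramp = ramp - ramp.mean()
        self._power_frac_db = 10.0 * np.log10(
            fb.band_power_fractions(self.sample_rate, n_channels=self.n_channels)
        )
        self._noise_std = fb.band_level_noise_std(
            self.duration_ms / 1000.0, self.sample_rate, self.n_channels
        )

    # -- direction-dependent band gains ----------------------------------
    def band_gains(self, azimuth, elevation=0.0):
        """Per-ear gain (dB) in each channel for a head-relative direction.

        Returns ``(gain_left, gain_right)`` with shape ``(..., n_channels)``.
        At azimuth 0, elevation 0 the two ears are identical by construction.
        """
        az = np.radians(wrap_deg(azimuth))[..., None]
        el = np.radians(np.asarray(elevation, dtype=float))[..., None]
        lateral = np.sin(az) * np.cos(el)  # sine of the lateral angle
        ild = self._ild_amp * lateral
        az_deg = np.abs(wrap_deg(azimuth))[..., None]
        lo, hi = self.rear_ramp
        rearness = np.clip((az_deg - lo) / (hi - lo), 0.0, 1.0)
        rear = self.tilt_db * rearness * self._hiband
        droop = self.elevation_droop_db * (1.0 - np.cos(el))
        el_cue = self.elevation_tilt_db * np.sin(el) * self._el_ramp
        common = -rear - droop + el_cue
        gain_right = 0.5 * ild + common
        gain_left = -0.5 * ild + common
        return gain_left, gain_right

    # -- level-domain fast path -------------------------------------------
    def band_level_pair(self, azimuth, elevation=0.0, level=70.0, rng=None):
        """Per-ear band levels (dB SPL) for a white-noise burst.

        This is the level-domain equivalent of rendering a fresh noise token
        and measuring its band levels: the nominal level (source level plus
        the channel's share of broadband power plus the direction gain) plus
        the token-to-token RMS fluctuation of a finite noise burst, drawn as
        Gaussian dB jitter with the chi-square-derived per-channel std.
        With ``rng=None`` the noiseless nominal levels are returned.
        """
        gl, gr = self.band_gains(azimuth, elevation)
        level = np.asarray(level, dtype=float)[..., None]
        base = level + self._power_frac_db
        left = base + gl
        right = base + gr
        if rng is not None:
            left = left + rng.standard_normal(left.shape) * self._noise_std
            right = right + rng.standard_normal(right.shape) * self._noise_std
        return left, right

    # -- waveform path -----------------------------------------------------
    def render(self, source: SoundSource, pose: HeadPose | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Render a binaural white-noise burst, shape ``(2, n_samples)``.

        A fresh white-noise token is spectrally shaped per ear by linearly
        interpolating the band gains over the ERB-rate axis.  The result is
        consistent with :meth:`band_level_pair`: measuring its band levels
        recovers the nominal levels up to finite-token RMS fluctuation.
        """
        if rng is None:
            rng = np.random.default_rng()
        pose = pose or HeadPose()
        rel_az, rel_el = pose.relative(source)
        n = int(round(source.duration / 1000.0 * self.sample_rate))
        noise = rng.standard_normal(n)
        noise *= (fb.P_REF * 10.0 ** (source.level / 20.0)) / np.sqrt(
            np.mean(noise**2)
        )
        spectrum = np.fft.rfft(noise)
        freqs = np.fft.rfftfreq(n, d=1.0 / self.sample_rate)
        gl, gr = self.band_gains(rel_az, rel_el)
        e_axis = fb.erb_rate(self.fc)
        e_f = fb.erb_rate(np.maximum(freqs, 1e-6))
        out = np.empty((2, n))
        for ear, gains in enumerate((np.ravel(gl), np.ravel(gr))):
            g_f = np.interp(e_f, e_axis, gains)
            shaped = spectrum * 10.0 ** (g_f / 20.0)
            out[ear] = np.fft.irfft(shaped, n=n)
        return out


class HRTFSet:
    """A measured HRTF set with barycentric interpolation between positions.

    Parameters
    ----------
    positions : (n, 2) array of (azimuth, elevation) in degrees
    impulse_responses : (n, 2, n_taps) array of per-position (left, right) HRIRs
    sample_rate : sampling rate of the HRIRs in Hz
    """

    def __init__(self, positions, impulse_responses, sample_rate):
        from scipy.spatial import Delaunay

        self.positions = np.asarray(positions, dtype=float)
        self.positions[:, 0] = wrap_deg(self.positions[:, 0])
        self.impulse_responses = np.asarray(impulse_responses, dtype=float)
        self.sample_rate = float(sample_rate)
        if self.positions.shape[0] != self.impulse_responses.shape[0]:
            raise ValueError("positions and impulse responses disagree in length")
        # pad the azimuth axis so triangulation wraps around the circle
        pads = []
        for shift in (-360.0, 360.0):
            pad = self.positions.copy()
            pad[:, 0] += shift
            pads.append(pad)
        self._tri_points = np.vstack([self.positions] + pads)
        self._tri_index = np.tile(np.arange(self.positions.shape[0]), 3)
        self._tri = Delaunay(self._tri_points)

    @classmethod
    def from_sofa(cls, path, sample_rate: float | None = None) -> "HRTFSet":
        """Load a SimpleFreeFieldHRIR SOFA file (SOFA is HDF5 underneath)."""
        import h5py
        from scipy.signal import resample_poly

        with h5py.File(path, "r") as f:
            ir = np.asarray(f["Data.IR"])  # (M, 2, N)
            pos = np.asarray(f["SourcePosition"])[:, :2]  # az, el in degrees
            fs = float(np.ravel(f["Data.SamplingRate"])[0])
        # SOFA azimuths are counter-clockwise 0..360; convert to clockwise
        pos = pos.copy()
        pos[:, 0] = wrap_deg(-pos[:, 0])
        if sample_rate is not None and sample_rate != fs:
            up, down = int(round(sample_rate)), int(round(fs))
            g = np.gcd(up, down)
            ir = resample_poly(ir, up // g, down // g, axis=-1)
            fs = sample_rate
        return cls(pos, ir, fs)

    def interpolation_weights(self, azimuth, elevation):
        """The 3 enclosing measured positions and their barycentric weights."""
        q = np.array([float(wrap_deg(azimuth)), float(elevation)])
        simplex = self._tri.find_simplex(q)
        if simplex < 0:
            raise ValueError(
                f"query ({azimuth}, {elevation}) outside the measured spherical cap"
            )
        transform = self._tri.transform[simplex]
        b = transform[:2].dot(q - transform[2])
        weights = np.append(b, 1.0 - b.sum())
        if not np.all(np.isfinite(weights)):
            raise ValueError("degenerate interpolation triangle")
        weights = np.clip(weights, 0.0, None)
        weights = weights / weights.sum()
        vertices = self._tri_index[self._tri.simplices[simplex]]
        return vertices, weights

    def interpolated_hrir(self, azimuth, elevation=0.0) -> np.ndarray:
        """Barycentric mix of the 3 nearest measured HRIR pairs, (2, n_taps)."""
        vertices, weights = self.interpolation_weights(azimuth, elevation)
        return np.tensordot(weights, self.impulse_responses[vertices], axes=1)

    def render(self, source: SoundSource, pose: HeadPose | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
        """Convolve a fresh white-noise token with the interpolated HRIR pair."""
        from scipy.signal import fftconvolve

        if rng is None:
            rng = np.random.default_rng()
        pose = pose or HeadPose()
        rel_az, rel_el = pose.relative(source)
        hrir = self.interpolated_hrir(rel_az, rel_el)
        n = int(round(source.duration / 1000.0 * self.sample_rate))
        noise = rng.standard_normal(n)
        noise *= (fb.P_REF * 10.0 ** (source.level / 20.0)) / np.sqrt(
            np.mean(noise**2)
        )
        return fftconvolve(hrir, noise[None, :], axes=-1)[:, :n]


def render_binaural(source: SoundSource, pose: HeadPose,
                    model, rng=None) -> np.ndarray:
    """Render ``source`` heard from ``pose`` through ``model`` (two waveforms)."""
    return model.render(source, pose, rng)


def write_wav(path, waveforms: np.ndarray, sample_rate: float) -> None:
    """Write rendered binaural waveforms to a WAV file (debugging aid)."""
    from scipy.io import wavfile

    data = np.asarray(waveforms, dtype=np.float32).T
    wavfile.write(path, int(sample_rate), data)
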