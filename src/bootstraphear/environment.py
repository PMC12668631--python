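"""The interactive acoustic environment seen by the agent.

An :class:`Environment` turns a head-relative source direction into the
48-dimensional binaural ANF magnitude vector (Lη, Rη) that both the Teacher
circuits and the Student network receive.  It applies the configured
hearing disruption, if any, after rendering — disruptions model changes in
the periphery, downstream of the acoustics.

The default backend is the level-domain fast path of
:class:`~bootstraphear.acoustics.SyntheticHeadModel`; the waveform path
(render + filterbank) produces statistically equivalent levels and is used
for verification and for measured :class:`~bootstraphear.acoustics.HRTFSet`
backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import filterbank as fb
from .acoustics import (DisruptionSpec, HeadPose, HRTFSet, SoundSource,
                        SyntheticHeadModel, neural_magnitudes)


@dataclass
class Environment:
    """Acoustic world plus peripheral transforms.

    ``level`` is the nominal stimulus level (dB SPL); during training the
    per-episode level is jittered uniformly by ±``level_jitter`` dB.
    """

    model: SyntheticHeadModel = field(default_factory=SyntheticHeadModel)
    level: float = 70.0
    level_jitter: float = 20.0
    duration_ms: float = 100.0
    disruption: DisruptionSpec | None = None

    @property
    def n_channels(self) -> int:
        return getattr(self.model, "n_channels", fb.N_CHANNELS)

    @property
    def input_dim(self) -> int:
        return 2 * self.n_channels

    def sample_levels(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.level + rng.uniform(-self.level_jitter, self.level_jitter, n)

    # ------------------------------------------------------------------
    def magnitudes(self, azimuth, elevation=0.0, level=None, rng=None):
        """(Lη, Rη) magnitude pair for head-relative directions.

        ``azimuth``/``elevation``/``level`` broadcast; the output arrays have
        shape ``(..., n_channels)``.  ``rng=None`` gives noiseless nominal
        levels (useful for deterministic teacher characterisation).
        """
        if level is None:
            level = self.level
        if isinstance(self.model, SyntheticHeadModel):
            left, right = self.model.band_level_pair(azimuth, elevation, level, rng)
        else:
            left, right = self._measured_pair(azimuth, elevation, level, rng)
        if self.disruption is not None:
            left, right = self.disruption.apply(left, right)
        return neural_magnitudes(left), neural_magnitudes(right)

    def _measured_pair(self, azimuth, elevation, level, rng):
        az = np.atleast_1d(np.asarray(azimuth, dtype=float))
        el = np.broadcast_to(np.asarray(elevation, dtype=float), az.shape)
        lv = np.broadcast_to(np.asarray(level, dtype=float), az.shape)
        if rng is None:
            rng = np.random.default_rng(0)
        left = np.empty(az.shape + (self.n_channels,))
        right = np.empty_like(left)
        for i in np.ndindex(az.shape):
            src = SoundSource(az[i], el[i], level=lv[i], duration=self.duration_ms)
            wave = self.model.render(src, HeadPose(), rng)
            levels = fb.band_levels(wave, self.model.sample_rate, self.n_channels)
            left[i], right[i] = levels[0], levels[1]
        if np.ndim(azimuth) == 0:
            return left[0], right[0]
        return left, right

    # ------------------------------------------------------------------
    def observe(self, azimuth, elevation=0.0, level=None, rng=None) -> np.ndarray:
        """Student input vector(s): concatenated (Lη, Rη), shape (..., 48)."""
        left, right = self.magnitudes(azimuth, elevation, level, rng)
        return np.concatenate([left, right], axis=-1)

    def monaural(self, azimuth, elevation=0.0, level=None, rng=None,
                 side: str = "right"):
        """Across-band mean magnitude of one ear (monaural circuit input)."""
        left, right = self.magnitudes(azimuth, elevation, level, rng)
        mags = left if side == "left" else right
        return np.asarray(mags).mean(axis=-1)

    def with_disruption(self, spec: DisruptionSpec | None) -> "Environment":
        return Environment(model=self.model, level=self.level,
                           level_jitter=self.level_jitter,
                           duration_ms=self.duration_ms, disruption=spec)
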