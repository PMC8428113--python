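"""Dynamic ripple sound synthesis.

Moving ripple sounds are broadband stimuli built from a dense bank of
log-spaced sinusoidal carriers whose joint spectrotemporal envelope drifts at
a *ripple velocity* omega (cycles/s) with a spectral density Omega
(cycles/octave):

    s(g, t) = D0 + D * cos(2*pi*(omega*t + Omega*g) + psi),   g = log2(f / f0)

Each carrier at frequency f is amplitude-modulated by ``s(g, t)`` and carries
an independent random phase so the composite is noise-like.  Such stimuli are
spectrotemporally speech-like but resist verbal/semantic memory strategies,
which makes them a standard probe of purely auditory working memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from ._seeds import child_rng

__all__ = ["RippleParams", "generate_ripple", "carrier_frequencies", "write_wav"]


@dataclass(frozen=True)
class RippleParams:
    """Parameters of a dynamic ripple stimulus.

    velocity
        Ripple velocity omega in cycles/s (temporal drift of the envelope).
    ripple_density
        Omega in cycles/octave (spectral density of the envelope).
    base_intensity
        D0, the DC term of the envelope (a.u.).
    modulation_depth
        D >= 0, depth of the sinusoidal envelope modulation (a.u.).
    phase
        psi, the ripple phase in radians.
    f0, f_max
        Lowest and highest carrier frequency (Hz).
    sinusoids_per_octave
        Carrier density of the log-spaced bank.
    duration
        Stimulus duration in seconds.
    sample_rate
        Output sampling rate (Hz); must satisfy Nyquist for f_max.
    """

    velocity: float = 8.0
    ripple_density: float = 1.0
    base_intensity: float = 1.0
    modulation_depth: float = 0.9
    phase: float = 0.0
    f0: float = 200.0
    f_max: float = 1600.0
    sinusoids_per_octave: int = 20
    duration: float = 1.0
    sample_rate: float = 16000.0

    def validate(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.f_max <= self.f0:
            raise ValueError(f"f_max ({self.f_max}) must exceed f0 ({self.f0})")
        if self.modulation_depth < 0:
            raise ValueError("modulation_depth must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate < 2 * self.f_max:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz aliases carriers up to "
                f"{self.f_max} Hz (need >= {2 * self.f_max} Hz)"
            )


def carrier_frequencies(params: RippleParams) -> np.ndarray:
    """Inclusive log2-spaced carrier grid from f0 to f_max.

    With ``sinusoids_per_octave`` carriers per octave over ``n`` octaves the
    grid has ``n * sinusoids_per_octave + 1`` members (both edges included);
    e.g. 200-1600 Hz at 20/octave gives 61 carriers.
    """
    params.validate()
    n_octaves = np.log2(params.f_max / params.f0)
    n_steps = int(round(n_octaves * params.sinusoids_per_octave))
    k = np.arange(n_steps + 1)
    return params.f0 * 2.0 ** (k / params.sinusoids_per_octave)


def generate_ripple(params: RippleParams, seed: int = 0, normalize: bool = True) -> np.ndarray:
    """Synthesize one ripple waveform.

    ``seed`` controls only the random starting phases of the carriers.  The
    output has ``round(duration * sample_rate)`` samples and is normalized to
    peak |amplitude| <= 1 (unless identically zero or ``normalize=False``).
    """
    params.validate()
    freqs = carrier_frequencies(params)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    rng = child_rng(seed, "ripple-carrier-phases")
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)

    g = np.log2(freqs / params.f0)  # octaves above f0
    # envelope per carrier: (n_carriers, n_samples)
    env = params.base_intensity + params.modulation_depth * np.cos(
        2.0 * np.pi * (params.velocity * t[None, :] + params.ripple_density * g[:, None])
        + params.phase
    )
    carriers = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    wave = np.sum(env * carriers, axis=0)
    if normalize:
        peak = np.max(np.abs(wave))
        if peak > 0:
            wave = wave / peak
    return wave


def write_wav(path, wave: np.ndarray, sample_rate: float, dtype: str = "float32") -> None:
    """Write a waveform as WAV (``float32`` or 16-bit PCM)."""
    if dtype == "float32":
        wavfile.write(path, int(sample_rate), wave.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(wave, -1.0, 1.0) * 32767.0
        wavfile.write(path, int(sample_rate), scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV dtype: {dtype!r}")
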