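"""Audible stimulus synthesis: pure tones, AM noise and the tone-pip masker.

These generators reproduce the sounds of the matching task -- a 1 s pure
tone or sinusoidally amplitude-modulated white noise as the memorandum, and
a 0.5 s stream of random-frequency 50 ms tone pips as the auditory masker.
All randomness is seeded.  Waveforms are float arrays in [-1, 1]; WAV export
quantises to 16-bit PCM with peak normalisation to -1 dBFS.
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np

__all__ = [
    "synthesize_tone",
    "synthesize_am_noise",
    "synthesize_masker",
    "am_envelope",
    "write_wav",
]

DEFAULT_SAMPLE_RATE = 44_100


def _n_samples(duration_s: float, sample_rate_hz: int) -> int:
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    return int(round(duration_s * sample_rate_hz))


def synthesize_tone(
    freq_hz: float, duration_s: float = 1.0, sample_rate_hz: int = DEFAULT_SAMPLE_RATE
) -> np.ndarray:
    """Unit-peak sine at ``freq_hz``; rejects frequencies at/above Nyquist."""
    if not (0 < freq_hz < sample_rate_hz / 2):
        raise ValueError(
            f"freq_hz must be in (0, Nyquist={sample_rate_hz / 2}); got {freq_hz}"
        )
    n = _n_samples(duration_s, sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    return np.sin(2 * np.pi * freq_hz * t)


def am_envelope(
    rate_hz: float, depth: float, duration_s: float, sample_rate_hz: int = DEFAULT_SAMPLE_RATE
) -> np.ndarray:
    """Sinusoidal amplitude envelope: 1 - depth/2 + (depth/2) sin(2 pi f t).

    At 100% depth the envelope spans [0, 1]; at 0% it is constant 1.
    """
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"depth must be in [0, 1]; got {depth}")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n = _n_samples(duration_s, sample_rate_hz)
    t = np.arange(n) / sample_rate_hz
    return 1.0 - depth / 2.0 + (depth / 2.0) * np.sin(2 * np.pi * rate_hz * t)


def synthesize_am_noise(
    rate_hz: float,
    depth: float = 1.0,
    duration_s: float = 1.0,
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> np.ndarray:
    """White noise multiplied by the sinusoidal envelope; seeded noise."""
    env = am_envelope(rate_hz, depth, duration_s, sample_rate_hz)
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-1.0, 1.0, env.size)
    return noise * env


def synthesize_masker(
    duration_s: float = 0.5,
    pip_ms: float = 50.0,
    freq_range: tuple[float, float] = (440.0, 880.0),
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    return_freqs: bool = False,
):
    """Concatenated random-frequency tone pips (the auditory masker).

    Pips are contiguous, unramped and non-overlapping; if ``pip_ms`` does not
    divide ``duration_s`` cleanly the final pip is truncated.  With
    ``return_freqs=True`` also returns the drawn pip frequencies.
    """
    if duration_s <= 0 or pip_ms <= 0:
        raise ValueError("duration_s and pip_ms must be positive")
    lo, hi = freq_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid freq_range {freq_range}")
    pip_s = pip_ms / 1000.0
    n_total = _n_samples(duration_s, sample_rate_hz)
    n_pip = _n_samples(pip_s, sample_rate_hz)
    n_pips = int(np.ceil(n_total / n_pip))

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, n_pips)
    pieces = []
    for f in freqs:
        t = np.arange(n_pip) / sample_rate_hz
        pieces.append(np.sin(2 * np.pi * f * t))
    wave_out = np.concatenate(pieces)[:n_total]
    if return_freqs:
        return wave_out, freqs
    return wave_out


def write_wav(
    path: str | Path, samples: np.ndarray, sample_rate_hz: int = DEFAULT_SAMPLE_RATE
) -> None:
    """Write mono 16-bit PCM RIFF WAV, peak-normalised to -1 dBFS."""
    samples = np.asarray(samples, dtype=np.float64)
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak * 10 ** (-1.0 / 20.0)
    pcm = np.clip(np.round(samples * 32767.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(sample_rate_hz)
        wf.writeframes(pcm.tobytes())
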