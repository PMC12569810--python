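"""Synthetic evoked waveforms: cochlear-microphonic + summating-potential traces
and tone-burst epoch sets for input–output functions.

A sound-evoked cochlear potential is modelled as an AC component at the
stimulus frequency (the cochlear microphonic, CM) superimposed on a sustained
DC deviation (the summating potential, SP), plus Gaussian instrumentation
noise.  Epoch sets emulate the audiometry protocol: 10-ms tone bursts with
1-ms cosine rise/fall, presented at descending levels (85…25 dB SPL), each
repeated and averaged offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cochleametrics.evoked import EpochSet
from cochleametrics.utils import rng_from

__all__ = ["synth_evoked_waveform", "synth_epoch_set", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = (85.0, 75.0, 65.0, 55.0, 45.0, 35.0, 25.0)  # dB SPL, as presented


def synth_evoked_waveform(
    frequency: float,
    ac_amplitude: float,
    dc_offset: float,
    noise_sd: float,
    duration: float,
    rate: float,
    seed: int = 0,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Steady-state evoked waveform: dc + ac*sin(2*pi*f*t + phase) + noise.

    Returns ``(t, waveform_uV, ground_truth)``.  Raises if the sampling rate
    would alias the stimulus frequency.
    """
    if rate <= 2 * frequency:
        raise ValueError("sampling rate must exceed twice the stimulus frequency")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = rng_from(seed, "waveform")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w = dc_offset + ac_amplitude * np.sin(2 * np.pi * frequency * t + phase)
    if noise_sd > 0:
        w = w + rng.normal(0, noise_sd, n)
    truth = {
        "frequency": frequency,
        "ac_amplitude": ac_amplitude,
        "dc_offset": dc_offset,
        "phase": phase,
        "noise_sd": noise_sd,
        "rate": rate,
    }
    return t, w, truth


def _burst_envelope(t: np.ndarray, onset: float, dur: float, ramp: float) -> np.ndarray:
    """Gated envelope with cosine-squared rise/fall ramps."""
    env = np.zeros_like(t)
    on = (t >= onset) & (t < onset + dur)
    env[on] = 1.0
    rise = (t >= onset) & (t < onset + ramp)
    env[rise] = np.sin(0.5 * np.pi * (t[rise] - onset) / ramp) ** 2
    fall = (t >= onset + dur - ramp) & (t < onset + dur)
    env[fall] = np.sin(0.5 * np.pi * (onset + dur - t[fall]) / ramp) ** 2
    return env


def synth_epoch_set(
    frequency: float = 2000.0,
    level: float = 85.0,
    amplitude_at_85: float = 10.0,  # uV response amplitude at 85 dB SPL
    growth_db_per_db: float = 1.0,
    dc_fraction: float = 0.0,
    noise_sd: float = 2.0,
    n_epochs: int = 200,
    rate: float = 100_000.0,
    burst_duration: float = 0.010,
    rise_fall: float = 0.001,
    pre_stimulus: float = 0.005,
    post_stimulus: float = 0.005,
    seed: int = 0,
) -> tuple[EpochSet, dict]:
    """Repetitions x samples tone-burst response epochs at one level.

    Response amplitude scales as ``amplitude_at_85 * 10**(growth*(level-85)/20)``
    so input–output functions have a known, monotone shape with level.
    """
    if rate <= 2 * frequency:
        raise ValueError("sampling rate must exceed twice the stimulus frequency")
    rng = rng_from(seed, "epochs", str(level))
    amp = amplitude_at_85 * 10 ** (growth_db_per_db * (level - 85.0) / 20.0)
    n = int(round((pre_stimulus + burst_duration + post_stimulus) * rate))
    t = np.arange(n) / rate
    env = _burst_envelope(t, pre_stimulus, burst_duration, rise_fall)
    clean = env * (amp * np.sin(2 * np.pi * frequency * (t - pre_stimulus)) + dc_fraction * amp)
    epochs = clean[None, :] + rng.normal(0, noise_sd, (n_epochs, n))
    es = EpochSet(
        epochs=epochs,
        rate=rate,
        stimulus_frequency=frequency,
        level=level,
        burst_duration=burst_duration,
        rise_fall=rise_fall,
        pre_stimulus=pre_stimulus,
    )
    truth = {
        "response_amplitude": amp,
        "dc": dc_fraction * amp,
        "noise_sd": noise_sd,
        "level": level,
        "frequency": frequency,
    }
    return es, truth
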