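"""Auditory evoked potential and emission analysis.

Covers the audiometry/electrophysiology signal chain of the study:

* epoch preprocessing — zero-phase band-pass (300–3000 Hz passband by default)
  and averaging of 100–500 tone-burst repetitions;
* input–output functions over descending levels (85…25 dB SPL) and threshold
  estimation (lowest level whose response reaches a criterion, interpolated);
* cochlear microphonic (CM): Fourier amplitude and phase at the stimulus
  frequency, phase referenced to the loudspeaker drive voltage;
* summating potential (SP): sustained baseline deviation during the stimulus,
  signed, with its absolute value for group comparisons;
* tuning curves over 60–820 Hz with best-frequency extraction;
* DPOAE components: amplitudes at f1, f2 and the cubic distortion product
  2·f1−f2 for primaries with f2/f1 = 1.2.

All Fourier analysis trims the window to whole stimulus cycles (rectangular
window thereafter), so amplitudes are leakage-free for periodic inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EpochSet",
    "ToneResponse",
    "InputOutputFunction",
    "preprocess_epochs",
    "io_function_and_threshold",
    "cm_component",
    "summating_potential",
    "tuning_curve",
    "dpoae_extract",
    "abr_peak_latency",
]


@dataclass
class EpochSet:
    epochs: np.ndarray  # (repetitions, samples)
    rate: float  # Hz
    stimulus_frequency: float  # Hz
    level: float  # dB SPL
    burst_duration: float = 0.010  # s
    rise_fall: float = 0.001  # s
    pre_stimulus: float = 0.0  # s before burst onset

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class ToneResponse:
    frequency: float
    level: float
    cm_amplitude: float  # uV
    cm_phase: float  # rad, relative to drive reference
    sp: float = np.nan  # uV, signed
    excluded: bool = False  # below the peak-response exclusion criterion

    @property
    def sp_abs(self) -> float:
        return abs(self.sp)


@dataclass
class InputOutputFunction:
    levels: np.ndarray  # dB SPL, descending as presented
    response_amplitudes: np.ndarray  # uV
    threshold: float  # dB SPL (nan when not reached)
    threshold_reached: bool
    criterion: float  # uV


def preprocess_epochs(
    epoch_set: EpochSet,
    band: tuple[float, float] = (300.0, 3000.0),
    n_average: int | None = None,
    gain: float = 1.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass then average of the first ``n_average`` epochs.

    Filtering is forward–backward (4th-order Butterworth run twice), so the CM
    phase is never biased by the filter.  ``gain`` removes the recording
    amplifier gain so outputs are in physical microvolts.
    """
    lo, hi = band
    nyq = epoch_set.rate / 2
    if not (0 < lo < hi < nyq):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    n_rep = epoch_set.epochs.shape[0]
    if n_average is None:
        n_average = n_rep
    if n_average > n_rep:
        raise ValueError(f"n_average={n_average} exceeds available repetitions ({n_rep})")
    sos = butter(order, [lo, hi], btype="band", fs=epoch_set.rate, output="sos")
    filtered = sosfiltfilt(sos, epoch_set.epochs[:n_average], axis=1)
    return filtered.mean(axis=0) / gain


def io_function_and_threshold(
    levels: np.ndarray,
    amplitudes: np.ndarray,
    criterion: float,
) -> InputOutputFunction:
    """Threshold = lowest level whose amplitude reaches ``criterion``.

    Scanning from the lowest tested level upward, the first level whose
    response amplitude is >= criterion defines the threshold; when the level
    below it responds under criterion, the threshold is linearly interpolated
    between the bracketing levels.  If no level qualifies, the not-reached flag
    is set (threshold = nan).
    """
    levels = np.asarray(levels, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if levels.size == 0:
        raise ValueError("empty response list")
    if levels.size != amplitudes.size:
        raise ValueError("levels and amplitudes must match")
    if levels.size < 2:
        raise ValueError("need at least 2 levels for an input-output function")
    order = np.argsort(levels)
    lv, amp = levels[order], amplitudes[order]
    reached = amp >= criterion
    if not reached.any():
        thr, ok = np.nan, False
    else:
        i = int(np.argmax(reached))
        if i == 0:
            thr = lv[0]
        else:
            a0, a1 = amp[i - 1], amp[i]
            thr = lv[i] if a1 == a0 else lv[i - 1] + (criterion - a0) * (lv[i] - lv[i - 1]) / (a1 - a0)
            thr = min(max(thr, lv[i - 1]), lv[i])
        ok = True
    desc = np.argsort(-levels)
    return InputOutputFunction(
        levels=levels[desc],
        response_amplitudes=amplitudes[desc],
        threshold=float(thr),
        threshold_reached=ok,
        criterion=criterion,
    )


def _whole_cycle_slice(n: int, rate: float, f0: float) -> int:
    """Largest sample count <= n spanning an integer number of f0 cycles."""
    n_cycles = math.floor(n * f0 / rate)
    if n_cycles < 1:
        raise ValueError("window shorter than one stimulus cycle: f0 not resolvable")
    return int(round(n_cycles * rate / f0))


def _fourier_component(w: np.ndarray, rate: float, f0: float) -> complex:
    n = w.size
    t = np.arange(n) / rate
    return 2.0 / n * np.sum(w * np.exp(-2j * np.pi * f0 * t))


def cm_component(
    waveform: np.ndarray,
    rate: float,
    f0: float,
    drive_reference: np.ndarray | None = None,
    exclusion_criterion: float | None = None,
) -> tuple[float, float]:
    """Amplitude (uV) and phase (rad) of the f0 Fourier component.

    The analysis window is trimmed to whole f0 cycles.  When a loudspeaker
    drive-voltage reference is given, the returned phase is the CM phase minus
    the drive phase at f0.  ``exclusion_criterion`` (uV) reproduces the rule of
    excluding low-amplitude preparations from phase analysis: below it, the
    phase is returned as nan.
    """
    w = np.asarray(waveform, dtype=float)
    n_use = _whole_cycle_slice(w.size, rate, f0)
    c = _fourier_component(w[:n_use], rate, f0)
    amplitude = float(abs(c))
    # component written as a*sin(2*pi*f*t + phi): phi = angle(c) + pi/2
    phase = float(np.angle(c) + np.pi / 2)
    if drive_reference is not None:
        ref = np.asarray(drive_reference, dtype=float)
        n_ref = _whole_cycle_slice(ref.size, rate, f0)
        phase -= float(np.angle(_fourier_component(ref[:n_ref], rate, f0)) + np.pi / 2)
    phase = float((phase + np.pi) % (2 * np.pi) - np.pi)
    if exclusion_criterion is not None and amplitude < exclusion_criterion:
        phase = np.nan
    return amplitude, phase


def summating_potential(
    waveform: np.ndarray,
    rate: float,
    f0: float,
    stimulus_on: tuple[float, float],
    baseline: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Signed SP (uV) and its absolute value.

    SP = mean of the waveform over whole stimulus cycles inside the
    stimulus-on window, minus the pre-stimulus baseline mean.  Positive values
    denote a depolarising deviation of the recorded potential; group
    comparisons use the absolute value because the SP's sign depends on
    stimulus level and frequency.
    """
    w = np.asarray(waveform, dtype=float)
    on0, on1 = (int(round(s * rate)) for s in stimulus_on)
    if not (0 <= on0 < on1 <= w.size):
        raise ValueError("stimulus-on window outside the waveform")
    seg = w[on0:on1]
    n_use = _whole_cycle_slice(seg.size, rate, f0)
    sp = float(seg[:n_use].mean())
    if baseline is not None:
        b0, b1 = (int(round(s * rate)) for s in baseline)
        if not (0 <= b0 < b1 <= w.size):
            raise ValueError("baseline window outside the waveform")
        sp -= float(w[b0:b1].mean())
    elif on0 > 0:
        sp -= float(w[:on0].mean())
    else:
        raise ValueError("no pre-stimulus baseline segment available")
    return sp, abs(sp)


def tuning_curve(responses: list[ToneResponse]) -> tuple[np.ndarray, float, bool]:
    """Amplitude-vs-frequency curve and best frequency.

    Returns ``(curve, best_frequency, tie)`` where curve is an (n, 2) array of
    (frequency, amplitude) sorted by frequency.  Ties for the maximum resolve
    to the lowest frequency and are flagged.
    """
    if len(responses) < 2:
        raise ValueError("need responses at >= 2 frequencies")
    arr = np.array(sorted((r.frequency, r.cm_amplitude) for r in responses))
    amax = arr[:, 1].max()
    at_max = np.isclose(arr[:, 1], amax)
    best = float(arr[at_max, 0].min())
    return arr, best, bool(at_max.sum() > 1)


def dpoae_extract(
    mic_waveform: np.ndarray,
    rate: float,
    f1: float,
    f2: float,
    ratio_tol: float = 0.02,
    leakage_tol: float = 1e-6,
) -> dict:
    """Amplitudes at f1, f2 and 2*f1−f2 from the ear-canal microphone signal.

    Preconditions: the primary ratio f2/f1 must be 1.2 (within ``ratio_tol``)
    and the analysis window must contain whole cycles of all three components;
    otherwise an error suggests a usable window length.
    """
    if abs(f2 / f1 - 1.2) > ratio_tol:
        raise ValueError(f"primary ratio f2/f1 = {f2 / f1:.4f}; expected 1.2")
    w = np.asarray(mic_waveform, dtype=float)
    fdp = 2 * f1 - f2
    if fdp <= 0:
        raise ValueError("distortion product 2*f1-f2 is not resolvable")
    # common fundamental via the rational ratio: f2/f1 = 6/5 => f_base = f1/5
    f_base = f1 / 5.0
    n_base = rate / f_base
    n_use = int(math.floor(w.size / n_base) * round(n_base))
    if n_use < 1 or abs(n_base - round(n_base)) > 1e-9 * n_base:
        raise ValueError(
            "window does not hold whole cycles of both primaries; use a length "
            f"that is a multiple of {n_base:.6g} samples (= 1/{f_base:.6g} Hz)"
        )
    seg = w[:n_use]
    out = {}
    for name, f in (("f1", f1), ("f2", f2), ("2f1-f2", fdp)):
        cycles = n_use * f / rate
        if abs(cycles - round(cycles)) > leakage_tol * max(cycles, 1.0):
            raise ValueError(
                f"spectral leakage at {name}: {cycles:.6f} cycles in window; "
                f"choose a window with whole cycles of {f:g} Hz"
            )
        out[name] = float(abs(_fourier_component(seg, rate, f)))
    out["n_samples"] = n_use
    return out


def abr_peak_latency(waveform: np.ndarray, rate: float, onset: float = 0.0) -> float:
    """Latency (s) of the largest peak after stimulus onset.

    Convention: the global absolute maximum after ``onset``; no wave I–V
    labelling is attempted.
    """
    w = np.asarray(waveform, dtype=float)
    i0 = int(round(onset * rate))
    if i0 >= w.size:
        raise ValueError("onset beyond waveform end")
    i = int(np.argmax(np.abs(w[i0:]))) + i0
    return i / rate - onset
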