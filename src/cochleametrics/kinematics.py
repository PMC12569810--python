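"""Stereocilia kinematics from phase-stamped confocal pixel streams.

The acquisition stamps every pixel with the acoustic-stimulus phase at which it
was scanned.  Sorting pixels into phase bins reconstructs one image per phase
of the stimulus cycle; per-pixel optical flow between the cycle-mean image and
each phase image then yields subpixel 2-D motion trajectories.  Stereocilia
deflection — the stimulus that gates mechanotransduction channels — is the
bin-wise vector difference between the bundle-tip and bundle-base trajectories,
each averaged over a 5 x 5 pixel region to improve signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.registration import optical_flow_ilk

__all__ = [
    "PhaseStampedStream",
    "MotionTrajectory",
    "DeflectionResult",
    "bin_phases",
    "lowpass_sequence",
    "estimate_motion",
    "region_average",
    "compute_deflection",
    "noise_floor_from_baseline",
]


@dataclass
class PhaseStampedStream:
    x: np.ndarray  # pixel column per record
    y: np.ndarray  # pixel row per record
    intensity: np.ndarray
    phase: np.ndarray  # rad, in [0, 2*pi)
    frame_shape: tuple[int, int]
    pixel_size: float  # nm / pixel
    stimulus_frequency: float  # Hz
    level: float | None = None  # dB SPL

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        n = self.x.size
        if not (self.y.size == self.intensity.size == self.phase.size == n):
            raise ValueError("record arrays must have equal length")
        if np.any(self.phase < 0) or np.any(self.phase >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2*pi)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class MotionTrajectory:
    phase_bins: np.ndarray  # bin-centre phases, rad
    displacement: np.ndarray  # (n_bins, 2) nm, (dx, dy), zero mean over the cycle
    anchor: tuple[float, float] | None = None  # (x, y) px
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.phase_bins = np.asarray(self.phase_bins, dtype=float)
        if self.displacement.shape != (self.phase_bins.size, 2):
            raise ValueError("displacement must be (n_bins, 2)")

    @property
    def amplitude(self) -> float:
        """Peak distance from the cycle mean, nm."""
        return float(np.linalg.norm(self.displacement, axis=1).max())

    @property
    def direction(self) -> float:
        """Principal-axis angle of the trajectory, rad."""
        d = self.displacement - self.displacement.mean(axis=0)
        _, vecs = np.linalg.eigh(d.T @ d)
        major = vecs[:, -1]
        return float(np.arctan2(major[1], major[0]))


@dataclass
class DeflectionResult:
    phase_bins: np.ndarray
    deflection_trajectory: np.ndarray  # (n_bins, 2) nm, tip - base
    deflection_amplitude: float  # nm
    normalised_deflection: float
    noise_floor: float  # nm
    normalisation: str = "base_amplitude"


def bin_phases(stream: PhaseStampedStream, n_bins: int = 16) -> np.ndarray:
    """Reconstruct one frame per phase bin: (n_bins, H, W) mean intensities.

    Bins are half-open ``[2*pi*b/n, 2*pi*(b+1)/n)``.  Every pixel must be
    sampled at least once in every bin; offending pixels are listed otherwise.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    H, W = stream.frame_shape
    b = np.floor(stream.phase * n_bins / (2 * np.pi)).astype(int)
    b = np.clip(b, 0, n_bins - 1)
    flat = (b * H + stream.y) * W + stream.x
    sums = np.bincount(flat, weights=stream.intensity, minlength=n_bins * H * W)
    counts = np.bincount(flat, minlength=n_bins * H * W)
    if np.any(counts == 0):
        missing = np.transpose(np.nonzero(counts.reshape(n_bins, H, W) == 0))
        head = [f"(bin={bi}, y={yi}, x={xi})" for bi, yi, xi in missing[:10]]
        raise ValueError(
            f"{len(missing)} pixel/bin combinations have no samples, e.g. {', '.join(head)}"
        )
    return (sums / counts).reshape(n_bins, H, W)


def lowpass_sequence(frames: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Spatial Gaussian smoothing per frame (sigma in pixels)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 3:
        raise ValueError("need a (n_frames >= 3, H, W) sequence")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return frames.copy()
    return gaussian_filter(frames, sigma=(0, sigma, sigma))


def estimate_motion(
    frames: np.ndarray,
    pixel_size: float,
    radius: int = 7,
    num_warp: int = 10,
    confidence_quantile: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel subpixel motion for each phase bin.

    Returns ``(phase_bins, displacement, low_confidence)`` where displacement is
    ``(n_bins, H, W, 2)`` in nm (dx, dy), zero-mean over the cycle per pixel,
    and ``low_confidence`` is a (H, W) bool mask of texture-free pixels whose
    flow is unreliable (flagged, not fabricated).

    Motion is estimated with an iterative, warping Lucas–Kanade scheme
    (skimage's ILK optical flow) between the cycle-mean image and each phase
    frame, which resolves displacements well below one pixel.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 8:
        raise ValueError("need at least 8 phase-bin frames")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    n_bins, H, W = frames.shape
    reference = frames.mean(axis=0)
    if np.ptp(reference) == 0:
        raise ValueError("texture-free sequence: motion is not estimable")

    disp = np.empty((n_bins, H, W, 2))
    for b in range(n_bins):
        flow = optical_flow_ilk(reference, frames[b], radius=radius, num_warp=num_warp,
                                gaussian=False, prefilter=True)
        disp[b, ..., 0] = flow[1]  # columns -> dx
        disp[b, ..., 1] = flow[0]  # rows -> dy
    disp -= disp.mean(axis=0, keepdims=True)  # zero mean over the cycle
    disp *= pixel_size

    # structure-tensor texture score; flat regions get flagged
    gy, gx = np.gradient(reference)
    score = gaussian_filter(gx * gx, 2) + gaussian_filter(gy * gy, 2)
    thresh = max(np.quantile(score, confidence_quantile), 1e-12 * max(score.max(), 1.0))
    low_confidence = score <= thresh

    centers = (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    return centers, disp, low_confidence


def region_average(
    phase_bins: np.ndarray,
    displacement_field: np.ndarray,
    anchor: tuple[float, float],
    half_width: int = 2,
) -> MotionTrajectory:
    """Bin-wise mean trajectory over the (2h+1) x (2h+1) region centred on ``anchor``.

    ``anchor`` is (x, y) in pixels; the default half-width of 2 gives the 5 x 5
    neighbourhood used to improve signal-to-noise.
    """
    n_bins, H, W, _ = displacement_field.shape
    ax, ay = int(round(anchor[0])), int(round(anchor[1]))
    if not (half_width <= ax < W - half_width and half_width <= ay < H - half_width):
        raise ValueError("anchor too close to the frame border for the averaging region")
    region = displacement_field[:, ay - half_width : ay + half_width + 1,
                                ax - half_width : ax + half_width + 1, :]
    traj = region.mean(axis=(1, 2))
    traj = traj - traj.mean(axis=0, keepdims=True)
    return MotionTrajectory(phase_bins=phase_bins, displacement=traj, anchor=(float(ax), float(ay)))


def compute_deflection(
    tip: MotionTrajectory,
    base: MotionTrajectory,
    reference_amplitude: float | None = None,
    noise_floor: float = 0.0,
) -> DeflectionResult:
    """Stereocilia deflection: bin-wise tip-minus-base trajectory difference.

    ``normalised_deflection`` divides the deflection amplitude by
    ``reference_amplitude`` (default: the base-trajectory amplitude), making
    preparations with different absolute motion comparable.
    """
    if tip.phase_bins.shape != base.phase_bins.shape or not np.allclose(
        tip.phase_bins, base.phase_bins
    ):
        raise ValueError("tip and base trajectories must share phase bins")
    traj = tip.displacement - base.displacement
    amplitude = float(np.linalg.norm(traj, axis=1).max())
    norm_kind = "base_amplitude" if reference_amplitude is None else "explicit"
    ref = base.amplitude if reference_amplitude is None else reference_amplitude
    return DeflectionResult(
        phase_bins=tip.phase_bins.copy(),
        deflection_trajectory=traj,
        deflection_amplitude=amplitude,
        normalised_deflection=amplitude / ref if ref > 0 else np.nan,
        noise_floor=noise_floor,
        normalisation=norm_kind,
    )


def noise_floor_from_baseline(
    baseline_frames: np.ndarray,
    pixel_size: float,
    anchor: tuple[float, float],
    **kwargs,
) -> float:
    """Apparent motion amplitude (nm) of a stimulus-free baseline image set.

    The experiment acquires two baseline image sets before stimulation; any
    motion recovered from them is measurement noise, and its amplitude at the
    analysis anchor serves as the noise floor for deflection results.
    """
    phase_bins, disp, _ = estimate_motion(baseline_frames, pixel_size, **kwargs)
    traj = region_average(phase_bins, disp, anchor)
    return traj.amplitude
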