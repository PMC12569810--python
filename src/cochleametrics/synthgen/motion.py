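"""Phase-stamped image streams of a sound-driven stereocilia bundle.

Acquisition in the experiment stamps every confocal pixel with the phase of
the acoustic stimulus at the instant it was scanned, so motion is reconstructed
by sorting pixels into phase bins rather than by frame-rate imaging.  The
phantom emulates this: two textured patches (bundle base and bundle tip)
translate along independent elliptic/linear trajectories as a function of
stimulus phase, and the generator emits long-format pixel records
``(x, y, intensity, phase)`` plus the ground-truth trajectories.

Patch intensity is an analytic sum of Gaussians, so subpixel translation is
exact — no interpolation artefacts enter the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from cochleametrics.kinematics import PhaseStampedStream
from cochleametrics.utils import rng_from

__all__ = ["TrajectorySpec", "MotionPhantomConfig", "render_motion_sequence"]


@dataclass(frozen=True)
class TrajectorySpec:
    """Sinusoidal 2-D path: displacement(phi) = amplitude * sin(phi + phase0) * (cos d, sin d).

    ``amplitude`` is in nm (peak distance from the cycle mean), ``direction``
    in radians (0 = +x, pi/2 = +y i.e. downward in image coordinates).
    A nonzero ``ellipticity`` adds a quadrature component of that relative
    amplitude perpendicular to the main axis, producing elliptic paths.
    """

    amplitude: float  # nm
    direction: float  # rad
    phase0: float = 0.0
    ellipticity: float = 0.0

    def displacement(self, phases: np.ndarray) -> np.ndarray:
        """(n, 2) displacement in nm at the given stimulus phases (x, y)."""
        phases = np.asarray(phases, dtype=float)
        main = self.amplitude * np.sin(phases + self.phase0)
        u = np.array([np.cos(self.direction), np.sin(self.direction)])
        disp = main[:, None] * u[None, :]
        if self.ellipticity:
            perp = np.array([-u[1], u[0]])
            disp = disp + (self.ellipticity * self.amplitude * np.cos(phases + self.phase0))[:, None] * perp[None, :]
        return disp


@dataclass(frozen=True)
class MotionPhantomConfig:
    frame_shape: tuple[int, int] = (96, 96)  # (rows, cols)
    pixel_size: float = 40.0  # nm / pixel
    stimulus_frequency: float = 200.0  # Hz
    n_phase_bins: int = 16
    base_trajectory: TrajectorySpec = field(
        default_factory=lambda: TrajectorySpec(amplitude=65.0, direction=np.deg2rad(60.0))
    )
    tip_trajectory: TrajectorySpec = field(
        default_factory=lambda: TrajectorySpec(amplitude=62.0, direction=np.pi / 2)
    )
    base_anchor: tuple[float, float] = (48.0, 62.0)  # (x, y) px
    tip_anchor: tuple[float, float] = (48.0, 34.0)
    noise_sd: float = 8.0
    samples_per_bin: int = 2
    n_texture_blobs: int = 6
    blob_sigma: float = 2.6  # px
    patch_radius: float = 6.0  # px
    level: float = 80.0  # dB SPL, carried as metadata
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phase_bins < 8:
            raise ValueError("need at least 8 phase bins")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _patch_blobs(anchor, cfg: MotionPhantomConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    offs = rng.uniform(-cfg.patch_radius, cfg.patch_radius, size=(cfg.n_texture_blobs, 2))
    centers = np.asarray(anchor, float)[None, :] + offs
    amps = rng.uniform(500.0, 1100.0, size=cfg.n_texture_blobs)
    return centers, amps


def _render_frame(xx, yy, blobs, disp_px, sigma) -> np.ndarray:
    img = np.zeros_like(xx, dtype=float)
    for (centers, amps), d in zip(blobs, disp_px):
        for (cx, cy), a in zip(centers, amps):
            img += a * np.exp(-(((xx - cx - d[0]) ** 2) + (yy - cy - d[1]) ** 2) / (2 * sigma**2))
    return img


def render_motion_sequence(config: MotionPhantomConfig) -> tuple[PhaseStampedStream, dict]:
    """Emit the phase-stamped pixel stream and ground-truth trajectories.

    Records are rendered at phase-bin centres (``samples_per_bin`` noisy
    samples per pixel per bin), matching the per-pixel phase assignment of the
    acquisition.  Ground truth holds the programmed base/tip displacement at
    each bin centre (nm) and the resulting deflection trajectory/amplitude.
    """
    H, W = config.frame_shape
    rng = rng_from(config.seed, "phantom", "motion")
    n = config.n_phase_bins
    centers = (np.arange(n) + 0.5) * 2 * np.pi / n

    base_disp = config.base_trajectory.displacement(centers)  # nm
    tip_disp = config.tip_trajectory.displacement(centers)
    for name, disp, anchor in (("base", base_disp, config.base_anchor),
                               ("tip", tip_disp, config.tip_anchor)):
        d_px = np.abs(disp).max() / config.pixel_size
        ax, ay = anchor
        margin = config.patch_radius + 3 * config.blob_sigma
        if (ax - margin - d_px < 0 or ax + margin + d_px > W - 1
                or ay - margin - d_px < 0 or ay + margin + d_px > H - 1):
            raise ValueError(f"{name} trajectory amplitude exceeds the frame")

    base_blobs = _patch_blobs(config.base_anchor, config, rng)
    tip_blobs = _patch_blobs(config.tip_anchor, config, rng)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    records = []
    for b in range(n):
        d_px = np.stack([base_disp[b], tip_disp[b]]) / config.pixel_size
        clean = 50.0 + _render_frame(xx, yy, [base_blobs, tip_blobs], d_px, config.blob_sigma)
        for _ in range(config.samples_per_bin):
            noisy = clean + rng.normal(0, config.noise_sd, clean.shape)
            records.append(
                np.column_stack([
                    xx.ravel(), yy.ravel(), noisy.ravel(),
                    np.full(xx.size, centers[b]),
                ])
            )
    rec = np.concatenate(records)
    stream = PhaseStampedStream(
        x=rec[:, 0].astype(int),
        y=rec[:, 1].astype(int),
        intensity=rec[:, 2],
        phase=rec[:, 3],
        frame_shape=(H, W),
        pixel_size=config.pixel_size,
        stimulus_frequency=config.stimulus_frequency,
        level=config.level,
    )
    defl = tip_disp - base_disp
    truth = {
        "phase_bin_centers": centers,
        "base_displacement_nm": base_disp,
        "tip_displacement_nm": tip_disp,
        "deflection_nm": defl,
        "base_amplitude_nm": float(np.linalg.norm(base_disp, axis=1).max()),
        "tip_amplitude_nm": float(np.linalg.norm(tip_disp, axis=1).max()),
        "deflection_amplitude_nm": float(np.linalg.norm(defl, axis=1).max()),
        "base_anchor": config.base_anchor,
        "tip_anchor": config.tip_anchor,
        "config": asdict(config),
    }
    return stream, truth
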