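"""Section-image phantoms: two labelled structures with a controllable gap.

The phantom emulates a mid-modiolar section (or a live confocal section): an
organ-of-Corti block whose top edge is the reticular lamina, and a tectorial
membrane block whose lower boundary sits ``gap_true`` micrometres above the
lamina (``gap_true = 0`` produces touching structures).  Rectangular ROIs keep
every configured quantity exact by construction: areas are width x height, the
minimal TM-to-lamina distance is the vertical offset, and the organ width is
the lamina span.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import shapely

from cochleametrics.morphometry import SectionGeometry
from cochleametrics.utils import rng_from

__all__ = ["SectionPhantomConfig", "render_section_phantom", "synth_detachment_cohort"]


@dataclass(frozen=True)
class SectionPhantomConfig:
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size: float = 0.5  # um / pixel
    gap_true: float = 6.0  # um
    tm_area_true: float = 2000.0  # um^2
    ooc_area_true: float = 5000.0  # um^2
    ooc_width_true: float = 120.0  # um
    noise_sd: float = 30.0  # intensity units
    tm_intensity: float = 1500.0
    ooc_intensity: float = 3000.0
    background: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_true < 0:
            raise ValueError("gap_true must be >= 0")
        if self.tm_area_true <= 0 or self.ooc_area_true <= 0:
            raise ValueError("areas must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def _rect(x0: float, y0: float, w: float, h: float) -> np.ndarray:
    """Closed rectangle polygon (x, y) vertices, y increasing downward."""
    return np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]], float)


def render_section_phantom(
    config: SectionPhantomConfig,
) -> tuple[np.ndarray, SectionGeometry, dict]:
    """Render the phantom image and its ROIs.

    Returns ``(image_uint16, geometry, ground_truth)``.  The geometry carries
    the TM polygon, OoC polygon, reticular-lamina polyline and width line in
    pixel coordinates (x = column, y = row), exactly as an annotator would
    supply them.
    """
    ps = config.pixel_size
    H, W = config.image_shape
    rng = rng_from(config.seed, "phantom", "section")

    ooc_w = config.ooc_width_true / ps
    ooc_h = config.ooc_area_true / ps**2 / ooc_w
    tm_w = 0.75 * ooc_w
    tm_h = config.tm_area_true / ps**2 / tm_w
    gap = config.gap_true / ps

    y_surf = 0.58 * H
    x0 = (W - ooc_w) / 2
    ooc = _rect(x0, y_surf, ooc_w, ooc_h)
    # TM bottom edge must sit at exactly y_surf - gap (gap 0 => touching),
    # so build the polygon from the bottom coordinate rather than top + height
    tm_x0 = x0 + (ooc_w - tm_w) / 2
    tm_bottom = y_surf - gap
    tm_top = tm_bottom - tm_h
    tm = np.array([[tm_x0, tm_top], [tm_x0 + tm_w, tm_top],
                   [tm_x0 + tm_w, tm_bottom], [tm_x0, tm_bottom]], float)
    lamina = np.array([[x0, y_surf], [x0 + ooc_w, y_surf]], float)
    width_line = np.array([[x0, y_surf + ooc_h / 2], [x0 + ooc_w, y_surf + ooc_h / 2]], float)

    for poly, name in ((ooc, "organ of Corti"), (tm, "tectorial membrane")):
        if poly[:, 0].min() < 1 or poly[:, 0].max() > W - 1 or poly[:, 1].min() < 1 or poly[:, 1].max() > H - 1:
            raise ValueError(f"{name} does not fit inside the image; enlarge image_shape")

    tm_poly = shapely.Polygon(tm)
    ooc_poly = shapely.Polygon(ooc)
    if config.gap_true > 0 and tm_poly.intersects(ooc_poly):
        raise RuntimeError("internal phantom failure: structures overlap despite gap_true > 0")

    yy, xx = np.mgrid[0:H, 0:W]
    img = np.full((H, W), config.background, dtype=float)
    ooc_mask = shapely.contains_xy(ooc_poly, xx.ravel(), yy.ravel()).reshape(H, W)
    tm_mask = shapely.contains_xy(tm_poly, xx.ravel(), yy.ravel()).reshape(H, W)
    img[ooc_mask] = config.ooc_intensity
    img[tm_mask] = config.tm_intensity
    if config.noise_sd > 0:
        img += rng.normal(0, config.noise_sd, img.shape)
    image = np.clip(img, 0, 65535).astype(np.uint16)

    geometry = SectionGeometry(
        tm_roi=tm,
        ooc_roi=ooc,
        reticular_lamina=lamina,
        width_line=width_line,
        pixel_size=ps,
    )
    truth = {
        "gap_true": config.gap_true,
        "tm_area_true": config.tm_area_true,
        "ooc_area_true": config.ooc_area_true,
        "ooc_width_true": config.ooc_width_true,
        "tm_mask": tm_mask,
        "ooc_mask": ooc_mask,
        "config": asdict(config),
    }
    return image, geometry, truth


def synth_detachment_cohort(
    n_animals: int,
    n_detached: int,
    seed: int = 0,
    gap_range: tuple[float, float] = (2.0, 15.0),
    image_shape: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,
):
    """Per-animal section phantoms for one treatment group.

    ``n_detached`` animals get a measurable TM-to-lamina gap (uniform within
    ``gap_range`` micrometres, the scale seen with high-dose lateral-wall
    block); the rest have a touching tectorial membrane.  Returns the list of
    :class:`~cochleametrics.morphometry.SectionMeasurement` obtained by running
    the morphometry pipeline on each phantom's ROIs.
    """
    from cochleametrics.morphometry import measure_section

    if not (0 <= n_detached <= n_animals):
        raise ValueError("need 0 <= n_detached <= n_animals")
    rng = rng_from(seed, "phantom", "cohort")
    gaps = np.zeros(n_animals)
    gaps[:n_detached] = rng.uniform(*gap_range, size=n_detached)
    rng.shuffle(gaps)
    out = []
    for i, gap in enumerate(gaps):
        cfg = SectionPhantomConfig(
            image_shape=image_shape, pixel_size=pixel_size, gap_true=float(gap),
            tm_area_true=rng.uniform(1500.0, 2500.0),
            ooc_area_true=rng.uniform(4000.0, 6000.0),
            ooc_width_true=rng.uniform(100.0, 140.0),
            noise_sd=20.0, seed=int(rng.integers(2**31)),
        )
        _, geom, _ = render_section_phantom(cfg)
        out.append(measure_section(geom, cochlea_id=f"animal{i:03d}"))
    return out
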