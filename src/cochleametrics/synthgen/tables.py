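"""Grouped molecular-brightness tables with compound-symmetric correlation.

Each animal contributes one brightness value per recording site (three
tectorial-membrane positions and one endolymph position).  Values from the
same animal share a random animal effect, which induces a compound-symmetric
covariance: equal correlation ``rho`` between any two sites of one animal and
zero across animals.  The marginal mean is

    intercept + dose_slope * dose + site_offset[site].

The dose is coded in arbitrary "dose units" (the treatment groups control/low/
high map to 0/1/2 by default); the slope is therefore in brightness units per
dose unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cochleametrics.utils import rng_from

__all__ = ["BrightnessTableConfig", "synth_brightness_table"]

_DEFAULT_SITES = ("TM1", "TM2", "TM3", "EndoL")


@dataclass(frozen=True)
class BrightnessTableConfig:
    n_animals_per_group: int = 25
    dose_levels: tuple[float, ...] = (0.0, 1.0, 2.0)
    sites: tuple[str, ...] = _DEFAULT_SITES
    intercept: float = 800.0  # counts / s / molecule
    dose_slope: float = -61.0  # counts / s / molecule per dose unit
    site_offsets: dict = field(default_factory=dict)
    intra_animal_correlation: float = 0.5
    residual_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        rho = self.intra_animal_correlation
        m = len(self.sites)
        # CS covariance sigma^2[(1-rho)I + rho J] is PD only for rho > -1/(m-1);
        # the random-intercept construction additionally needs rho >= 0.
        if not (0 <= rho < 1):
            raise ValueError("intra_animal_correlation must lie in [0, 1): "
                             "the implied covariance is otherwise not positive definite here")
        if m < 1 or self.n_animals_per_group < 1:
            raise ValueError("need at least one site and one animal per group")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def _group_name(dose: float, doses: tuple[float, ...]) -> str:
    if tuple(doses) == (0.0, 1.0, 2.0):
        return {0.0: "control", 1.0: "low", 2.0: "high"}[dose]
    return f"dose_{dose:g}"


def synth_brightness_table(config: BrightnessTableConfig) -> pd.DataFrame:
    """Tidy table with columns animal, group, dose, site, brightness."""
    rng = rng_from(config.seed, "brightness_table")
    rho, sd = config.intra_animal_correlation, config.residual_sd
    sd_animal = sd * np.sqrt(rho)
    sd_within = sd * np.sqrt(1 - rho)
    rows = []
    animal_id = 0
    for dose in config.dose_levels:
        group = _group_name(dose, config.dose_levels)
        for _ in range(config.n_animals_per_group):
            a = rng.normal(0, sd_animal)
            for site in config.sites:
                mu = config.intercept + config.dose_slope * dose + config.site_offsets.get(site, 0.0)
                rows.append({
                    "animal": f"a{animal_id:04d}",
                    "group": group,
                    "dose": dose,
                    "site": site,
                    "brightness": mu + a + rng.normal(0, sd_within),
                })
            animal_id += 1
    return pd.DataFrame(rows)
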