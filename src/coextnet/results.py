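"""Result containers shared by the simulators and the analytics layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NetworkValidationError

__all__ = ["SurvivalSurface"]


@dataclass(frozen=True)
class SurvivalSurface:
    """Per-plant survival probability as a function of extinction-event index.

    ``survival[i, k]`` is the estimated probability that plant ``i`` is
    extant after ``k`` primary pollinator-removal events settled
    (``k = 0..n_pollinators``; column 0 is all ones).  Community richness
    trajectories (fractions of surviving plants, pollinators and all
    species) are carried alongside, as simulated under the same replicates.
    """

    plant_ids: tuple[str, ...]
    survival: np.ndarray  # (n_plants, n_events + 1)
    frac_plants: np.ndarray  # (n_events + 1,)
    frac_pollinators: np.ndarray
    frac_species: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "survival", surv)
        if surv.ndim != 2 or surv.shape[0] != len(self.plant_ids):
            raise NetworkValidationError("survival matrix shape mismatch")
        if np.any((surv < -1e-12) | (surv > 1 + 1e-12)):
            raise NetworkValidationError("survival probabilities outside [0, 1]")
        if not np.allclose(surv[:, 0], 1.0):
            raise NetworkValidationError("survival at event 0 must be 1")
        if np.any(np.diff(surv, axis=1) > 1e-12):
            raise NetworkValidationError("survival must be non-increasing in events")
        surv.setflags(write=False)

    @property
    def n_events(self) -> int:
        return self.survival.shape[1] - 1

    def trajectory(self, plant: str) -> np.ndarray:
        try:
            i = self.plant_ids.index(plant)
        except ValueError:
            raise KeyError(f"unknown plant {plant!r}") from None
        return self.survival[i]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (plant, event, survival) table."""
        n_ev = self.n_events + 1
        return pd.DataFrame(
            {
                "plant": np.repeat(self.plant_ids, n_ev),
                "event": np.tile(np.arange(n_ev), len(self.plant_ids)),
                "survival": self.survival.ravel(),
            }
        )

    def richness_frame(self) -> pd.DataFrame:
        """Tidy per-event richness decay table (Fig. 2-style curves)."""
        return pd.DataFrame(
            {
                "event": np.arange(self.n_events + 1),
                "frac_species": self.frac_species,
                "frac_plants": self.frac_plants,
                "frac_pollinators": self.frac_pollinators,
            }
        )
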