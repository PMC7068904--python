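"""Analytic planted-optimum response for pipeline testing.

A convex quadratic bowl over the three alignment angles stands in for the
peak-contact-pressure response so the design/analysis pipeline can be
exercised — and its optimum-recovery behaviour measured — independently of
the mechanical solver.  The default bowl places its optimum at 0 deg varus,
1 deg cut slope, 4 deg external rotation with curvature weights ordered
varus > slope > rotation, and a base value of 16.4 MPa, so that a noiseless
L9 screening recovers the optimum exactly and factor influence ranks in the
configured order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import ImplantAlignment
from .ranges import RESPONSE_COLUMN

__all__ = ["PlantedBowl", "planted_response", "evaluate_design_planted"]


@dataclass(frozen=True)
class PlantedBowl:
    """Smooth convex bowl: base + sum_f w_f (angle_f - optimum_f)^2.

    Angles are (varus, cut slope, external rotation) in degrees; weights in
    MPa/deg^2 must be non-negative.  ``noise_sd_mpa`` adds seeded Gaussian
    noise at evaluation time (an explicit rng/seed is then required).
    """

    base_mpa: float = 16.4
    optimum_deg: tuple[float, float, float] = (0.0, 1.0, 4.0)
    weights_mpa_per_deg2: tuple[float, float, float] = (0.9, 0.7, 0.6)
    noise_sd_mpa: float = 0.0

    def __post_init__(self) -> None:
        if self.base_mpa <= 0:
            raise ValueError("base pressure must be positive")
        w = tuple(float(v) for v in self.weights_mpa_per_deg2)
        if any(v < 0 for v in w):
            raise ValueError(f"curvature weights must be non-negative, got {w}")
        if self.noise_sd_mpa < 0:
            raise ValueError("noise standard deviation must be non-negative")
        object.__setattr__(self, "weights_mpa_per_deg2", w)
        object.__setattr__(self, "optimum_deg", tuple(float(v) for v in self.optimum_deg))


def planted_response(
    alignment: ImplantAlignment,
    bowl: PlantedBowl = PlantedBowl(),
    rng: np.random.Generator | None = None,
) -> float:
    """Deterministic bowl response (MPa) at the given alignment; optional
    additive Gaussian noise drawn from ``rng``."""
    angles = (alignment.varus_deg, alignment.cut_slope_deg, alignment.external_rotation_deg)
    value = bowl.base_mpa + sum(
        w * (a - o) ** 2
        for w, a, o in zip(bowl.weights_mpa_per_deg2, angles, bowl.optimum_deg)
    )
    if bowl.noise_sd_mpa > 0:
        if rng is None:
            raise ValueError("noisy planted responses require an explicit random generator")
        value += float(rng.normal(0.0, bowl.noise_sd_mpa))
    return float(value)


def evaluate_design_planted(
    design: pd.DataFrame,
    bowl: PlantedBowl = PlantedBowl(),
    seed: int | None = None,
    inherent_slope_deg: float = 3.0,
) -> pd.DataFrame:
    """Evaluate the bowl over a design table, returning a response table."""
    rng = np.random.default_rng(seed) if seed is not None else None
    out = design.copy()
    values = []
    for _, row in design.iterrows():
        alignment = ImplantAlignment(
            varus_deg=row["varus_deg"],
            cut_slope_deg=row["slope_deg"],
            inherent_slope_deg=inherent_slope_deg,
            external_rotation_deg=row["rotation_deg"],
        )
        values.append(planted_response(alignment, bowl, rng))
    out[RESPONSE_COLUMN] = values
    return out
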