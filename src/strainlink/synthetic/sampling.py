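"""Counting noise in density estimates.

A density measurement counts the individuals in a fixed imaged volume.
The count is Poisson around density x volume; an optional gamma mixing
stage (negative-binomial marginal) adds the extra spread produced by
cells clustering together despite mixing before sampling:
Var = m + m^2 / theta for mean m and overdispersion theta.
"""

from __future__ import annotations

import numpy as np

__all__ = ["observe_density", "observe_count"]


def observe_count(
    true_density: float,
    sample_volume_ml: float,
    rng: np.random.Generator,
    overdispersion: float | None = None,
) -> int:
    """Draw the number of individuals counted in ``sample_volume_ml``."""
    if true_density < 0:
        raise ValueError("true_density must be non-negative")
    if sample_volume_ml <= 0:
        raise ValueError("sample_volume_ml must be positive")
    mean = true_density * sample_volume_ml
    if mean == 0.0:
        return 0
    if overdispersion is None:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=overdispersion, scale=mean / overdispersion)
    return int(rng.poisson(lam))


def observe_density(
    true_density: float,
    sample_volume_ml: float,
    rng: np.random.Generator,
    overdispersion: float | None = None,
) -> float:
    """Observed density (cells/mL) = count / volume."""
    return (
        observe_count(true_density, sample_volume_ml, rng, overdispersion)
        / sample_volume_ml
    )
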