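"""Experiment design and strain-profile configuration.

`DesignConfig` describes the factorial layout of a microcosm dilution
experiment; `StrainProfile` holds the generative demography and trait
parameters of one clonal strain. Both round-trip through YAML so a whole
study is reproducible from a single config file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "DesignConfig",
    "StrainProfile",
    "default_strain_profiles",
    "load_design",
    "save_design",
]

TRAIT_NAMES = ("speed", "linearity", "size", "shape")


@dataclass
class DesignConfig:
    """Factorial layout of a dilution-assay experiment.

    Defaults mirror a two-species ciliate microcosm study: 2 species x
    3 clonal strains x 3 temperatures (20/22/24 degC) x 3 atrazine
    levels (0/10/20 ug/mL), five dilutions of a log-phase source culture
    (20-80%), three replicate assays and three sampling time points,
    imaged as 10 s bursts at 10 fps (100 frames) of an 810 uL sample.

    The sampling schedule (days 0, 0.25, 0.5) keeps growth intervals
    short relative to 1/mu so that the per-capita growth-rate regression
    (the short-interval linearization of the logistic) recovers the
    generative parameters with a small, quantified bias; the source
    culture sits at 75% of carrying capacity, placing starting densities
    at 15-60% of K where the linearization is best conditioned.
    """

    species: Sequence[str] = ("Colpidium", "Tetrahymena")
    strains_per_species: int = 3
    temperatures: Sequence[float] = (20.0, 22.0, 24.0)
    pollutant_levels: Sequence[float] = (0.0, 10.0, 20.0)
    dilution_fractions: Sequence[float] = (0.20, 0.35, 0.50, 0.65, 0.80)
    replicates: int = 3
    time_points: int = 3
    sampling_days: Sequence[float] = (0.0, 0.25, 0.5)
    source_fraction_of_k: float = 0.75
    overdispersion: float | None = 1000.0
    frames_per_sample: int = 100
    frame_rate: float = 10.0
    sample_volume_ul: float = 810.0
    arena_size: tuple[int, int] = (512, 512)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must be non-empty")
        if not self.temperatures or not self.pollutant_levels:
            raise ValueError("temperatures and pollutant_levels must be non-empty")
        if self.strains_per_species < 1:
            raise ValueError("strains_per_species must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.time_points < 2:
            raise ValueError("time_points must be >= 2")
        if self.frames_per_sample < 2:
            raise ValueError("frames_per_sample must be >= 2")
        dil = tuple(self.dilution_fractions)
        if not dil:
            raise ValueError("dilution_fractions must be non-empty")
        if any(not (0.0 < d <= 1.0) for d in dil):
            raise ValueError("dilution_fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(dil, dil[1:])):
            raise ValueError("dilution_fractions must be strictly increasing")
        days = tuple(self.sampling_days)
        if len(days) != self.time_points:
            raise ValueError("sampling_days must have one entry per time point")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        if not (0.0 < self.source_fraction_of_k <= 1.0):
            raise ValueError("source_fraction_of_k must lie in (0, 1]")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive or None")
        if self.frame_rate <= 0 or self.sample_volume_ul <= 0:
            raise ValueError("frame_rate and sample_volume_ul must be positive")

    @property
    def sample_volume_ml(self) -> float:
        return self.sample_volume_ul / 1000.0

    def strain_labels(self, species: str) -> list[str]:
        return [f"{species}-S{i + 1}" for i in range(self.strains_per_species)]


@dataclass
class StrainProfile:
    """Generative parameters of one clonal strain.

    Demography: low-density growth rate ``base_mu`` (per day) and
    interaction coefficient ``base_alpha`` (per day per cells/mL,
    negative = self-limitation) at the centre of the treatment grid,
    with linear responses to centred temperature (degC) and pollutant
    (ug/mL), plus an optional temperature x pollutant product term on mu
    (default 0: additive drivers).

    Traits: per-individual draws of movement speed (px/s), path
    linearity (net/gross displacement, in (0, 1]), cell size (px^2) and
    cell shape (aspect ratio, >= 1). Trait means drift linearly with
    time in treatment: ``trait_drift`` is the strain's baseline drift
    per day and ``trait_responses`` the additional drift per day per
    unit of centred driver, so index responses over the growth interval
    carry strain and treatment signal. ``trait_sd`` is the
    per-individual (plasticity) SD, constant over a burst.
    """

    strain_id: str
    species: str = ""
    base_mu: float = 1.0
    base_alpha: float = -2.0e-4
    mu_response: tuple[float, float] = (0.05, -0.005)  # per degC, per ug/mL
    alpha_response: tuple[float, float] = (0.0, 0.0)
    interaction_coef: float = 0.0
    trait_means: tuple[float, float, float, float] = (60.0, 0.75, 150.0, 2.0)
    trait_drift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    trait_responses: tuple[tuple[float, float], ...] = (
        (0.0, 0.0),
        (0.0, 0.0),
        (0.0, 0.0),
        (0.0, 0.0),
    )
    trait_sd: tuple[float, float, float, float] = (15.0, 0.08, 30.0, 0.3)
    temperature_center: float = 22.0
    pollutant_center: float = 10.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.trait_sd):
            raise ValueError("trait_sd must be non-negative")
        speed, linearity, size, shape = self.trait_means
        if not (0.0 < linearity <= 1.0):
            raise ValueError("linearity mean must lie in (0, 1]")
        if shape < 1.0:
            raise ValueError("shape (aspect ratio) mean must be >= 1")
        if size <= 0 or speed < 0:
            raise ValueError("size mean must be positive and speed non-negative")

    def demography_at(self, temperature: float, pollutant: float) -> tuple[float, float]:
        """(mu, alpha) at a treatment; linear in centred drivers."""
        dt = temperature - self.temperature_center
        dp = pollutant - self.pollutant_center
        mu = (
            self.base_mu
            + self.mu_response[0] * dt
            + self.mu_response[1] * dp
            + self.interaction_coef * dt * dp
        )
        alpha = self.base_alpha + self.alpha_response[0] * dt + self.alpha_response[1] * dp
        return mu, alpha

    def trait_means_at(
        self, temperature: float, pollutant: float, t_days: float = 0.0
    ) -> tuple[float, ...]:
        """Per-individual trait means after ``t_days`` in treatment."""
        dt = temperature - self.temperature_center
        dp = pollutant - self.pollutant_center
        return tuple(
            m + t_days * (d + r[0] * dt + r[1] * dp)
            for m, d, r in zip(self.trait_means, self.trait_drift, self.trait_responses)
        )


def default_strain_profiles(config: DesignConfig) -> dict[str, StrainProfile]:
    """Three clonal strains per species with realistic ciliate parameters.

    Colpidium (larger, slower): mu ~ 0.8/day, K ~ 5000 cells/mL;
    Tetrahymena (smaller, faster): mu ~ 1.2/day, K ~ 10000 cells/mL.
    Strains differ in base demography (intraspecific variation) and in
    how their traits drift under the drivers; driver effects on mu and
    alpha are additive (no temperature x pollutant product term).
    """
    species_base = {
        "Colpidium": dict(
            mu=0.8,
            k=5000.0,
            trait_means=(100.0, 0.70, 400.0, 1.8),
            trait_sd=(25.0, 0.10, 80.0, 0.25),
        ),
        "Tetrahymena": dict(
            mu=1.2,
            k=10000.0,
            trait_means=(60.0, 0.80, 150.0, 2.1),
            trait_sd=(15.0, 0.08, 30.0, 0.30),
        ),
    }
    # strain-level offsets (fractions of base mu / K) and trait drifts
    mu_offsets = (-0.10, 0.0, 0.10)
    k_offsets = (0.10, -0.05, -0.10)
    # per-day drift of (speed, linearity, size, shape) per strain slot
    drifts = (
        (-4.0, -0.02, 8.0, -0.05),
        (0.0, 0.0, 0.0, 0.0),
        (6.0, 0.03, -10.0, 0.08),
    )
    profiles: dict[str, StrainProfile] = {}
    for sp in config.species:
        base = species_base.get(sp, species_base["Tetrahymena"])
        fast = base["mu"] >= 1.0
        for i, label in enumerate(config.strain_labels(sp)):
            mu = base["mu"] * (1.0 + mu_offsets[i % 3])
            k = base["k"] * (1.0 + k_offsets[i % 3])
            # temperature raises growth for all strains; atrazine lowers
            # it, more strongly for the last strain slot
            mu_resp = (0.035 if fast else 0.02, -0.006 if i % 3 == 2 else -0.003)
            # alpha responds to drivers only in the fast species
            alpha_mag = mu / k
            a_resp = (
                (-0.01 * alpha_mag if i % 3 == 2 else 0.0, 0.005 * alpha_mag if i % 3 else 0.0)
                if fast
                else (0.0, 0.0)
            )
            trait_resp = (
                (1.5 if fast else 0.4, 0.25 if not fast else -0.25),  # speed
                (0.008, 0.0012 if not fast else -0.0012),  # linearity
                (-3.0, -0.8 if not fast else 0.8),  # size
                (0.02, 0.004 if not fast else -0.004),  # shape
            )
            profiles[label] = StrainProfile(
                strain_id=label,
                species=sp,
                base_mu=mu,
                base_alpha=-mu / k,
                mu_response=mu_resp,
                alpha_response=a_resp,
                interaction_coef=0.0,
                trait_means=base["trait_means"],
                trait_drift=drifts[i % 3],
                trait_responses=trait_resp,
                trait_sd=base["trait_sd"],
            )
    return profiles


def save_design(config: DesignConfig, path: str | Path) -> None:
    data = asdict(config)
    data["species"] = list(config.species)
    data["arena_size"] = list(config.arena_size)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_design(path: str | Path) -> DesignConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in (
        "species", "temperatures", "pollutant_levels", "dilution_fractions",
        "sampling_days", "arena_size",
    ):
        if key in data:
            data[key] = tuple(data[key])
    return DesignConfig(**data)
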