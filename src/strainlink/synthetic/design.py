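"""Enumeration of the factorial assay design.

A *condition* is one (species, strain, temperature, pollutant) cell and
yields one density-dependence curve; an *assay* is a condition x
replicate; a *sample pair* is an assay x dilution (one growth
observation); a *picture series* is one imaged sample (assay x dilution
x time point). The default two-species design gives 54 conditions, 162
assays, 810 sample pairs and 2430 picture series.
"""

from __future__ import annotations

from dataclasses import dataclass

from strainlink.config import DesignConfig

__all__ = ["AssaySample", "enumerate_design", "design_counts"]


@dataclass(frozen=True)
class AssaySample:
    """Descriptor of one microcosm (assay x dilution), imaged at every
    time point."""

    species: str
    strain: str
    temperature: float
    pollutant: float
    replicate: int
    dilution: float

    @property
    def condition_id(self) -> str:
        return f"{self.strain}|T{self.temperature:g}|A{self.pollutant:g}"

    @property
    def assay_id(self) -> str:
        return f"{self.condition_id}|R{self.replicate}"

    def sample_id(self, time_point: int) -> str:
        return f"{self.assay_id}|D{self.dilution:g}|t{time_point}"


def enumerate_design(config: DesignConfig) -> list[AssaySample]:
    """One descriptor per (species, strain, temperature, pollutant,
    replicate, dilution), in deterministic nested order."""
    out = []
    for sp in config.species:
        for strain in config.strain_labels(sp):
            for temp in config.temperatures:
                for poll in config.pollutant_levels:
                    for rep in range(1, config.replicates + 1):
                        for dil in config.dilution_fractions:
                            out.append(
                                AssaySample(sp, strain, float(temp), float(poll), rep, float(dil))
                            )
    return out


def design_counts(config: DesignConfig) -> dict[str, int]:
    """Exact-arithmetic size of the design at every level."""
    conditions = (
        len(config.species)
        * config.strains_per_species
        * len(config.temperatures)
        * len(config.pollutant_levels)
    )
    assays = conditions * config.replicates
    sample_pairs = assays * len(config.dilution_fractions)
    picture_series = sample_pairs * config.time_points
    return {
        "conditions": conditions,
        "assays": assays,
        "sample_pairs": sample_pairs,
        "picture_series": picture_series,
        "points_per_curve": config.replicates * len(config.dilution_fractions),
        "frames_per_sample": config.frames_per_sample,
    }
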