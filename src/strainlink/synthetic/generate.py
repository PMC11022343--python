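"""End-to-end synthetic experiment.

`simulate_experiment` walks the full design and, per microcosm and time
point, propagates the logistic growth curve, draws an observed count
for the imaged volume, and draws per-individual traits for the counted
cells. The result is a tidy per-sample table with the same schema the
tracking module produces from image stacks, so every downstream stage
runs identically on simulated summaries or on tracked video.

With ``render=True`` it additionally simulates correlated-random-walk
trajectories and writes one multi-page TIFF plus a ground-truth CSV per
sample — the expensive path, used for tracking validation rather than
for whole-design runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from strainlink.config import DesignConfig, StrainProfile, TRAIT_NAMES, default_strain_profiles
from strainlink.synthetic.design import enumerate_design
from strainlink.synthetic.growth import grow_population
from strainlink.synthetic.sampling import observe_count
from strainlink.synthetic.walkers import MicrocosmState, draw_individuals, simulate_individuals
from strainlink.synthetic.render import render_frames, write_stack, RENDER_NOISE_SD_DEFAULT

__all__ = ["simulate_experiment", "condition_truth", "summarize_draws"]

RENDER_NOISE_SD = RENDER_NOISE_SD_DEFAULT
# individuals actually rendered in the arena: cap so stacks stay tractable
MAX_RENDERED = 60


def summarize_draws(traits: np.ndarray) -> dict[str, float]:
    """Sample-level mean and unbiased variance per trait."""
    out: dict[str, float] = {}
    n = len(traits)
    for j, name in enumerate(TRAIT_NAMES):
        col = traits[:, j]
        out[f"{name}_mean"] = float(np.mean(col)) if n else np.nan
        out[f"{name}_var"] = float(np.var(col, ddof=1)) if n >= 2 else np.nan
    return out


def condition_truth(
    config: DesignConfig, profiles: dict[str, StrainProfile] | None = None
) -> pd.DataFrame:
    """Generative (mu, alpha, K) per condition — the recovery oracle."""
    profiles = profiles or default_strain_profiles(config)
    rows = []
    seen = set()
    for s in enumerate_design(config):
        if s.condition_id in seen:
            continue
        seen.add(s.condition_id)
        mu, alpha = profiles[s.strain].demography_at(s.temperature, s.pollutant)
        rows.append(
            {
                "condition_id": s.condition_id,
                "species": s.species,
                "strain": s.strain,
                "temperature": s.temperature,
                "pollutant": s.pollutant,
                "mu_true": mu,
                "alpha_true": alpha,
                "k_true": -mu / alpha if alpha != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: DesignConfig,
    profiles: dict[str, StrainProfile] | None = None,
    seed: int | None = None,
    render: bool = False,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate every picture series of the design.

    Returns one row per sample (assay x dilution x time point) with the
    observed density, the underlying truth, and per-trait sample moments
    over the counted individuals. Deterministic given (config, seed).
    """
    profiles = profiles or default_strain_profiles(config)
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if render and out_dir is None:
        raise ValueError("render=True requires out_dir")
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    days = list(config.sampling_days)
    vol = config.sample_volume_ml
    rows = []
    for samp in enumerate_design(config):
        prof = profiles[samp.strain]
        mu, alpha = prof.demography_at(samp.temperature, samp.pollutant)
        if alpha >= 0:
            raise ValueError(f"profile {samp.strain} must be self-limiting (alpha < 0)")
        k = -mu / alpha
        n0 = samp.dilution * config.source_fraction_of_k * k
        for tp, t in enumerate(days):
            true_density = grow_population(mu, alpha, n0, t)
            count = observe_count(true_density, vol, rng, config.overdispersion)
            traits = draw_individuals(
                prof, count, samp.temperature, samp.pollutant, t, rng
            )
            row = {
                "sample_id": samp.sample_id(tp),
                "condition_id": samp.condition_id,
                "assay_id": samp.assay_id,
                "species": samp.species,
                "strain": samp.strain,
                "temperature": samp.temperature,
                "pollutant": samp.pollutant,
                "replicate": samp.replicate,
                "dilution": samp.dilution,
                "time_point": tp,
                "t_days": t,
                "true_density": true_density,
                "count": count,
                "density": count / vol,
                "n_trajectories": count,
            }
            row.update(summarize_draws(traits))
            rows.append(row)
            if render:
                state = MicrocosmState(
                    species=samp.species,
                    strain=samp.strain,
                    temperature=samp.temperature,
                    pollutant=samp.pollutant,
                    replicate=samp.replicate,
                    dilution=samp.dilution,
                    time_point=tp,
                    t_days=t,
                    true_density=true_density,
                )
                tracks = simulate_individuals(
                    state,
                    prof,
                    config.frames_per_sample,
                    config.frame_rate,
                    rng,
                    arena_size=config.arena_size,
                    n_individuals=min(count, MAX_RENDERED),
                )
                stack, _ = render_frames(
                    tracks, config.arena_size, RENDER_NOISE_SD, rng,
                    n_frames=config.frames_per_sample,
                )
                safe = samp.sample_id(tp).replace("|", "_")
                write_stack(out_dir / f"{safe}.tif", stack)
                _truth_csv(out_dir / f"{safe}_truth.csv", samp.sample_id(tp), tracks)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(out_dir / "samples.csv", index=False)
    return df


def _truth_csv(path: Path, sample_id: str, tracks) -> None:
    recs = []
    for t in tracks:
        for f, (x, y) in enumerate(t.positions):
            recs.append(
                {
                    "sample_id": sample_id,
                    "track_id": t.track_id,
                    "frame": f,
                    "x": x,
                    "y": y,
                    "area": t.area,
                    "aspect_ratio": t.aspect,
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)
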