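"""Correlated-random-walk trajectories for individual cells.

Each individual swims with a constant step length (drawn speed divided
by the frame rate, so gross displacement over duration equals the drawn
speed exactly) and von Mises turning angles whose concentration kappa
is chosen so the walk's expected straightness (net/gross displacement)
matches the individual's drawn linearity. Cells keep a fixed ellipse
(area, aspect ratio) for the whole burst and reflect off arena walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruthTrack",
    "MicrocosmState",
    "draw_individuals",
    "kappa_for_linearity",
    "mean_cosine",
    "simulate_individuals",
]


@dataclass
class GroundTruthTrack:
    """Planted trajectory: per-frame positions plus fixed morphology."""

    track_id: int
    positions: np.ndarray  # (n_frames, 2) pixel coordinates (x, y)
    headings: np.ndarray  # (n_frames,) radians
    area: float  # px^2
    aspect: float  # major/minor >= 1
    speed: float  # drawn gross speed, px/s
    linearity: float  # drawn target net/gross
    clipped: bool = False  # touched an arena wall

    @property
    def n_frames(self) -> int:
        return len(self.positions)


@dataclass
class MicrocosmState:
    """One microcosm at one time point: context plus ground truth."""

    species: str
    strain: str
    temperature: float
    pollutant: float
    replicate: int
    dilution: float
    time_point: int
    t_days: float
    true_density: float  # cells/mL
    individuals: np.ndarray | None = None  # (n, 4) trait draws
    tracks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.true_density <= 0:
            raise ValueError("true_density must be positive")


def draw_individuals(profile, n, temperature, pollutant, t_days, rng) -> np.ndarray:
    """Draw (speed, linearity, size, shape) for ``n`` cells.

    Normal draws around the strain's treatment- and time-shifted means,
    truncated to the physically admissible ranges (speed >= 0,
    linearity in (0, 1], size > 0, shape >= 1).
    """
    means = np.asarray(profile.trait_means_at(temperature, pollutant, t_days))
    sds = np.asarray(profile.trait_sd)
    draws = rng.normal(means, sds, size=(n, 4))
    draws[:, 0] = np.clip(draws[:, 0], 0.0, None)  # speed
    draws[:, 1] = np.clip(draws[:, 1], 1e-3, 1.0)  # linearity
    draws[:, 2] = np.clip(draws[:, 2], 1.0, None)  # size
    draws[:, 3] = np.clip(draws[:, 3], 1.0, None)  # shape
    return draws


def mean_cosine(kappa: float) -> float:
    """Mean resultant length A(kappa) = I1(kappa)/I0(kappa) of a von
    Mises turning-angle distribution."""
    from scipy.special import i0e, i1e

    if np.isinf(kappa):
        return 1.0
    if kappa <= 0:
        return 0.0
    return i1e(kappa) / i0e(kappa)


def _inv_mean_cosine(c: float) -> float:
    # standard piecewise approximation for A^{-1} (directional statistics)
    if c >= 1.0:
        return np.inf
    if c <= 0.0:
        return 0.0
    if c < 0.53:
        return 2 * c + c**3 + 5 * c**5 / 6
    if c < 0.85:
        return -0.4 + 1.39 * c + 0.43 / (1 - c)
    return 1.0 / (c**3 - 4 * c**2 + 3 * c)


def kappa_for_linearity(linearity: float, n_steps: int) -> float:
    """Turning concentration giving expected net/gross ~ ``linearity``.

    For a correlated random walk of ``n`` equal steps with turning-angle
    mean cosine c, E[net^2] ~ n s^2 (1+c)/(1-c) for persistent walks, so
    the straightness ratio is ~ sqrt((1+c)/((1-c) n)). Inverting gives
    c = (r^2 n - 1)/(r^2 n + 1), clamped to [0, 1); r = 1 maps to a
    straight walker (kappa = inf).
    """
    if linearity >= 1.0:
        return np.inf
    r2n = linearity**2 * n_steps
    c = (r2n - 1.0) / (r2n + 1.0)
    return _inv_mean_cosine(max(c, 0.0))


def simulate_individuals(
    state: MicrocosmState,
    profile,
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
    arena_size: tuple[int, int] = (512, 512),
    n_individuals: int | None = None,
) -> list[GroundTruthTrack]:
    """Simulate one burst: trait draws plus a CRW per individual.

    ``n_individuals`` defaults to a Poisson draw around the number of
    cells expected in the imaged volume scaled to the arena (kept small
    and explicit in tests by passing it directly).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if n_individuals is None:
        n_individuals = int(rng.poisson(max(state.true_density, 0.0)))
    traits = draw_individuals(
        profile, n_individuals, state.temperature, state.pollutant, state.t_days, rng
    )
    state.individuals = traits
    width, height = arena_size
    tracks: list[GroundTruthTrack] = []
    n_steps = n_frames - 1
    for i in range(n_individuals):
        speed, linearity, size, shape = traits[i]
        step = speed / frame_rate
        kappa = kappa_for_linearity(linearity, n_steps)
        margin = min(width, height) * 0.05
        pos = np.empty((n_frames, 2))
        pos[0] = rng.uniform([margin, margin], [width - margin, height - margin])
        heading = rng.uniform(0, 2 * np.pi)
        headings = np.empty(n_frames)
        headings[0] = heading
        clipped = False
        if np.isinf(kappa):
            turns = np.zeros(n_steps)
        else:
            turns = rng.vonmises(0.0, kappa, size=n_steps) if kappa > 0 else rng.uniform(
                -np.pi, np.pi, size=n_steps
            )
        for f in range(1, n_frames):
            heading = heading + turns[f - 1]
            x = pos[f - 1, 0] + step * np.cos(heading)
            y = pos[f - 1, 1] + step * np.sin(heading)
            # reflect off walls; preserves step length
            if x < 0 or x > width - 1:
                x = np.clip(2 * np.clip(x, 0, width - 1) - x, 0, width - 1)
                heading = np.pi - heading
                clipped = True
            if y < 0 or y > height - 1:
                y = np.clip(2 * np.clip(y, 0, height - 1) - y, 0, height - 1)
                heading = -heading
                clipped = True
            pos[f] = (x, y)
            headings[f] = heading
        tracks.append(
            GroundTruthTrack(
                track_id=i,
                positions=pos,
                headings=headings,
                area=float(size),
                aspect=float(shape),
                speed=float(speed),
                linearity=float(linearity),
                clipped=clipped,
            )
        )
    state.tracks = tracks
    return tracks
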