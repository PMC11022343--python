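"""Movement analysis: per-trajectory metrics.

Speed is gross displacement (summed step lengths) over displacement
duration; linearity relates net displacement (straight line from start
to end) to gross displacement. Under the default ``net_over_gross``
convention linearity lies in [0, 1] with 1 = perfectly straight; the
literal ``gross_over_net`` variant (>= 1, growing with tortuosity) is
available for comparison with pipelines that report it that way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from strainlink.tracking.detect import Particle

__all__ = ["Trajectory", "compute_metrics"]


@dataclass
class Trajectory:
    track_id: int
    detections: list[Particle]
    frame_rate: float
    gross_displacement: float = np.nan  # px
    net_displacement: float = np.nan  # px
    duration: float = np.nan  # s
    speed: float = np.nan  # px/s
    linearity: float = np.nan
    mean_area: float = np.nan  # px^2
    mean_aspect: float = np.nan
    detection_frequency: float = np.nan
    valid: bool = False  # metrics defined (>= 2 detections)

    @property
    def n_detections(self) -> int:
        return len(self.detections)


def _interpolated_path(dets: list[Particle]) -> np.ndarray:
    """Positions at every spanned frame, linearly interpolating frames
    missed inside a gap (used for gross displacement only)."""
    frames = np.array([d.frame for d in dets])
    xs = np.array([d.x for d in dets])
    ys = np.array([d.y for d in dets])
    full = np.arange(frames[0], frames[-1] + 1)
    return np.column_stack([np.interp(full, frames, xs), np.interp(full, frames, ys)])


def compute_metrics(
    track_id: int,
    detections: list[Particle],
    frame_rate: float,
    linearity_convention: str = "net_over_gross",
) -> Trajectory:
    """Fill movement and morphology metrics for one linked track."""
    if linearity_convention not in ("net_over_gross", "gross_over_net"):
        raise ValueError("unknown linearity convention")
    dets = sorted(detections, key=lambda d: d.frame)
    traj = Trajectory(track_id=track_id, detections=dets, frame_rate=frame_rate)
    if len(dets) < 2:
        return traj  # metrics stay NaN, valid stays False
    path = _interpolated_path(dets)
    steps = np.diff(path, axis=0)
    gross = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    net = float(np.hypot(path[-1, 0] - path[0, 0], path[-1, 1] - path[0, 1]))
    span = dets[-1].frame - dets[0].frame
    duration = span / frame_rate
    traj.gross_displacement = gross
    traj.net_displacement = net
    traj.duration = duration
    traj.speed = gross / duration if duration > 0 else np.nan
    if gross == 0.0:
        # a perfectly still cell is maximally straight by convention
        traj.linearity = 1.0
    elif linearity_convention == "net_over_gross":
        traj.linearity = net / gross
    else:
        traj.linearity = gross / net if net > 0 else np.inf
    traj.mean_area = float(np.mean([d.area for d in dets]))
    traj.mean_aspect = float(np.mean([d.aspect for d in dets]))
    traj.detection_frequency = len(dets) / (span + 1)
    traj.valid = True
    return traj
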