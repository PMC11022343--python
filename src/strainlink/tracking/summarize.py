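"""Per-sample summaries: density and population-level trait moments.

Density is the number of QC-passing trajectories corrected for the
imaged sample volume; traits are averaged over all trajectories of the
sample (the population is the replication unit, not the cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from strainlink.tracking.detect import detect_stack
from strainlink.tracking.link import link_particles
from strainlink.tracking.metrics import Trajectory, compute_metrics
from strainlink.tracking.params import DetectionParams, LinkingParams, QCParams
from strainlink.tracking.qc import qc_filter

__all__ = ["SampleSummary", "summarize_sample", "track_stack"]


@dataclass
class SampleSummary:
    sample_id: str
    n_trajectories: int
    density: float  # trajectories per mL
    speed_mean: float = np.nan
    speed_var: float = np.nan
    linearity_mean: float = np.nan
    linearity_var: float = np.nan
    size_mean: float = np.nan
    size_var: float = np.nan
    shape_mean: float = np.nan
    shape_var: float = np.nan
    traits_defined: bool = False
    variance_defined: bool = False


def summarize_sample(
    kept: list[Trajectory], sample_volume_ml: float, sample_id: str = ""
) -> SampleSummary:
    """Density plus mean/unbiased-variance of each trait over tracks."""
    if sample_volume_ml <= 0:
        raise ValueError("sample_volume_ml must be positive")
    n = len(kept)
    s = SampleSummary(sample_id=sample_id, n_trajectories=n, density=n / sample_volume_ml)
    if n == 0:
        return s
    traits = {
        "speed": np.array([t.speed for t in kept]),
        "linearity": np.array([t.linearity for t in kept]),
        "size": np.array([t.mean_area for t in kept]),
        "shape": np.array([t.mean_aspect for t in kept]),
    }
    for name, vals in traits.items():
        setattr(s, f"{name}_mean", float(np.mean(vals)))
        if n >= 2:
            setattr(s, f"{name}_var", float(np.var(vals, ddof=1)))
    s.traits_defined = True
    s.variance_defined = n >= 2
    return s


def track_stack(
    stack: np.ndarray,
    frame_rate: float,
    sample_volume_ml: float,
    detection: DetectionParams | None = None,
    linking: LinkingParams | None = None,
    qc: QCParams | None = None,
    sample_id: str = "",
    linearity_convention: str = "net_over_gross",
    method: str = "greedy",
):
    """Full detection -> linking -> metrics -> QC -> summary pass.

    Returns ``(summary, kept, discarded)``.
    """
    detection = detection or DetectionParams()
    linking = linking or LinkingParams()
    qc = qc or QCParams()
    dets = detect_stack(stack, detection)
    raw = link_particles(dets, linking, method=method)
    trajs = [
        compute_metrics(i, parts, frame_rate, linearity_convention)
        for i, parts in enumerate(raw)
    ]
    kept, discarded = qc_filter(trajs, qc)
    summary = summarize_sample(kept, sample_volume_ml, sample_id=sample_id)
    return summary, kept, discarded
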