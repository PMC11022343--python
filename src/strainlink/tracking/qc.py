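"""Trajectory quality control.

A track is kept only if it lasts long enough, moved far enough, and was
detected often enough over its span — the gates that separate real
swimming cells from debris, noise blobs and broken fragments.
"""

from __future__ import annotations

from strainlink.tracking.metrics import Trajectory
from strainlink.tracking.params import QCParams

__all__ = ["qc_filter"]


def qc_filter(
    trajectories: list[Trajectory], params: QCParams
) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Split tracks into (kept, discarded-with-reason).

    The first failed criterion is recorded, checked in the order
    duration, net displacement, detection frequency; tracks with
    undefined metrics (single detection) fail as "undefined".
    """
    kept: list[Trajectory] = []
    discarded: list[tuple[Trajectory, str]] = []
    for t in trajectories:
        if not t.valid:
            discarded.append((t, "undefined"))
        elif t.duration < params.min_duration:
            discarded.append((t, "duration"))
        elif t.net_displacement < params.min_net_displacement:
            discarded.append((t, "net_displacement"))
        elif t.detection_frequency < params.min_detection_frequency:
            discarded.append((t, "detection_frequency"))
        else:
            kept.append(t)
    return kept, discarded
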