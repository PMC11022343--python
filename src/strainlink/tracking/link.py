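"""Particle tracking: associate detections on consecutive frames.

Greedy globally-nearest-neighbour linking under a maximum-step
constraint, the deterministic analogue of constraint-based trackers:
all candidate (track, detection) pairs of a frame are ranked by
distance and assigned greedily. Detections are first canonicalized by
(x, y) within each frame so the output does not depend on detection
order. An optimal-assignment (Hungarian) mode is available for
robustness comparisons.
"""

from __future__ import annotations

import numpy as np

from strainlink.tracking.params import LinkingParams
from strainlink.tracking.detect import Particle

__all__ = ["link_particles"]


def link_particles(
    detections: list[list[Particle]],
    params: LinkingParams,
    method: str = "greedy",
) -> list[list[Particle]]:
    """Reconstruct trajectories from per-frame detection lists.

    ``detections[f]`` holds the detections of frame ``f`` (ordered
    frames). Returns one list of particles per track, ordered by frame;
    track identity is positional (creation order).

    A detection may join an open track whose last detection is at most
    ``max_gap + 1`` frames behind and within ``max_step`` px per elapsed
    frame of its position. Ties are broken by smaller distance, then
    lower track id, then canonical scan order.
    """
    if method not in ("greedy", "hungarian"):
        raise ValueError("method must be 'greedy' or 'hungarian'")
    open_tracks: list[dict] = []
    closed: list[list[Particle]] = []
    all_tracks: list[list[Particle]] = []

    for f, dets in enumerate(detections):
        dets = sorted(dets, key=lambda p: (p.x, p.y))
        # retire tracks that exceeded the allowed gap
        still = []
        for tr in open_tracks:
            if f - tr["last_frame"] > params.max_gap + 1:
                closed.append(tr["particles"])
            else:
                still.append(tr)
        open_tracks = still

        assigned_dets: set[int] = set()
        if open_tracks and dets:
            if method == "greedy":
                cands = []
                for ti, tr in enumerate(open_tracks):
                    gap = f - tr["last_frame"]
                    last = tr["particles"][-1]
                    limit = params.max_step * gap
                    for di, d in enumerate(dets):
                        dist = float(np.hypot(d.x - last.x, d.y - last.y))
                        if dist <= limit:
                            cands.append((dist, tr["id"], di, ti))
                cands.sort()
                used_tracks: set[int] = set()
                for dist, _tid, di, ti in cands:
                    if ti in used_tracks or di in assigned_dets:
                        continue
                    open_tracks[ti]["particles"].append(dets[di])
                    open_tracks[ti]["last_frame"] = f
                    used_tracks.add(ti)
                    assigned_dets.add(di)
            else:
                from scipy.optimize import linear_sum_assignment

                big = 1e12
                cost = np.full((len(open_tracks), len(dets)), big)
                for ti, tr in enumerate(open_tracks):
                    gap = f - tr["last_frame"]
                    last = tr["particles"][-1]
                    limit = params.max_step * gap
                    for di, d in enumerate(dets):
                        dist = float(np.hypot(d.x - last.x, d.y - last.y))
                        if dist <= limit:
                            cost[ti, di] = dist
                rows, cols = linear_sum_assignment(cost)
                for ti, di in zip(rows, cols):
                    if cost[ti, di] >= big:
                        continue
                    open_tracks[ti]["particles"].append(dets[di])
                    open_tracks[ti]["last_frame"] = f
                    assigned_dets.add(di)
        for di, d in enumerate(dets):
            if di not in assigned_dets:
                track: list[Particle] = [d]
                open_tracks.append(
                    {"id": len(all_tracks), "particles": track, "last_frame": f}
                )
                all_tracks.append(track)

    # note: all_tracks already references every particle list (closed
    # tracks were never copied), so it is the complete, ordered answer
    return all_tracks
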