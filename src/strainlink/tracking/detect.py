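"""Per-frame particle analysis.

Bright connected components above a grey threshold are characterized by
centroid, area and the aspect ratio of a fitted ellipse (major/minor
axis), then gated on area and aspect — the same constraints a manual
dark-field pipeline applies to separate cells from noise and artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from strainlink.tracking.params import DetectionParams

__all__ = ["Particle", "detect_particles", "detect_stack"]


@dataclass(frozen=True)
class Particle:
    frame: int
    x: float  # column, px
    y: float  # row, px
    area: float  # px^2
    aspect: float  # major/minor >= 1


def detect_particles(
    frame: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Particle]:
    """Detect and characterize all particles in one grey-scale frame."""
    if frame.ndim != 2:
        raise ValueError("expected a single-channel image")
    mask = frame > params.grey_threshold
    if not mask.any():
        return []
    out = []
    for region in regionprops(label(mask, connectivity=2)):
        area = float(region.area)
        if not (params.min_area <= area <= params.max_area):
            continue
        minor = region.axis_minor_length
        major = region.axis_major_length
        # degenerate (line-like) regions get an infinite aspect and are
        # dropped by the max_aspect gate
        aspect = major / minor if minor > 0 else np.inf
        if not (params.min_aspect <= aspect <= params.max_aspect):
            continue
        cy, cx = region.centroid
        out.append(Particle(frame_index, float(cx), float(cy), area, float(aspect)))
    return out


def detect_stack(stack: np.ndarray, params: DetectionParams) -> list[list[Particle]]:
    """Run detection on every frame of a (n_frames, h, w) stack."""
    return [detect_particles(stack[f], params, frame_index=f) for f in range(len(stack))]
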