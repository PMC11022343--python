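"""Dark-field frame rendering.

Cells appear as filled bright ellipses on a near-black background, the
way an indirect-light/black-background (dark-field) imaging rig records
them: background ~0 plus Gaussian read noise, cell interior at a fixed
grey level. Frames are 8-bit; a stack is one 10 s burst.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = ["render_frames", "ellipse_axes", "write_stack", "read_stack"]

CELL_INTENSITY = 200
RENDER_NOISE_SD_DEFAULT = 8.0


def ellipse_axes(area: float, aspect: float) -> tuple[float, float]:
    """Semi-axes (major, minor) of an ellipse with given area (px^2) and
    aspect ratio (major/minor >= 1)."""
    if area <= 0 or aspect < 1:
        raise ValueError("need area > 0 and aspect >= 1")
    minor = np.sqrt(area / (np.pi * aspect))
    return aspect * minor, minor


def render_frames(
    tracks,
    arena_size: tuple[int, int],
    noise_sd: float,
    rng: np.random.Generator,
    n_frames: int | None = None,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Rasterize planted tracks into an 8-bit grey stack.

    Returns ``(stack, overlaps)`` where ``stack`` has shape
    (n_frames, height, width) and ``overlaps`` lists
    (frame, track_a, track_b) pairs whose painted pixels collided —
    bookkeeping for tests, overlapping cells are rendered anyway.
    """
    width, height = arena_size
    if n_frames is None:
        n_frames = max((t.n_frames for t in tracks), default=2)
    stack = np.zeros((n_frames, height, width), dtype=np.uint8)
    overlaps: list[tuple[int, int, int]] = []
    for f in range(n_frames):
        owner = np.full((height, width), -1, dtype=np.int32)
        frame = stack[f]
        for t in tracks:
            if f >= t.n_frames:
                continue
            x, y = t.positions[f]
            major, minor = ellipse_axes(t.area, t.aspect)
            rot = -((t.headings[f] + np.pi) % (2 * np.pi) - np.pi)  # wrap to (-pi, pi]
            rr, cc = draw_ellipse(
                y, x, minor, major, shape=(height, width), rotation=rot
            )
            hit = owner[rr, cc]
            for other in np.unique(hit[hit >= 0]):
                overlaps.append((f, int(other), int(t.track_id)))
            owner[rr, cc] = t.track_id
            frame[rr, cc] = CELL_INTENSITY
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=frame.shape)
            stack[f] = np.clip(frame.astype(np.float64) + noise, 0, 255).astype(np.uint8)
    return stack, overlaps


def write_stack(path, stack: np.ndarray) -> None:
    """Write a burst as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, stack, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
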