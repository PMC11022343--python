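"""Parameter sets for the three tracking stages.

Defaults are a species-agnostic starting point for dark-field stacks of
ciliate-sized cells; real studies tune them per species, so everything
is overridable from the tracking config.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DetectionParams", "LinkingParams", "QCParams"]


@dataclass
class DetectionParams:
    """Thresholding and shape gates for per-frame particle analysis."""

    grey_threshold: float = 100.0  # half of the nominal cell intensity
    min_area: float = 20.0  # px^2
    max_area: float = 5000.0  # px^2
    min_aspect: float = 1.0  # major/minor, normalized >= 1
    max_aspect: float = 10.0

    def __post_init__(self) -> None:
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        if self.min_aspect > self.max_aspect:
            raise ValueError("min_aspect must be <= max_aspect")


@dataclass
class LinkingParams:
    """Constraints on plausible movement between consecutive frames."""

    max_step: float = 15.0  # px per frame of elapsed time
    max_gap: int = 6  # frames an individual may go undetected
    tie_rule: str = "distance-trackid-scan"  # documented deterministic order

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class QCParams:
    """Minimal quality gates a trajectory must meet to be kept."""

    min_duration: float = 3.0  # s
    min_net_displacement: float = 5.0  # px
    min_detection_frequency: float = 0.5  # detected fraction of spanned frames

    def __post_init__(self) -> None:
        if min(self.min_duration, self.min_net_displacement, self.min_detection_frequency) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if self.min_detection_frequency > 1:
            raise ValueError("min_detection_frequency must be <= 1")
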