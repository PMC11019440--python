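"""Domain types shared by every pipeline stage.

Coordinate conventions: pixel coordinates are 0-based with the origin at the
top-left corner, ``x`` increasing rightward (columns) and ``y`` increasing
downward (rows).  Linking and kinematic distances are computed in
sample-plane micrometres (pixel distance times the pixel-to-micron scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MOTILITY_CLASSES = ("slow", "medium", "rapid")
UNCLASSIFIED = "unclassified"


class CasatrackError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(CasatrackError):
    """A value violates a documented invariant."""


@dataclass(frozen=True)
class Detection:
    """One apparent head centroid (AC) found in one frame.

    The AC is the brightest point of the filtered sperm-head image; ``score``
    is the detector's accumulator response at the accepted peak.
    """

    frame_index: int
    x: float
    y: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError("frame_index must be >= 0")
        if self.score < 0:
            raise ValidationError("score must be >= 0")


@dataclass(eq=False)
class Track:
    """Ordered per-frame positions of one sperm head.

    ``frames`` are strictly increasing; after gap interpolation they are
    consecutive.  ``interpolated`` flags points filled in by gap closing
    rather than detected.
    """

    track_id: int
    frames: np.ndarray       # (n,) int
    xy: np.ndarray           # (n, 2) float, pixels
    interpolated: np.ndarray = None  # (n,) bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.frames), dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("xy must have shape (n, 2)")
        n = len(self.frames)
        if n < 2:
            raise ValidationError("a track needs at least 2 points")
        if len(self.xy) != n or len(self.interpolated) != n:
            raise ValidationError("frames, xy and interpolated must align")
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError("frame indices must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def is_frame_consecutive(self) -> bool:
        return bool(np.all(np.diff(self.frames) == 1))

    def xy_um(self, um_per_pixel: float) -> np.ndarray:
        return self.xy * float(um_per_pixel)

    def step_lengths(self) -> np.ndarray:
        """Euclidean distances between consecutive points, in pixels."""
        return np.linalg.norm(np.diff(self.xy, axis=0), axis=1)


@dataclass
class CircleFit:
    """Algebraic circle fitted to a trajectory, in micrometres."""

    cx: float
    cy: float
    radius: float
    rms_residual: float
    turning_angle: float  # signed total swept angle about the centre, rad

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("fitted radius must be > 0")
        if self.rms_residual < 0:
            raise ValidationError("rms_residual must be >= 0")


@dataclass
class KinematicsRecord:
    """Kinematic summary of one track: velocities, class and circle flag."""

    track_id: int
    n_points: int
    vsl: float                      # um/s
    vcl: float                      # um/s
    lin: float                      # percent
    motility_class: str = UNCLASSIFIED
    is_circular: bool = False
    circle_radius: Optional[float] = None  # um
    condition: Optional[str] = None
    time_step: Optional[str] = None

    def __post_init__(self) -> None:
        if self.circle_radius is not None and not self.is_circular:
            raise ValidationError("circle_radius present requires is_circular")
        if not (-1e-9 <= self.lin <= 100 + 1e-9):
            raise ValidationError("LIN must lie in [0, 100]")
        if self.vsl > self.vcl * (1 + 1e-9) + 1e-12:
            raise ValidationError("VSL cannot exceed VCL")


@dataclass
class PopulationSummary:
    """Per-class composition of the motile population at one time-step.

    Percentages are over the motile tracks only (slow + medium + rapid);
    unclassified tracks are excluded from the denominator.
    """

    condition: str
    time_step: str
    counts: dict = field(default_factory=dict)       # class -> int
    percentages: dict = field(default_factory=dict)  # class -> float
    total_motile: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("counts must be >= 0")
        if self.total_motile > 0:
            s = sum(self.percentages.get(c, 0.0) for c in MOTILITY_CLASSES)
            if abs(s - 100.0) > 1e-6:
                raise ValidationError("class percentages must sum to 100")
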