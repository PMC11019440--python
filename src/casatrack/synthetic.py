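"""Synthetic swimmers and rendered brightfield-like videos with ground truth.

The generator emulates the reference acquisition geometry: 10 s recordings
at 100 fps through a 20x objective (sample-plane scale 0.325 um/pixel, a
512 x 512 px field of ~166 x 166 um) of bull sperm swimming in an unconfined
chamber.  Three motion kinds are simulated in 2-D:

* ``straight_wobble`` -- constant drift along a heading plus a sinusoidal
  transverse head oscillation (the projected flagellar yaw).  The drift
  speed is calibrated numerically so that the *sampled* curvilinear path
  length per second equals the programmed VCL exactly.
* ``circular`` -- constant angular speed on a circle; the angular rate is
  chosen so the sampled chord speed equals the programmed VCL.
* ``immotile`` -- isotropic Gaussian positional jitter about a fixed point.

Straight swimmers are kept inside the field by reflecting (folding) their
unbounded path at the field margins; folding preserves per-step path length,
hence VCL and the class label, while real recordings instead lose fast
swimmers over the field edge -- a documented difference.  Heads are rendered
as 2-D Gaussian spots on a constant background with additive Gaussian pixel
noise.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import AcquisitionParams
from .core import Detection, Track, ValidationError
from .detection import FrameStack
from .kinematics import classify

MOTION_KINDS = ("straight_wobble", "circular", "immotile")


@dataclass
class SwimmerSpec:
    """Programmed kinematics of one synthetic swimmer (micrometre units)."""

    motion_kind: str
    vcl_um_s: float = 0.0
    start_um: Tuple[float, float] = (0.0, 0.0)
    heading_rad: float = 0.0
    wobble_amplitude_um: float = 0.0
    wobble_freq_hz: float = 10.0
    wobble_phase_rad: float = 0.0
    circle_radius_um: Optional[float] = None
    circle_direction: int = 1           # +1 counter-clockwise, -1 clockwise
    jitter_sigma_um: float = 0.3        # immotile only

    def __post_init__(self) -> None:
        if self.motion_kind not in MOTION_KINDS:
            raise ValidationError(f"unknown motion_kind {self.motion_kind!r}")
        if self.vcl_um_s < 0:
            raise ValidationError("programmed VCL must be >= 0")
        if self.motion_kind == "circular":
            if not self.circle_radius_um or self.circle_radius_um <= 0:
                raise ValidationError("circular swimmers need a radius > 0")

    @property
    def class_label(self) -> str:
        """Motility class implied by the programmed VCL."""
        return classify(self.vcl_um_s)


@dataclass
class GroundTruth:
    """True trajectories (um) of every simulated swimmer."""

    specs: List[SwimmerSpec]
    frames: np.ndarray                  # (n_frames,) int
    xy_um: np.ndarray                   # (n_swimmers, n_frames, 2)
    frame_rate: float

    @property
    def n_swimmers(self) -> int:
        return len(self.specs)

    def track(self, i: int, um_per_pixel: float) -> Track:
        """Ground-truth track of swimmer ``i`` in pixel coordinates."""
        return Track(track_id=i, frames=self.frames,
                     xy=self.xy_um[i] / um_per_pixel)

    def detections_by_frame(self, um_per_pixel: float,
                            field_shape_px: Optional[Tuple[int, int]] = None,
                            ) -> List[List[Detection]]:
        """Per-frame ground-truth detection lists in pixel coordinates.

        With ``field_shape_px`` given, positions outside the field are
        dropped (as a real detector would miss them).
        """
        out: List[List[Detection]] = []
        for k, f in enumerate(self.frames):
            dets = []
            for i in range(self.n_swimmers):
                x, y = self.xy_um[i, k] / um_per_pixel
                if field_shape_px is not None:
                    h, w = field_shape_px
                    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                        continue
                dets.append(Detection(frame_index=int(f), x=float(x),
                                      y=float(y), score=1.0))
            out.append(dets)
        return out


def _fold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect unbounded coordinates into [lo, hi] (triangle-wave map)."""
    if hi <= lo:
        raise ValidationError("invalid folding interval")
    span = hi - lo
    v = np.mod(values - lo, 2.0 * span)
    return lo + np.where(v <= span, v, 2.0 * span - v)


def _sampled_vcl(xy: np.ndarray, frame_rate: float) -> float:
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return float(steps.sum()) * frame_rate / (len(xy) - 1)


def _straight_wobble_path(spec: SwimmerSpec, t: np.ndarray,
                          frame_rate: float) -> np.ndarray:
    """Drift + transverse sine, drift speed calibrated to the sampled VCL."""
    ux, uy = math.cos(spec.heading_rad), math.sin(spec.heading_rad)
    nx, ny = -uy, ux
    wob = spec.wobble_amplitude_um * np.sin(
        2.0 * math.pi * spec.wobble_freq_hz * t + spec.wobble_phase_rad)

    def path(drift: float) -> np.ndarray:
        ax = drift * t * ux + wob * nx
        ay = drift * t * uy + wob * ny
        return np.column_stack([ax, ay])

    target = spec.vcl_um_s
    if target <= 0:
        return path(0.0) + spec.start_um
    wobble_only = _sampled_vcl(path(0.0), frame_rate)
    if wobble_only >= target:
        raise ValidationError(
            f"wobble alone yields VCL {wobble_only:.1f} um/s >= programmed "
            f"{target:.1f} um/s; reduce amplitude or frequency")
    if wobble_only < 1e-12:
        drift = target
    else:
        drift = brentq(lambda v: _sampled_vcl(path(v), frame_rate) - target,
                       0.0, target, xtol=1e-10)
    return path(drift) + spec.start_um


def _circular_path(spec: SwimmerSpec, t: np.ndarray,
                   frame_rate: float) -> np.ndarray:
    """Constant angular speed; chord speed matches the programmed VCL."""
    R = float(spec.circle_radius_um)
    dt = 1.0 / frame_rate
    chord = spec.vcl_um_s * dt
    if chord > 2.0 * R:
        raise ValidationError("programmed VCL too high for the circle radius")
    omega = 2.0 / dt * math.asin(chord / (2.0 * R)) * spec.circle_direction
    theta0 = spec.heading_rad
    cx = spec.start_um[0] - R * math.cos(theta0)
    cy = spec.start_um[1] - R * math.sin(theta0)
    theta = theta0 + omega * t
    return np.column_stack([cx + R * np.cos(theta), cy + R * np.sin(theta)])


def simulate_tracks(specs: Sequence[SwimmerSpec], duration_s: float,
                    frame_rate: float, seed: int = 0,
                    field_um: Optional[Tuple[float, float]] = None,
                    margin_um: float = 5.0) -> GroundTruth:
    """Simulate ground-truth trajectories for all swimmers.

    ``field_um`` (width, height) activates reflective folding of straight
    swimmers at ``margin_um`` from the field edge; circular and immotile
    swimmers are assumed placed inside the field by the caller.
    """
    if frame_rate <= 0 or duration_s <= 0:
        raise ValidationError("frame_rate and duration must be > 0")
    n_frames = int(round(duration_s * frame_rate))
    if n_frames < 2:
        raise ValidationError("simulation needs at least 2 frames")
    t = np.arange(n_frames) / frame_rate
    rng = np.random.default_rng(seed)

    xy = np.empty((len(specs), n_frames, 2))
    for i, spec in enumerate(specs):
        if spec.motion_kind == "straight_wobble":
            path = _straight_wobble_path(spec, t, frame_rate)
            if field_um is not None:
                w, h = field_um
                path = np.column_stack([
                    _fold(path[:, 0], margin_um, w - margin_um),
                    _fold(path[:, 1], margin_um, h - margin_um)])
            xy[i] = path
        elif spec.motion_kind == "circular":
            xy[i] = _circular_path(spec, t, frame_rate)
        else:  # immotile
            jitter = rng.normal(0.0, spec.jitter_sigma_um, size=(n_frames, 2))
            xy[i] = np.asarray(spec.start_um) + jitter
    return GroundTruth(specs=list(specs), frames=np.arange(n_frames),
                       xy_um=xy, frame_rate=frame_rate)


def render_video(ground_truth: GroundTruth, shape_px: Tuple[int, int],
                 um_per_pixel: float, head_sigma_px: float = 2.0,
                 amplitude: float = 1.0, background: float = 0.1,
                 noise_sigma: float = 0.05, seed: int = 0) -> FrameStack:
    """Render swimmers as Gaussian spots on a noisy constant background.

    ``noise_sigma`` is additive Gaussian pixel noise (default 5% of the head
    peak amplitude).  Deterministic given ``seed``.
    """
    h, w = shape_px
    n_frames = len(ground_truth.frames)
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), background, dtype=np.float32)
    half = int(math.ceil(4.0 * head_sigma_px))
    for k in range(n_frames):
        img = frames[k]
        if noise_sigma > 0:
            img += rng.normal(0.0, noise_sigma, size=(h, w)).astype(np.float32)
        for i in range(ground_truth.n_swimmers):
            x, y = ground_truth.xy_um[i, k] / um_per_pixel
            if not (-half <= x <= w - 1 + half and -half <= y <= h - 1 + half):
                continue
            x0, x1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
            y0, y1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
            xs = np.arange(max(x0, 0), min(x1, w))
            ys = np.arange(max(y0, 0), min(y1, h))
            if len(xs) == 0 or len(ys) == 0:
                continue
            gx = np.exp(-0.5 * ((xs - x) / head_sigma_px) ** 2)
            gy = np.exp(-0.5 * ((ys - y) / head_sigma_px) ** 2)
            img[np.ix_(ys, xs)] += (amplitude * np.outer(gy, gx)).astype(np.float32)
    return FrameStack(frames=frames, frame_rate=ground_truth.frame_rate)


def degrade_detections(detections_by_frame: Sequence[Sequence[Detection]],
                       dropout_prob: float = 0.0,
                       false_positive_rate: float = 0.0,
                       field_shape_px: Tuple[int, int] = (512, 512),
                       seed: int = 0) -> List[List[Detection]]:
    """Stress detections: random dropout plus spurious uniform detections.

    Each detection is deleted independently with ``dropout_prob``; spurious
    detections are added per frame with Poisson mean ``false_positive_rate``
    at uniform positions.  Deterministic given ``seed``.
    """
    if not (0.0 <= dropout_prob <= 1.0) or false_positive_rate < 0:
        raise ValidationError("rates out of range")
    rng = np.random.default_rng(seed)
    h, w = field_shape_px
    out: List[List[Detection]] = []
    for f, dets in enumerate(detections_by_frame):
        kept = [d for d in dets if rng.random() >= dropout_prob]
        n_fp = rng.poisson(false_positive_rate) if false_positive_rate > 0 else 0
        for _ in range(n_fp):
            kept.append(Detection(frame_index=f,
                                  x=float(rng.uniform(0, w - 1)),
                                  y=float(rng.uniform(0, h - 1)), score=0.0))
        out.append(kept)
    return out


def add_localization_noise(detections_by_frame: Sequence[Sequence[Detection]],
                           sigma_px: float, seed: int = 0) -> List[List[Detection]]:
    """Add iid Gaussian localization error (pixels) to every detection."""
    rng = np.random.default_rng(seed)
    out: List[List[Detection]] = []
    for dets in detections_by_frame:
        noisy = []
        for d in dets:
            dx, dy = rng.normal(0.0, sigma_px, size=2)
            noisy.append(Detection(frame_index=d.frame_index, x=d.x + dx,
                                   y=d.y + dy, score=d.score))
        out.append(noisy)
    return out


def population_specs(n_slow: int, n_medium: int, n_rapid: int,
                     field_um: Tuple[float, float], seed: int = 0,
                     n_circular: int = 0, n_immotile: int = 0,
                     margin_um: float = 12.0) -> List[SwimmerSpec]:
    """Draw a mixed population across the three VCL bands.

    Speeds are uniform within each class band (slow 25-80, medium 80-150,
    rapid 150-250 um/s); wobble amplitude scales with speed so the lateral
    oscillation contributes a realistic ~40% of the path speed; wobble
    frequency is uniform in 8-15 Hz.  Circular swimmers are placed so the
    whole circle stays inside the field.
    """
    rng = np.random.default_rng(seed)
    w, h = field_um

    def uni(lo: float, hi: float) -> float:
        # degenerate interval (tiny field): fall back to the midpoint
        return float(rng.uniform(lo, hi)) if hi > lo else 0.5 * (lo + hi)

    specs: List[SwimmerSpec] = []
    bands = ([(25.0, 80.0)] * n_slow + [(80.0, 150.0)] * n_medium
             + [(150.0, 250.0)] * n_rapid)
    for lo, hi in bands:
        vcl = float(rng.uniform(lo, hi))
        freq = float(rng.uniform(8.0, 15.0))
        amp = 0.1 * vcl / freq          # sampled lateral speed ~ 0.4 * VCL
        specs.append(SwimmerSpec(
            motion_kind="straight_wobble", vcl_um_s=vcl,
            start_um=(uni(margin_um, w - margin_um),
                      uni(margin_um, h - margin_um)),
            heading_rad=float(rng.uniform(0.0, 2.0 * math.pi)),
            wobble_amplitude_um=amp, wobble_freq_hz=freq,
            wobble_phase_rad=float(rng.uniform(0.0, 2.0 * math.pi))))
    r_hi = min(60.0, max(15.0, min(w, h) / 2.0 - margin_um - 5.0))
    for _ in range(n_circular):
        radius = float(rng.uniform(15.0, r_hi)) if r_hi > 15.0 else 15.0
        vcl = float(rng.uniform(80.0, 250.0))
        pad = radius + margin_um
        cx = uni(pad, w - pad)
        cy = uni(pad, h - pad)
        theta0 = float(rng.uniform(0.0, 2.0 * math.pi))
        specs.append(SwimmerSpec(
            motion_kind="circular", vcl_um_s=vcl, circle_radius_um=radius,
            circle_direction=int(rng.choice([-1, 1])),
            start_um=(cx + radius * math.cos(theta0),
                      cy + radius * math.sin(theta0)),
            heading_rad=theta0))
    for _ in range(n_immotile):
        specs.append(SwimmerSpec(
            motion_kind="immotile",
            start_um=(uni(margin_um, w - margin_um),
                      uni(margin_um, h - margin_um))))
    return specs


def default_scenario(seed: int = 0, params: Optional[AcquisitionParams] = None,
                     duration_s: float = 10.0,
                     shape_px: Tuple[int, int] = (512, 512)):
    """The reference desk-scale scenario: 10 s at 100 fps, 30 swimmers.

    Composition: 9 slow, 9 medium, 7 rapid straight swimmers, 3 circular and
    2 immotile.  Returns ``(specs, ground_truth, params)``.
    """
    params = params or AcquisitionParams()
    h, w = shape_px
    field_um = (w * params.um_per_pixel, h * params.um_per_pixel)
    specs = population_specs(9, 9, 7, field_um, seed=seed,
                             n_circular=3, n_immotile=2)
    gt = simulate_tracks(specs, duration_s, params.frame_rate, seed=seed,
                         field_um=field_um)
    return specs, gt, params
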