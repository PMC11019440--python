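"""Per-frame preprocessing and apparent-head-centroid (AC) detection.

A frame is first pushed through a fixed enhancement chain -- Gaussian filter,
grey-scale morphological opening, mean subtraction and an adaptive Wiener
filter, in that order -- so that sperm heads stand out as bright, roughly
circular blobs on a zero-mean background.  Detection then evaluates a
circular matched-filter accumulator (normalised cross-correlation against
disk templates spanning ``head_radius_range``) and accepts local maxima whose
accumulator response exceeds ``1 - S``, where ``S`` is the sensitivity: a
larger ``S`` lowers the acceptance threshold, so the detection count is
non-decreasing in ``S`` on any fixed frame, at the price of more false
positives.  An absolute intensity gate at ``noise_floor_k`` robust noise
sigmas rejects accumulator peaks that are shaped like a head but carry no
signal.  Accepted peaks are refined to sub-pixel precision by the
intensity-weighted centroid of the filtered image inside the matched disk,
the practical estimator of the brightest point of the head area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import match_template, peak_local_max
from skimage.morphology import disk

from .config import AcquisitionParams, ConfigError
from .core import Detection, ValidationError

log = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """An ordered stack of same-shaped grayscale frames at constant rate."""

    frames: np.ndarray          # (t, h, w)
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (t, h, w) array")
        if len(self.frames) == 0:
            raise ValidationError("no frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("pixel values must be finite")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self):
        return self.frames.shape[1:]


def _adaptive_wiener(img: np.ndarray, window: int) -> np.ndarray:
    """Locally adaptive Wiener filter (local mean/variance shrinkage).

    Degenerate neighbourhoods with zero variance pass the local mean
    through unchanged instead of dividing by zero.
    """
    local_mean = ndi.uniform_filter(img, window)
    local_sq = ndi.uniform_filter(img * img, window)
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise = float(local_var.mean())
    gain = np.zeros_like(img)
    np.divide(np.maximum(local_var - noise, 0.0), local_var, out=gain,
              where=local_var > 0)
    return local_mean + gain * (img - local_mean)


def preprocess_frame(frame: np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Enhance sperm heads: Gaussian -> opening -> mean subtraction -> Wiener."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValidationError(f"expected a 2-D frame, got ndim={frame.ndim}")
    if params.invert:
        frame = -frame
    out = ndi.gaussian_filter(frame, params.gaussian_sigma)
    if params.opening_radius > 0:
        out = ndi.grey_opening(out, footprint=disk(params.opening_radius))
    out = out - out.mean()
    return _adaptive_wiener(out, params.wiener_window)


def _disk_template(radius: float) -> np.ndarray:
    """Zero-mean soft-edged disk used as the matched-filter template."""
    r_int = max(int(np.ceil(radius)), 1)
    yy, xx = np.mgrid[-r_int - 1:r_int + 2, -r_int - 1:r_int + 2]
    rho = np.hypot(xx, yy)
    tmpl = np.clip(radius + 0.5 - rho, 0.0, 1.0)
    return tmpl - tmpl.mean()


def _template_radii(lo: float, hi: float, n_max: int = 4) -> np.ndarray:
    if hi <= lo:
        return np.array([lo])
    n = min(n_max, max(2, int(round(hi - lo)) + 1))
    return np.linspace(lo, hi, n)


def detect_heads(filtered: np.ndarray, params: AcquisitionParams) -> List[Detection]:
    """Detect bright circular heads in a preprocessed frame.

    Returns sub-pixel centroids with the accumulator response as score.
    """
    lo, hi = params.head_radius_range
    if not (0 < lo <= hi):
        raise ConfigError("head_radius_range must satisfy 0 < min <= max")
    filtered = np.asarray(filtered, dtype=np.float64)
    if filtered.ndim != 2:
        raise ValidationError("detect_heads expects a 2-D image")

    radii = _template_radii(lo, hi)
    acc = np.full(filtered.shape, -1.0)
    best_r = np.full(filtered.shape, radii[0])
    for r in radii:
        resp = match_template(filtered, _disk_template(r), pad_input=True)
        better = resp > acc
        acc[better] = resp[better]
        best_r[better] = r

    threshold = 1.0 - params.sensitivity
    # absolute gate: peak intensity must clear the robust noise floor
    mad = float(np.median(np.abs(filtered - np.median(filtered))))
    floor = params.noise_floor_k * 1.4826 * mad
    if not np.any(acc >= threshold):
        return []
    peaks = peak_local_max(acc, min_distance=max(int(np.floor(lo)), 1),
                           threshold_abs=threshold, exclude_border=False)

    h, w = filtered.shape
    detections: List[Detection] = []
    for py, px in peaks:
        if filtered[py, px] < floor:
            continue
        r = best_r[py, px]
        x, y = _weighted_centroid(filtered, px, py, r)
        x = float(np.clip(x, 0, w - 1))
        y = float(np.clip(y, 0, h - 1))
        detections.append(Detection(frame_index=0, x=x, y=y,
                                    score=float(acc[py, px])))
    return detections


def _weighted_centroid(img: np.ndarray, px: int, py: int, radius: float):
    """Intensity-weighted centroid of positive pixels within the disk."""
    r_int = int(np.ceil(radius))
    h, w = img.shape
    y0, y1 = max(py - r_int, 0), min(py + r_int + 1, h)
    x0, x1 = max(px - r_int, 0), min(px + r_int + 1, w)
    patch = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (np.hypot(xx - px, yy - py) <= radius) & (patch > 0)
    wts = np.where(mask, patch, 0.0)
    total = wts.sum()
    if total <= 0:
        return float(px), float(py)
    return float((wts * xx).sum() / total), float((wts * yy).sum() / total)


def detect_stack(stack: FrameStack, params: AcquisitionParams) -> List[List[Detection]]:
    """Run preprocessing and head detection over every frame of a stack.

    Returns one detection list per frame, in frame order, with
    ``frame_index`` set.  A frame with no heads contributes an empty list.
    """
    if len(stack) == 0:
        raise ValidationError("no frames")
    per_frame: List[List[Detection]] = []
    for i, frame in enumerate(stack.frames):
        filtered = preprocess_frame(frame, params)
        dets = [Detection(frame_index=i, x=d.x, y=d.y, score=d.score)
                for d in detect_heads(filtered, params)]
        per_frame.append(dets)
        log.debug("frame %d: %d detections", i, len(dets))
    log.info("detected %d ACs over %d frames",
             sum(len(d) for d in per_frame), len(per_frame))
    return per_frame
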