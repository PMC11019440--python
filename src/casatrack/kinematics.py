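"""CASA kinematic parameters, noise filters and motility classification.

For a track P1..PN sampled at frame rate FR with sample-plane scale gamma
(um/pixel):

* VSL (straight-line velocity) = d(P1, PN) * FR / (N - 1) * gamma
* VCL (curvilinear velocity)   = sum_i d(Pi, Pi+1) * FR / (N - 1) * gamma
* LIN (linearity)              = VSL / VCL * 100

Velocity sub-populations follow the bovine SCA-style VCL cutoffs: slow
progressive [25, 80), medium progressive [80, 150), rapid progressive
[150, inf) um/s; tracks below 25 um/s are left unclassified and excluded
from the three-class percentages.  The half-open convention resolves the
measure-zero boundary cases the strict printed inequalities leave open.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Tuple

import numpy as np

from .config import AcquisitionParams
from .core import KinematicsRecord, Track, UNCLASSIFIED, ValidationError

log = logging.getLogger(__name__)

#: VCL class cutoffs in um/s: [25, 80) slow, [80, 150) medium, [150, inf) rapid.
VCL_CUTOFFS = (25.0, 80.0, 150.0)


class UndefinedTrackError(ValidationError):
    """Kinematics requested on a track with fewer than 2 points."""


def _check_track(track: Track) -> None:
    if track.n_points < 2:
        raise UndefinedTrackError("kinematics need at least 2 points")
    if not track.is_frame_consecutive:
        raise ValidationError(
            "kinematics require a frame-consecutive track; interpolate gaps first")


def compute_vsl(track: Track, frame_rate: float, um_per_pixel: float) -> float:
    """Straight-line velocity in um/s."""
    _check_track(track)
    d = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    return d * frame_rate / (track.n_points - 1) * um_per_pixel


def compute_vcl(track: Track, frame_rate: float, um_per_pixel: float) -> float:
    """Curvilinear velocity in um/s."""
    _check_track(track)
    return float(track.step_lengths().sum()) * frame_rate / (track.n_points - 1) * um_per_pixel


def compute_lin(vsl: float, vcl: float) -> float:
    """Linearity VSL/VCL in percent; undefined for VCL = 0."""
    if vcl <= 0:
        raise ValidationError("LIN is undefined for VCL = 0 (immotile)")
    return float(np.clip(100.0 * vsl / vcl, 0.0, 100.0))


def classify(vcl: float) -> str:
    """Motility class from VCL (um/s) using the half-open band convention."""
    if vcl < 0:
        raise ValidationError("VCL must be >= 0")
    slow, medium, rapid = VCL_CUTOFFS
    if vcl < slow:
        return UNCLASSIFIED
    if vcl < medium:
        return "slow"
    if vcl < rapid:
        return "medium"
    return "rapid"


def evaluate_track(track: Track, params: AcquisitionParams) -> KinematicsRecord:
    """VSL, VCL, LIN and motility class for one track.

    A track with zero path length (VCL = 0) is immotile: LIN is reported as
    0 and the record is left unclassified.
    """
    vsl = compute_vsl(track, params.frame_rate, params.um_per_pixel)
    vcl = compute_vcl(track, params.frame_rate, params.um_per_pixel)
    if vcl > 0:
        lin = compute_lin(vsl, vcl)
        cls = classify(vcl)
    else:
        lin = 0.0
        cls = UNCLASSIFIED
    return KinematicsRecord(track_id=track.track_id, n_points=track.n_points,
                            vsl=vsl, vcl=vcl, lin=lin, motility_class=cls)


def evaluate_tracks(tracks: Sequence[Track],
                    params: AcquisitionParams) -> List[KinematicsRecord]:
    return [evaluate_track(t, params) for t in tracks]


def filter_tracks(records: Sequence[KinematicsRecord],
                  params: AcquisitionParams,
                  ) -> Tuple[List[KinematicsRecord], List[Tuple[KinematicsRecord, str]]]:
    """Apply the noise and immotile filters.

    A record is kept iff length >= ``min_track_length`` AND
    VSL >= ``min_vsl`` AND LIN >= ``min_lin``.  Checks run in that order
    (length and VSL cut tracking noise; the LIN floor cuts immotile cells
    and out-of-focus objects) and a reject reports only the first failed
    criterion.  Returns ``(kept, rejects)`` with rejects as
    ``(record, reason)`` and reason in {"length", "vsl", "lin"}.
    """
    kept: List[KinematicsRecord] = []
    rejects: List[Tuple[KinematicsRecord, str]] = []
    for rec in records:
        if rec.n_points < params.min_track_length:
            rejects.append((rec, "length"))
        elif rec.vsl < params.min_vsl:
            rejects.append((rec, "vsl"))
        elif rec.lin < params.min_lin:
            rejects.append((rec, "lin"))
        else:
            kept.append(rec)
    log.info("filters: kept %d, rejected %d", len(kept), len(rejects))
    return kept, rejects
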