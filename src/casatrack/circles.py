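"""Circular-trajectory detection via Pratt's algebraic circle fit.

A circle is written algebraically as ``a(x^2 + y^2) + b x + c y + d = 0``.
Pratt's method minimises the algebraic residual ``||Z v||`` over parameter
vectors ``v = (a, b, c, d)`` under the normalisation ``b^2 + c^2 - 4ad = 1``,
which removes the trivial solution and makes the algebraic residual a close
proxy for geometric distance.  The constrained minimisation reduces to a
generalised eigenproblem ``M v = eta B v`` with ``M`` the data scatter matrix
and ``B`` the constraint matrix; the optimum is the eigenvector of the
smallest non-negative eigenvalue.  The fit is invariant under translation
and rotation and equivariant under scaling.

Whether a fitted track counts as a circular swimmer is decided by an
explicit, configurable criterion (relative residual, accumulated turning
angle, radius cap), so circle statistics are fully reproducible rather than
a manual call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .config import AcquisitionParams
from .core import CircleFit, CasatrackError, KinematicsRecord, MOTILITY_CLASSES, Track


class DegenerateFitError(CasatrackError):
    """Circle fit impossible: fewer than 3 points or (near-)collinear data."""


_B = np.array([[0.0, 0.0, 0.0, -2.0],
               [0.0, 1.0, 0.0, 0.0],
               [0.0, 0.0, 1.0, 0.0],
               [-2.0, 0.0, 0.0, 0.0]])


def pratt_fit(points: Sequence) -> CircleFit:
    """Fit a circle to 2-D points (micrometres) by Pratt's method.

    Returns centre, radius, RMS orthogonal residual and the signed total
    turning angle of the ordered point sequence about the fitted centre.
    Raises :class:`DegenerateFitError` for < 3 points or collinear data
    (infinite radius).
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    n = len(pts)
    if n < 3:
        raise DegenerateFitError("a circle fit needs at least 3 points")

    centroid = pts.mean(axis=0)
    xy = pts - centroid            # centring for numerical conditioning
    scale = float(np.sqrt((xy**2).sum(axis=1).mean()))
    if scale <= 0:
        raise DegenerateFitError("all points coincide")
    xy = xy / scale

    z = (xy**2).sum(axis=1)
    Z = np.column_stack([z, xy[:, 0], xy[:, 1], np.ones(n)])
    M = Z.T @ Z / n

    eigvals, eigvecs = linalg.eig(M, _B)
    eigvals = np.real_if_close(eigvals)
    real = np.isfinite(eigvals.real) & (np.abs(eigvals.imag) < 1e-8)
    candidates = [(val.real, eigvecs[:, i].real)
                  for i, val in enumerate(eigvals) if real[i]]
    # smallest non-negative eigenvalue (tiny negatives are round-off)
    candidates = [(v, vec) for v, vec in candidates if v > -1e-9]
    if not candidates:
        raise DegenerateFitError("no admissible Pratt solution")
    _, v = min(candidates, key=lambda t: t[0])

    a, b, c, d = v
    if abs(a) < 1e-12:
        raise DegenerateFitError("collinear points: infinite radius")
    cx_n = -b / (2.0 * a)
    cy_n = -c / (2.0 * a)
    r2 = (b * b + c * c - 4.0 * a * d) / (4.0 * a * a)
    if r2 <= 0:
        raise DegenerateFitError("degenerate circle (non-positive radius)")
    radius_n = float(np.sqrt(r2))

    centre = np.array([cx_n, cy_n]) * scale + centroid
    radius = radius_n * scale
    dists = np.linalg.norm(pts - centre, axis=1)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return CircleFit(cx=float(centre[0]), cy=float(centre[1]), radius=radius,
                     rms_residual=rms,
                     turning_angle=_turning_angle(pts, centre))


def _turning_angle(pts: np.ndarray, centre: np.ndarray) -> float:
    """Signed total angle swept about ``centre`` along the point order."""
    ang = np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0])
    d = np.diff(ang)
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    return float(d.sum())


def fit_track(track: Track, params: AcquisitionParams) -> Optional[CircleFit]:
    """Pratt fit of a track in micrometres; ``None`` when degenerate."""
    try:
        return pratt_fit(track.xy_um(params.um_per_pixel))
    except DegenerateFitError:
        return None


def is_circular(fit: Optional[CircleFit], params: AcquisitionParams) -> bool:
    """Automatic circular-swimmer criterion.

    True iff the relative fit residual is small
    (rms/R <= ``circle_residual_tol``), the trajectory accumulates at least
    ``circle_min_turning`` radians of turning about the fitted centre (a
    drifting circle accumulates beyond 2*pi), and the radius does not exceed
    ``circle_max_radius`` um (a straight track fits a huge circle well).
    """
    if fit is None:
        return False
    return (fit.rms_residual / fit.radius <= params.circle_residual_tol
            and abs(fit.turning_angle) >= params.circle_min_turning
            and fit.radius <= params.circle_max_radius)


def annotate_circles(records: Sequence[KinematicsRecord],
                     tracks: Sequence[Track],
                     params: AcquisitionParams) -> List[CircleFit]:
    """Fit every track, set circle flags/radii on the matching records.

    ``records`` and ``tracks`` are aligned by position.  Returns the fits
    (``None`` entries for degenerate tracks).
    """
    fits: List[Optional[CircleFit]] = []
    for rec, trk in zip(records, tracks):
        fit = fit_track(trk, params)
        flag = is_circular(fit, params)
        rec.is_circular = flag
        rec.circle_radius = fit.radius if flag else None
        fits.append(fit)
    return fits


def summarize_circles(records: Sequence[KinematicsRecord]) -> pd.DataFrame:
    """Counts, percentages and radii of circular swimmers per motility class.

    Percentages are over the circular swimmers (how the circular population
    divides among classes).  Empty input yields an empty frame.
    """
    circular = [r for r in records if r.is_circular]
    if not circular:
        return pd.DataFrame(columns=["class", "n", "pct_of_circular",
                                     "mean_radius_um", "std_radius_um"])
    total = len(circular)
    rows = []
    for cls in (*MOTILITY_CLASSES, "unclassified"):
        radii = np.array([r.circle_radius for r in circular
                          if r.motility_class == cls], dtype=float)
        if len(radii) == 0:
            continue
        rows.append({"class": cls, "n": len(radii),
                     "pct_of_circular": 100.0 * len(radii) / total,
                     "mean_radius_um": float(radii.mean()),
                     "std_radius_um": float(radii.std(ddof=1)) if len(radii) > 1 else 0.0})
    return pd.DataFrame(rows)
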