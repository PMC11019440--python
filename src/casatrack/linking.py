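"""Assemble per-frame detections into trajectories.

Frame-to-frame linking solves a global linear assignment (Hungarian
algorithm) on the pairwise distance matrix: among the assignments that pair
as many detections as possible at distances not exceeding the maximum
linking distance D, the one minimising the total paired distance is chosen.
Pairs beyond D are *forbidden*, not merely penalised.  Tracks that were
interrupted by missed detections are then repaired in a gap-closing pass
(nearest-pair-first greedy merge under frame and distance budgets), missing
frames are filled by linear interpolation, and tracks containing an
anomalously large jump -- a symptom of a wrong merge or identity swap -- are
split at the offending step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import AcquisitionParams
from .core import Detection, Track

log = logging.getLogger(__name__)

# finite stand-ins for "unmatched" and "forbidden" in the augmented
# assignment matrix; any feasible pairing (<= D um) is always preferred to
# leaving two detections unmatched, and forbidden cells are never selected.
_UNMATCHED_COST = 1.0e6
_FORBIDDEN_COST = 1.0e12


@dataclass
class Assignment:
    """Optimal one-to-one linking between two consecutive detection sets."""

    pairs: List[Tuple[int, int]] = field(default_factory=list)
    unmatched_prev: List[int] = field(default_factory=list)
    unmatched_next: List[int] = field(default_factory=list)
    total_cost: float = 0.0  # um, sum over paired distances


def _positions(dets: Sequence[Detection]) -> np.ndarray:
    if len(dets) == 0:
        return np.empty((0, 2))
    return np.array([[d.x, d.y] for d in dets], dtype=np.float64)


def link_frames(prev: Sequence[Detection], next_: Sequence[Detection],
                max_link_distance: float, um_per_pixel: float) -> Assignment:
    """Globally optimal assignment of ACs between two consecutive frames.

    Distances are evaluated in micrometres; pairs farther apart than
    ``max_link_distance`` are infeasible.  Empty inputs yield an empty
    assignment.
    """
    n, m = len(prev), len(next_)
    if n == 0 or m == 0:
        return Assignment(unmatched_prev=list(range(n)),
                          unmatched_next=list(range(m)))
    dist = cdist(_positions(prev), _positions(next_)) * float(um_per_pixel)
    feasible = dist <= max_link_distance

    size = n + m
    cost = np.full((size, size), _FORBIDDEN_COST)
    cost[:n, :m] = np.where(feasible, dist, _FORBIDDEN_COST)
    cost[n:, m:] = 0.0
    for i in range(n):                   # leave i of prev unmatched
        cost[i, m + i] = _UNMATCHED_COST
    for j in range(m):                   # leave j of next unmatched
        cost[n + j, j] = _UNMATCHED_COST

    rows, cols = linear_sum_assignment(cost)
    out = Assignment()
    matched_next = set()
    for r, c in zip(rows, cols):
        if r < n and c < m and feasible[r, c]:
            out.pairs.append((r, c))
            out.total_cost += dist[r, c]
            matched_next.add(c)
    matched_prev = {p for p, _ in out.pairs}
    out.unmatched_prev = [i for i in range(n) if i not in matched_prev]
    out.unmatched_next = [j for j in range(m) if j not in matched_next]
    return out


def build_tracks(detections_by_frame: Sequence[Sequence[Detection]],
                 params: AcquisitionParams) -> List[Track]:
    """Chain frame-consecutive links into maximal tracks.

    ``detections_by_frame[t]`` holds the detections of frame ``t``.  A track
    ends when its AC finds no partner within D in the next frame; chains
    shorter than 2 points are dropped.
    """
    tracks = []
    for frames, xy in _chains(detections_by_frame, params):
        if len(frames) < 2:
            continue
        tracks.append(Track(track_id=len(tracks), frames=frames, xy=xy))
    log.info("built %d tracks from %d frames", len(tracks),
             len(detections_by_frame))
    return tracks


def _chains(detections_by_frame: Sequence[Sequence[Detection]],
            params: AcquisitionParams) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Maximal frame-consecutive link chains, singletons included.

    Returns ``(frames, xy)`` array pairs.  Singleton chains are kept here so
    gap closing can use an isolated detection as a stepping stone between
    two fragments; :func:`build_tracks` drops them for its public contract.
    """
    open_chains: dict = {}   # index in current frame -> list[(frame, x, y)]
    finished: List[List[Tuple[int, float, float]]] = []

    prev_dets: Sequence[Detection] = []
    for t in range(len(detections_by_frame)):
        cur = detections_by_frame[t]
        assign = link_frames(prev_dets, cur, params.max_link_distance,
                             params.um_per_pixel)
        new_chains: dict = {}
        for p, c in assign.pairs:
            chain = open_chains.pop(p)
            chain.append((t, cur[c].x, cur[c].y))
            new_chains[c] = chain
        # chains whose AC went unmatched terminate here
        finished.extend(open_chains.values())
        for j in assign.unmatched_next:
            new_chains[j] = [(t, cur[j].x, cur[j].y)]
        open_chains = new_chains
        prev_dets = cur
    finished.extend(open_chains.values())

    out = []
    for chain in finished:
        arr = np.array(chain)
        out.append((arr[:, 0].astype(np.int64), arr[:, 1:3]))
    out.sort(key=lambda fr: (int(fr[0][0]), float(fr[1][0, 0]),
                             float(fr[1][0, 1])))
    return out


def close_gaps(tracks: List[Track], params: AcquisitionParams) -> List[Track]:
    """Merge track fragments separated by a detection gap.

    A fragment starting within ``gap_max_distance`` um of another fragment's
    endpoint, with 1..``gap_max_frames`` missing frames in between, is
    appended to it.  Candidate pairs are consumed greedily in ascending
    distance order (ties: smaller frame gap, then lower track id), and the
    pass repeats until no eligible pair remains, so the outcome does not
    depend on input order.
    """
    if params.gap_max_frames < 1 or not tracks:
        return list(tracks)
    frags = [(t.frames, t.xy, t.interpolated) for t in tracks]
    merged = _close_fragments(frags, params)
    out = [Track(i, fr, xy, interp)
           for i, (fr, xy, interp) in enumerate(merged)]
    log.info("gap closing: %d merges, %d tracks remain",
             len(tracks) - len(out), len(out))
    return out


def _close_fragments(frags, params: AcquisitionParams):
    """Greedy nearest-pair-first gap closing over ``(frames, xy[, interp])``
    fragments (singletons allowed).

    Candidates are end->start pairs with 1..G missing frames and end
    distance <= D_gapclosing, consumed in ascending (distance, frame gap,
    fragment order).  Merging a's end onto b's start never creates a new
    candidate endpoint (the merged fragment keeps a's start and b's end), so
    one sorted pass over the precomputed candidates realises the
    repeat-until-stable nearest-neighbour merge exactly.
    """
    if not frags:
        return []
    frags = [(np.asarray(f[0]), np.asarray(f[1]),
              np.asarray(f[2]) if len(f) > 2 else np.zeros(len(f[0]), bool))
             for f in frags]
    ends = np.array([f[1][-1] for f in frags])
    starts = np.array([f[1][0] for f in frags])
    end_frames = np.array([f[0][-1] for f in frags])
    start_frames = np.array([f[0][0] for f in frags])

    gaps = start_frames[None, :] - end_frames[:, None] - 1
    dist = cdist(ends, starts) * params.um_per_pixel
    ok = ((gaps >= 1) & (gaps <= params.gap_max_frames)
          & (dist <= params.gap_max_distance))
    np.fill_diagonal(ok, False)
    ai, bi = np.nonzero(ok)
    order = sorted(range(len(ai)),
                   key=lambda k: (dist[ai[k], bi[k]], gaps[ai[k], bi[k]],
                                  int(ai[k]), int(bi[k])))
    succ = {}
    end_used, start_used = set(), set()
    for k in order:
        a, b = int(ai[k]), int(bi[k])
        if a in end_used or b in start_used:
            continue
        succ[a] = b
        end_used.add(a)
        start_used.add(b)

    out = []
    for i, frag in enumerate(frags):
        if i in start_used:
            continue  # consumed as a continuation of an earlier fragment
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        parts = [frags[j] for j in chain]
        out.append((np.concatenate([p[0] for p in parts]),
                    np.concatenate([p[1] for p in parts]),
                    np.concatenate([p[2] for p in parts])))
    return out


def interpolate_gaps(track: Track) -> Track:
    """Fill missing frames by linear interpolation, flagging filled points."""
    if track.is_frame_consecutive:
        return track
    full_frames = np.arange(track.frames[0], track.frames[-1] + 1)
    x = np.interp(full_frames, track.frames, track.xy[:, 0])
    y = np.interp(full_frames, track.frames, track.xy[:, 1])
    interp = np.ones(len(full_frames), dtype=bool)
    interp[np.searchsorted(full_frames, track.frames)] = track.interpolated
    return Track(track.track_id, full_frames, np.column_stack([x, y]), interp)


def split_anomalous(track: Track, split_factor: float) -> List[Track]:
    """Split a track at anomalously large jumps.

    If any consecutive step exceeds ``split_factor`` times the mean step of
    the track, the track is split in two at the first such step; both halves
    are then re-examined recursively.  Pieces shorter than 2 points are
    discarded.  The operation is idempotent.
    """
    steps = track.step_lengths()
    mean_step = steps.mean()
    if mean_step <= 0:
        return [track]
    offending = np.nonzero(steps > split_factor * mean_step)[0]
    if len(offending) == 0:
        return [track]
    i = int(offending[0])
    pieces: List[Track] = []
    for sl in (slice(0, i + 1), slice(i + 1, None)):
        frames, xy, interp = track.frames[sl], track.xy[sl], track.interpolated[sl]
        if len(frames) < 2:
            continue
        piece = Track(track.track_id, frames, xy, interp)
        pieces.extend(split_anomalous(piece, split_factor))
    return pieces


def track_pipeline(detections_by_frame: Sequence[Sequence[Detection]],
                   params: AcquisitionParams) -> List[Track]:
    """Full trajectory assembly: link, close gaps, interpolate, split.

    Gap closing here runs over all link chains including isolated single
    detections, so a fragment pair bridged by a stepping-stone detection is
    still restored; only merged chains of >= 2 points become tracks.  Track
    ids are renumbered 0..n-1 in (first frame, position) order so output is
    deterministic.
    """
    chains = _chains(detections_by_frame, params)
    merged = _close_fragments(
        [(fr, xy, np.zeros(len(fr), bool)) for fr, xy in chains], params)
    tracks = [Track(i, fr, xy, interp)
              for i, (fr, xy, interp) in enumerate(merged) if len(fr) >= 2]
    tracks = [interpolate_gaps(t) for t in tracks]
    split: List[Track] = []
    n_splits = 0
    for t in tracks:
        pieces = split_anomalous(t, params.split_factor)
        n_splits += len(pieces) - 1
        split.extend(pieces)
    split.sort(key=lambda t: (int(t.frames[0]), t.track_id))
    out = [Track(i, t.frames, t.xy, t.interpolated)
           for i, t in enumerate(split)]
    log.info("pipeline: %d tracks after %d splits", len(out), n_splits)
    return out
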