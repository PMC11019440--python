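"""Shared fixtures and synthetic geometry helpers."""

from __future__ import annotations

import math
from typing import List, Sequence

import numpy as np
import pytest

from casatrack import AcquisitionParams, SwimmerSpec


@pytest.fixture
def params() -> AcquisitionParams:
    return AcquisitionParams()


def lane_specs(speeds_um_s: Sequence[float], field_um, seed: int = 0,
               margin_um: float = 8.0) -> List[SwimmerSpec]:
    """Parallel horizontal swimmers in separate lanes (never cross).

    Wobble amplitude is capped at a third of the lane spacing so neighbours
    stay well separated; used to probe linking and recovery without the
    confound of identity swaps at physical crossings.
    """
    rng = np.random.default_rng(seed)
    w, h = field_um
    n = len(speeds_um_s)
    lane_y = np.linspace(margin_um, h - margin_um, n + 2)[1:-1]
    spacing = (h - 2 * margin_um) / (n + 1)
    specs = []
    for vcl, y in zip(speeds_um_s, lane_y):
        freq = float(rng.uniform(8.0, 15.0))
        amp = min(0.1 * vcl / freq, spacing / 3.0)
        specs.append(SwimmerSpec(
            motion_kind="straight_wobble", vcl_um_s=float(vcl),
            start_um=(float(rng.uniform(margin_um, w - margin_um)), float(y)),
            heading_rad=0.0, wobble_amplitude_um=amp, wobble_freq_hz=freq,
            wobble_phase_rad=float(rng.uniform(0, 2 * math.pi))))
    return specs


def brute_force_assignment(prev_xy: np.ndarray, next_xy: np.ndarray,
                           max_dist: float):
    """Exhaustive-enumeration linking oracle.

    Among all partial one-to-one matchings whose pairs lie within
    ``max_dist``, prefer more pairs, then lower total distance.  Returns
    ``(n_matches, total_cost)``.  Independent of the Hungarian solver.
    """
    n, m = len(prev_xy), len(next_xy)
    if n and m:
        dist = np.linalg.norm(prev_xy[:, None, :] - next_xy[None, :, :], axis=2)
    best = [0, 0.0]

    def rec(i: int, used: int, matches: int, cost: float) -> None:
        if i == n:
            if matches > best[0] or (matches == best[0] and cost < best[1]):
                best[0], best[1] = matches, cost
            return
        rec(i + 1, used, matches, cost)
        for j in range(m):
            if not used & (1 << j) and dist[i, j] <= max_dist:
                rec(i + 1, used | (1 << j), matches + 1, cost + dist[i, j])

    rec(0, 0, 0, 0.0)
    return best[0], best[1]
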