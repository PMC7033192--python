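"""From multi-agent trajectories to weighted adjacency-matrix series.

Positions of ten players (five attackers, five defenders), the ball and a
fixed goal ("ring") are converted into an 11-node graph per frame: nodes
are the players and the ring, and the edge weight between nodes ``i`` and
``j`` is the Gaussian kernel of their distance,

    A_ij = exp(-||y_i - y_j||^2 / (2 sigma)),

which is 1 for coincident agents and decays to 0 with separation.  The
bandwidth ``sigma`` is calibrated through the distance at which the weight
is 0.5 (1.5 m for player pairs, 6 m for player-ring pairs by default).

Because agent identity is arbitrary across segments, node slots are
assigned by a greedy ball-proximity rule: the two attackers nearest the
ball fill slots A1 and A2, each further attacker is the one minimising the
summed distance to the already-placed attackers, defenders fill D1-D5 by
the identical rule, and the ring is the last slot.  The ball itself is not
a graph node; it only anchors the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ValidationError
from .spectral import SnapshotTensor

ATTACKER = "attacker"
DEFENDER = "defender"
BALL = "ball"
RING = "ring"

ROLES = (ATTACKER, DEFENDER, BALL, RING)

#: node-slot names in matrix order (ball excluded; 11 nodes)
SLOT_NAMES = ("A1", "A2", "A3", "A4", "A5", "D1", "D2", "D3", "D4", "D5", "R")

#: half-weight distances calibrating the kernel bandwidths (metres)
PLAYER_HALF_DISTANCE_M = 1.5
RING_HALF_DISTANCE_M = 6.0


@dataclass(frozen=True)
class TrajectorySegment:
    """Per-frame 2-D agent positions with roles.

    ``positions`` has shape ``(n_agents, T, 2)`` in metres; ``roles`` gives
    one of ``attacker | defender | ball | ring`` per agent.  When the
    basketball-style ordering is used the segment must contain exactly one
    ball and one ring, and the ring must not move.
    """

    positions: np.ndarray
    roles: tuple
    fps: float
    segment_id: str = "segment"
    label: Optional[int] = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "roles", tuple(self.roles))
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValidationError(f"positions must have shape (n, T, 2), got {pos.shape}")
        if len(self.roles) != pos.shape[0]:
            raise ValidationError("one role per agent required")
        for role in self.roles:
            if role not in ROLES:
                raise ValidationError(f"unknown role {role!r}")
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"segment {self.segment_id}: non-finite positions")
        if not self.fps > 0:
            raise ValidationError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def role_indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)


def _require_full_lineup(segment: TrajectorySegment) -> None:
    counts = {role: len(segment.role_indices(role)) for role in ROLES}
    expected = {ATTACKER: 5, DEFENDER: 5, BALL: 1, RING: 1}
    if counts != expected:
        raise ValidationError(
            f"segment {segment.segment_id}: need 5 attackers, 5 defenders, "
            f"1 ball, 1 ring; got {counts}"
        )
    ring = segment.positions[segment.role_indices(RING)[0]]
    if np.ptp(ring, axis=0).max() > 1e-9:
        raise ValidationError(f"segment {segment.segment_id}: ring position must be constant")


def lowpass_filter(
    segment: TrajectorySegment, cutoff_hz: float = 2.0, order: int = 2
) -> TrajectorySegment:
    """Zero-phase Butterworth low-pass of every moving agent's coordinates.

    A second-order filter applied forward and backward (``filtfilt``), so
    the effective magnitude response is the squared Butterworth response
    and no phase lag is introduced.  The ring is left untouched.
    """
    if not segment.fps > 2.0 * cutoff_hz:
        raise ValidationError("sampling rate must exceed twice the cutoff frequency")
    b, a = butter(order, cutoff_hz, btype="low", fs=segment.fps)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if segment.n_frames <= padlen:
        raise ValidationError(
            f"segment {segment.segment_id}: {segment.n_frames} frames is too short "
            f"for the filter warm-up ({padlen + 1} required)"
        )
    out = segment.positions.copy()
    for i, role in enumerate(segment.roles):
        if role == RING:
            continue
        out[i] = filtfilt(b, a, segment.positions[i], axis=0)
    return replace(segment, positions=out)


def _greedy_order(points: np.ndarray, indices: np.ndarray, ball_xy: np.ndarray) -> list:
    """Greedy ball-proximity ordering of one role group.

    The two agents nearest the ball come first (ascending distance); each
    subsequent slot takes the remaining agent with the smallest summed
    distance to the agents already placed.  Ties break on the lowest
    original agent index.
    """
    d_ball = np.linalg.norm(points - ball_xy, axis=1)
    by_ball = sorted(range(len(indices)), key=lambda k: (d_ball[k], indices[k]))
    chosen = [by_ball[0], by_ball[1]]
    remaining = [k for k in range(len(indices)) if k not in chosen]
    while remaining:
        sums = {
            k: float(np.sum(np.linalg.norm(points[chosen] - points[k], axis=1)))
            for k in remaining
        }
        nxt = min(remaining, key=lambda k: (sums[k], indices[k]))
        chosen.append(nxt)
        remaining.remove(nxt)
    return [int(indices[k]) for k in chosen]


def order_nodes(frame_positions: np.ndarray, roles: Sequence[str]) -> np.ndarray:
    """Assign the 11 node slots (A1-A5, D1-D5, R) for one frame.

    Returns an array of 11 agent indices, one per slot in
    :data:`SLOT_NAMES` order.  Requires exactly 5 attackers, 5 defenders,
    1 ball and 1 ring among the agents.
    """
    pos = np.asarray(frame_positions, dtype=float)
    roles = tuple(roles)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] != len(roles):
        raise ValidationError("frame_positions must be (n_agents, 2) matching roles")
    groups = {role: np.array([i for i, r in enumerate(roles) if r == role]) for role in ROLES}
    if (
        len(groups[ATTACKER]) != 5
        or len(groups[DEFENDER]) != 5
        or len(groups[BALL]) != 1
        or len(groups[RING]) != 1
    ):
        raise ValidationError(
            "ordering requires exactly 5 attackers, 5 defenders, 1 ball, 1 ring"
        )
    ball_xy = pos[groups[BALL][0]]
    slots = _greedy_order(pos[groups[ATTACKER]], groups[ATTACKER], ball_xy)
    slots += _greedy_order(pos[groups[DEFENDER]], groups[DEFENDER], ball_xy)
    slots.append(int(groups[RING][0]))
    return np.array(slots, dtype=int)


def sigma_from_half_distance(d_half: float) -> float:
    """Kernel bandwidth such that the weight equals 0.5 at distance ``d_half``.

    Solves ``exp(-d_half^2 / (2 sigma)) = 1/2``, i.e.
    ``sigma = d_half^2 / (2 ln 2)``.
    """
    if not d_half > 0:
        raise ValidationError("half-weight distance must be positive")
    return d_half**2 / (2.0 * log(2.0))


def gaussian_kernel(distances: np.ndarray, sigma: float) -> np.ndarray:
    """Proximity weights ``exp(-d^2 / (2 sigma))`` for an array of distances."""
    return np.exp(-np.asarray(distances, dtype=float) ** 2 / (2.0 * sigma))


def build_adjacency(
    segment: TrajectorySegment,
    sigma_players: Optional[float] = None,
    sigma_ring: Optional[float] = None,
    ordering: str = "per_frame",
) -> SnapshotTensor:
    """Kernel adjacency series over the ordered 11 nodes of a segment.

    ``ordering='per_frame'`` recomputes the slot assignment every frame (the
    default); ``'per_segment'`` freezes the first frame's assignment.  The
    ring bandwidth applies to every pair involving the ring slot, the
    player bandwidth to all other pairs; the diagonal is 1 by construction.
    """
    _require_full_lineup(segment)
    if ordering not in ("per_frame", "per_segment"):
        raise ValidationError(f"unknown ordering mode {ordering!r}")
    if sigma_players is None:
        sigma_players = sigma_from_half_distance(PLAYER_HALF_DISTANCE_M)
    if sigma_ring is None:
        sigma_ring = sigma_from_half_distance(RING_HALF_DISTANCE_M)
    if not (sigma_players > 0 and sigma_ring > 0):
        raise ValidationError("kernel bandwidths must be positive")

    T = segment.n_frames
    m = 11
    ring_slot = m - 1
    sigma = np.full((m, m), float(sigma_players))
    sigma[ring_slot, :] = sigma[:, ring_slot] = float(sigma_ring)

    frozen = order_nodes(segment.positions[:, 0, :], segment.roles)
    values = np.empty((m, m, T))
    for t in range(T):
        if ordering == "per_frame":
            perm = order_nodes(segment.positions[:, t, :], segment.roles)
        else:
            perm = frozen
        pts = segment.positions[perm, t, :]
        diff = pts[:, None, :] - pts[None, :, :]
        sq = np.sum(diff**2, axis=2)
        W = np.exp(-sq / (2.0 * sigma))
        np.fill_diagonal(W, 1.0)
        values[:, :, t] = 0.5 * (W + W.T)  # guard rounding asymmetry
    return SnapshotTensor(values, dt=segment.dt)
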