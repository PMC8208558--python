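"""Motion-based multi-object tracking and unique-track counting.

Each target is tracked with a first-order (constant-velocity) Kalman filter
on the blob centroid: the state is (x, y, vx, vy) with accelerations fixed
at zero, reflecting animals tumbling through the field of view with the
water current at near-constant speed.  Detections are assigned to predicted
track positions with the Hungarian algorithm on a Euclidean-distance cost
matrix augmented with a non-assignment cost.  Tracks coast while unmatched
and are marked lost after a configurable miss streak; every unique track
that passes the confirmation gate contributes one unit to the automatic
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection
from .imaging import ConfigError

# constant-velocity transition and position-only measurement matrices
_F = np.array(
    [[1.0, 0.0, 1.0, 0.0],
     [0.0, 1.0, 0.0, 1.0],
     [0.0, 0.0, 1.0, 0.0],
     [0.0, 0.0, 0.0, 1.0]]
)
_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


@dataclass
class KalmanState:
    """State of one constant-velocity filter (pixels and pixels/frame)."""

    x: np.ndarray  # (4,) state vector (x, y, vx, vy)
    P: np.ndarray  # (4, 4) state covariance
    Q: np.ndarray  # (4, 4) process noise
    R: np.ndarray  # (2, 2) measurement noise

    @classmethod
    def init(
        cls,
        position: tuple[float, float],
        position_var: float = 200.0,
        velocity_var: float = 50.0,
        process_var: tuple[float, float] = (100.0, 25.0),
        measurement_var: float = 100.0,
    ) -> "KalmanState":
        """New filter at a measured position with zero initial velocity."""
        x = np.array([position[0], position[1], 0.0, 0.0])
        P = np.diag([position_var, position_var, velocity_var, velocity_var])
        Q = np.diag([process_var[0], process_var[0], process_var[1], process_var[1]])
        R = np.eye(2) * measurement_var
        return cls(x=x, P=P, Q=Q, R=R)

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.x[0]), float(self.x[1]))


def kalman_predict(k: KalmanState) -> KalmanState:
    """Time update: positions advance by one frame of velocity."""
    x = _F @ k.x
    P = _F @ k.P @ _F.T + k.Q
    return KalmanState(x=x, P=P, Q=k.Q, R=k.R)


def kalman_update(k: KalmanState, measurement: tuple[float, float]) -> KalmanState:
    """Measurement update with an observed centroid."""
    z = np.asarray(measurement, dtype=float)
    y = z - _H @ k.x
    S = _H @ k.P @ _H.T + k.R
    K = k.P @ _H.T @ np.linalg.solve(S.T, np.eye(2)).T
    x = k.x + K @ y
    P = (np.eye(4) - K @ _H) @ k.P
    # symmetrize against accumulated round-off
    P = (P + P.T) / 2.0
    return KalmanState(x=x, P=P, Q=k.Q, R=k.R)


@dataclass(frozen=True)
class TrackerConfig:
    """Lifecycle and assignment parameters.

    ``max_invisible`` is the miss streak after which a track is marked lost
    (the object has likely left the image); the confirmation gate
    (``min_visible_for_count`` and ``min_visibility_fraction``) suppresses
    short noise tracks from the automatic count.
    """

    max_invisible: int = 10
    min_visible_for_count: int = 8
    min_visibility_fraction: float = 0.6
    non_assignment_cost: float = 150.0

    def __post_init__(self) -> None:
        if min(self.max_invisible, self.min_visible_for_count) < 1:
            raise ConfigError("frame counts must be positive")
        if not (0 < self.min_visibility_fraction <= 1 and self.non_assignment_cost > 0):
            raise ConfigError("invalid tracker gate parameters")


@dataclass
class Track:
    """One tracked identity and its lifecycle counters."""

    id: int
    kalman: KalmanState
    first_frame: int
    age: int = 1
    total_visible: int = 1
    consecutive_invisible: int = 0
    status: str = "tentative"  # tentative | confirmed | lost
    last_frame: int = 0
    history: list[tuple[int, float, float]] = field(default_factory=list)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def visibility(self) -> float:
        """Fraction of frames with a detection over the track's visible span.

        The span runs from creation to the last assigned detection, so a
        coasting tail after the animal leaves the image does not dilute the
        confirmation gate.
        """
        span = max(1, self.last_frame - self.first_frame + 1)
        return self.total_visible / span


def assign(
    tracks: list[Track],
    detections: list[Detection],
    cfg: TrackerConfig,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal track-detection assignment.

    The cost matrix is the Euclidean distance between predicted track
    positions and detection centroids, padded with ``non_assignment_cost``
    dummy rows/columns so that any pairing more expensive than not pairing
    at all is dropped.  Returns (matched index pairs, unmatched track
    indices, unmatched detection indices).
    """
    nt, nd = len(tracks), len(detections)
    if nt == 0 or nd == 0:
        return [], list(range(nt)), list(range(nd))
    pred = np.array([t.kalman.position for t in tracks])  # (nt, 2)
    meas = np.array([d.centroid for d in detections])  # (nd, 2)
    cost = np.linalg.norm(pred[:, None, :] - meas[None, :, :], axis=2)

    # pad to (nt+nd) x (nd+nt): diagonal non-assignment blocks
    big = cost.max() + cfg.non_assignment_cost + 1.0
    padded = np.full((nt + nd, nd + nt), big)
    padded[:nt, :nd] = cost
    padded[:nt, nd:] = np.where(np.eye(nt, dtype=bool), cfg.non_assignment_cost, big)
    padded[nt:, :nd] = np.where(np.eye(nd, dtype=bool), cfg.non_assignment_cost, big)
    padded[nt:, nd:] = 0.0
    rows, cols = linear_sum_assignment(padded)

    pairs, unmatched_t, unmatched_d = [], [], []
    matched_d: set[int] = set()
    for r, c in zip(rows, cols):
        if r < nt and c < nd:
            pairs.append((r, c))
            matched_d.add(c)
    matched_t = {r for r, _ in pairs}
    unmatched_t = [i for i in range(nt) if i not in matched_t]
    unmatched_d = [j for j in range(nd) if j not in matched_d]
    return pairs, unmatched_t, unmatched_d


@dataclass
class TrackerState:
    """All live and lost tracks plus id bookkeeping."""

    tracks: list[Track] = field(default_factory=list)
    lost: list[Track] = field(default_factory=list)
    next_id: int = 1
    last_frame_index: int = -1


def step(
    state: TrackerState,
    detections: list[Detection],
    frame_index: int,
    cfg: TrackerConfig,
) -> TrackerState:
    """Advance the tracker by one frame of detections.

    Predict all live tracks, assign detections, update matched filters,
    age unmatched tracks, retire tracks whose miss streak exceeds
    ``max_invisible`` and seed new tracks from unmatched detections.
    """
    if frame_index <= state.last_frame_index:
        raise ConfigError(
            f"frame_index must increase (got {frame_index} after {state.last_frame_index})"
        )
    state.last_frame_index = frame_index

    for t in state.tracks:
        t.kalman = kalman_predict(t.kalman)
        t.age += 1

    pairs, unmatched_t, unmatched_d = assign(state.tracks, detections, cfg)

    for ti, di in pairs:
        t = state.tracks[ti]
        det = detections[di]
        t.kalman = kalman_update(t.kalman, det.centroid)
        t.total_visible += 1
        t.consecutive_invisible = 0
        t.last_frame = frame_index
        px, py = t.kalman.position
        t.history.append((frame_index, px, py))
        t.bboxes[frame_index] = det.bbox
        if t.status == "tentative" and t.total_visible >= 3:
            t.status = "confirmed"

    for ti in unmatched_t:
        t = state.tracks[ti]
        t.consecutive_invisible += 1
        px, py = t.kalman.position
        t.history.append((frame_index, px, py))

    still_live = []
    for t in state.tracks:
        if t.consecutive_invisible > cfg.max_invisible:
            t.status = "lost"
            state.lost.append(t)
        else:
            still_live.append(t)
    state.tracks = still_live

    for di in unmatched_d:
        det = detections[di]
        t = Track(
            id=state.next_id,
            kalman=KalmanState.init(det.centroid),
            first_frame=frame_index,
            last_frame=frame_index,
            history=[(frame_index, det.centroid[0], det.centroid[1])],
            bboxes={frame_index: det.bbox},
        )
        state.next_id += 1
        state.tracks.append(t)
    return state


@dataclass
class CountReport:
    """Automatic count plus per-track summaries."""

    total_count: int
    tracks: list[dict]

    def to_dict(self) -> dict:
        return {"total_count": self.total_count, "tracks": self.tracks}


def _counted(t: Track, cfg: TrackerConfig) -> bool:
    return (
        t.total_visible >= cfg.min_visible_for_count
        and t.visibility >= cfg.min_visibility_fraction
    )


def finalize_count(state: TrackerState, cfg: TrackerConfig) -> CountReport:
    """Tally unique tracks that pass the confirmation gate.

    Tracks still active when the video ends are included; tentative
    flickers below the gate are not.
    """
    summaries = []
    for t in state.lost + state.tracks:
        if not _counted(t, cfg):
            continue
        path = np.array([(x, y) for _, x, y in t.history])
        path_length = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum()) if len(path) > 1 else 0.0
        summaries.append(
            {
                "id": t.id,
                "first_frame": t.first_frame,
                "last_frame": t.last_frame,
                "total_visible": t.total_visible,
                "age": t.age,
                "path_length": path_length,
            }
        )
    summaries.sort(key=lambda s: s["id"])
    return CountReport(total_count=len(summaries), tracks=summaries)


def counted_tracks(state: TrackerState, cfg: TrackerConfig) -> list[Track]:
    """The Track objects behind :func:`finalize_count` (for evaluation)."""
    return sorted(
        (t for t in state.lost + state.tracks if _counted(t, cfg)),
        key=lambda t: t.id,
    )
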