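"""Turn calling: from centroid trajectories to left/right choice sequences.

A Y-maze has three symmetric 12-mm arms joined at a central hub. A fly's
centroid track is reduced to a sequence of arm visits (center -> arm
transitions), and each pair of consecutive *distinct* arms is scored as one
left or right turn. Re-entering the same arm is not a turn: the choice the
assay measures is between the two other arms.

Per-fly summaries (turn count, right-turn proportion, turns per minute) feed
the variability analysis; flies with fewer than 30 turns are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: factor levels used throughout the pipeline
PREDATOR_LEVELS = ("yes", "no")
DRUG_LEVELS = ("none", "5htp", "amw")

#: zone code for the central hub (arms are 0, 1, 2)
CENTER = -1


@dataclass(frozen=True)
class MazeGeometry:
    """Geometry of one Y-maze in millimeters.

    Arms are indexed 0..2 in increasing bearing order (bearings normalised to
    [0, 360)). ``center_radius`` bounds the hub zone; beyond it a point
    belongs to the arm whose 120-degree sector contains its bearing.
    """

    center: tuple[float, float] = (0.0, 0.0)
    arm_angles: tuple[float, float, float] = (0.0, 120.0, 240.0)
    arm_length: float = 12.0
    center_radius: float = 2.0
    angle_tol: float = 1.0

    def __post_init__(self) -> None:
        angles = tuple(sorted(a % 360.0 for a in self.arm_angles))
        if len(angles) != 3:
            raise ValueError("a Y-maze has exactly three arms")
        seps = np.diff(list(angles) + [angles[0] + 360.0])
        if not np.allclose(seps, 120.0, atol=self.angle_tol):
            raise ValueError(
                f"arm bearings must be 120 degrees apart (got separations {seps})"
            )
        if not 0 < self.center_radius < self.arm_length:
            raise ValueError("need 0 < center_radius < arm_length")
        object.__setattr__(self, "arm_angles", angles)

    @property
    def arm_angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.arm_angles))

    def arm_tip(self, arm: int) -> tuple[float, float]:
        th = self.arm_angles_rad[arm]
        return (
            self.center[0] + self.arm_length * np.cos(th),
            self.center[1] + self.arm_length * np.sin(th),
        )


@dataclass
class Trajectory:
    """Timestamped centroid positions of one fly (seconds, millimeters)."""

    fly_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"timestamps must be strictly increasing ({self.fly_id})")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"non-finite coordinates ({self.fly_id})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_min(self) -> float:
        return float(self.t[-1] - self.t[0]) / 60.0 if len(self.t) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fly_id": self.fly_id, "t_s": self.t, "x_mm": self.x, "y_mm": self.y}
        )


@dataclass
class ArmVisitSequence:
    """Ordered arm entries: which arm, and when it was entered."""

    arms: np.ndarray
    entry_times: np.ndarray

    def __post_init__(self) -> None:
        self.arms = np.asarray(self.arms, dtype=int)
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        if len(self.arms) != len(self.entry_times):
            raise ValueError("arms and entry_times must align")
        if len(self.entry_times) > 1 and not np.all(np.diff(self.entry_times) > 0):
            raise ValueError("entry times must be strictly increasing")
        if len(self.arms) and not np.isin(self.arms, [0, 1, 2]).all():
            raise ValueError("arm indices must be 0, 1 or 2")

    def __len__(self) -> int:
        return len(self.arms)


@dataclass
class TurnSequence:
    """Ordered left/right turn events with times in seconds.

    ``duration_min`` is the recording duration the rate is computed over,
    not the time of the last event.
    """

    times: np.ndarray
    directions: np.ndarray  # array of 'L' / 'R'
    duration_min: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.directions = np.asarray(self.directions, dtype="U1")
        if len(self.times) != len(self.directions):
            raise ValueError("times and directions must align")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if len(self.directions) and not np.isin(self.directions, ["L", "R"]).all():
            raise ValueError("directions must be 'L' or 'R'")
        if len(self.times) and (
            self.times.min() < 0 or self.times.max() > self.duration_min * 60.0 + 1e-9
        ):
            raise ValueError("event times must lie within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_right(self) -> int:
        return int((self.directions == "R").sum())

    @property
    def n_left(self) -> int:
        return int((self.directions == "L").sum())


@dataclass
class FlyRecord:
    """One fly's group factors and turn-behavior summary."""

    fly_id: str
    predator: str
    drug: str
    n_turns: int
    turn_bias: float | None
    turn_rate: float
    included: bool = True

    def __post_init__(self) -> None:
        if self.predator not in PREDATOR_LEVELS:
            raise ValueError(
                f"predator must be one of {PREDATOR_LEVELS}, got {self.predator!r}"
            )
        if self.drug not in DRUG_LEVELS:
            raise ValueError(f"drug must be one of {DRUG_LEVELS}, got {self.drug!r}")
        if self.n_turns == 0 and self.turn_bias is not None:
            raise ValueError("turn_bias is undefined for a fly with no turns")

    @property
    def group(self) -> str:
        return f"{self.predator}:{self.drug}"


def next_arm(arm: int, direction: str, clockwise_is_right: bool = True) -> int:
    """Arm reached from ``arm`` by turning ``direction``.

    Arms are indexed in increasing-bearing order. With the default
    convention, a right turn is the transition to the next arm clockwise in
    image coordinates (y increasing downward), i.e. increasing bearing.
    """
    step = 1 if (direction == "R") == clockwise_is_right else -1
    return (arm + step) % 3


def assign_zone(point: tuple[float, float], geometry: MazeGeometry) -> int:
    """Zone of a single point: ``CENTER`` (-1) or an arm index 0..2."""
    z = assign_zones(
        np.asarray([point[0]]), np.asarray([point[1]]), geometry, warn_outside=True
    )
    return int(z[0])


def assign_zones(
    x: np.ndarray,
    y: np.ndarray,
    geometry: MazeGeometry,
    warn_outside: bool = True,
) -> np.ndarray:
    """Vectorised zone assignment for arrays of coordinates.

    Points within ``center_radius`` of the hub map to ``CENTER``; others to
    the arm whose sector contains their bearing (boundary ties break to the
    lower arm index). Points beyond ``arm_length`` (plus a small tolerance)
    raise an out-of-maze warning but are still assigned to the nearest arm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - geometry.center[0]
    dy = y - geometry.center[1]
    r = np.hypot(dx, dy)
    bearing = np.rad2deg(np.arctan2(dy, dx)) % 360.0

    # angular distance to each arm bearing; argmin picks the lowest index on
    # ties, which is the documented boundary rule
    diff = np.abs(bearing[:, None] - np.asarray(geometry.arm_angles)[None, :])
    ang_dist = np.minimum(diff, 360.0 - diff)
    arm = np.argmin(ang_dist, axis=1)

    if warn_outside:
        outside = r > geometry.arm_length * 1.05
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} point(s) beyond arm length; "
                "assigned to nearest arm",
                stacklevel=2,
            )
    zones = np.where(r <= geometry.center_radius, CENTER, arm)
    return zones.astype(int)


def _run_length_encode(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(values, run start indices, run lengths) of a 1-D array."""
    change = np.flatnonzero(np.diff(z) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [len(z)])))
    return z[starts], starts, lengths


def extract_arm_visits(
    traj: Trajectory,
    geometry: MazeGeometry,
    debounce: int = 3,
) -> ArmVisitSequence:
    """Reduce a trajectory to its sequence of arm entries.

    The per-sample zone sequence is run-length encoded and runs shorter than
    ``debounce`` samples are suppressed (tracking flicker across a sector or
    hub boundary). An arm visit is logged each time the debounced zone
    changes to an arm; consecutive samples in one arm are one visit.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    zones = assign_zones(traj.x, traj.y, geometry, warn_outside=False)
    values, starts, lengths = _run_length_encode(zones)
    keep = lengths >= max(debounce, 1)
    if not keep.any():  # pathologically jittery track: fall back to all runs
        keep = np.ones_like(keep, dtype=bool)
    values, starts = values[keep], starts[keep]
    # merge adjacent runs that became equal after flicker removal
    if len(values):
        first = np.concatenate(([True], np.diff(values) != 0))
        values, starts = values[first], starts[first]
    in_arm = values != CENTER
    return ArmVisitSequence(arms=values[in_arm], entry_times=traj.t[starts[in_arm]])


def call_turns(
    visits: ArmVisitSequence,
    duration_min: float,
    clockwise_is_right: bool = True,
) -> TurnSequence:
    """Score consecutive distinct-arm transitions as left/right turns.

    For a transition a -> b (a != b), the turn is right when b is the next
    arm in increasing-bearing order (clockwise on the camera image under the
    default convention); flipping ``clockwise_is_right`` flips every label.
    Transitions a -> a (re-entries) emit no turn. The turn time is the entry
    time into the destination arm.
    """
    if len(visits) < 2:
        return TurnSequence(np.empty(0), np.empty(0, dtype="U1"), duration_min)
    a = visits.arms[:-1]
    b = visits.arms[1:]
    distinct = a != b
    ccw = (b - a) % 3 == 1  # increasing-bearing neighbor
    labels = np.where(ccw == clockwise_is_right, "R", "L")
    return TurnSequence(
        times=visits.entry_times[1:][distinct],
        directions=labels[distinct],
        duration_min=duration_min,
    )


def compute_turn_bias(turns: TurnSequence) -> float:
    """Proportion of right turns, n_R / (n_R + n_L); undefined when empty."""
    n = len(turns)
    if n == 0:
        raise ValueError("turn bias is undefined for an empty turn sequence")
    return turns.n_right / n


def compute_turn_rate(turns: TurnSequence) -> float:
    """Turns per minute over the recording duration."""
    return len(turns) / turns.duration_min


def make_fly_record(
    fly_id: str,
    predator: str,
    drug: str,
    turns: TurnSequence,
    min_turns: int = 30,
) -> FlyRecord:
    """Summarise one fly's turn sequence into a record with inclusion flag."""
    n = len(turns)
    return FlyRecord(
        fly_id=fly_id,
        predator=predator,
        drug=drug,
        n_turns=n,
        turn_bias=compute_turn_bias(turns) if n else None,
        turn_rate=compute_turn_rate(turns),
        included=n >= min_turns,
    )


def filter_flies(records: list[FlyRecord], min_turns: int = 30) -> list[FlyRecord]:
    """Keep flies with at least ``min_turns`` turns (default 30, inclusive).

    Low-activity flies give noisy bias estimates; the count of discarded
    records is logged.
    """
    kept = [replace(r, included=True) for r in records if r.n_turns >= min_turns]
    n_discarded = len(records) - len(kept)
    if n_discarded:
        logger.info(
            "discarded %d of %d flies with fewer than %d turns",
            n_discarded,
            len(records),
            min_turns,
        )
    return kept


def records_to_frame(records: list[FlyRecord]) -> pd.DataFrame:
    """Tabulate fly records (one row per fly)."""
    return pd.DataFrame(
        {
            "fly_id": [r.fly_id for r in records],
            "predator": [r.predator for r in records],
            "drug": [r.drug for r in records],
            "group": [r.group for r in records],
            "n_turns": [r.n_turns for r in records],
            "turn_bias": [r.turn_bias for r in records],
            "turn_rate": [r.turn_rate for r in records],
            "included": [r.included for r in records],
        }
    )
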