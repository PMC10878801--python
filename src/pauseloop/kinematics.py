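"""Fictive-path reconstruction, bout segmentation, and kinematic metrics.

A tethered walker on a trackball never translates, but the rotations it
imparts to the ball define the 2D path it "would have" walked.  Here the ball
geometry is abstracted away: the trace increments are consumed directly as
arc lengths (cm) and heading changes (rad), so the ball radius never enters.
Dead-reckoning in the tether frame (origin at trial start, +x along the
initial heading) gives the fictive path; a speed threshold with smoothing and
minimum-bout rules segments walking from pausing; and the summary computes
the four headline metrics — walking fraction, mean pause duration, total
distance travelled, and total side motion — plus path straightness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import TrackballTrace
from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "FictivePath",
    "SegmentationConfig",
    "Bout",
    "BoutSequence",
    "SideMotionDefinition",
    "integrate_path",
    "segment_bouts",
    "summarize",
    "KinematicSummary",
    "analyze_trace",
]


@dataclass
class FictivePath:
    """Reconstructed 2D trajectory in the tether frame.

    Arrays have one more entry than the trace (the origin is included);
    ``heading[0] = 0`` and the path starts at (0, 0).
    """

    t: np.ndarray        # s
    x: np.ndarray        # cm
    y: np.ndarray        # cm
    heading: np.ndarray  # rad

    @property
    def n_samples(self) -> int:
        return int(self.t.size) - 1

    def net_displacement(self) -> float:
        return float(np.hypot(self.x[-1], self.y[-1]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "x_cm": self.x, "y_cm": self.y, "heading_rad": self.heading}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate_path(trace: TrackballTrace) -> FictivePath:
    """Dead-reckon the fictive path from trackball increments.

    Per sample: the heading first absorbs the yaw increment, then the forward
    and lateral arc lengths are rotated into the tether frame and accumulated:
    ``x += d_fwd * cos(phi) - d_lat * sin(phi)``,
    ``y += d_fwd * sin(phi) + d_lat * cos(phi)``.
    """
    n = trace.n_samples
    if n == 0:
        raise InsufficientDataError("empty trace")
    phi = np.concatenate(([0.0], np.cumsum(trace.d_yaw)))
    c = np.cos(phi[1:])
    s = np.sin(phi[1:])
    dx = trace.d_forward * c - trace.d_lateral * s
    dy = trace.d_forward * s + trace.d_lateral * c
    x = np.concatenate(([0.0], np.cumsum(dx)))
    y = np.concatenate(([0.0], np.cumsum(dy)))
    t = np.arange(n + 1) / trace.sample_rate
    return FictivePath(t=t, x=x, y=y, heading=phi)


@dataclass(frozen=True)
class SegmentationConfig:
    """Walk/pause segmentation rule.

    The per-sample displacement vector (forward, lateral) is smoothed by a
    centred moving average over ``smoothing_window`` seconds, its magnitude
    converted to a speed, and thresholded; runs shorter than
    ``min_bout_duration`` (other than the first and last) are merged into
    their neighbours.  Smoothing the vector rather than the rectified
    magnitude keeps zero-mean sensor noise from biasing pause-time speed
    upward.  The default threshold is 10 % of the walker's default speed.
    """

    smoothing_window: float = 0.25   # s
    speed_threshold: float = 0.3     # cm/s
    min_bout_duration: float = 0.3   # s

    def __post_init__(self):
        for name in ("smoothing_window", "speed_threshold", "min_bout_duration"):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")


class BoutKind(enum.Enum):
    WALK = "WALK"
    PAUSE = "PAUSE"


@dataclass(frozen=True)
class Bout:
    kind: BoutKind
    start: float      # s
    duration: float   # s


@dataclass
class BoutSequence:
    """Contiguous, alternating walk/pause bouts covering [0, T]."""

    bouts: list[Bout]
    total_duration: float

    def durations(self, kind: BoutKind) -> np.ndarray:
        return np.array(
            [b.duration for b in self.bouts if b.kind is kind], dtype=float
        )

    def walk_time(self) -> float:
        return float(self.durations(BoutKind.WALK).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [b.kind.value for b in self.bouts],
                "start_s": [b.start for b in self.bouts],
                "duration_s": [b.duration for b in self.bouts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def smoothed_speed(trace: TrackballTrace, config: SegmentationConfig) -> np.ndarray:
    """Centred-moving-average speed (cm/s) per sample."""
    win = max(1, int(round(config.smoothing_window * trace.sample_rate)))
    if win % 2 == 0:
        win += 1
    if trace.n_samples < win:
        raise InsufficientDataError(
            f"trace ({trace.n_samples} samples) shorter than smoothing window ({win})"
        )
    f = (
        pd.Series(trace.d_forward)
        .rolling(win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    l = (
        pd.Series(trace.d_lateral)
        .rolling(win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return np.sqrt(f * f + l * l) * trace.sample_rate


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """(start, end-exclusive, value) runs of a boolean array."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [mask.size]))
    return [(int(s), int(e), bool(mask[s])) for s, e in zip(starts, ends)]


def segment_bouts(
    trace: TrackballTrace, config: SegmentationConfig
) -> BoutSequence:
    """Segment a trace into alternating walk and pause bouts.

    WALK wherever the smoothed speed exceeds the threshold, PAUSE elsewhere;
    then interior bouts shorter than the minimum duration are merged into
    their (identical-kind) neighbours, shortest bout first, ties resolved by
    merging into the preceding bout.  The first and last bouts are exempt
    from the minimum — the trial window truncates them.
    """
    speed = smoothed_speed(trace, config)
    mask = speed > config.speed_threshold
    runs = [[s, e, v] for s, e, v in _runs(mask)]

    min_len = int(round(config.min_bout_duration * trace.sample_rate))
    while len(runs) > 2:
        # shortest interior run below the minimum; ties -> earliest
        interior = [
            (runs[i][1] - runs[i][0], i) for i in range(1, len(runs) - 1)
        ]
        length, i = min(interior, key=lambda p: (p[0], p[1]))
        if length >= min_len:
            break
        # absorb run i into its neighbours (both are the opposite kind,
        # so the three coalesce into one run of the neighbours' kind)
        merged = [runs[i - 1][0], runs[i + 1][1], runs[i - 1][2]]
        runs[i - 1 : i + 2] = [merged]

    sr = trace.sample_rate
    bouts = [
        Bout(
            kind=BoutKind.WALK if v else BoutKind.PAUSE,
            start=s / sr,
            duration=(e - s) / sr,
        )
        for s, e, v in runs
    ]
    return BoutSequence(bouts=bouts, total_duration=trace.n_samples / sr)


class SideMotionDefinition(enum.Enum):
    """How "total side motion" is accumulated.

    ``TETHER_FRAME`` (default): the sum of absolute per-sample lateral
    displacements of the fictive path, measured perpendicular to the initial
    heading axis.  ``HEADING_TURN``: the total absolute heading rotation
    (rad), a pure turning-intensity alternative.
    """

    TETHER_FRAME = "TETHER_FRAME"
    HEADING_TURN = "HEADING_TURN"


@dataclass(frozen=True)
class KinematicSummary:
    """The four headline metrics plus path straightness for one trial."""

    walking_fraction: float     # in [0, 1]
    mean_pause_duration: float  # s (0 when has_pause is False)
    total_distance: float       # cm
    total_side_motion: float    # cm (or rad under HEADING_TURN)
    straightness: float         # |net displacement| / total distance, in [0, 1]
    has_pause: bool

    def to_dict(self) -> dict:
        return {
            "walking_fraction": self.walking_fraction,
            "mean_pause_duration": self.mean_pause_duration,
            "total_distance": self.total_distance,
            "total_side_motion": self.total_side_motion,
            "straightness": self.straightness,
            "has_pause": self.has_pause,
        }


def summarize(
    path: FictivePath,
    bouts: BoutSequence,
    trace: TrackballTrace,
    side_motion: SideMotionDefinition = SideMotionDefinition.TETHER_FRAME,
) -> KinematicSummary:
    """Compute the trial summary from path, bouts and raw trace.

    * walking fraction = total WALK time / trial duration
    * mean pause duration = mean of PAUSE bout durations (0, flagged, if the
      subject never paused)
    * total distance = sum of per-sample planar displacement magnitudes
    * total side motion = sum of |dy| along the fictive path (tether frame)
    * straightness = net displacement / total distance (1 for an idle trial)
    """
    if path.n_samples != trace.n_samples:
        raise ConfigurationError("path and trace lengths disagree")
    T = bouts.total_duration
    walk_time = bouts.walk_time()
    pauses = bouts.durations(BoutKind.PAUSE)
    has_pause = pauses.size > 0
    mean_pause = float(pauses.mean()) if has_pause else 0.0
    total_distance = float(
        np.sqrt(trace.d_forward**2 + trace.d_lateral**2).sum()
    )
    if side_motion is SideMotionDefinition.TETHER_FRAME:
        side = float(np.abs(np.diff(path.y)).sum())
    else:
        side = float(np.abs(trace.d_yaw).sum())
    straightness = (
        path.net_displacement() / total_distance if total_distance > 0 else 1.0
    )
    return KinematicSummary(
        walking_fraction=float(walk_time / T),
        mean_pause_duration=mean_pause,
        total_distance=total_distance,
        total_side_motion=side,
        straightness=float(min(straightness, 1.0)),
        has_pause=bool(has_pause),
    )


def analyze_trace(
    trace: TrackballTrace,
    config: SegmentationConfig | None = None,
    side_motion: SideMotionDefinition = SideMotionDefinition.TETHER_FRAME,
) -> tuple[FictivePath, BoutSequence, KinematicSummary]:
    """Full per-trial analysis: path + bouts + summary."""
    if config is None:
        config = SegmentationConfig()
    path = integrate_path(trace)
    bouts = segment_bouts(trace, config)
    return path, bouts, summarize(path, bouts, trace, side_motion=side_motion)


def write_summary(summaries: list[dict], path) -> pd.DataFrame:
    """Write one CSV row per trial from summary dicts (plus any id columns)."""
    df = pd.DataFrame(summaries)
    df.to_csv(path, index=False)
    return df
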