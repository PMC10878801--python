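"""Two-screen random-dot kinematogram (RDK) stimulus engine.

The stimulus is the classic motion-perception RDK: a field of dots in which a
``coherence`` fraction (the SIGNAL dots) drift in a common direction along the
walker's heading axis, while the remainder (NOISE dots) drift at the same speed
along fixed random directions.  Two screens — one on each side of the tethered
subject — carry independent dot fields.  Each frame carries an ``active`` flag:
when inactive the field is frozen in place, which is how the closed-loop
controller gates the stimulus on the subject's motion state.

Dots are points on a toroidal screen (re-entering at the opposite edge), in cm
coordinates with the origin at the bottom-left corner; the x axis is the
heading axis projected onto the screen, so a FORWARD signal drifts toward +x
and a BACKWARD signal toward -x.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "SignalDirection",
    "StimulusConfig",
    "ScreenDots",
    "DotField",
    "init_dot_field",
    "step_dots",
    "measure_field_speed",
    "replay_frames",
    "write_frame_log",
]

SCREENS = ("left", "right")


class SignalDirection(enum.Enum):
    """Direction of coherent dot drift relative to the subject's heading."""

    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"

    @property
    def sign(self) -> float:
        """+1 for drift along the heading (+x), -1 for drift against it."""
        return 1.0 if self is SignalDirection.FORWARD else -1.0


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the two-screen RDK.

    Defaults follow the published stimulus: 100 % coherence, dot speed
    5 cm/s, 120 frames per second.  Screen geometry and dot count are not
    reported for the original display and are free choices here.
    """

    n_dots_per_screen: int = 50
    dot_speed: float = 5.0          # cm/s
    coherence: float = 1.0          # fraction of SIGNAL dots in [0, 1]
    frame_rate: float = 120.0       # frames/s
    screen_width: float = 30.0      # cm
    screen_height: float = 20.0     # cm
    signal_direction: SignalDirection = SignalDirection.FORWARD
    seed: int = 0

    def __post_init__(self):
        if self.n_dots_per_screen < 1:
            raise ConfigurationError("n_dots_per_screen must be >= 1")
        if not (self.dot_speed > 0):
            raise ConfigurationError("dot_speed must be > 0")
        if not (0.0 <= self.coherence <= 1.0):
            raise ConfigurationError("coherence must lie in [0, 1]")
        if not (self.frame_rate > 0):
            raise ConfigurationError("frame_rate must be > 0")
        if not (self.screen_width > 0):
            raise ConfigurationError("screen_width must be > 0")
        if not (self.screen_height > 0):
            raise ConfigurationError("screen_height must be > 0")
        if not isinstance(self.signal_direction, SignalDirection):
            raise ConfigurationError("signal_direction must be a SignalDirection")

    @property
    def step_length(self) -> float:
        """Per-frame dot displacement in cm."""
        return self.dot_speed / self.frame_rate

    @property
    def n_signal(self) -> int:
        """Number of SIGNAL dots per screen (round-half-up of coherence * n)."""
        return int(math.floor(self.coherence * self.n_dots_per_screen + 0.5))


@dataclass(frozen=True)
class ScreenDots:
    """Dot state of one screen: positions, roles and fixed noise headings."""

    x: np.ndarray            # cm, in [0, width)
    y: np.ndarray            # cm, in [0, height)
    is_signal: np.ndarray    # bool per dot
    noise_angle: np.ndarray  # rad, fixed per dot; used only by NOISE dots


@dataclass(frozen=True)
class DotField:
    """Joint per-frame state of both screens."""

    screens: tuple[ScreenDots, ScreenDots]
    frame_index: int = 0


def init_dot_field(config: StimulusConfig) -> DotField:
    """Place dots uniformly at random and assign SIGNAL/NOISE roles.

    The two screens use distinct sub-seeds of ``config.seed``, so their dot
    streams are independent.  Deterministic given the seed.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(SCREENS))
    screens = []
    for child in children:
        rng = np.random.default_rng(child)
        n = config.n_dots_per_screen
        x = rng.uniform(0.0, config.screen_width, n)
        y = rng.uniform(0.0, config.screen_height, n)
        roles = np.zeros(n, dtype=bool)
        roles[rng.permutation(n)[: config.n_signal]] = True
        angle = rng.uniform(0.0, 2.0 * np.pi, n)
        screens.append(ScreenDots(x=x, y=y, is_signal=roles, noise_angle=angle))
    return DotField(screens=tuple(screens), frame_index=0)


def step_dots(field: DotField, config: StimulusConfig, active: bool) -> DotField:
    """Advance the field by one frame.

    When ``active``, SIGNAL dots move ``dot_speed / frame_rate`` cm along the
    signal direction and NOISE dots the same distance along their own fixed
    random directions, with toroidal wrap-around.  When inactive, all
    positions are left untouched (the freeze used by closed-loop gating).
    The frame index advances either way.
    """
    if not active:
        return replace(field, frame_index=field.frame_index + 1)
    step = config.step_length
    sx = config.signal_direction.sign * step
    new_screens = []
    for sc in field.screens:
        dx = np.where(sc.is_signal, sx, np.cos(sc.noise_angle) * step)
        dy = np.where(sc.is_signal, 0.0, np.sin(sc.noise_angle) * step)
        new_screens.append(
            ScreenDots(
                x=np.mod(sc.x + dx, config.screen_width),
                y=np.mod(sc.y + dy, config.screen_height),
                is_signal=sc.is_signal,
                noise_angle=sc.noise_angle,
            )
        )
    return DotField(screens=tuple(new_screens), frame_index=field.frame_index + 1)


def measure_field_speed(frame_log: Sequence[DotField], config: StimulusConfig) -> float:
    """Mean per-dot speed (cm/s) over a logged frame sequence.

    Computed as the mean per-frame displacement of all dots that did not wrap
    between consecutive frames, multiplied by the frame rate.  A diagnostic
    used to verify stimulus fidelity.
    """
    if len(frame_log) < 2:
        raise InsufficientDataError("need at least 2 frames to measure speed")
    disps = []
    for prev, curr in zip(frame_log[:-1], frame_log[1:]):
        for sp, sc in zip(prev.screens, curr.screens):
            dx = sc.x - sp.x
            dy = sc.y - sp.y
            ok = (np.abs(dx) < config.screen_width / 2.0) & (
                np.abs(dy) < config.screen_height / 2.0
            )
            disps.append(np.sqrt(dx[ok] ** 2 + dy[ok] ** 2))
    all_disp = np.concatenate(disps)
    if all_disp.size == 0:
        raise InsufficientDataError("every dot wrapped between frames")
    return float(all_disp.mean() * config.frame_rate)


def replay_frames(config: StimulusConfig, active: Iterable[bool]) -> list[DotField]:
    """Materialize the full frame log for a sequence of active flags.

    Because frozen frames do not change dot state, a trial's frame log is a
    deterministic function of the stimulus seed and the active-flag sequence;
    this reconstructs it (initial field plus one frame per flag).
    """
    frames = [init_dot_field(config)]
    for a in active:
        frames.append(step_dots(frames[-1], config, bool(a)))
    return frames


def write_frame_log(
    frames: Sequence[DotField],
    active: Sequence[bool],
    path,
) -> pd.DataFrame:
    """Write a frame log as CSV: frame_index, screen, dot_id, role, x_cm, y_cm, active.

    ``active[i]`` is the flag that produced the step into ``frames[i + 1]``;
    the initial frame is logged with active = the first flag (or False).
    """
    rows = []
    for i, f in enumerate(frames):
        a = bool(active[i - 1]) if 1 <= i <= len(active) else (
            bool(active[0]) if len(active) else False
        )
        for name, sc in zip(SCREENS, f.screens):
            rows.append(
                pd.DataFrame(
                    {
                        "frame_index": f.frame_index,
                        "screen": name,
                        "dot_id": np.arange(sc.x.size),
                        "role": np.where(sc.is_signal, "SIGNAL", "NOISE"),
                        "x_cm": sc.x,
                        "y_cm": sc.y,
                        "active": a,
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False)
    return df
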