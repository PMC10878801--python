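"""Motion-state detection and stimulus gating.

The original rig read an optical displacement sensor on the trackball, applied
a threshold in the microcontroller to suppress sensor noise, and broadcast a
Boolean "the animal is moving" state that each screen process used to decide
whether its dots move or freeze.  This module reproduces that chain as a
causal hysteresis automaton (threshold + debounce) plus the per-mode gating
truth table:

* ``OPEN_LOOP``     — stimulus always active, regardless of the animal.
* ``IN_PHASE``      — stimulus active while the animal is detected moving.
* ``OUT_OF_PHASE``  — stimulus active only while the animal is detected still.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "GatingMode",
    "MotionDetectorConfig",
    "detect_motion",
    "gate",
    "gate_stream",
    "active_flags",
    "write_gate_log",
]


class GatingMode(enum.Enum):
    OPEN_LOOP = "OPEN_LOOP"
    IN_PHASE = "IN_PHASE"
    OUT_OF_PHASE = "OUT_OF_PHASE"


# stable integer codes used by the fast simulation kernel
MODE_CODES = {
    GatingMode.OPEN_LOOP: 0,
    GatingMode.IN_PHASE: 1,
    GatingMode.OUT_OF_PHASE: 2,
}


@dataclass(frozen=True)
class MotionDetectorConfig:
    """Threshold-plus-debounce detector on per-sample displacement magnitudes.

    ``threshold`` is in cm of ball-surface displacement per sample.  The
    detector enters MOVING after ``debounce_on`` consecutive supra-threshold
    samples and leaves it after ``debounce_off`` consecutive sub-threshold
    samples; the initial state is NOT_MOVING.
    """

    threshold: float = 0.01      # cm per sample
    debounce_on: int = 5         # samples
    debounce_off: int = 5        # samples
    sample_rate: float = 120.0   # Hz

    def __post_init__(self):
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.debounce_on < 1:
            raise ConfigurationError("debounce_on must be >= 1")
        if self.debounce_off < 1:
            raise ConfigurationError("debounce_off must be >= 1")
        if not (self.sample_rate > 0):
            raise ConfigurationError("sample_rate must be > 0")


def detect_motion(displacements, config: MotionDetectorConfig) -> np.ndarray:
    """Run the hysteresis automaton over a displacement-magnitude stream.

    Returns a Boolean MOVING flag per sample, aligned with the input.  The
    automaton is causal: the flag at sample ``t`` depends only on samples
    ``<= t``, and the state flips on the sample that completes a debounce run.
    """
    mags = np.asarray(displacements, dtype=float)
    if mags.size == 0:
        raise InsufficientDataError("empty displacement stream")
    if np.any(mags < 0):
        raise ConfigurationError("displacement magnitudes must be >= 0")
    out = np.empty(mags.size, dtype=bool)
    moving = False
    run_on = 0
    run_off = 0
    thr = config.threshold
    for t in range(mags.size):
        if mags[t] > thr:
            run_on += 1
            run_off = 0
        else:
            run_off += 1
            run_on = 0
        if not moving and run_on >= config.debounce_on:
            moving = True
        elif moving and run_off >= config.debounce_off:
            moving = False
        out[t] = moving
    return out


def gate(mode: GatingMode, moving: bool) -> bool:
    """Per-mode stimulus activity given the detected motion state."""
    if mode is GatingMode.OPEN_LOOP:
        return True
    if mode is GatingMode.IN_PHASE:
        return bool(moving)
    return not moving


def gate_stream(mode: GatingMode, moving) -> np.ndarray:
    """Vectorized :func:`gate` over a Boolean stream."""
    moving = np.asarray(moving, dtype=bool)
    if mode is GatingMode.OPEN_LOOP:
        return np.ones(moving.shape, dtype=bool)
    if mode is GatingMode.IN_PHASE:
        return moving.copy()
    return ~moving


def active_flags(mode: GatingMode, moving, latency: int = 1) -> np.ndarray:
    """Stimulus-active flag per frame under the controller latency contract.

    The controller that observed sample ``t`` gates the stimulus frame at
    ``t + latency`` (default one sample, mirroring the sensor -> controller ->
    display chain).  Frames before the first gated one use the initial
    NOT_MOVING state.
    """
    moving = np.asarray(moving, dtype=bool)
    if latency < 0:
        raise ConfigurationError("latency must be >= 0")
    shifted = np.empty(moving.size, dtype=bool)
    shifted[:latency] = False
    if latency < moving.size:
        shifted[latency:] = moving[: moving.size - latency]
    return gate_stream(mode, shifted)


def write_gate_log(
    displacements,
    moving,
    mode: GatingMode,
    active,
    path,
) -> pd.DataFrame:
    """Write the gate log as CSV: sample_index, displacement, moving, mode, active."""
    df = pd.DataFrame(
        {
            "sample_index": np.arange(len(np.asarray(displacements))),
            "displacement": np.asarray(displacements, dtype=float),
            "moving": np.asarray(moving, dtype=bool),
            "mode": mode.value,
            "active": np.asarray(active, dtype=bool),
        }
    )
    df.to_csv(path, index=False)
    return df
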