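"""Generative pause-and-go walker: the synthetic stand-in for the animal.

The agent alternates walking bouts and pauses on a virtual trackball:

* **Walk bouts** terminate at random with no memory — durations are
  exponential with mean ``mean_walk_duration`` (a Markov termination process,
  matching what is known of locust intermittent walking).
* **Pauses** are heavy-tailed.  The baseline hazard ``h0(t) =
  (alpha - 1) / (t + t_min)`` yields the bounded power-law survival
  ``S(t) = (t_min / (t + t_min))**(alpha - 1)`` with a hard cap at ``t_max``.
* **Perception is pause-weighted.**  A leaky integrator accumulates signed
  visual-motion evidence ``E`` while the stimulus is active, with weight
  ``w_pause`` during pauses and ``w_walk`` during walking (``w_pause >=
  w_walk``); positive ``E`` means net percept along the heading.  This
  embodies the hypothesis that the information relevant to joining a moving
  crowd is taken in mostly during pauses.
* **Decisions happen at pause end.**  Evidence opposite the heading
  (``E < 0``) multiplies the pause hazard by ``1 + beta * |E|`` (the urge to
  get going and rejoin the crowd) and raises the probability
  ``1 / (1 + exp(-(k*(-E) + b)))`` of starting a turning bout rather than a
  straight one.  The turn direction is drawn once per subject and kept — a
  tethered animal cannot actually reorient, so "turning" is persistent yaw in
  the fictive frame.

The emitted trackball trace is forward/yaw/lateral increments per sample with
additive Gaussian sensor noise, plus noiseless ground-truth labels
(behaviour, stimulus-active flag, evidence), which is what makes every
downstream stage testable without animal data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .errors import ConfigurationError, InsufficientDataError
from .gating import MODE_CODES, GatingMode, MotionDetectorConfig
from .stimulus_rdk import (
    DotField,
    SignalDirection,
    StimulusConfig,
    replay_frames,
    write_frame_log,
)

__all__ = [
    "Behaviour",
    "AgentConfig",
    "AgentState",
    "TrackballTrace",
    "TrialResult",
    "update_evidence",
    "pause_hazard",
    "baseline_pause_survival",
    "sample_baseline_pause",
    "expected_pause_duration",
    "turn_probability",
    "choose_bout_at_pause_end",
    "step_agent",
    "run_trial",
]


class Behaviour(enum.Enum):
    PAUSE = "PAUSE"
    WALK_FORWARD = "WALK_FORWARD"
    WALK_TURN = "WALK_TURN"


BEHAVIOUR_CODES = {
    Behaviour.PAUSE: _kernel.PAUSE,
    Behaviour.WALK_FORWARD: _kernel.WALK_FORWARD,
    Behaviour.WALK_TURN: _kernel.WALK_TURN,
}
CODE_TO_BEHAVIOUR = {v: k for k, v in BEHAVIOUR_CODES.items()}


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of the generative walker.

    Units: durations in s, speeds in cm/s, yaw rate in rad/s, evidence
    weights in 1/s, sensor noise in cm per sample.  ``turn_bias = -2.944``
    puts the baseline (no-evidence) turning probability at 5 %.
    """

    mean_walk_duration: float = 2.0    # tau_w, s
    pause_t_min: float = 0.5           # s, power-law onset scale
    pause_exponent: float = 1.8        # alpha > 1
    pause_t_max: float = 60.0          # s, hard cap on pause length
    walk_speed: float = 3.0            # cm/s
    turn_yaw_rate: float = 1.0         # rad/s during turning bouts
    w_pause: float = 1.0               # 1/s, evidence weight while pausing
    w_walk: float = 0.0                # 1/s, evidence weight while walking
    evidence_tau: float = 3.0          # s, leaky-integrator time constant
    pause_shortening_gain: float = 3.0  # beta, hazard gain per unit |E|
    turn_gain: float = 4.0             # k, logistic slope on -E
    turn_bias: float = -2.944          # b, logistic offset
    sensor_noise: float = 0.002        # cm per sample, per channel
    sample_rate: float = 120.0         # Hz
    seed: int = 0

    def __post_init__(self):
        if not (self.mean_walk_duration > 0):
            raise ConfigurationError("mean_walk_duration must be > 0")
        if not (self.pause_t_min > 0):
            raise ConfigurationError("pause_t_min must be > 0")
        if not (self.pause_t_max > self.pause_t_min):
            raise ConfigurationError("pause_t_max must exceed pause_t_min")
        if not (self.pause_exponent > 1):
            raise ConfigurationError("pause_exponent must be > 1")
        if not (self.walk_speed > 0):
            raise ConfigurationError("walk_speed must be > 0")
        if self.w_walk < 0 or self.w_pause < self.w_walk:
            raise ConfigurationError("need w_pause >= w_walk >= 0")
        if not (self.evidence_tau > 0):
            raise ConfigurationError("evidence_tau must be > 0")
        if self.pause_shortening_gain < 0:
            raise ConfigurationError("pause_shortening_gain must be >= 0")
        if self.sensor_noise < 0:
            raise ConfigurationError("sensor_noise must be >= 0")
        if not (self.sample_rate > 0):
            raise ConfigurationError("sample_rate must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class AgentState:
    """Mutable per-sample state of the walker."""

    behaviour: Behaviour = Behaviour.PAUSE
    time_in_bout: float = 0.0
    walk_bout_end: float = 0.0   # scheduled duration of the current walk bout
    evidence: float = 0.0
    heading: float = 0.0         # rad, fictive
    turn_sign: int = 1


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------

def update_evidence(
    E: float,
    stimulus_active: bool,
    signal_direction: SignalDirection,
    behaviour: Behaviour,
    dt: float,
    config: AgentConfig,
) -> float:
    """One Euler step of the leaky evidence integrator.

    ``E' = E + dt * (-E / tau_e + w(behaviour) * s * [active])`` where
    ``s = +1`` for a FORWARD signal and ``-1`` for BACKWARD, and the weight is
    ``w_pause`` during pauses, ``w_walk`` otherwise.  Steady state under a
    constantly active stimulus during an indefinite pause is
    ``s * w_pause * tau_e``.
    """
    if not (dt > 0):
        raise ConfigurationError("dt must be > 0")
    w = config.w_pause if behaviour is Behaviour.PAUSE else config.w_walk
    drive = w * signal_direction.sign if stimulus_active else 0.0
    return E + dt * (-E / config.evidence_tau + drive)


def pause_hazard(t: float, E: float, config: AgentConfig) -> float:
    """Instantaneous pause-termination hazard (1/s) at pause age ``t``.

    Baseline ``h0(t) = (alpha - 1) / (t + t_min)`` (infinite at the hard cap
    ``t_max``), multiplied by ``1 + beta * max(0, -E)``: only evidence
    opposite the heading shortens pauses.
    """
    if t < 0:
        raise ConfigurationError("pause age t must be >= 0")
    if t >= config.pause_t_max:
        return math.inf
    h0 = (config.pause_exponent - 1.0) / (t + config.pause_t_min)
    return h0 * (1.0 + config.pause_shortening_gain * max(0.0, -E))


def baseline_pause_survival(t, config: AgentConfig):
    """Analytic survival of the baseline (E = 0) pause law, with hard cap."""
    t = np.asarray(t, dtype=float)
    s = (config.pause_t_min / (t + config.pause_t_min)) ** (
        config.pause_exponent - 1.0
    )
    return np.where(t >= config.pause_t_max, 0.0, s)


def sample_baseline_pause(
    config: AgentConfig, rng: np.random.Generator, size=None
):
    """Draw baseline pause durations by inverse transform, capped at t_max.

    Inverting ``S(t) = u`` gives ``t = t_min * (u**(-1/(alpha-1)) - 1)``; draws
    beyond the cap collapse onto ``t_max`` (the cap is an atom, matching the
    infinite hazard there).
    """
    u = rng.uniform(size=size)
    t = config.pause_t_min * (
        u ** (-1.0 / (config.pause_exponent - 1.0)) - 1.0
    )
    return np.minimum(t, config.pause_t_max)


def expected_pause_duration(config: AgentConfig) -> float:
    """Closed-form mean of the capped baseline pause duration.

    ``E[min(T, t_max)] = integral of S(t) over [0, t_max]``.
    """
    a = config.pause_exponent
    tm = config.pause_t_min
    T = config.pause_t_max
    if abs(a - 2.0) < 1e-12:
        return tm * math.log((T + tm) / tm)
    return tm ** (a - 1.0) * ((T + tm) ** (2.0 - a) - tm ** (2.0 - a)) / (2.0 - a)


def turn_probability(E: float, config: AgentConfig) -> float:
    """Probability of starting a turning (rather than straight) walk bout."""
    z = config.turn_gain * (-E) + config.turn_bias
    return 1.0 / (1.0 + math.exp(-z))


def choose_bout_at_pause_end(
    E: float, config: AgentConfig, rng: np.random.Generator
) -> tuple[Behaviour, float]:
    """Decision taken when a pause ends: bout kind plus its drawn duration.

    Turning is chosen with logistic probability in ``-E``; the walk-bout
    duration is exponential with mean ``mean_walk_duration`` either way.  The
    *direction* of turning is not decided here — it is a persistent per-subject
    trait (see :class:`AgentState.turn_sign`).
    """
    kind = (
        Behaviour.WALK_TURN
        if rng.uniform() < turn_probability(E, config)
        else Behaviour.WALK_FORWARD
    )
    duration = rng.exponential(config.mean_walk_duration)
    return kind, duration


def step_agent(
    state: AgentState,
    config: AgentConfig,
    signal_direction: SignalDirection,
    stimulus_active: bool,
    dt: float,
    rng: np.random.Generator,
) -> tuple[AgentState, tuple[float, float, float]]:
    """Advance the walker by one sample; returns the new state and the
    (forward, yaw, lateral) sensor increments in (cm, rad, cm).

    Reference single-step implementation of the loop body (the compiled
    trial kernel applies the same update order sample by sample).
    """
    if abs(dt - config.dt) > 1e-12:
        raise ConfigurationError(
            f"dt={dt} does not match 1/sample_rate={config.dt}"
        )
    s = AgentState(**vars(state))
    beh = s.behaviour
    fwd = config.walk_speed * dt if beh is not Behaviour.PAUSE else 0.0
    yaw = (
        s.turn_sign * config.turn_yaw_rate * dt
        if beh is Behaviour.WALK_TURN
        else 0.0
    )
    sigma = config.sensor_noise
    noise = rng.normal(0.0, sigma, 3) if sigma > 0 else np.zeros(3)
    sample = (fwd + noise[0], yaw + noise[1], noise[2])
    s.heading += yaw

    s.evidence = update_evidence(
        s.evidence, stimulus_active, signal_direction, beh, dt, config
    )

    if beh is Behaviour.PAUSE:
        h = pause_hazard(s.time_in_bout, s.evidence, config)
        p = min(1.0, h * dt) if math.isfinite(h) else 1.0
        s.time_in_bout += dt
        if s.time_in_bout >= config.pause_t_max or rng.uniform() < p:
            kind, duration = choose_bout_at_pause_end(s.evidence, config, rng)
            s.behaviour = kind
            s.walk_bout_end = duration
            s.time_in_bout = 0.0
    else:
        s.time_in_bout += dt
        if s.time_in_bout >= s.walk_bout_end:
            s.behaviour = Behaviour.PAUSE
            s.time_in_bout = 0.0
    return s, sample


# ---------------------------------------------------------------------------
# trace container and full-trial simulation
# ---------------------------------------------------------------------------

TRACE_COLUMNS = [
    "t_s",
    "d_forward_cm",
    "d_yaw_rad",
    "d_lateral_cm",
    "true_behaviour",
    "stimulus_active",
    "evidence",
]


@dataclass
class TrackballTrace:
    """Per-sample trackball increments plus noiseless ground-truth labels."""

    sample_rate: float
    d_forward: np.ndarray    # cm per sample (noisy)
    d_yaw: np.ndarray        # rad per sample (noisy)
    d_lateral: np.ndarray    # cm per sample (noisy)
    behaviour: np.ndarray    # int8 codes, see BEHAVIOUR_CODES
    stimulus_active: np.ndarray  # bool per sample
    evidence: np.ndarray     # evidence E at each sample

    @property
    def n_samples(self) -> int:
        return int(self.d_forward.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def magnitudes(self) -> np.ndarray:
        """Planar displacement magnitude per sample (the detector's input)."""
        return np.sqrt(self.d_forward**2 + self.d_lateral**2)

    def behaviour_labels(self) -> np.ndarray:
        return np.array([CODE_TO_BEHAVIOUR[c].value for c in self.behaviour])

    def true_walking_fraction(self) -> float:
        """Walking fraction straight from the ground-truth labels."""
        return float(np.mean(self.behaviour != _kernel.PAUSE))

    def true_bout_durations(self, kind: Behaviour) -> np.ndarray:
        """Durations (s) of completed ground-truth bouts of one kind.

        The trailing bout is censored by the end of the trial and excluded.
        """
        walk = self.behaviour != _kernel.PAUSE
        want = ~walk if kind is Behaviour.PAUSE else walk
        edges = np.flatnonzero(np.diff(want.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [want.size]))
        durs = [
            (e - s) / self.sample_rate
            for s, e in zip(starts, ends)
            if want[s] and e < want.size
        ]
        return np.asarray(durs, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.time(),
                "d_forward_cm": self.d_forward,
                "d_yaw_rad": self.d_yaw,
                "d_lateral_cm": self.d_lateral,
                "true_behaviour": self.behaviour_labels(),
                "stimulus_active": self.stimulus_active,
                "evidence": self.evidence,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate: Optional[float] = None) -> "TrackballTrace":
        df = pd.read_csv(path)
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise InsufficientDataError(f"trace CSV missing columns {missing}")
        if len(df) == 0:
            raise InsufficientDataError("empty trace CSV")
        if sample_rate is None:
            if len(df) > 1:
                sample_rate = 1.0 / float(df["t_s"].iloc[1] - df["t_s"].iloc[0])
            else:
                raise InsufficientDataError(
                    "cannot infer sample rate from a single-row trace"
                )
        codes = np.array(
            [BEHAVIOUR_CODES[Behaviour(b)] for b in df["true_behaviour"]],
            dtype=np.int8,
        )
        return cls(
            sample_rate=float(sample_rate),
            d_forward=df["d_forward_cm"].to_numpy(float),
            d_yaw=df["d_yaw_rad"].to_numpy(float),
            d_lateral=df["d_lateral_cm"].to_numpy(float),
            behaviour=codes,
            stimulus_active=df["stimulus_active"].to_numpy(bool),
            evidence=df["evidence"].to_numpy(float),
        )


@dataclass
class TrialResult:
    """Everything one simulated trial produced.

    The trace carries the per-sample labels; the gate log and the stimulus
    frame log are derived deterministically on demand (frozen frames change
    nothing, so the frame log is a pure function of the stimulus seed and the
    active-flag sequence).
    """

    trace: TrackballTrace
    moving: np.ndarray
    mode: GatingMode
    agent_config: AgentConfig
    stimulus_config: StimulusConfig
    detector_config: MotionDetectorConfig
    seed: int
    turn_sign: int

    def gate_log(self, path=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_index": np.arange(self.trace.n_samples),
                "displacement": self.trace.magnitudes(),
                "moving": self.moving,
                "mode": self.mode.value,
                "active": self.trace.stimulus_active,
            }
        )
        if path is not None:
            df.to_csv(path, index=False)
        return df

    def frames(self, max_frames: Optional[int] = None) -> list[DotField]:
        active = self.trace.stimulus_active
        if max_frames is not None:
            active = active[:max_frames]
        return replay_frames(self.stimulus_config, active)

    def write_frame_log(self, path, max_frames: Optional[int] = None):
        active = self.trace.stimulus_active
        if max_frames is not None:
            active = active[:max_frames]
        return write_frame_log(self.frames(max_frames), active, path)


def _tapes(rng: np.random.Generator, n: int, sigma: float):
    """Pre-draw the randomness a trial consumes, in a fixed order."""
    if sigma > 0:
        noise = rng.normal(0.0, sigma, (3, n))
    else:
        noise = np.zeros((3, n))
    u_pause = rng.uniform(size=n)
    u_turn = rng.uniform(size=n // 2 + 2)
    return noise, u_pause, u_turn


def run_trial(
    agent_config: AgentConfig,
    stimulus_config: StimulusConfig,
    mode: GatingMode,
    duration: float,
    seed: Optional[int] = None,
    detector_config: Optional[MotionDetectorConfig] = None,
    turn_sign: Optional[int] = None,
) -> TrialResult:
    """Simulate one closed-loop trial of ``duration`` seconds.

    The sensor, controller, and display share one clock (``sample_rate`` must
    equal the stimulus frame rate): each sample the sensor reading updates the
    motion detector, whose state gates the next stimulus frame, which drives
    the evidence integrator, which modulates the walker.  Deterministic given
    ``seed``; ``turn_sign`` (the subject's persistent turning direction) is
    drawn from the seed when not supplied, so it can be pinned across the
    trials of a within-subject session.
    """
    if not (duration > 0):
        raise ConfigurationError("duration must be > 0")
    if abs(agent_config.sample_rate - stimulus_config.frame_rate) > 1e-9:
        raise ConfigurationError(
            "agent sample_rate must equal stimulus frame_rate (shared clock)"
        )
    if detector_config is None:
        detector_config = MotionDetectorConfig(sample_rate=agent_config.sample_rate)
    if abs(detector_config.sample_rate - agent_config.sample_rate) > 1e-9:
        raise ConfigurationError("detector sample_rate must match the agent's")
    if seed is None:
        seed = agent_config.seed

    ss = np.random.SeedSequence(seed)
    tape_ss, turn_ss, stim_ss = ss.spawn(3)
    rng = np.random.default_rng(tape_ss)
    if turn_sign is None:
        turn_sign = 1 if np.random.default_rng(turn_ss).uniform() < 0.5 else -1
    elif turn_sign not in (1, -1):
        raise ConfigurationError("turn_sign must be +1 or -1")

    n = int(round(duration * agent_config.sample_rate))
    if n < 1:
        raise ConfigurationError("duration shorter than one sample")
    noise, u_pause, u_turn = _tapes(rng, n, agent_config.sensor_noise)
    walk_durations = rng.exponential(
        agent_config.mean_walk_duration, n // 2 + 2
    )

    out = _kernel.simulate_trial_kernel(
        n,
        agent_config.dt,
        agent_config.pause_t_min,
        agent_config.pause_exponent,
        agent_config.pause_t_max,
        agent_config.walk_speed,
        agent_config.turn_yaw_rate,
        agent_config.w_pause,
        agent_config.w_walk,
        agent_config.evidence_tau,
        agent_config.pause_shortening_gain,
        agent_config.turn_gain,
        agent_config.turn_bias,
        float(turn_sign),
        stimulus_config.signal_direction.sign,
        MODE_CODES[mode],
        detector_config.threshold,
        detector_config.debounce_on,
        detector_config.debounce_off,
        noise[0],
        noise[1],
        noise[2],
        u_pause,
        u_turn,
        walk_durations,
    )
    d_fwd, d_yaw, d_lat, behaviour, moving, active, evidence, _heading = out

    # the stimulus field replay uses a per-trial sub-seed
    stim = replace(
        stimulus_config, seed=int(stim_ss.generate_state(1)[0] & 0x7FFFFFFF)
    )
    trace = TrackballTrace(
        sample_rate=agent_config.sample_rate,
        d_forward=d_fwd,
        d_yaw=d_yaw,
        d_lateral=d_lat,
        behaviour=behaviour,
        stimulus_active=active,
        evidence=evidence,
    )
    return TrialResult(
        trace=trace,
        moving=moving,
        mode=mode,
        agent_config=agent_config,
        stimulus_config=stim,
        detector_config=detector_config,
        seed=int(seed),
        turn_sign=int(turn_sign),
    )
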