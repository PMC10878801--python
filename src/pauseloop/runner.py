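"""Orchestration of full virtual experiments.

An experiment is a grid of cells (gating condition x stimulus direction),
each run on ``n_subjects`` synthetic subjects.  Two protocols are supported:

* ``BETWEEN_SUBJECT`` (default) — every cell gets its own subjects, matching
  the main published design where distinct animals saw distinct stimuli.
* ``WITHIN_SUBJECT`` — each subject experiences every cell once, in a
  seeded random order, with its persistent traits (turning direction) pinned
  across cells.

Seeding is splittable and counter-based: the seed of the trial for subject
``i`` in cell ``(condition, direction)`` is derived from the master seed via
``numpy``'s ``SeedSequence`` spawn keys, so adding or removing cells never
perturbs the random streams of other cells.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .agent import AgentConfig, TrialResult, run_trial
from .errors import ConfigurationError
from .gating import MODE_CODES, GatingMode, MotionDetectorConfig
from .kinematics import SegmentationConfig, SideMotionDefinition, analyze_trace
from .stats import compare_all, write_comparisons
from .stimulus_rdk import SignalDirection, StimulusConfig

__all__ = [
    "Protocol",
    "ExperimentConfig",
    "TrialRecord",
    "run_experiment",
    "trial_seed",
    "subject_cell_order",
]

_DIRECTION_CODES = {SignalDirection.FORWARD: 0, SignalDirection.BACKWARD: 1}


class Protocol(enum.Enum):
    BETWEEN_SUBJECT = "BETWEEN_SUBJECT"
    WITHIN_SUBJECT = "WITHIN_SUBJECT"


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one virtual experiment."""

    agent: AgentConfig = field(default_factory=AgentConfig)
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    detector: MotionDetectorConfig = field(default_factory=MotionDetectorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    conditions: tuple[GatingMode, ...] = (
        GatingMode.OPEN_LOOP,
        GatingMode.IN_PHASE,
        GatingMode.OUT_OF_PHASE,
    )
    directions: tuple[SignalDirection, ...] = (
        SignalDirection.FORWARD,
        SignalDirection.BACKWARD,
    )
    n_subjects: int = 15
    protocol: Protocol = Protocol.BETWEEN_SUBJECT
    trial_duration: float = 300.0   # s
    master_seed: int = 0
    output_dir: Optional[str] = None
    save_traces: bool = False
    side_motion: SideMotionDefinition = SideMotionDefinition.TETHER_FRAME

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if len(self.conditions) == 0:
            raise ConfigurationError("conditions must be non-empty")
        if len(self.directions) == 0:
            raise ConfigurationError("directions must be non-empty")
        if not (self.trial_duration > 0):
            raise ConfigurationError("trial_duration must be > 0")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, enum.Enum):
                return obj.value
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        return plain(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        kwargs: dict = {}
        if "agent" in d:
            kwargs["agent"] = AgentConfig(**d.pop("agent"))
        if "stimulus" in d:
            sd = dict(d.pop("stimulus"))
            if "signal_direction" in sd:
                sd["signal_direction"] = SignalDirection(sd["signal_direction"])
            kwargs["stimulus"] = StimulusConfig(**sd)
        if "detector" in d:
            kwargs["detector"] = MotionDetectorConfig(**d.pop("detector"))
        if "segmentation" in d:
            kwargs["segmentation"] = SegmentationConfig(**d.pop("segmentation"))
        if "conditions" in d:
            kwargs["conditions"] = tuple(GatingMode(c) for c in d.pop("conditions"))
        if "directions" in d:
            kwargs["directions"] = tuple(
                SignalDirection(x) for x in d.pop("directions")
            )
        if "protocol" in d:
            kwargs["protocol"] = Protocol(d.pop("protocol"))
        if "side_motion" in d:
            kwargs["side_motion"] = SideMotionDefinition(d.pop("side_motion"))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TrialRecord:
    """Bookkeeping for one subject x cell trial."""

    subject: str
    condition: GatingMode
    direction: SignalDirection
    trial_order: int
    seed: int
    turn_sign: int
    artifacts: dict = field(default_factory=dict)


def trial_seed(
    master_seed: int,
    condition: GatingMode,
    direction: SignalDirection,
    subject_index: int,
) -> int:
    """Deterministic per-trial seed from the master seed and cell address."""
    ss = np.random.SeedSequence(
        master_seed,
        spawn_key=(
            MODE_CODES[condition],
            _DIRECTION_CODES[direction],
            subject_index,
        ),
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(subject_index,))
    )


def subject_cell_order(
    master_seed: int,
    subject_index: int,
    cells: Sequence[tuple[GatingMode, SignalDirection]],
) -> list[tuple[GatingMode, SignalDirection]]:
    """Seeded random presentation order of cells for a within-subject session."""
    rng = _subject_rng(master_seed, subject_index)
    rng.uniform()  # first draw is reserved for the subject's turn sign
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def _subject_turn_sign(master_seed: int, subject_index: int) -> int:
    return 1 if _subject_rng(master_seed, subject_index).uniform() < 0.5 else -1


def run_experiment(
    config: ExperimentConfig,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full design and return (trial table, comparison table).

    The trial table has one row per subject trial (ids, seed, and the
    kinematic summary); the comparison table holds the Mann-Whitney contrast
    of forward vs backward stimuli for each metric x condition.  When
    ``config.output_dir`` is set, both tables, a machine-readable manifest
    (config echo + per-trial seeds + package version), and optionally all
    per-trial trace/path/bout CSVs are written there.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        if config.save_traces:
            (out_dir / "trials").mkdir(exist_ok=True)

    cells = [(c, d) for c in config.conditions for d in config.directions]
    jobs: list[TrialRecord] = []
    if config.protocol is Protocol.BETWEEN_SUBJECT:
        for cond, direction in cells:
            for i in range(config.n_subjects):
                jobs.append(
                    TrialRecord(
                        subject=f"{cond.value}-{direction.value}-s{i:02d}",
                        condition=cond,
                        direction=direction,
                        trial_order=0,
                        seed=trial_seed(config.master_seed, cond, direction, i),
                        turn_sign=0,  # drawn inside run_trial from the seed
                    )
                )
    else:
        for i in range(config.n_subjects):
            sign = _subject_turn_sign(config.master_seed, i)
            order = subject_cell_order(config.master_seed, i, cells)
            for k, (cond, direction) in enumerate(order):
                jobs.append(
                    TrialRecord(
                        subject=f"s{i:02d}",
                        condition=cond,
                        direction=direction,
                        trial_order=k,
                        seed=trial_seed(config.master_seed, cond, direction, i),
                        turn_sign=sign,
                    )
                )

    rows = []
    manifest_trials = []
    for rec in jobs:
        stim = replace(config.stimulus, signal_direction=rec.direction)
        result: TrialResult = run_trial(
            config.agent,
            stim,
            rec.condition,
            config.trial_duration,
            seed=rec.seed,
            detector_config=config.detector,
            turn_sign=rec.turn_sign if rec.turn_sign in (1, -1) else None,
        )
        _, bouts, summary = analyze_trace(
            result.trace, config.segmentation, side_motion=config.side_motion
        )
        artifacts = {}
        if out_dir is not None and config.save_traces:
            stem = f"{rec.subject}_{rec.condition.value}_{rec.direction.value}"
            trace_path = out_dir / "trials" / f"{stem}_trace.csv"
            bouts_path = out_dir / "trials" / f"{stem}_bouts.csv"
            path_path = out_dir / "trials" / f"{stem}_path.csv"
            result.trace.to_csv(trace_path)
            bouts.to_csv(bouts_path)
            from .kinematics import integrate_path

            integrate_path(result.trace).to_csv(path_path)
            artifacts = {
                "trace": str(trace_path),
                "bouts": str(bouts_path),
                "path": str(path_path),
            }
        row = {
            "subject": rec.subject,
            "condition": rec.condition.value,
            "direction": rec.direction.value,
            "trial_order": rec.trial_order,
            "seed": rec.seed,
            "turn_sign": result.turn_sign,
        }
        row.update(summary.to_dict())
        rows.append(row)
        manifest_trials.append({**row, "artifacts": artifacts})
        if progress:
            print(
                f"[pauseloop] {rec.subject} {rec.condition.value} "
                f"{rec.direction.value} seed={rec.seed} "
                f"wf={summary.walking_fraction:.3f}"
            )

    trials_df = pd.DataFrame(rows)
    stats_rng = np.random.default_rng(
        np.random.SeedSequence(config.master_seed, spawn_key=(97, 1))
    )
    comparisons_df = compare_all(trials_df, rng=stats_rng)

    if out_dir is not None:
        trials_df.to_csv(out_dir / "trials.csv", index=False)
        write_comparisons(comparisons_df, out_dir / "comparisons.csv")
        manifest = {
            "package": "pauseloop",
            "version": _pkg_version,
            "config": config.to_dict(),
            "trials": manifest_trials,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return trials_df, comparisons_df


def plot_summary_panels(trials: pd.DataFrame, out_path) -> None:
    """Bar panels (mean +/- s.e.m. per condition x direction) for the four
    headline metrics; a quick human-inspection figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [
        ("walking_fraction", "Walking fraction"),
        ("mean_pause_duration", "Mean pause duration (s)"),
        ("total_side_motion", "Total side motion (cm)"),
        ("total_distance", "Total distance (cm)"),
    ]
    conditions = list(dict.fromkeys(trials["condition"]))
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    width = 0.35
    for ax, (metric, label) in zip(axes.ravel(), metrics):
        xs = np.arange(len(conditions))
        for off, (direction, color) in enumerate(
            [("FORWARD", "white"), ("BACKWARD", "0.6")]
        ):
            means, sems = [], []
            for cond in conditions:
                vals = trials.loc[
                    (trials["condition"] == cond)
                    & (trials["direction"] == direction),
                    metric,
                ].to_numpy(float)
                means.append(vals.mean() if vals.size else np.nan)
                sems.append(
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
                )
            ax.bar(
                xs + (off - 0.5) * width,
                means,
                width,
                yerr=sems,
                color=color,
                edgecolor="black",
                label=direction.lower(),
                capsize=3,
            )
        ax.set_xticks(xs)
        ax.set_xticklabels([c.replace("_", " ").lower() for c in conditions])
        ax.set_ylabel(label)
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
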