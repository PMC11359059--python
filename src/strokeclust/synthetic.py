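"""Seeded synthetic motion cohorts with known severity-group structure.

The generator emulates the statistical shape of upper-limb reach-and-grasp
recordings used for unsupervised severity staging: every subject performs
``n_tasks`` tasks, ``n_repetitions`` times each, producing 3-D position
trajectories for a small set of body-segment channels at a fixed sampling
rate.  Severity enters through the trunk channel only — stroke survivors
compensate for impaired arm function with trunk motion, so more severe
groups are given a larger trunk oscillation amplitude.  Non-trunk channels
carry a task-dependent sinusoid that is *common across groups*, so any
method that recovers the groups must rely on trunk-linked features.

The cohort is fully deterministic for a fixed seed: subject ``i`` draws all
of its noise from ``default_rng(seed + i)``, so extending a cohort with
more subjects never reshuffles existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LabelingError

# Axis split of the trunk compensation amplitude (x: forward lean dominates).
_TRUNK_AXIS_FRACTION = np.array([1.0, 0.5, 0.25])

# FMA-UE bounds and the severe cutoff anchored by the clinical categorization.
FMA_MAX = 66.0
FMA_SEVERE_BOUNDARY = 29.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for a synthetic cohort.

    Defaults mirror the wearable-sensor arm of the study design: 60 Hz
    sampling, five upper-limb channels including the sternum (T8) trunk
    channel, four tasks with three repetitions each, and trunk-compensation
    amplitudes that increase strictly with severity.
    """

    n_subjects_per_group: int = 10
    group_names: tuple[str, ...] = ("mild", "moderate", "severe")
    trunk_amplitude_per_group: tuple[float, ...] = (1.0, 2.0, 4.0)
    base_frequency_hz: float = 1.5
    sampling_rate_hz: float = 60.0
    duration_s: float = 3.0
    n_tasks: int = 4
    n_repetitions: int = 3
    channel_names: tuple[str, ...] = (
        "hand",
        "shoulder",
        "upper_arm",
        "forearm",
        "sternum_t8",
    )
    trunk_channel: str = "sternum_t8"
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        amps = self.trunk_amplitude_per_group
        if len(self.group_names) != len(amps):
            raise ConfigurationError(
                "trunk_amplitude_per_group must have one amplitude per group"
            )
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ConfigurationError(
                "trunk_amplitude_per_group must be strictly increasing with severity"
            )
        if self.sampling_rate_hz <= 2.0 * self.base_frequency_hz:
            raise ConfigurationError(
                "sampling_rate_hz must exceed 2 x base_frequency_hz (Nyquist)"
            )
        for name in ("n_subjects_per_group", "n_tasks", "n_repetitions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.group_names:
            raise ConfigurationError("group_names must be non-empty")
        if self.trunk_channel not in self.channel_names:
            raise ConfigurationError("channel_names must include the trunk channel")
        if self.n_samples < 11:
            raise ConfigurationError(
                "duration_s x sampling_rate_hz must give >= 11 samples "
                "(baseline window of 10 + 1)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_group * len(self.group_names)


@dataclass(frozen=True)
class MotionTrial:
    """One subject/task/repetition recording.

    ``positions`` has shape (time, channel, 3) in length units, all channels
    on one shared time base with no missing samples.
    """

    subject_id: str
    group: str | None
    task_id: str
    repetition: int
    sampling_rate_hz: float
    positions: np.ndarray
    channel_names: tuple[str, ...]
    fma_score: float | None = None

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the (time, 3) trajectory of one named channel."""
        return self.positions[:, self.channel_names.index(name), :]


def _task_signal(t: np.ndarray, f: float, task: int, ch: int) -> np.ndarray:
    """Shared (group-independent) task motion for one non-trunk channel."""
    out = np.empty((t.size, 3))
    amp = (0.8 + 0.1 * ch) * (1.0 + 0.05 * task)
    for axis in range(3):
        phase = 2.0 * np.pi * ((0.13 * task + 0.29 * axis + 0.17 * ch) % 1.0)
        out[:, axis] = amp * np.sin(2.0 * np.pi * f * t + phase)
    return out


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[MotionTrial], dict[str, str]]:
    """Generate all trials of a cohort plus ground-truth group labels.

    Returns exactly ``n_subjects_per_group x |groups| x n_tasks x
    n_repetitions`` trials, ordered by subject, task, repetition.  The trunk
    channel of each subject is a sinusoid whose amplitude is its group's
    trunk amplitude, plus i.i.d. Gaussian noise of sd ``noise_sd``;
    non-trunk channels carry the shared task signal plus noise.
    """
    config.validate()
    t = np.arange(config.n_samples) / config.sampling_rate_hz
    trunk_idx = config.channel_names.index(config.trunk_channel)
    omega = 2.0 * np.pi * config.base_frequency_hz

    trials: list[MotionTrial] = []
    groups: dict[str, str] = {}
    # fixed per-channel resting offsets; trunk displacement is baseline
    # referenced so these carry no information
    offsets = 0.3 * np.arange(len(config.channel_names))[:, None] + np.array(
        [0.0, 0.1, 0.9]
    )

    subject_idx = 0
    for g_idx, group in enumerate(config.group_names):
        amp = config.trunk_amplitude_per_group[g_idx]
        for _ in range(config.n_subjects_per_group):
            sid = f"S{subject_idx:04d}"
            groups[sid] = group
            rng = np.random.default_rng(config.seed + subject_idx)
            clean = np.empty((config.n_samples, len(config.channel_names), 3))
            for task in range(config.n_tasks):
                for ch in range(len(config.channel_names)):
                    if ch == trunk_idx:
                        clean[:, ch, :] = (
                            amp * _TRUNK_AXIS_FRACTION[None, :] * np.sin(omega * t)[:, None]
                        )
                    else:
                        clean[:, ch, :] = _task_signal(
                            t, config.base_frequency_hz, task, ch
                        )
                clean[:, :, :] += offsets[None, :, :]
                for rep in range(config.n_repetitions):
                    noise = rng.normal(0.0, config.noise_sd, clean.shape)
                    trials.append(
                        MotionTrial(
                            subject_id=sid,
                            group=group,
                            task_id=f"T{task}",
                            repetition=rep,
                            sampling_rate_hz=config.sampling_rate_hz,
                            positions=clean + noise,
                            channel_names=config.channel_names,
                        )
                    )
                clean[:, :, :] -= offsets[None, :, :]
            subject_idx += 1
    return trials, groups


def _fma_range(severity_index: int, n_groups: int) -> tuple[float, float]:
    """FMA-UE score band for a severity position (0 = mildest).

    The most severe group always scores below the clinical severe cutoff of
    29.  Three-group cohorts use the package's default mild/moderate
    boundary of 43 (mild 43-66, moderate 29-43); other group counts split
    [29, 66] into equal descending bands.  A single-group cohort is treated
    as the most severe group.
    """
    if severity_index == n_groups - 1:
        return (13.0, FMA_SEVERE_BOUNDARY - 0.1)
    if n_groups == 3:
        return (43.0, FMA_MAX) if severity_index == 0 else (FMA_SEVERE_BOUNDARY, 43.0)
    width = (FMA_MAX - FMA_SEVERE_BOUNDARY) / (n_groups - 1)
    hi = FMA_MAX - severity_index * width
    return (hi - width, hi)


def assign_reference_fma(
    trials: list[MotionTrial], config: CohortConfig
) -> list[MotionTrial]:
    """Attach per-subject reference FMA-UE scores drawn from group bands.

    Scores are monotone decreasing in severity: the most severe group draws
    below 29, milder groups from successively higher bands.  Seeded by the
    cohort seed plus the subject index, so a rerun reproduces scores
    exactly.
    """
    n_groups = len(config.group_names)
    subject_order: list[str] = []
    for tr in trials:
        if tr.subject_id not in subject_order:
            subject_order.append(tr.subject_id)
    scores: dict[str, float] = {}
    for idx, sid in enumerate(subject_order):
        group = next(tr.group for tr in trials if tr.subject_id == sid)
        if group not in config.group_names:
            raise LabelingError(f"unknown group {group!r} for subject {sid}")
        lo, hi = _fma_range(config.group_names.index(group), n_groups)
        rng = np.random.default_rng(config.seed + 1_000_003 + idx)
        scores[sid] = float(rng.uniform(lo, hi))
    return [dataclasses.replace(tr, fma_score=scores[tr.subject_id]) for tr in trials]


# ---------------------------------------------------------------------------
# CSV / manifest round trip


def write_cohort(
    trials: list[MotionTrial], groups: dict[str, str], out_dir: str | Path
) -> Path:
    """Write one CSV per trial plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for tr in trials:
        fname = f"{tr.subject_id}_{tr.task_id}_r{tr.repetition}.csv"
        cols = {"time_s": np.arange(tr.n_samples) / tr.sampling_rate_hz}
        for c, ch in enumerate(tr.channel_names):
            for a, axis in enumerate("xyz"):
                cols[f"{ch}_{axis}"] = tr.positions[:, c, a]
        pd.DataFrame(cols).to_csv(out / fname, index=False)
        entries.append(
            {
                "subject_id": tr.subject_id,
                "group": tr.group,
                "task_id": tr.task_id,
                "repetition": tr.repetition,
                "sampling_rate_hz": tr.sampling_rate_hz,
                "fma_score": tr.fma_score,
                "path": fname,
                "channels": list(tr.channel_names),
            }
        )
    manifest = {"groups": groups, "trials": entries}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_cohort(manifest_path: str | Path) -> tuple[list[MotionTrial], dict[str, str]]:
    """Load a cohort previously written by :func:`write_cohort`."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    trials = []
    for e in manifest["trials"]:
        df = pd.read_csv(mpath.parent / e["path"])
        channels = tuple(e["channels"])
        pos = np.stack(
            [
                np.column_stack([df[f"{ch}_{a}"].to_numpy() for a in "xyz"])
                for ch in channels
            ],
            axis=1,
        )
        trials.append(
            MotionTrial(
                subject_id=e["subject_id"],
                group=e["group"],
                task_id=e["task_id"],
                repetition=int(e["repetition"]),
                sampling_rate_hz=float(e["sampling_rate_hz"]),
                positions=pos,
                channel_names=channels,
                fma_score=e["fma_score"],
            )
        )
    return trials, manifest["groups"]
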