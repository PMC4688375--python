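"""Experiment timing: run schedules and scan-count bookkeeping.

The paradigm has two run types. *Alternating* runs interleave two
self-paced mental tasks -- counting down numbers (task A, signalling
"yes") and recalling positive autobiographical memories (task B,
signalling "no") -- in 32 s blocks separated by 16 s rest, three cycles
per run. *Binary-answer* runs play six spoken statements; 12 s after each
statement onset the subject is prompted to answer by performing task A
(true) or task B (false) for 24 s, followed by 16 s rest.

Scans are indexed 0-based over the whole run, dummies included; scan ``i``
covers the half-open interval ``[i*TR, (i+1)*TR)`` seconds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "Answer",
    "BlockLabel",
    "AcquisitionParams",
    "BlockEvent",
    "SentenceTrial",
    "RunSchedule",
    "RunKind",
    "InvalidConfigError",
    "ScheduleError",
    "build_alternating_run",
    "build_binary_answer_run",
    "count_training_scans",
    "response_scan_indices",
    "task_block_scan_indices",
    "schedule_to_events",
    "schedule_from_events",
    "mark_unacknowledged",
]


class InvalidConfigError(ValueError):
    """Raised when timing or configuration values are inconsistent."""


class ScheduleError(ValueError):
    """Raised when an operation falls outside a run's schedule."""


class BlockLabel(str, enum.Enum):
    TASK_A = "task_a"  # countdown / yes
    TASK_B = "task_b"  # autobiographical memory / no
    REST = "rest"
    DUMMY = "dummy"


class Answer(str, enum.Enum):
    YES = "yes"
    NO = "no"

    @property
    def sign(self) -> int:
        """+1 for yes (task A), -1 for no (task B)."""
        return 1 if self is Answer.YES else -1

    @property
    def task(self) -> BlockLabel:
        return BlockLabel.TASK_A if self is Answer.YES else BlockLabel.TASK_B


class RunKind(str, enum.Enum):
    ALTERNATING = "alternating"
    BINARY_ANSWER = "binary_answer"


@dataclass(frozen=True)
class AcquisitionParams:
    """Scanner timing and grid geometry.

    tr_seconds
        Repetition time between whole-brain volumes (s).
    n_dummy_scans
        Lead-in volumes discarded before analysis (magnetic saturation).
    grid_shape
        Voxel grid (x, y, z).
    voxel_size_mm
        Voxel edge lengths (mm).
    """

    tr_seconds: float = 2.0
    n_dummy_scans: int = 3
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise InvalidConfigError("tr_seconds must be positive")
        if self.n_dummy_scans < 0:
            raise InvalidConfigError("n_dummy_scans must be non-negative")
        if any(d < 1 for d in self.grid_shape):
            raise InvalidConfigError("all grid dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidConfigError("voxel sizes must be positive")


@dataclass(frozen=True)
class BlockEvent:
    label: BlockLabel
    onset_seconds: float
    duration_seconds: float
    acknowledged: bool = True

    @property
    def end_seconds(self) -> float:
        return self.onset_seconds + self.duration_seconds


@dataclass(frozen=True)
class SentenceTrial:
    """One statement-and-response trial of a binary-answer run.

    ``true_answer`` is ground truth recorded for scoring only; decoding
    never reads it.
    """

    sentence_id: int
    sentence_onset_seconds: float
    prompt_onset_seconds: float
    response_duration_seconds: float
    true_answer: Answer
    acknowledged: bool = True


@dataclass(frozen=True)
class RunSchedule:
    run_id: int
    day: int
    kind: RunKind
    acquisition: AcquisitionParams
    events: tuple[BlockEvent, ...]
    trials: tuple[SentenceTrial, ...] = field(default=())
    n_scans: int = 0
    duration_seconds: float = 0.0

    def __post_init__(self) -> None:
        tr = self.acquisition.tr_seconds
        if not math.isclose(self.n_scans * tr, self.duration_seconds):
            raise InvalidConfigError(
                f"duration {self.duration_seconds} s is not n_scans ({self.n_scans}) x TR ({tr})"
            )
        t = 0.0
        for ev in self.events:
            if not math.isclose(ev.onset_seconds, t, abs_tol=1e-9):
                raise InvalidConfigError("events must be contiguous and non-overlapping")
            t = ev.end_seconds
        if self.events and not math.isclose(t, self.duration_seconds, abs_tol=1e-9):
            raise InvalidConfigError("event durations must sum to run duration")

    @property
    def n_analysis_scans(self) -> int:
        """Scans remaining after the dummy lead-in is discarded."""
        return self.n_scans - self.acquisition.n_dummy_scans

    def task_blocks(self, label: BlockLabel) -> list[BlockEvent]:
        return [ev for ev in self.events if ev.label is label]


def _check_multiple_of_tr(value: float, tr: float, name: str) -> None:
    if value <= 0:
        raise InvalidConfigError(f"{name} must be positive")
    if not math.isclose(value / tr, round(value / tr)):
        raise InvalidConfigError(f"{name}={value} s is not a multiple of TR={tr} s")


def build_alternating_run(
    acq: AcquisitionParams,
    n_cycles: int = 3,
    task_seconds: float = 32.0,
    rest_seconds: float = 16.0,
    *,
    run_id: int = 0,
    day: int = 1,
) -> RunSchedule:
    """Build one alternating task-A/task-B run schedule.

    Events are ``[DUMMY] + n_cycles * [TASK_A, REST, TASK_B, REST]``.
    With the default timing (TR 2 s, 3 dummies, 3 cycles of 32 s task and
    16 s rest) a run spans 294 s and 147 scans.
    """
    if n_cycles < 0:
        raise InvalidConfigError("n_cycles must be >= 0")
    tr = acq.tr_seconds
    _check_multiple_of_tr(task_seconds, tr, "task_seconds")
    _check_multiple_of_tr(rest_seconds, tr, "rest_seconds")

    events: list[BlockEvent] = []
    t = 0.0
    if acq.n_dummy_scans:
        dur = acq.n_dummy_scans * tr
        events.append(BlockEvent(BlockLabel.DUMMY, t, dur))
        t += dur
    for _ in range(n_cycles):
        for label, dur in (
            (BlockLabel.TASK_A, task_seconds),
            (BlockLabel.REST, rest_seconds),
            (BlockLabel.TASK_B, task_seconds),
            (BlockLabel.REST, rest_seconds),
        ):
            events.append(BlockEvent(label, t, dur))
            t += dur
    n_scans = round(t / tr)
    return RunSchedule(
        run_id=run_id,
        day=day,
        kind=RunKind.ALTERNATING,
        acquisition=acq,
        events=tuple(events),
        n_scans=n_scans,
        duration_seconds=t,
    )


def build_binary_answer_run(
    acq: AcquisitionParams,
    answer_key: list[Answer],
    pre_prompt: float = 12.0,
    response: float = 24.0,
    rest: float = 16.0,
    *,
    run_id: int = 0,
    day: int = 2,
) -> RunSchedule:
    """Build one binary-answer run schedule from a yes/no answer key.

    Each trial spans ``pre_prompt + response + rest`` seconds: the
    statement plays at trial onset, the answer prompt arrives
    ``pre_prompt`` s later, and the subject performs the answering task
    for ``response`` s. The answer key is ground truth used by the
    simulator and by scoring; decoding operations never see it.
    """
    if not answer_key:
        raise InvalidConfigError("answer_key must be non-empty")
    tr = acq.tr_seconds
    for name, val in (("pre_prompt", pre_prompt), ("response", response), ("rest", rest)):
        _check_multiple_of_tr(val, tr, name)

    events: list[BlockEvent] = []
    trials: list[SentenceTrial] = []
    t = 0.0
    if acq.n_dummy_scans:
        dur = acq.n_dummy_scans * tr
        events.append(BlockEvent(BlockLabel.DUMMY, t, dur))
        t += dur
    for i, ans in enumerate(answer_key, start=1):
        ans = Answer(ans)
        trials.append(
            SentenceTrial(
                sentence_id=i,
                sentence_onset_seconds=t,
                prompt_onset_seconds=t + pre_prompt,
                response_duration_seconds=response,
                true_answer=ans,
            )
        )
        events.append(BlockEvent(BlockLabel.REST, t, pre_prompt))
        events.append(BlockEvent(ans.task, t + pre_prompt, response))
        events.append(BlockEvent(BlockLabel.REST, t + pre_prompt + response, rest))
        t += pre_prompt + response + rest
    n_scans = round(t / tr)
    return RunSchedule(
        run_id=run_id,
        day=day,
        kind=RunKind.BINARY_ANSWER,
        acquisition=acq,
        events=tuple(events),
        trials=tuple(trials),
        n_scans=n_scans,
        duration_seconds=t,
    )


def count_training_scans(n_runs: int, blocks_per_task_per_run: int, scans_per_block: int) -> int:
    """Training scans contributed per class: runs x blocks/run x scans/block."""
    if min(n_runs, blocks_per_task_per_run, scans_per_block) < 0:
        raise InvalidConfigError("arguments must be non-negative")
    return n_runs * blocks_per_task_per_run * scans_per_block


def response_scan_indices(schedule: RunSchedule, shift_seconds: float = 4.0) -> list[list[int]]:
    """Per-trial 0-based scan indices of the hemodynamically shifted response window.

    Each trial maps to ``response_duration / TR`` consecutive indices
    starting at ``(prompt_onset + shift) / TR``, counted over the full run
    including dummy scans. The default 4 s (two TR) shift accounts for
    the hemodynamic delay between task onset and the BOLD response.
    """
    if schedule.kind is not RunKind.BINARY_ANSWER:
        raise ScheduleError("response_scan_indices requires a binary-answer run")
    tr = schedule.acquisition.tr_seconds
    if not math.isclose(shift_seconds / tr, round(shift_seconds / tr)):
        raise InvalidConfigError(f"shift_seconds={shift_seconds} is not a multiple of TR={tr}")
    out: list[list[int]] = []
    for trial in schedule.trials:
        start = round((trial.prompt_onset_seconds + shift_seconds) / tr)
        n = round(trial.response_duration_seconds / tr)
        idx = list(range(start, start + n))
        if idx[0] < 0 or idx[-1] >= schedule.n_scans:
            raise ScheduleError(
                f"shifted response window {idx[0]}..{idx[-1]} exceeds run of {schedule.n_scans} scans"
            )
        out.append(idx)
    return out


def mark_unacknowledged(schedule: RunSchedule, block_indices: list[int]) -> RunSchedule:
    """Return a copy with the given task blocks flagged as unacknowledged.

    ``block_indices`` count task blocks only (A and B interleaved, in
    onset order, 0-based). The paradigm never infers acknowledgement;
    this is set by the simulator or read from the events file.
    """
    task_positions = [
        i for i, ev in enumerate(schedule.events)
        if ev.label in (BlockLabel.TASK_A, BlockLabel.TASK_B)
    ]
    events = list(schedule.events)
    for bi in block_indices:
        if bi < 0 or bi >= len(task_positions):
            raise ScheduleError(f"no task block with index {bi}")
        pos = task_positions[bi]
        events[pos] = replace(events[pos], acknowledged=False)
    trials = schedule.trials
    if schedule.kind is RunKind.BINARY_ANSWER:
        new_trials = []
        for ti, trial in enumerate(trials):
            new_trials.append(replace(trial, acknowledged=ti not in set(block_indices)))
        trials = tuple(new_trials)
    return replace(schedule, events=tuple(events), trials=trials)


def schedule_to_events(schedule: RunSchedule) -> pd.DataFrame:
    """Events table (BIDS-events dialect): onset, duration, trial_type, acknowledged, true_answer."""
    answer_by_onset = {
        t.prompt_onset_seconds: t.true_answer.value for t in schedule.trials
    }
    rows = []
    for ev in schedule.events:
        rows.append(
            {
                "onset": ev.onset_seconds,
                "duration": ev.duration_seconds,
                "trial_type": ev.label.value,
                "acknowledged": int(ev.acknowledged),
                "true_answer": answer_by_onset.get(ev.onset_seconds, "n/a"),
            }
        )
    return pd.DataFrame(rows)


def schedule_from_events(
    events: pd.DataFrame,
    acq: AcquisitionParams,
    *,
    run_id: int,
    day: int,
    kind: RunKind,
) -> RunSchedule:
    """Rebuild a RunSchedule from an events table plus acquisition metadata."""
    evs = []
    for _, row in events.iterrows():
        evs.append(
            BlockEvent(
                BlockLabel(row["trial_type"]),
                float(row["onset"]),
                float(row["duration"]),
                bool(int(row["acknowledged"])),
            )
        )
    duration = evs[-1].end_seconds if evs else 0.0
    trials: list[SentenceTrial] = []
    if kind is RunKind.BINARY_ANSWER:
        sid = 0
        for _, row in events.iterrows():
            if row["trial_type"] in (BlockLabel.TASK_A.value, BlockLabel.TASK_B.value):
                sid += 1
                trials.append(
                    SentenceTrial(
                        sentence_id=sid,
                        sentence_onset_seconds=_sentence_onset_of(events, float(row["onset"])),
                        prompt_onset_seconds=float(row["onset"]),
                        response_duration_seconds=float(row["duration"]),
                        true_answer=Answer(row["true_answer"]),
                        acknowledged=bool(int(row["acknowledged"])),
                    )
                )
    return RunSchedule(
        run_id=run_id,
        day=day,
        kind=kind,
        acquisition=acq,
        events=tuple(evs),
        trials=tuple(trials),
        n_scans=round(duration / acq.tr_seconds),
        duration_seconds=duration,
    )


def _sentence_onset_of(events: pd.DataFrame, prompt_onset: float) -> float:
    # sentence onset = onset of the rest block immediately preceding the prompt
    prior = events[(events["onset"] < prompt_onset) & (events["trial_type"] == BlockLabel.REST.value)]
    if prior.empty:
        return prompt_onset
    return float(prior.iloc[-1]["onset"])


def task_block_scan_indices(
    schedule: RunSchedule, shift_seconds: float = 4.0
) -> list[tuple[BlockEvent, list[int]]]:
    """Shifted scan-index windows for each task block of an alternating run.

    A 32 s block covers 16 scans in the window ``[onset+shift,
    onset+duration+shift)``; the block length is preserved, only shifted.
    """
    tr = schedule.acquisition.tr_seconds
    if not math.isclose(shift_seconds / tr, round(shift_seconds / tr)):
        raise InvalidConfigError(f"shift_seconds={shift_seconds} is not a multiple of TR={tr}")
    out = []
    for ev in schedule.events:
        if ev.label not in (BlockLabel.TASK_A, BlockLabel.TASK_B):
            continue
        start = round((ev.onset_seconds + shift_seconds) / tr)
        n = round(ev.duration_seconds / tr)
        idx = [i for i in range(start, start + n) if i < schedule.n_scans]
        out.append((ev, idx))
    return out
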