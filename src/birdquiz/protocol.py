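"""Experiment schedule: tests and training days for simulated cohorts.

The default schedule runs a pretest on day 0, fifty-question training
sessions on days 1, 2, 4 and 5, a midterm on day 3, a posttest on day 6 and
a delayed test on day 20 (a 14-day retention gap).  Tests present every
catalog species once, with the whole catalog as the choice set, and give no
feedback; training items come from the quiz engine and do give feedback.

Each participant is driven by three independent RNG streams derived from
(master_seed, participant_id): one for the engine, one for learner answers
and one for test administration.  The arm label only ever touches the engine
stream, so pretest results are arm-invariant by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .catalog import SpeciesCatalog
from .engine import (
    AnswerRecord,
    EngineConfig,
    ProficiencyState,
    QuizItem,
    next_item,
    update_proficiency,
)
from .learner import LearnerConfig, LearnerState, answer_item, observe_feedback

TEST_PHASES = ("pretest", "midterm", "posttest", "delayed")

DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("pretest", 0),
    ("training1", 1),
    ("training2", 2),
    ("midterm", 3),
    ("training3", 4),
    ("training4", 5),
    ("posttest", 6),
    ("delayed", 20),
)


def is_training_phase(phase: str) -> bool:
    return phase.startswith("training")


@dataclass
class ProtocolConfig:
    schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    questions_per_training_day: int = 50
    session_duration: float = 0.02  # days; ~30 min per sitting

    def __post_init__(self) -> None:
        offsets = [day for _, day in self.schedule]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("schedule day offsets must be strictly increasing")
        if self.questions_per_training_day < 1:
            raise ValueError("questions_per_training_day must be >= 1")
        if self.session_duration < 0:
            raise ValueError("session_duration cannot be negative")

    def day_of(self, phase: str) -> float:
        for name, day in self.schedule:
            if name == phase:
                return day
        raise KeyError(f"phase {phase!r} not in schedule")


@dataclass(frozen=True)
class LogEvent:
    """One answered item, test or training."""

    phase: str
    time_days: float
    item_index: int
    correct: str
    choices: tuple[str, ...]  # presented order
    selected: str
    is_correct: bool


@dataclass
class ExperimentLog:
    """Ordered event stream for one participant plus per-phase proficiency
    snapshots; the unit of analysis for every metric."""

    participant_id: int
    arm: str
    events: list[LogEvent] = field(default_factory=list)
    snapshots: dict[str, dict[str, int]] = field(default_factory=dict)

    def events_in(self, phase: str) -> list[LogEvent]:
        return [e for e in self.events if e.phase == phase]

    def training_events(self) -> list[LogEvent]:
        return [e for e in self.events if is_training_phase(e.phase)]

    def phases(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.events:
            if e.phase not in seen:
                seen.append(e.phase)
        return tuple(seen)


Responder = Callable[[QuizItem], str]


def run_test(
    learner: LearnerState,
    catalog: SpeciesCatalog,
    phase: str,
    time: float,
    rng: np.random.Generator,
    responder: Responder | None = None,
) -> list[LogEvent]:
    """Administer one test: every species once, in shuffled order, with the
    whole catalog as choices; no feedback and no learner update.

    ``responder`` overrides the simulated learner (used for oracle
    responders); it receives each :class:`QuizItem` and returns an
    abbreviation.
    """
    abbrevs = list(catalog.abbreviations)
    order = rng.permutation(len(abbrevs))
    events = []
    for idx, species_i in enumerate(order):
        correct = abbrevs[species_i]
        perm = rng.permutation(len(abbrevs))
        presented = tuple(abbrevs[i] for i in perm)
        item = QuizItem(
            correct=correct,
            distracters=tuple(a for a in abbrevs if a != correct),
            presented_order=presented,
            item_index=idx,
            time=time,
        )
        if responder is not None:
            selected = responder(item)
        else:
            selected = answer_item(learner, item, catalog, rng)
        if learner.config.test_feedback:
            observe_feedback(learner, correct, time)
        events.append(
            LogEvent(
                phase=phase,
                time_days=time,
                item_index=idx,
                correct=correct,
                choices=presented,
                selected=selected,
                is_correct=selected == correct,
            )
        )
    return events


def run_training_day(
    proficiency: ProficiencyState,
    learner: LearnerState,
    catalog: SpeciesCatalog,
    engine_config: EngineConfig,
    protocol_config: ProtocolConfig,
    phase: str,
    day: float,
    engine_rng: np.random.Generator,
    learner_rng: np.random.Generator,
    start_index: int = 0,
) -> list[LogEvent]:
    """One training session: generate, answer, and score
    ``questions_per_training_day`` items, updating proficiency and memory
    after each.  Item timestamps are evenly spaced over
    ``session_duration`` starting at the day offset."""
    q = protocol_config.questions_per_training_day
    step = protocol_config.session_duration / q
    events = []
    for i in range(q):
        t = day + i * step
        item = next_item(
            proficiency,
            catalog,
            engine_config,
            engine_rng,
            item_index=start_index + i,
            time=t,
        )
        selected = answer_item(learner, item, catalog, learner_rng)
        answer = AnswerRecord(item=item, selected=selected)
        update_proficiency(proficiency, answer)
        observe_feedback(learner, item.correct, t)
        events.append(
            LogEvent(
                phase=phase,
                time_days=t,
                item_index=start_index + i,
                correct=item.correct,
                choices=item.presented_order,
                selected=selected,
                is_correct=answer.is_correct,
            )
        )
    return events


def participant_rngs(
    master_seed: int, participant_id: int
) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """(engine, learner, test) streams for one participant, all derived from
    (master_seed, participant_id)."""
    children = np.random.SeedSequence([master_seed, participant_id]).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]


def run_participant(
    arm: str,
    catalog: SpeciesCatalog,
    learner_config: LearnerConfig,
    engine_config: EngineConfig,
    protocol_config: ProtocolConfig,
    participant_id: int,
    master_seed: int,
) -> ExperimentLog:
    """Run the full schedule for one simulated participant.

    Fully reproducible from (master_seed, participant_id); the ``arm`` label
    selects the engine mode and nothing else.
    """
    engine_rng, learner_rng, test_rng = participant_rngs(master_seed, participant_id)
    engine_config = EngineConfig(
        **{**engine_config.__dict__, "mode": arm}
    )
    proficiency = ProficiencyState.from_catalog(catalog)
    learner = LearnerState(learner_config, catalog.abbreviations)
    log = ExperimentLog(participant_id=participant_id, arm=arm)
    training_counter = 0
    for phase, day in protocol_config.schedule:
        if is_training_phase(phase):
            events = run_training_day(
                proficiency,
                learner,
                catalog,
                engine_config,
                protocol_config,
                phase,
                day,
                engine_rng,
                learner_rng,
                start_index=training_counter,
            )
            training_counter += len(events)
        else:
            events = run_test(learner, catalog, phase, day, test_rng)
        log.events.extend(events)
        log.snapshots[phase] = proficiency.snapshot()
    return log


def run_cohort(
    n_per_arm: int,
    catalog: SpeciesCatalog,
    learner_config: LearnerConfig,
    engine_config: EngineConfig,
    protocol_config: ProtocolConfig,
    master_seed: int,
) -> list[ExperimentLog]:
    """Simulate ``n_per_arm`` participants per arm with independent seeds.

    Participant ids run 1..n (adaptive) and n+1..2n (baseline).
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    logs = []
    for i in range(n_per_arm):
        logs.append(
            run_participant(
                "adaptive", catalog, learner_config, engine_config,
                protocol_config, i + 1, master_seed,
            )
        )
    for i in range(n_per_arm):
        logs.append(
            run_participant(
                "baseline", catalog, learner_config, engine_config,
                protocol_config, n_per_arm + i + 1, master_seed,
            )
        )
    return logs


# -- JSON-lines serialization ----------------------------------------------


class LogParseError(ValueError):
    """Raised with file and line number when a log line cannot be parsed."""


def write_log(log: ExperimentLog, path: str | Path) -> None:
    """Serialize one participant log as JSON-lines (one event per line,
    proficiency snapshots as separate typed lines)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in log.events:
            fh.write(
                json.dumps(
                    {
                        "type": "event",
                        "participant_id": log.participant_id,
                        "arm": log.arm,
                        "phase": e.phase,
                        "time_days": float(e.time_days),
                        "item_index": int(e.item_index),
                        "correct_abbrev": e.correct,
                        "choice_abbrevs": list(e.choices),
                        "selected_abbrev": e.selected,
                        "is_correct": e.is_correct,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
        for phase, levels in log.snapshots.items():
            fh.write(
                json.dumps(
                    {
                        "type": "snapshot",
                        "participant_id": log.participant_id,
                        "arm": log.arm,
                        "phase": phase,
                        "levels": levels,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_log(path: str | Path) -> ExperimentLog:
    path = Path(path)
    log: ExperimentLog | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                kind = rec["type"]
                if log is None:
                    log = ExperimentLog(
                        participant_id=int(rec["participant_id"]), arm=rec["arm"]
                    )
                if kind == "event":
                    log.events.append(
                        LogEvent(
                            phase=rec["phase"],
                            time_days=float(rec["time_days"]),
                            item_index=int(rec["item_index"]),
                            correct=rec["correct_abbrev"],
                            choices=tuple(rec["choice_abbrevs"]),
                            selected=rec["selected_abbrev"],
                            is_correct=bool(rec["is_correct"]),
                        )
                    )
                elif kind == "snapshot":
                    log.snapshots[rec["phase"]] = {
                        k: int(v) for k, v in rec["levels"].items()
                    }
                else:
                    raise ValueError(f"unknown record type {kind!r}")
            except (ValueError, KeyError, TypeError) as exc:
                raise LogParseError(f"{path}:{lineno}: {exc}") from exc
    if log is None:
        raise LogParseError(f"{path}: empty log file")
    return log


def read_logs(directory: str | Path, pattern: str = "*.jsonl") -> list[ExperimentLog]:
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise LogParseError(f"{directory}: no log files matching {pattern}")
    return [read_log(p) for p in paths]
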