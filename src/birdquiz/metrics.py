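"""Descriptive metrics over experiment logs.

Per participant and species: number of training questions, inverse lag time
(reciprocal days between the species' last training item and a test), and
median question interval (median number of questions between successive
training items on the same species, measured in item-index units).  Per
species and arm: test accuracy with binomial standard errors and confusion
counts.  Arm contrasts use a label-permutation test on mean scores rather
than any model fit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .protocol import TEST_PHASES, ExperimentLog, is_training_phase


def test_scores(log: ExperimentLog) -> dict[str, int]:
    """Number of correct answers per test phase present in the log."""
    scores: dict[str, int] = {}
    for e in log.events:
        if not is_training_phase(e.phase):
            scores[e.phase] = scores.get(e.phase, 0) + int(e.is_correct)
    if not scores:
        raise KeyError("log contains no test phases")
    return scores


def phase_score(log: ExperimentLog, phase: str) -> int:
    events = log.events_in(phase)
    if not events:
        raise KeyError(f"phase {phase!r} not present in log")
    return sum(e.is_correct for e in events)


def _events_before_phase(log: ExperimentLog, upto_phase: str | None):
    if upto_phase is None:
        return log.events
    for i, e in enumerate(log.events):
        if e.phase == upto_phase:
            return log.events[:i]
    raise KeyError(f"phase {upto_phase!r} not present in log")


def training_question_count(
    log: ExperimentLog, species: str, upto_phase: str | None = None
) -> int:
    """Training items with ``species`` as the correct choice (before
    ``upto_phase`` if given)."""
    return sum(
        1
        for e in _events_before_phase(log, upto_phase)
        if is_training_phase(e.phase) and e.correct == species
    )


def inverse_lag_time(log: ExperimentLog, species: str, test_phase: str) -> float | None:
    """1 / (days between the species' last pre-test training item and the
    test).  ``None`` (missing, not zero) if the species was never a training
    correct choice before the test."""
    test_events = log.events_in(test_phase)
    if not test_events:
        raise KeyError(f"phase {test_phase!r} not present in log")
    test_time = min(e.time_days for e in test_events)
    last = None
    for e in _events_before_phase(log, test_phase):
        if is_training_phase(e.phase) and e.correct == species:
            last = e.time_days
    if last is None:
        return None
    return 1.0 / (test_time - last)


def median_question_interval(log: ExperimentLog, species: str) -> float | None:
    """Median gap (in questions) between successive training items on the
    species, using the global training item index; ``None`` with fewer than
    two occurrences."""
    indices = [e.item_index for e in log.training_events() if e.correct == species]
    if len(indices) < 2:
        return None
    return float(np.median(np.diff(sorted(indices))))


def species_accuracy(
    logs: Sequence[ExperimentLog], species: str, test_phase: str, arm: str
) -> tuple[float, float]:
    """(mean accuracy, binomial SE) for one species' test item across the
    participants of one arm."""
    outcomes = []
    for log in logs:
        if log.arm != arm:
            continue
        for e in log.events_in(test_phase):
            if e.correct == species:
                outcomes.append(int(e.is_correct))
    if not outcomes:
        raise ValueError(f"no {arm!r} logs with {species!r} in {test_phase!r}")
    n = len(outcomes)
    p_hat = float(np.mean(outcomes))
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return p_hat, se


def confusion_matrix(
    logs: Sequence[ExperimentLog],
    test_phase: str,
    arm: str,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Counts of (correct species, selected species) over one arm's test
    items; rows are the true species.  Row order follows ``order`` when
    given, else sorted abbreviations."""
    arm_logs = [log for log in logs if log.arm == arm]
    if not arm_logs:
        raise ValueError(f"no logs for arm {arm!r}")
    species: set[str] = set()
    for log in arm_logs:
        for e in log.events_in(test_phase):
            species.add(e.correct)
            species.add(e.selected)
    labels = list(order) if order is not None else sorted(species)
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for log in arm_logs:
        for e in log.events_in(test_phase):
            mat.loc[e.correct, e.selected] += 1
    return mat


def permutation_arm_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_perm: int = 9999,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Monte-Carlo over ``n_perm`` label shuffles with the add-one correction,
    so the smallest attainable p is 1/(n_perm + 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[: a.size].mean() - perm[a.size :].mean())
        if diff >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# -- tabular exports --------------------------------------------------------


def scores_frame(logs: Sequence[ExperimentLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for phase, score in test_scores(log).items():
            rows.append(
                {
                    "participant": log.participant_id,
                    "arm": log.arm,
                    "phase": phase,
                    "score": score,
                }
            )
    return pd.DataFrame(rows, columns=["participant", "arm", "phase", "score"])


def species_metrics_frame(
    logs: Sequence[ExperimentLog],
    test_phase: str = "posttest",
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (participant, species) explanatory variables plus the species'
    outcome on ``test_phase``.  Missing values stay empty in the CSV."""
    rows = []
    for log in logs:
        if species_order is not None:
            species = list(species_order)
        else:
            species = sorted({e.correct for e in log.events_in(test_phase)})
        test_correct = {
            e.correct: int(e.is_correct) for e in log.events_in(test_phase)
        }
        for sp in species:
            rows.append(
                {
                    "participant": log.participant_id,
                    "arm": log.arm,
                    "species": sp,
                    "n_training_questions": training_question_count(
                        log, sp, upto_phase=test_phase
                    ),
                    "inverse_lag_per_day": inverse_lag_time(log, sp, test_phase),
                    "median_question_interval": median_question_interval(log, sp),
                    "test_correct": test_correct.get(sp),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "arm",
            "species",
            "n_training_questions",
            "inverse_lag_per_day",
            "median_question_interval",
            "test_correct",
        ],
    )


def export_metrics(
    logs: Sequence[ExperimentLog],
    out_dir: str | Path,
    test_phase: str = "posttest",
    confusion_phases: Iterable[str] = TEST_PHASES,
    species_order: Sequence[str] | None = None,
) -> list[Path]:
    """Write scores.csv, species_metrics.csv and confusion_<phase>.csv files;
    returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    scores_path = out_dir / "scores.csv"
    scores_frame(logs).to_csv(scores_path, index=False)
    written.append(scores_path)
    sm_path = out_dir / "species_metrics.csv"
    species_metrics_frame(logs, test_phase, species_order).to_csv(sm_path, index=False)
    written.append(sm_path)
    arms = sorted({log.arm for log in logs})
    for phase in confusion_phases:
        for arm in arms:
            mat = confusion_matrix(logs, phase, arm, order=species_order)
            path = out_dir / f"confusion_{phase}_{arm}.csv"
            mat.to_csv(path, index_label="correct")
            written.append(path)
    return written
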