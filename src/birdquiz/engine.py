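"""Adaptive and baseline quiz generation with per-species proficiency.

Every species starts at proficiency 0.  A correct answer raises the correct
species by one; a wrong answer lowers both the correct species and the
selected distracter by one, floored at zero.  A species is "mastered" once
its level reaches ``mastery_threshold`` (default 3, i.e. level > 2).

In adaptive mode the correct choice is normally drawn from the unmastered
pool; with review probability

    P = p * (w * N_u) / (N_u + w * N_m)          (printed form)

it is drawn from the mastered pool instead, where N_u / N_m count unmastered
and mastered species, p is the maximum review probability and w the review
weight.  The printed numerator shrinks as mastery grows; the
``mastered_variant`` numerator (w * N_m) is provided as a switchable
alternative since review arguably should grow with the mastered pool.

Distracter composition depends on the proficiency L of the correct choice:
low-L items pair the correct species with well-known (high-proficiency)
alternatives, and as L rises the alternatives shift toward low-proficiency
and similar-song species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import SpeciesCatalog

MODES = ("adaptive", "baseline")
REVIEW_NUMERATORS = ("printed", "mastered_variant")


@dataclass
class EngineConfig:
    mode: str = "adaptive"
    n_choices: int = 5
    max_review_probability: float = 0.25
    review_weight: float = 0.5
    mastery_threshold: int = 3
    review_numerator: str = "printed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.review_numerator not in REVIEW_NUMERATORS:
            raise ValueError(
                f"review_numerator must be one of {REVIEW_NUMERATORS}, "
                f"got {self.review_numerator!r}"
            )
        if not 0.0 <= self.max_review_probability <= 1.0:
            raise ValueError("max_review_probability must be in [0, 1]")
        if self.review_weight <= 0:
            raise ValueError("review_weight must be positive")
        if self.mastery_threshold < 1:
            raise ValueError("mastery_threshold must be >= 1")
        if self.n_choices < 2:
            raise ValueError("n_choices must be >= 2")


class ProficiencyState:
    """Non-negative integer proficiency per species, all initialised to 0."""

    def __init__(self, abbreviations):
        self._level: dict[str, int] = {a: 0 for a in abbreviations}
        if not self._level:
            raise ValueError("proficiency state needs at least one species")

    @classmethod
    def from_catalog(cls, catalog: SpeciesCatalog) -> "ProficiencyState":
        return cls(catalog.abbreviations)

    def level(self, abbreviation: str) -> int:
        return self._level[abbreviation]

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self._level)

    def pools(self, threshold: int) -> tuple[list[str], list[str]]:
        """(unmastered, mastered) species lists, in catalog order."""
        unmastered = [a for a, lv in self._level.items() if lv < threshold]
        mastered = [a for a, lv in self._level.items() if lv >= threshold]
        return unmastered, mastered

    def all_mastered(self, threshold: int) -> bool:
        return all(lv >= threshold for lv in self._level.values())

    def snapshot(self) -> dict[str, int]:
        return dict(self._level)

    def _bump(self, abbreviation: str, delta: int) -> None:
        self._level[abbreviation] = max(0, self._level[abbreviation] + delta)


@dataclass(frozen=True)
class QuizItem:
    """One multiple-choice question: a correct species plus distracters,
    shown in ``presented_order``."""

    correct: str
    distracters: tuple[str, ...]
    presented_order: tuple[str, ...]
    item_index: int
    time: float

    def __post_init__(self) -> None:
        choices = (self.correct,) + self.distracters
        if len(set(choices)) != len(choices):
            raise ValueError("quiz choices must be distinct")
        if sorted(self.presented_order) != sorted(choices):
            raise ValueError("presented_order must permute the choices")


@dataclass(frozen=True)
class AnswerRecord:
    item: QuizItem
    selected: str
    is_correct: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "is_correct", self.selected == self.item.correct)


def is_mastered(level: int, config: EngineConfig) -> bool:
    if level < 0:
        raise ValueError("proficiency level cannot be negative")
    return level >= config.mastery_threshold


def review_probability(n_unmastered: int, n_mastered: int, config: EngineConfig) -> float:
    """Probability that the next correct choice is drawn from the mastered pool."""
    if n_unmastered < 0 or n_mastered < 0:
        raise ValueError("counts must be non-negative")
    if n_unmastered + n_mastered == 0:
        raise ValueError("at least one species required")
    p = config.max_review_probability
    w = config.review_weight
    denom = n_unmastered + w * n_mastered
    if config.review_numerator == "printed":
        value = p * (w * n_unmastered) / denom
    else:
        value = p * (w * n_mastered) / denom
    return min(1.0, max(0.0, value))


def select_correct(
    state: ProficiencyState, config: EngineConfig, rng: np.random.Generator
) -> str:
    """Draw the correct choice for the next item.

    Baseline: uniform over the catalog.  Adaptive: uniform over the
    unmastered pool, except that with the review probability the draw comes
    from the mastered pool; an empty pool falls through to the other one.
    """
    if config.mode == "baseline":
        return str(rng.choice(state.species))
    unmastered, mastered = state.pools(config.mastery_threshold)
    if not mastered:
        return str(rng.choice(unmastered))
    if not unmastered:
        return str(rng.choice(mastered))
    p_review = review_probability(len(unmastered), len(mastered), config)
    pool = mastered if rng.random() < p_review else unmastered
    return str(rng.choice(pool))


def _shuffled(cands: list[str], rng: np.random.Generator) -> list[str]:
    order = rng.permutation(len(cands))
    return [cands[i] for i in order]


def select_distracters(
    state: ProficiencyState,
    correct: str,
    catalog: SpeciesCatalog,
    config: EngineConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Choose the incorrect alternatives for ``correct``.

    Adaptive tiers, with L the proficiency of the correct choice and
    k = n_choices - 1 slots (ties in proficiency broken uniformly at random):

    * L = 0  — the k highest-proficiency species.
    * L = 1  — the k//2 highest plus the remaining lowest-proficiency
      species; if the correct choice has an E-level similar species not
      already picked, it takes one low slot.
    * L >= 2 — all similar species of the correct choice (E before D), then
      lowest-proficiency fillers.

    Baseline: a uniform sample without replacement from the rest of the
    catalog.
    """
    k = config.n_choices - 1
    cands = [a for a in catalog.abbreviations if a != correct]
    if len(cands) < k:
        raise ValueError(
            f"catalog of {len(catalog)} species cannot supply {k} distracters"
        )
    if config.mode == "baseline":
        picked = rng.choice(len(cands), size=k, replace=False)
        return tuple(cands[i] for i in picked)

    level = state.level
    shuffled = _shuffled(cands, rng)
    lvl = state.level(correct)
    if lvl == 0:
        ranked = sorted(shuffled, key=lambda a: -level(a))  # stable: ties random
        return tuple(ranked[:k])
    if lvl == 1:
        n_hi = k // 2
        hi = sorted(shuffled, key=lambda a: -level(a))[:n_hi]
        rest = [a for a in shuffled if a not in hi]
        lo = sorted(rest, key=level)[: k - n_hi]
        picks = hi + lo
        easy = [
            r.abbreviation
            for r in catalog.similar_of(correct)
            if r.level == "E" and r.abbreviation not in picks
        ]
        if easy:
            picks[-1] = easy[int(rng.integers(len(easy)))] if len(easy) > 1 else easy[0]
        return tuple(picks)
    # L >= 2, including review items on mastered species
    sims = sorted(catalog.similar_of(correct), key=lambda r: r.level != "E")
    picks = [r.abbreviation for r in sims][:k]
    rest = [a for a in shuffled if a not in picks]
    fillers = sorted(rest, key=level)[: k - len(picks)]
    return tuple(picks + fillers)


def next_item(
    state: ProficiencyState,
    catalog: SpeciesCatalog,
    config: EngineConfig,
    rng: np.random.Generator,
    item_index: int = 0,
    time: float = 0.0,
) -> QuizItem:
    """Generate the next quiz item: correct choice, distracters, and a
    uniformly random presentation order."""
    correct = select_correct(state, config, rng)
    distracters = select_distracters(state, correct, catalog, config, rng)
    choices = (correct,) + distracters
    perm = rng.permutation(len(choices))
    presented = tuple(choices[i] for i in perm)
    return QuizItem(
        correct=correct,
        distracters=distracters,
        presented_order=presented,
        item_index=item_index,
        time=time,
    )


def update_proficiency(state: ProficiencyState, answer: AnswerRecord) -> ProficiencyState:
    """Apply one answer's bookkeeping (in place; the state is returned).

    Correct: +1 on the correct species.  Incorrect: -1 on both the correct
    species and the selected distracter, never below zero.
    """
    if answer.is_correct:
        state._bump(answer.item.correct, +1)
    else:
        state._bump(answer.item.correct, -1)
        state._bump(answer.selected, -1)
    return state
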