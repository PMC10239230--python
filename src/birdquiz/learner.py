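"""Simulated trainee with an exponential-forgetting memory.

Each species has a retention half-life.  Recall probability decays as
``2**(-dt / half_life)`` since the last exposure; a training exposure with
feedback multiplies the half-life by ``1 + (alpha - 1) * (1 - r)**beta``
where ``r`` is the recall probability at exposure time, so widely spaced
exposures (low ``r``) consolidate more — the spacing effect.  Recall failure
falls back to guessing among the presented choices, with extra weight on
species whose songs are similar to the correct one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .catalog import SpeciesCatalog
from .engine import QuizItem


@dataclass
class LearnerConfig:
    initial_half_life: float = 0.02  # days; ~30 min
    consolidation_gain: float = 4.0
    spacing_exponent: float = 0.5
    similarity_confusion_weight: float = 3.0
    #: sigma of the lognormal per-species memorability multiplier; species
    #: with low memorability consolidate slowly, so they stay hard even when
    #: trained often (0 = homogeneous species).
    memorability_sigma: float = 0.8
    test_feedback: bool = False  # tests are silent: no memory update
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_half_life <= 0:
            raise ValueError("initial_half_life must be positive")
        if self.consolidation_gain <= 1:
            raise ValueError("consolidation_gain must exceed 1")
        if not 0.0 <= self.spacing_exponent <= 1.0:
            raise ValueError("spacing_exponent must be in [0, 1]")
        if self.similarity_confusion_weight < 1:
            raise ValueError("similarity_confusion_weight must be >= 1")
        if self.memorability_sigma < 0:
            raise ValueError("memorability_sigma cannot be negative")


class LearnerState:
    """Per-species memory: half-life, last exposure time, exposure count.

    When ``species`` is given, a lognormal memorability multiplier is drawn
    once per species from ``config.seed``; it scales the consolidation gain,
    making some species persistently harder to learn than others.  The draw
    depends only on the config seed, so species difficulty is shared across
    a cohort — as it would be for real song characteristics.
    """

    def __init__(
        self,
        config: LearnerConfig,
        species: Sequence[str] | None = None,
    ):
        self.config = config
        self.half_life: dict[str, float] = {}
        self.last_exposure: dict[str, float] = {}
        self.exposures: dict[str, int] = {}
        self.memorability: dict[str, float] = {}
        if species is not None and config.memorability_sigma > 0:
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 997]))
            draws = np.exp(rng.normal(0.0, config.memorability_sigma, len(species)))
            self.memorability = dict(zip(species, draws.tolist()))

    def exposure_count(self, abbreviation: str) -> int:
        return self.exposures.get(abbreviation, 0)

    def current_half_life(self, abbreviation: str) -> float:
        return self.half_life.get(abbreviation, self.config.initial_half_life)

    def memorability_of(self, abbreviation: str) -> float:
        return self.memorability.get(abbreviation, 1.0)


def recall_prob(state: LearnerState, abbreviation: str, time: float) -> float:
    """Probability of recalling a species at ``time`` (days).

    Never-exposed species are never recalled.  Otherwise the exponential
    forgetting curve ``2**(-dt / half_life)`` applies.
    """
    if state.exposure_count(abbreviation) == 0:
        return 0.0
    dt = time - state.last_exposure[abbreviation]
    if dt < 0:
        raise ValueError(f"time {time} precedes last exposure for {abbreviation}")
    return float(2.0 ** (-dt / state.half_life[abbreviation]))


def answer_item(
    state: LearnerState,
    item: QuizItem,
    catalog: SpeciesCatalog,
    rng: np.random.Generator,
) -> str:
    """Answer one quiz item.

    With probability ``recall_prob(correct)`` the learner recalls the song
    and answers correctly; otherwise it guesses among the presented choices,
    weighting similar-song species by ``similarity_confusion_weight`` (the
    correct species stays in the guess pool at weight 1, so lucky hits
    happen).
    """
    r = recall_prob(state, item.correct, item.time)
    if r >= 1.0 or rng.random() < r:
        return item.correct
    similar = {ref.abbreviation for ref in catalog.similar_of(item.correct)}
    gamma = state.config.similarity_confusion_weight
    weights = np.array(
        [gamma if c in similar else 1.0 for c in item.presented_order]
    )
    weights /= weights.sum()
    return str(rng.choice(list(item.presented_order), p=weights))


def observe_feedback(state: LearnerState, abbreviation: str, time: float) -> LearnerState:
    """Register one training exposure with feedback (in place; returned).

    The half-life grows by ``1 + (alpha - 1) * (1 - r)**beta`` with ``r`` the
    recall probability at exposure time; a first exposure uses r = 0 and so
    gets the maximal boost.  Half-lives never shrink.
    """
    cfg = state.config
    r = recall_prob(state, abbreviation, time)
    h = state.current_half_life(abbreviation)
    gain = (cfg.consolidation_gain - 1.0) * state.memorability_of(abbreviation)
    boost = 1.0 + gain * (1.0 - r) ** cfg.spacing_exponent
    state.half_life[abbreviation] = h * boost
    state.last_exposure[abbreviation] = time
    state.exposures[abbreviation] = state.exposure_count(abbreviation) + 1
    return state
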