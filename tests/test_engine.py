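import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from birdquiz.engine import (
    AnswerRecord,
    EngineConfig,
    ProficiencyState,
    QuizItem,
    is_mastered,
    next_item,
    review_probability,
    select_correct,
    select_distracters,
    update_proficiency,
)


def make_state(levels):
    state = ProficiencyState(levels.keys())
    for a, lv in levels.items():
        state._level[a] = lv
    return state


class TestReviewProbability:
    @pytest.mark.parametrize(
        "n_u,n_m,expected",
        [
            (0, 26, 0.0),
            (26, 0, 0.125),
            (13, 13, 0.25 * 0.5 * 13 / (13 + 0.5 * 13)),
            (1, 25, 0.25 * 0.5 * 1 / (1 + 0.5 * 25)),
            (10, 16, 0.25 * 0.5 * 10 / (10 + 0.5 * 16)),
        ],
    )
    def test_printed_formula(self, n_u, n_m, expected):
        config = EngineConfig()
        assert review_probability(n_u, n_m, config) == pytest.approx(expected)

    def test_mastered_variant(self):
        config = EngineConfig(review_numerator="mastered_variant")
        # p * w * N_m / (N_u + w * N_m)
        assert review_probability(13, 13, config) == pytest.approx(
            0.25 * 0.5 * 13 / (13 + 0.5 * 13)
        )
        # approaches p as N_u -> 0
        assert review_probability(0, 26, config) == pytest.approx(0.25)

    def test_printed_bounded_by_pw(self):
        config = EngineConfig()
        for n_u in range(0, 30):
            for n_m in range(0, 30):
                if n_u + n_m == 0:
                    continue
                assert review_probability(n_u, n_m, config) <= 0.25 * 0.5 + 1e-12

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            review_probability(0, 0, EngineConfig())

    def test_clamped_to_unit_interval(self):
        config = EngineConfig(max_review_probability=1.0, review_weight=50.0)
        assert review_probability(10, 1, config) <= 1.0


class TestMastery:
    @pytest.mark.parametrize("level,expected", [(3, True), (2, False), (0, False), (5, True)])
    def test_default_threshold(self, level, expected):
        assert is_mastered(level, EngineConfig()) is expected

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            is_mastered(-1, EngineConfig())


class TestUpdateProficiency:
    def _item(self, correct, distracters):
        choices = (correct,) + tuple(distracters)
        return QuizItem(correct, tuple(distracters), choices, 0, 0.0)

    def test_correct_increments(self, catalog):
        state = make_state({a: 0 for a in catalog.abbreviations})
        state._level["Hyam"] = 2
        item = self._item("Hyam", ["Cedi", "Pamo", "Coma", "Gaca"])
        update_proficiency(state, AnswerRecord(item, "Hyam"))
        assert state.level("Hyam") == 3
        assert is_mastered(state.level("Hyam"), EngineConfig())

    def test_incorrect_decrements_both(self, catalog):
        state = make_state({a: 0 for a in catalog.abbreviations})
        state._level["Cedi"] = 1
        state._level["Pamo"] = 2
        item = self._item("Cedi", ["Pamo", "Hyam", "Coma", "Gaca"])
        update_proficiency(state, AnswerRecord(item, "Pamo"))
        assert state.level("Cedi") == 0
        assert state.level("Pamo") == 1

    def test_floor_at_zero(self, catalog):
        state = make_state({a: 0 for a in catalog.abbreviations})
        item = self._item("Cedi", ["Pamo", "Hyam", "Coma", "Gaca"])
        update_proficiency(state, AnswerRecord(item, "Pamo"))
        assert state.level("Cedi") == 0
        assert state.level("Pamo") == 0

    def test_other_species_untouched(self, catalog):
        state = make_state({a: 1 for a in catalog.abbreviations})
        item = self._item("Cedi", ["Pamo", "Hyam", "Coma", "Gaca"])
        update_proficiency(state, AnswerRecord(item, "Cedi"))
        untouched = set(catalog.abbreviations) - {"Cedi"}
        assert all(state.level(a) == 1 for a in untouched)


class TestSelectCorrect:
    def test_all_zero_adaptive_uniform(self, catalog, rng):
        state = ProficiencyState.from_catalog(catalog)
        config = EngineConfig(mode="adaptive")
        draws = [select_correct(state, config, rng) for _ in range(10_000)]
        counts = [draws.count(a) for a in catalog.abbreviations]
        assert chisquare(counts).pvalue > 0.01

    def test_baseline_uniform_ignores_state(self, catalog, rng):
        levels = {a: (5 if i % 2 else 0) for i, a in enumerate(catalog.abbreviations)}
        state = make_state(levels)
        config = EngineConfig(mode="baseline")
        draws = [select_correct(state, config, rng) for _ in range(10_000)]
        counts = [draws.count(a) for a in catalog.abbreviations]
        assert chisquare(counts).pvalue > 0.01

    def test_all_mastered_returns_mastered(self, catalog, rng):
        state = make_state({a: 3 for a in catalog.abbreviations})
        config = EngineConfig(mode="adaptive")
        assert select_correct(state, config, rng) in catalog.abbreviations

    def test_review_frequency_matches_probability(self, catalog, rng):
        # 13 mastered, 13 unmastered: P = 0.25*0.5*13/(13+6.5)
        abbrevs = catalog.abbreviations
        levels = {a: (3 if i < 13 else 0) for i, a in enumerate(abbrevs)}
        state = make_state(levels)
        config = EngineConfig(mode="adaptive")
        mastered = {a for a, lv in levels.items() if lv >= 3}
        n = 10_000
        hits = sum(select_correct(state, config, rng) in mastered for _ in range(n))
        p = review_probability(13, 13, config)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestSelectDistracters:
    def test_level0_any_four_when_all_tied(self, catalog, rng):
        state = ProficiencyState.from_catalog(catalog)
        config = EngineConfig(mode="adaptive")
        d = select_distracters(state, "Hyam", catalog, config, rng)
        assert len(set(d)) == 4 and "Hyam" not in d

    def test_level0_prefers_high_proficiency(self, catalog, rng):
        levels = {a: 0 for a in catalog.abbreviations}
        for a in ("Cedi", "Pamo", "Coma", "Gaca"):
            levels[a] = 4
        state = make_state(levels)
        config = EngineConfig(mode="adaptive")
        d = select_distracters(state, "Hyam", catalog, config, rng)
        assert set(d) == {"Cedi", "Pamo", "Coma", "Gaca"}

    def test_level2_includes_similar(self, catalog, rng):
        levels = {a: 0 for a in catalog.abbreviations}
        levels["Pami"] = 2
        state = make_state(levels)
        config = EngineConfig(mode="adaptive")
        d = select_distracters(state, "Pami", catalog, config, rng)
        assert "Pova" in d

    def test_level1_substitutes_easy_similar(self, catalog, rng):
        levels = {a: 0 for a in catalog.abbreviations}
        levels["Pami"] = 1
        state = make_state(levels)
        config = EngineConfig(mode="adaptive")
        for _ in range(50):
            d = select_distracters(state, "Pami", catalog, config, rng)
            assert "Pova" in d

    def test_baseline_uniform_sample(self, catalog, rng):
        state = ProficiencyState.from_catalog(catalog)
        config = EngineConfig(mode="baseline")
        n = 10_000
        counts = {a: 0 for a in catalog.abbreviations if a != "Hyam"}
        for _ in range(n):
            for a in select_distracters(state, "Hyam", catalog, config, rng):
                counts[a] += 1
        assert chisquare(list(counts.values())).pvalue > 0.01

    def test_catalog_too_small(self, tiny5, rng):
        state = ProficiencyState.from_catalog(tiny5)
        config = EngineConfig(mode="adaptive", n_choices=6)
        with pytest.raises(ValueError, match="cannot supply"):
            select_distracters(state, "Sp01", tiny5, config, rng)


class TestNextItem:
    def test_structure(self, catalog, rng):
        state = ProficiencyState.from_catalog(catalog)
        item = next_item(state, catalog, EngineConfig(), rng, item_index=7, time=1.5)
        assert len(item.presented_order) == 5
        assert len(set(item.presented_order)) == 5
        assert item.correct in item.presented_order
        assert item.correct not in item.distracters
        assert item.item_index == 7 and item.time == 1.5

    def test_deterministic_given_seed(self, catalog):
        config = EngineConfig()
        items = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            state = ProficiencyState.from_catalog(catalog)
            items.append(next_item(state, catalog, config, rng))
        assert items[0] == items[1]

    def test_perfect_responder_mastery_in_78_unmastered_answers(self, catalog):
        # 3 correct answers per species x 26 species, review items excluded
        rng = np.random.default_rng(5)
        state = ProficiencyState.from_catalog(catalog)
        config = EngineConfig(mode="adaptive")
        unmastered_answers = 0
        for i in range(10_000):
            item = next_item(state, catalog, config, rng, item_index=i)
            if not is_mastered(state.level(item.correct), config):
                unmastered_answers += 1
            update_proficiency(state, AnswerRecord(item, item.correct))
            if state.all_mastered(config.mastery_threshold):
                break
        assert state.all_mastered(config.mastery_threshold)
        assert unmastered_answers == 78

    def test_mastered_draws_track_review_probability(self, catalog):
        # Poisson-binomial check along a perfect-responder trajectory, while
        # the unmastered pool is nonempty.
        rng = np.random.default_rng(11)
        state = ProficiencyState.from_catalog(catalog)
        config = EngineConfig(mode="adaptive")
        expected, variance, observed = 0.0, 0.0, 0
        while not state.all_mastered(config.mastery_threshold):
            n_u, n_m = (len(p) for p in state.pools(config.mastery_threshold))
            item = next_item(state, catalog, config, rng)
            if n_m > 0:
                p = review_probability(n_u, n_m, config)
                expected += p
                variance += p * (1 - p)
                observed += is_mastered(state.level(item.correct), config)
            update_proficiency(state, AnswerRecord(item, item.correct))
        assert abs(observed - expected) <= 3 * np.sqrt(variance) + 1


@st.composite
def answer_sequences(draw):
    n_species = draw(st.integers(min_value=5, max_value=8))
    abbrevs = [f"Sp{i:02d}" for i in range(n_species)]
    n_answers = draw(st.integers(min_value=1, max_value=40))
    answers = []
    for _ in range(n_answers):
        idx = draw(st.permutations(range(n_species)))
        correct = abbrevs[idx[0]]
        selected = abbrevs[draw(st.sampled_from(idx[:5]))]
        answers.append((correct, tuple(abbrevs[i] for i in idx[1:5]), selected))
    return abbrevs, answers


class TestProficiencyInvariants:
    @given(answer_sequences())
    @settings(max_examples=60, deadline=None)
    def test_nonnegative_under_any_answer_sequence(self, data):
        abbrevs, answers = data
        state = ProficiencyState(abbrevs)
        for correct, distracters, selected in answers:
            choices = (correct,) + distracters
            item = QuizItem(correct, distracters, choices, 0, 0.0)
            update_proficiency(state, AnswerRecord(item, selected))
            assert all(state.level(a) >= 0 for a in abbrevs)

    @given(answer_sequences())
    @settings(max_examples=60, deadline=None)
    def test_total_change_per_answer_bounded(self, data):
        abbrevs, answers = data
        state = ProficiencyState(abbrevs)
        for correct, distracters, selected in answers:
            before = sum(state.level(a) for a in abbrevs)
            choices = (correct,) + distracters
            item = QuizItem(correct, distracters, choices, 0, 0.0)
            update_proficiency(state, AnswerRecord(item, selected))
            after = sum(state.level(a) for a in abbrevs)
            assert after - before in (-2, -1, 0, 1)


class TestConfigValidation:
    def test_defaults(self):
        config = EngineConfig()
        assert config.max_review_probability == 0.25
        assert config.review_weight == 0.5
        assert config.mastery_threshold == 3
        assert config.n_choices == 5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "psychic"},
            {"max_review_probability": 1.5},
            {"review_weight": 0.0},
            {"mastery_threshold": 0},
            {"n_choices": 1},
            {"review_numerator": "whatever"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EngineConfig(**kwargs)
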