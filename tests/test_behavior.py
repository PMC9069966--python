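"""Survey arithmetic, agreement statistics, boundary fitting, chance model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebra import behavior, survey_tables
from cerebra.attributes import ATTRIBUTES
from cerebra.corpus import Sentence, parse_tokens

ATTRS = list(ATTRIBUTES)


# --- published-count arithmetic -------------------------------------------

def test_unanimous_chance_baseline_is_sixty_eight_percent():
    rate = behavior.majority_chance_rate(survey_tables.UNANIMOUS_LABEL_COUNTS)
    assert round(rate) == 68


def test_majority_of_three_chance_baseline_is_forty_five_percent():
    rate = behavior.majority_chance_rate(survey_tables.MAJORITY3_LABEL_COUNTS)
    assert round(rate) == 45


def test_unanimous_share_of_questions_is_eighteen_percent():
    share = 100.0 * survey_tables.UNANIMOUS_COUNT / survey_tables.TOTAL_QUESTIONS
    assert round(share) == 18


def test_majority_of_three_share_is_fifty_five_percent():
    share = 100.0 * survey_tables.MAJORITY3_COUNT / survey_tables.TOTAL_QUESTIONS
    assert round(share) == 55


def test_average_pairwise_agreement_is_forty_seven_percent():
    matches = list(survey_tables.PAIRWISE_MATCHES.values())
    percent = 100.0 * sum(matches) / (
        len(matches) * survey_tables.TOTAL_QUESTIONS)
    assert round(percent) == 47


def test_response_distributions_sum_to_the_question_total():
    for counts in survey_tables.RESPONSE_DISTRIBUTION.values():
        assert sum(counts.values()) == survey_tables.TOTAL_QUESTIONS


# --- rater statistics on raw responses ------------------------------------

def _responses(matrix):
    """Long responses frame from a question x participant rating matrix."""
    rows = []
    for qid, ratings in enumerate(matrix):
        for j, r in enumerate(ratings):
            rows.append({"question_id": qid, "participant": f"P{j+1}",
                         "rating": r})
    return pd.DataFrame(rows)


def test_pairwise_agreement_counts_identical_answers():
    responses = _responses([[1, 1], [0, 1], [-1, -1], [0, 0]])
    result = behavior.pairwise_agreement(responses)
    pair = result["pair_matches"][("P1", "P2")]
    assert pair == {"matches": 3, "common": 4}
    assert result["average_percent"] == 75.0


def test_consensus_selection_keeps_majority_questions_with_labels():
    responses = _responses([
        [1, 1, 1, 1],     # unanimous +1
        [0, 0, 0, 1],     # 3-of-4 consensus on 0
        [1, 0, -1, 0],    # only 2 agree -> excluded at min_agree=3
    ])
    ids, share, labels = behavior.select_consensus_questions(
        responses, min_agree=3)
    assert ids == [0, 1]
    assert share == pytest.approx(2 / 3)
    assert labels.to_dict() == {0: 1, 1: 0}


def test_invalid_rating_values_are_rejected():
    responses = _responses([[1, 2]])
    with pytest.raises(ValueError, match="invalid rating"):
        behavior.pairwise_agreement(responses)


def test_fleiss_kappa_matches_statsmodels_reference():
    statsmodels = pytest.importorskip("statsmodels.stats.inter_rater")
    rng = np.random.default_rng(0)
    counts = rng.multinomial(6, [0.5, 0.2, 0.3], size=40).astype(float)
    ours = behavior.fleiss_kappa(counts)
    reference = statsmodels.fleiss_kappa(counts, method="fleiss")
    assert ours["kappa"] == pytest.approx(reference, abs=1e-12)


def test_perfect_agreement_gives_kappa_one():
    counts = np.zeros((10, 3))
    counts[:5, 0] = 4
    counts[5:, 2] = 4
    assert behavior.fleiss_kappa(counts)["kappa"] == pytest.approx(1.0)


def test_unequal_rater_counts_are_rejected():
    counts = np.array([[2, 1, 1], [3, 1, 1]], dtype=float)
    with pytest.raises(ValueError, match="unequal"):
        behavior.fleiss_kappa(counts)


# --- change scores ---------------------------------------------------------

def _revised_frame(vectors):
    rows = []
    for (sid, pos, word), vec in vectors.items():
        rec = {"subject": "S0", "sentence_id": sid, "position": pos,
               "role": "Agent", "word": word}
        rec.update(dict(zip(ATTRS, vec)))
        rows.append(rec)
    return pd.DataFrame(rows)


def test_relative_change_subtracts_the_other_words_average():
    cars = pd.DataFrame(np.zeros((2, 66)),
                        index=pd.Index(["a", "b"], name="word"), columns=ATTRS)
    sentences = [Sentence(0, "t", parse_tokens("Agent:a;Verb:b"))]
    va = np.full(66, 0.3)
    vb = np.full(66, 0.1)
    revised = _revised_frame({(0, 0, "a"): va, (0, 1, "b"): vb})
    scores = behavior.change_scores(revised, cars, sentences, approach=1)
    # a's raw change is 0.3, its single other word changed by 0.1 -> 0.2
    assert np.allclose(scores.loc[0, ATTRS], 0.2)
    assert np.allclose(scores.loc[1, ATTRS], -0.2)


def test_whole_sentence_average_reference_includes_the_target():
    cars = pd.DataFrame(np.zeros((2, 66)),
                        index=pd.Index(["a", "b"], name="word"), columns=ATTRS)
    sentences = [Sentence(0, "t", parse_tokens("Agent:a;Verb:b"))]
    revised = _revised_frame({(0, 0, "a"): np.full(66, 0.3),
                              (0, 1, "b"): np.full(66, 0.1)})
    scores = behavior.change_scores(revised, cars, sentences, approach=2)
    assert np.allclose(scores.loc[0, ATTRS], 0.1)   # 0.3 - mean(0.3, 0.1)
    assert np.allclose(scores.loc[1, ATTRS], -0.1)


def test_word_across_contexts_reference_centers_each_word():
    cars = pd.DataFrame(np.zeros((1, 66)),
                        index=pd.Index(["a"], name="word"), columns=ATTRS)
    sentences = [Sentence(0, "t", parse_tokens("Agent:a")),
                 Sentence(1, "u", parse_tokens("Agent:a"))]
    revised = _revised_frame({(0, 0, "a"): np.full(66, 0.4),
                              (1, 0, "a"): np.full(66, 0.2)})
    scores = behavior.change_scores(revised, cars, sentences, approach=3)
    assert np.allclose(scores.loc[0, ATTRS], 0.1)
    assert np.allclose(scores.loc[1, ATTRS], -0.1)


# --- boundary fitting and chance -------------------------------------------

def test_boundary_sweep_finds_a_perfect_separator():
    scores = np.array([-0.8, -0.2, 0.3, 0.9])
    labels = np.array([0, 0, 1, 1])
    fit = behavior.fit_boundaries(scores, labels)
    assert -0.2 <= fit.boundary_upper < 0.3
    assert fit.match_rate == 100.0


def test_two_boundary_fit_recovers_three_way_thresholds():
    rng = np.random.default_rng(4)
    scores = rng.uniform(-1, 1, 400)
    labels = behavior.labels_from_scores(scores, upper=0.25, lower=-0.4)
    fit = behavior.fit_boundaries(scores, labels, two_boundary=True)
    predicted = behavior.labels_from_scores(
        scores, fit.boundary_upper, fit.boundary_lower)
    assert fit.boundary_lower is not None
    assert fit.boundary_lower <= fit.boundary_upper
    assert behavior.match_rate(predicted, labels)[0] == 100.0


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_chance_scores_stay_inside_the_score_range(seed):
    draws = behavior.chance_model(50, (-0.3, 0.7), seed=seed)
    assert draws.min() >= -0.3 and draws.max() <= 0.7
    assert draws.shape == (50,)


def test_fitted_chance_converges_to_the_majority_class_rate():
    # With random scores, the best two-boundary fit can do no better than
    # always predicting the majority label (up to the sweep's granularity).
    rng = np.random.default_rng(5)
    labels = rng.choice([-1, 0, 1], p=[0.2, 0.5, 0.3], size=2000)
    chance = behavior.chance_model(2000, (-1.0, 1.0), seed=6)
    fit = behavior.fit_boundaries(chance, labels, two_boundary=True)
    uniq, counts = np.unique(labels, return_counts=True)
    majority = behavior.majority_chance_rate(dict(zip(uniq, counts)))
    assert abs(fit.match_rate - majority) < 3.0


def test_match_rate_confusion_table_is_complete():
    rate, confusion = behavior.match_rate(
        np.array([1, 0, -1, 1]), np.array([1, 1, -1, 0]))
    assert rate == 50.0
    assert confusion.to_numpy().sum() == 4
    assert confusion.loc[-1, -1] == 1


def test_survey_design_excludes_sentences_without_enough_significance():
    rows = []
    for sid, p in ((0, 0.001), (1, 0.9)):
        for attr in ATTRS[:12]:
            rows.append({"sentence_id": sid, "role": "Agent", "word": "w",
                         "attribute": attr, "mean_diff": 0.2, "p": p})
    changes = pd.DataFrame(rows)
    questions, excluded = behavior.design_survey(changes, seed=0, n_pick=10)
    assert (1, "Agent", "w") in excluded
    assert set(questions["sentence_id"]) == {0}
    assert len(questions) == 10
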