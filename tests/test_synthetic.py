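"""Generator invariants: determinism, coverage, planted-shift identities."""

import numpy as np
import pandas as pd
import pytest

from cerebra import synthetic
from cerebra.attributes import ATTRIBUTES
from cerebra.fgrep import training_pairs
from cerebra.network import TrainingConfig, train
from cerebra.synthetic import (
    SynthesisConfig, gen_context_shifts, gen_corpus, gen_lexicon, gen_raters,
    make_dataset,
)


def test_lexicon_vectors_are_unit_norm_nonnegative_and_named(small_config):
    lexicon, categories = gen_lexicon(small_config)
    values = lexicon.to_numpy(float)
    assert np.allclose(np.linalg.norm(values, axis=1), 1.0)
    assert (values >= 0).all()
    assert len(lexicon) == small_config.n_words
    assert set(categories.values()) <= {"animate", "action", "object"}


def test_generation_is_deterministic_given_the_seed(small_config):
    a = make_dataset(small_config)
    b = make_dataset(SynthesisConfig(**vars(small_config)))
    assert a.lexicon.equals(b.lexicon)
    assert [s.text for s in a.sentences] == [s.text for s in b.sentences]
    for key in a.contextual:
        assert np.array_equal(a.contextual[key], b.contextual[key])
    for subject in a.fmri:
        assert a.fmri[subject].equals(b.fmri[subject])


def test_different_seeds_give_different_data(small_config):
    a = make_dataset(small_config)
    b = make_dataset(SynthesisConfig(**{**vars(small_config), "seed": 1}))
    assert not a.lexicon.equals(b.lexicon)


def test_every_lexicon_word_occurs_in_some_sentence(small_dataset):
    used = {t.word for s in small_dataset.sentences for t in s.tokens}
    assert used == set(small_dataset.lexicon.index)


def test_sentences_have_agent_verb_and_bounded_length(default_dataset):
    cfg = default_dataset.config
    for s in default_dataset.sentences:
        roles = [t.role for t in s.tokens]
        assert roles[0] == "Agent" and roles[1] == "Verb"
        assert set(roles[2:]) <= {"POLE"}
        assert cfg.min_words <= len(s.tokens) <= cfg.max_words


def test_zero_mixing_plants_no_shift(small_dataset):
    shifts = gen_context_shifts(
        small_dataset.sentences, small_dataset.lexicon, lam=0.0)
    for s in small_dataset.sentences:
        cars = small_dataset.lexicon.loc[s.words].to_numpy(float)
        for pos in range(len(s.tokens)):
            assert np.allclose(shifts[(s.id, pos)], cars[pos])


def test_full_mixing_replaces_the_word_with_its_context(small_dataset):
    shifts = gen_context_shifts(
        small_dataset.sentences, small_dataset.lexicon, lam=1.0)
    for s in small_dataset.sentences:
        if len(s.tokens) < 2:
            continue
        cars = small_dataset.lexicon.loc[s.words].to_numpy(float)
        for pos in range(len(s.tokens)):
            ows = np.delete(cars, pos, axis=0).mean(axis=0)
            assert np.allclose(shifts[(s.id, pos)], np.clip(ows, 0, 1))


def test_intermediate_mixing_is_the_convex_combination(small_dataset):
    lam = 0.5
    shifts = gen_context_shifts(
        small_dataset.sentences, small_dataset.lexicon, lam=lam)
    s = next(s for s in small_dataset.sentences if len(s.tokens) >= 2)
    cars = small_dataset.lexicon.loc[s.words].to_numpy(float)
    ows = np.delete(cars, 0, axis=0).mean(axis=0)
    expected = np.clip((1 - lam) * cars[0] + lam * ows, 0, 1)
    assert np.allclose(shifts[(s.id, 0)], expected)


def test_planted_shifts_sum_to_zero_within_a_sentence_before_clamping():
    # The mixing construction moves each token toward the mean of the others,
    # so the within-sentence sum of shifts is zero wherever no clamp binds.
    cfg = SynthesisConfig(n_words=12, n_sentences=8, n_subjects=1, seed=3)
    lexicon, categories = gen_lexicon(cfg)
    sentences = gen_corpus(cfg, lexicon, categories)
    shifts = gen_context_shifts(sentences, lexicon, lam=0.3)
    for s in sentences:
        if len(s.tokens) < 2:
            continue
        cars = lexicon.loc[s.words].to_numpy(float)
        deltas = np.stack([
            shifts[(s.id, pos)] - cars[pos] for pos in range(len(s.tokens))
        ])
        m = len(s.tokens)
        unclamped = np.stack([
            (1 - 0.3) * cars[p] + 0.3 * np.delete(cars, p, 0).mean(0)
            for p in range(m)
        ])
        if (unclamped >= 0).all() and (unclamped <= 1).all():
            assert np.allclose(deltas.sum(axis=0), 0.0, atol=1e-12)


def test_fmri_values_are_scaled_to_the_target_interval(small_dataset):
    for frame in small_dataset.fmri.values():
        values = frame.to_numpy(float)
        assert values.min() >= 0.2 - 1e-12
        assert values.max() <= 0.8 + 1e-12


def test_subjects_get_distinct_brain_maps():
    data = make_dataset(SynthesisConfig(
        n_words=12, n_sentences=8, n_voxels=50, n_subjects=2,
        n_repetitions=4, hidden_dim=24, seed=0))
    assert not data.fmri["S0"].equals(data.fmri["S1"])


def test_noiseless_control_corpus_is_learnable(small_dataset):
    # With no planted context (lambda = 0) the SynthWord targets are
    # consistent across sentences, so the network fits them well.
    cfg = SynthesisConfig(
        **{**vars(small_dataset.config), "lam": 0.0, "sigma": 0.0})
    data = make_dataset(cfg)
    subject = next(iter(data.fmri))
    X, Y, _ = training_pairs(
        data.sentences, data.lexicon, data.fmri[subject], subject)
    _, curve = train(X, Y, TrainingConfig(
        max_epochs=2000, target_mse=0.0, seed=0))
    assert curve[-1] < 0.01


def test_rating_table_covers_words_raters_and_scale(small_config):
    lexicon, _ = gen_lexicon(small_config)
    table = synthetic.gen_rating_table(lexicon, small_config)
    assert set(table["word"]) == set(lexicon.index)
    per_word = table.groupby("word")["rater"].nunique()
    assert (per_word == small_config.n_raters).all()
    finite = table["rating"].dropna()
    assert finite.between(0, 6).all()
    assert table["rating"].isna().any()


def test_simulated_survey_raters_threshold_the_true_scores():
    scores = np.array([-0.5, -0.4, 0.0, 0.1, 0.5, 0.6])
    responses = gen_raters(scores, flip_rate=0.0, n_raters=3, seed=0,
                           thresholds=(-0.2, 0.2))
    pivot = responses.pivot_table(index="question_id", columns="participant",
                                  values="rating")
    expected = [-1, -1, 0, 0, 1, 1]
    for participant in pivot.columns:
        assert pivot[participant].tolist() == expected


def test_rater_flips_occur_at_about_the_requested_rate():
    rng = np.random.default_rng(0)
    scores = rng.uniform(-1, 1, 2000)
    base = np.where(scores > 0.3, 1, np.where(scores < -0.3, -1, 0))
    responses = gen_raters(scores, flip_rate=0.2, n_raters=1, seed=1,
                           thresholds=(-0.3, 0.3))
    observed = responses.sort_values("question_id")["rating"].to_numpy()
    flip_fraction = float(np.mean(observed != base))
    assert 0.15 < flip_fraction < 0.25


def test_invalid_mixing_strength_is_rejected():
    with pytest.raises(ValueError, match="lambda"):
        SynthesisConfig(lam=1.5)
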