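"""Clustering, per-dimension change tests, and OWS correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage

from cerebra import aggregation
from cerebra.attributes import ATTRIBUTES
from cerebra.corpus import Sentence, parse_tokens

ATTRS = list(ATTRIBUTES)


def _token_frame(rows):
    """Tidy revised-CAR frame from (sentence_id, position, role, word, vec)."""
    records = []
    for sid, pos, role, word, vec in rows:
        rec = {"subject": "S0", "sentence_id": sid, "position": pos,
               "role": role, "word": word}
        rec.update(dict(zip(ATTRS, vec)))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _cars(words):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.uniform(0, 1, (len(words), 66)),
        index=pd.Index(words, name="word"), columns=ATTRS,
    )


def test_two_well_separated_groups_cluster_apart():
    rng = np.random.default_rng(1)
    near_zero = rng.uniform(0.0, 0.1, (5, 66))
    near_one = rng.uniform(0.9, 1.0, (5, 66))
    frame = pd.DataFrame(
        np.vstack([near_zero, near_one]),
        index=pd.Index(range(10), name="sentence_id"),
    )
    assignment = aggregation.cluster_sentences(frame, k=2)
    labels = assignment.labels
    low = {labels[i] for i in range(5)}
    high = {labels[i] for i in range(5, 10)}
    assert len(low) == 1 and len(high) == 1 and low != high


def test_clustering_matches_scipy_ward_reference():
    rng = np.random.default_rng(2)
    X = rng.normal(0, 1, (12, 8))
    frame = pd.DataFrame(X, index=pd.Index(range(12), name="sentence_id"))
    assignment = aggregation.cluster_sentences(frame, k=4)
    expected = fcluster(linkage(X, method="ward"), t=4, criterion="maxclust")
    assert list(assignment.labels.values()) == expected.tolist()


def test_fewer_sentences_than_clusters_gives_singletons():
    frame = pd.DataFrame(np.eye(3), index=pd.Index([7, 8, 9]))
    assignment = aggregation.cluster_sentences(frame, k=30)
    assert assignment.k == 3
    assert sorted(assignment.labels.values()) == [1, 2, 3]


def test_sentence_representation_is_token_mean():
    vec_a = np.full(66, 0.2)
    vec_b = np.full(66, 0.6)
    revised = _token_frame([
        (0, 0, "Agent", "a", vec_a),
        (0, 1, "Verb", "b", vec_b),
    ])
    sent = aggregation.assemble_sentence_cars(revised, "S0")
    assert np.allclose(sent.loc[0], 0.4)


def test_unchanged_tokens_yield_null_t_statistics():
    cars = _cars(["a", "b"])
    revised = _token_frame([
        (0, 0, "Agent", "a", cars.loc["a"].to_numpy()),
        (1, 0, "Agent", "b", cars.loc["b"].to_numpy()),
    ])
    table = aggregation.dimension_change_tests(revised, cars)
    assert (table["t"] == 0.0).all()
    assert (table["p"] == 1.0).all()


def test_consistent_shift_on_one_dimension_is_detected():
    cars = _cars(["a", "b", "c", "d"])
    rng = np.random.default_rng(3)
    rows = []
    for i, w in enumerate(["a", "b", "c", "d"]):
        vec = cars.loc[w].to_numpy().copy()
        vec += rng.normal(0, 1e-4, 66)       # tiny jitter everywhere
        vec[0] += 0.3                        # large shift on one attribute
        rows.append((i, 0, "Agent", w, vec))
    table = aggregation.dimension_change_tests(_token_frame(rows), cars)
    shifted = table[table["attribute"] == ATTRS[0]].iloc[0]
    others = table[table["attribute"] != ATTRS[0]]
    assert shifted["p"] < 1e-4 and shifted["mean_diff"] > 0.25
    assert (others["mean_diff"].abs() < 0.01).all()


def test_single_token_cells_report_nan_statistics():
    cars = _cars(["a"])
    revised = _token_frame([(0, 0, "Agent", "a", np.full(66, 0.5))])
    table = aggregation.dimension_change_tests(revised, cars)
    assert table["t"].isna().all() and (table["n"] == 1).all()


def test_ows_average_excludes_the_target_word():
    sentence = Sentence(0, "t", parse_tokens("Agent:a;Verb:b;POLE:c"))
    vectors = {"a": np.full(66, 0.0), "b": np.full(66, 0.4),
               "c": np.full(66, 0.8)}
    ows = aggregation.ows_average(sentence, 0, lambda pos, w: vectors[w])
    assert np.allclose(ows, 0.6)


def test_ows_average_needs_at_least_two_tokens():
    sentence = Sentence(0, "t", parse_tokens("Verb:alone"))
    with pytest.raises(ValueError, match="other words"):
        aggregation.ows_average(sentence, 0, lambda pos, w: np.zeros(66))


def test_feature_transfer_raises_ows_correlation():
    # Original CARs are orthogonal block vectors; the revision mixes 40% of
    # the sentence partner into each word, so the revised token must
    # correlate more with its (revised) OWS than the original does.
    sentences = [Sentence(0, "t", parse_tokens("Agent:a;Verb:b"))]
    a = np.zeros(66)
    a[:20] = 1.0
    b = np.zeros(66)
    b[30:50] = 1.0
    cars = pd.DataFrame([a, b], index=pd.Index(["a", "b"], name="word"),
                        columns=ATTRS)
    revised = _token_frame([
        (0, 0, "Agent", "a", 0.6 * a + 0.4 * b),
        (0, 1, "Verb", "b", 0.6 * b + 0.4 * a),
    ])
    table = aggregation.correlation_analysis(revised, cars, sentences)
    assert (table["gap"] > 0).all()
    assert (table["mean_r_revised"] > table["mean_r_original"]).all()


def test_identity_revision_yields_zero_ows_gap():
    cars = _cars(["a", "b", "c"])
    sentences = [Sentence(0, "t", parse_tokens("Agent:a;Verb:b;POLE:c"))]
    revised = _token_frame([
        (0, pos, role, w, cars.loc[w].to_numpy())
        for pos, (role, w) in enumerate(
            [("Agent", "a"), ("Verb", "b"), ("POLE", "c")])
    ])
    table = aggregation.correlation_analysis(revised, cars, sentences)
    assert np.allclose(table["gap"], 0.0, atol=1e-12)


def test_zero_variance_tokens_are_skipped_not_crashed():
    cars = _cars(["a", "b"])
    sentences = [Sentence(0, "t", parse_tokens("Agent:a;Verb:b"))]
    revised = _token_frame([
        (0, 0, "Agent", "a", np.full(66, 0.5)),   # constant vector
        (0, 1, "Verb", "b", cars.loc["b"].to_numpy()),
    ])
    table = aggregation.correlation_analysis(revised, cars, sentences)
    assert table["n_skipped"].sum() >= 1
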