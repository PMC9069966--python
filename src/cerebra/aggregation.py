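"""Corpus-level statistics on revised CARs.

Three analyses quantify the conceptual-combination effect across a corpus:

* Ward/Euclidean hierarchical clustering of sentence representations
  (assembled by averaging each sentence's revised CARs), cut at k clusters.
* Per-dimension change tests: within each (cluster, role) cell, a one-sample
  two-tailed t-test of the revised-minus-original differences per attribute.
* OWS correlations: per token, the Pearson correlation across the 66
  dimensions between the (revised) CAR and the average CAR of the Other
  Words in the Sentence, compared with the same correlation for the
  original CARs. If revision increases that correlation, features are being
  transferred between the words of a sentence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, ttest_1samp, ttest_rel

from .attributes import ATTRIBUTES
from .corpus import Sentence


@dataclass
class ClusterAssignment:
    labels: dict          # sentence_id -> cluster label (1..k)
    linkage: np.ndarray | None
    k: int


def cluster_sentences(
    synthsents: pd.DataFrame, k: int = 30
) -> ClusterAssignment:
    """Agglomerative Ward/Euclidean clustering of sentence vectors, cut at k.

    ``synthsents`` is a sentences x dimensions frame indexed by sentence_id.
    With n <= k each sentence becomes its own cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(synthsents.index)
    X = synthsents.to_numpy(dtype=float)
    if len(ids) <= k:
        return ClusterAssignment(
            labels={sid: i + 1 for i, sid in enumerate(ids)},
            linkage=None, k=len(ids),
        )
    Z = linkage(X, method="ward", metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(labels=dict(zip(ids, flat.tolist())), linkage=Z, k=k)


def assemble_sentence_cars(
    revised: pd.DataFrame, subject, attributes: Sequence[str] = ATTRIBUTES
) -> pd.DataFrame:
    """Sentence representations: mean revised CAR over each sentence's tokens."""
    sub = revised[revised["subject"] == subject]
    return sub.groupby("sentence_id")[list(attributes)].mean()


def dimension_change_tests(
    revised: pd.DataFrame,
    original_cars: pd.DataFrame,
    clusters: ClusterAssignment | None = None,
    attributes: Sequence[str] = ATTRIBUTES,
) -> pd.DataFrame:
    """Per (cluster, role, attribute) t-tests of revised-minus-original.

    One-sample, two-tailed Student's t against zero mean difference. All-zero
    differences use the convention t = 0, p = 1; cells with n < 2 are
    reported with NaN statistics. With ``clusters=None`` every sentence is
    treated as one cluster (label 0).
    """
    attrs = list(attributes)
    rev = revised.copy()
    if clusters is None:
        rev["cluster"] = 0
    else:
        rev["cluster"] = rev["sentence_id"].map(clusters.labels)
    diffs = rev[attrs].to_numpy(float) - original_cars.loc[
        rev["word"], attrs
    ].to_numpy(float)
    diff_frame = pd.DataFrame(diffs, columns=attrs)
    diff_frame[["cluster", "role"]] = rev[["cluster", "role"]].to_numpy()
    rows = []
    for (cluster, role), cell in diff_frame.groupby(["cluster", "role"]):
        n = len(cell)
        for attr in attrs:
            d = cell[attr].to_numpy(float)
            if n < 2:
                t, p = np.nan, np.nan
            elif np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                res = ttest_1samp(d, 0.0)
                t, p = float(res.statistic), float(res.pvalue)
                if np.isnan(t):  # zero variance around a nonzero mean
                    t, p = np.inf * np.sign(d.mean()), 0.0
            rows.append(
                {"cluster": cluster, "role": role, "attribute": attr,
                 "mean_diff": float(d.mean()), "t": t, "p": p, "n": n}
            )
    return pd.DataFrame(rows)


def ows_average(
    sentence: Sentence,
    target_position: int,
    car_lookup,
) -> np.ndarray:
    """Mean CAR of the Other Words in the Sentence (all tokens but the target).

    ``car_lookup(position, word)`` returns the 66-vector to use for the token
    at ``position`` — pass the generic CARs or the revised ones.
    """
    if len(sentence.tokens) < 2:
        raise ValueError(f"sentence {sentence.id} has no other words")
    others = [
        np.asarray(car_lookup(pos, tok.word), dtype=float)
        for pos, tok in enumerate(sentence.tokens)
        if pos != target_position
    ]
    return np.mean(others, axis=0)


def correlation_analysis(
    revised: pd.DataFrame,
    original_cars: pd.DataFrame,
    sentences: Sequence[Sentence],
    clusters: Mapping[str, ClusterAssignment] | None = None,
    attributes: Sequence[str] = ATTRIBUTES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Token-level OWS correlations, averaged per subject and role.

    For each token: Pearson r across the 66 dimensions between (a) the
    revised CAR and the mean revised CAR of the other words in the sentence,
    and (b) the original CAR and the mean original CAR of the other words.
    The paired difference is tested with Student's t. Zero-variance vectors
    make r undefined; those tokens are skipped and counted. When ``clusters``
    is given (one assignment per subject) the per-role averages are computed
    within clusters first and then averaged, otherwise over all tokens
    directly.
    """
    attrs = list(attributes)
    sent_by_id = {s.id: s for s in sentences}
    results = []
    for subject, sub in revised.groupby("subject"):
        rev_lookup = {
            (r.sentence_id, r.position): np.array([getattr(r, a) for a in attrs])
            for r in sub.itertuples()
        }
        rows = []
        for r in sub.itertuples():
            s = sent_by_id[r.sentence_id]
            if len(s.tokens) < 2:
                continue
            rev_vec = rev_lookup[(r.sentence_id, r.position)]
            orig_vec = original_cars.loc[r.word, attrs].to_numpy(float)
            ows_rev = ows_average(
                s, r.position,
                lambda pos, w: rev_lookup[(s.id, pos)],
            )
            ows_orig = ows_average(
                s, r.position,
                lambda pos, w: original_cars.loc[w, attrs].to_numpy(float),
            )
            if (np.std(rev_vec) == 0 or np.std(orig_vec) == 0
                    or np.std(ows_rev) == 0 or np.std(ows_orig) == 0):
                rows.append({"role": r.role, "skipped": True,
                             "r_revised": np.nan, "r_original": np.nan,
                             "sentence_id": r.sentence_id})
                continue
            r_rev = pearsonr(rev_vec, ows_rev).statistic
            r_orig = pearsonr(orig_vec, ows_orig).statistic
            rows.append({"role": r.role, "skipped": False,
                         "r_revised": float(r_rev), "r_original": float(r_orig),
                         "sentence_id": r.sentence_id})
        token_frame = pd.DataFrame(rows)
        cl = clusters.get(subject) if clusters else None
        for role, cell in token_frame.groupby("role"):
            ok = cell[~cell["skipped"]]
            n = len(ok)
            if n >= 2:
                res = ttest_rel(ok["r_revised"], ok["r_original"])
                t, p = float(res.statistic), float(res.pvalue)
                if np.isnan(t):
                    t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
            if cl is not None and n > 0:
                grouped = ok.assign(
                    cluster=ok["sentence_id"].map(cl.labels)
                ).groupby("cluster")[["r_revised", "r_original"]].mean()
                mean_rev = float(grouped["r_revised"].mean())
                mean_orig = float(grouped["r_original"].mean())
            else:
                mean_rev = float(ok["r_revised"].mean()) if n else np.nan
                mean_orig = float(ok["r_original"].mean()) if n else np.nan
            results.append({
                "subject": subject, "role": role,
                "mean_r_revised": mean_rev, "mean_r_original": mean_orig,
                "gap": mean_rev - mean_orig,
                "t": t, "p": p, "significant": bool(p < alpha) if n >= 2 else False,
                "n_tokens": n, "n_skipped": int(cell["skipped"].sum()),
            })
    return pd.DataFrame(results)
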