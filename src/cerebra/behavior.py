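"""Behavioral comparison of model change scores with human judgements.

Humans rate whether a target word's attribute increased ("more", +1),
decreased ("less", -1), or stayed the same (0) in a sentence. The model's
raw attribute changes (revised - original) are turned into relative change
scores by subtracting a reference average (three approaches), a decision
boundary on those scores is fitted by sweeping (-1, 1) to maximize matches
with human labels, and the resulting match rate is compared against a
chance model that draws uniform scores over the same range. Inter-rater
statistics (distribution, pairwise agreement, Fleiss' kappa) characterize
the human data itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .attributes import ATTRIBUTES
from .corpus import Sentence

VALID_RATINGS = (-1, 0, 1)


@dataclass
class BoundaryFit:
    boundary_upper: float
    boundary_lower: float | None
    step: float
    matches: int
    total: int

    @property
    def match_rate(self) -> float:
        return 100.0 * self.matches / self.total if self.total else np.nan


def design_survey(
    changes: pd.DataFrame,
    seed: int,
    n_top: int = 25,
    n_pick: int = 10,
    sentences_per_questionnaire: int = 15,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list]:
    """Build survey questions from per-sentence attribute-change statistics.

    ``changes`` has one row per (sentence_id, role, word, attribute) with
    columns ``mean_diff`` and ``p``. Sentences (assumed to be cluster
    centroids) with fewer than ``n_pick`` significant attribute changes are
    excluded (returned in the log); for the rest, ``n_pick`` attributes are
    drawn uniformly at random (seeded) from the ``n_top`` significant
    attributes with the largest absolute change, and sentences are packed
    into questionnaires of ``sentences_per_questionnaire``.
    """
    rng = np.random.default_rng(seed)
    questions = []
    excluded = []
    groups = sorted(
        changes.groupby(["sentence_id", "role", "word"]).groups.keys()
    )
    kept_keys = []
    for key in groups:
        sid, role, word = key
        cell = changes[
            (changes["sentence_id"] == sid) & (changes["role"] == role)
            & (changes["word"] == word)
        ]
        sig = cell[cell["p"] < alpha]
        if len(sig) < n_pick:
            excluded.append(key)
            continue
        top = sig.reindex(
            sig["mean_diff"].abs().sort_values(ascending=False).index
        ).head(n_top)
        chosen = rng.choice(len(top), size=n_pick, replace=False)
        kept_keys.append((key, top.iloc[sorted(chosen)]["attribute"].tolist()))
    for i, (key, attrs) in enumerate(kept_keys):
        sid, role, word = key
        questionnaire = i // sentences_per_questionnaire
        for attr in attrs:
            questions.append({
                "question_id": len(questions),
                "questionnaire": questionnaire,
                "sentence_id": sid, "role": role, "word": word,
                "attribute": attr,
            })
    return pd.DataFrame(questions), excluded


def _validate_responses(responses: pd.DataFrame) -> None:
    bad = ~responses["rating"].isin(VALID_RATINGS)
    if bad.any():
        raise ValueError(
            f"invalid rating(s) outside {VALID_RATINGS}: "
            f"{responses.loc[bad, 'rating'].unique()[:5]}"
        )


def response_distribution(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant counts of -1 / 0 / +1 ratings."""
    _validate_responses(responses)
    counts = (
        responses.groupby("participant")["rating"]
        .value_counts().unstack(fill_value=0)
        .reindex(columns=list(VALID_RATINGS), fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    return counts


def pairwise_agreement(responses: pd.DataFrame) -> dict:
    """Pairwise match counts and the average percent agreement.

    For every participant pair, matches are questions answered identically;
    the average percent agreement is the mean over pairs of
    matches / common-question count. Pairs with no common questions are
    skipped (and listed).
    """
    _validate_responses(responses)
    pivot = responses.pivot_table(
        index="question_id", columns="participant", values="rating",
        aggfunc="first",
    )
    participants = list(pivot.columns)
    if len(participants) < 2:
        raise ValueError("need >=2 participants")
    matches = {}
    percents = []
    skipped = []
    for a, b in combinations(participants, 2):
        both = pivot[[a, b]].dropna()
        if both.empty:
            skipped.append((a, b))
            continue
        m = int((both[a] == both[b]).sum())
        matches[(a, b)] = {"matches": m, "common": len(both)}
        percents.append(m / len(both))
    return {
        "pair_matches": matches,
        "average_percent": 100.0 * float(np.mean(percents)),
        "skipped_pairs": skipped,
    }


def fleiss_kappa(counts: np.ndarray) -> dict:
    """Fleiss' kappa with standard error, z and p for multi-rater agreement.

    ``counts`` is an items x categories matrix of rating counts with the
    same number of raters on every item. Returns kappa, its standard error
    under the null of chance agreement, the z statistic and two-sided p.
    """
    counts = np.asarray(counts, dtype=float)
    n_items, _ = counts.shape
    raters = counts.sum(axis=1)
    if not np.all(raters == raters[0]):
        raise ValueError("unequal rater count per item")
    n = float(raters[0])
    if n < 2:
        raise ValueError("need >=2 raters per item")
    p_cat = counts.sum(axis=0) / (n_items * n)
    p_bar_e = float(np.sum(p_cat ** 2))
    if p_bar_e >= 1.0:
        raise ValueError("all ratings in one category; kappa undefined")
    p_items = (np.sum(counts ** 2, axis=1) - n) / (n * (n - 1))
    p_bar = float(np.mean(p_items))
    kappa = (p_bar - p_bar_e) / (1.0 - p_bar_e)
    # Fleiss (1971) large-sample variance under the null hypothesis kappa=0
    num = p_bar_e - (2 * n - 3) * p_bar_e ** 2 + 2 * (n - 2) * float(
        np.sum(p_cat ** 3)
    )
    var = 2.0 * num / (n_items * n * (n - 1) * (1.0 - p_bar_e) ** 2)
    se = float(np.sqrt(var))
    z = kappa / se if se > 0 else np.inf * np.sign(kappa)
    p = 2.0 * float(norm.sf(abs(z)))
    return {"kappa": float(kappa), "se": se, "z": float(z), "p": p,
            "p_bar": p_bar, "p_bar_e": p_bar_e}


def responses_to_counts(responses: pd.DataFrame) -> np.ndarray:
    """Question x category count matrix for Fleiss' kappa."""
    _validate_responses(responses)
    tab = (
        responses.groupby("question_id")["rating"].value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(VALID_RATINGS), fill_value=0)
    )
    return tab.to_numpy(dtype=float)


def select_consensus_questions(
    responses: pd.DataFrame, min_agree: int = 4
) -> tuple[list, float, pd.Series]:
    """Questions where >= ``min_agree`` raters gave the same rating.

    Returns the question ids, their share of the total question set, and the
    consensus label per selected question (the agreed rating).
    """
    _validate_responses(responses)
    pivot = responses.pivot_table(
        index="question_id", columns="participant", values="rating",
        aggfunc="first",
    )
    labels = {}
    for qid, row in pivot.iterrows():
        vals = row.dropna().astype(int)
        if vals.empty:
            continue
        counts = vals.value_counts()
        if counts.iloc[0] >= min_agree:
            labels[qid] = int(counts.index[0])
    share = len(labels) / len(pivot) if len(pivot) else np.nan
    ids = sorted(labels)
    return ids, share, pd.Series({q: labels[q] for q in ids}, dtype=int)


def majority_chance_rate(label_counts: Mapping[int, int]) -> float:
    """Largest-category share, in percent (always-guess-the-majority rate)."""
    counts = list(label_counts.values())
    total = sum(counts)
    if total == 0:
        raise ValueError("empty label counts")
    return 100.0 * max(counts) / total


def change_scores(
    revised: pd.DataFrame,
    original_cars: pd.DataFrame,
    sentences: Sequence[Sentence],
    approach: int = 1,
    attributes: Sequence[str] = ATTRIBUTES,
) -> pd.DataFrame:
    """Relative change scores per (token, attribute), three reference sets.

    Raw change = revised - original per token. The score subtracts a
    reference-average change: approach 1 uses the other words in the
    sentence, approach 2 all words in the sentence (target included), and
    approach 3 the same word's changes across all its sentence contexts.
    Approach 1 on a single-word sentence returns the raw change. Returns the
    same tidy format as ``revised`` with score values in the attribute
    columns.
    """
    if approach not in (1, 2, 3):
        raise ValueError(f"approach must be 1, 2 or 3, got {approach}")
    attrs = list(attributes)
    sent_len = {s.id: len(s.tokens) for s in sentences}
    out = revised.copy()
    delta = revised[attrs].to_numpy(float) - original_cars.loc[
        revised["word"], attrs
    ].to_numpy(float)
    dframe = pd.DataFrame(delta, columns=attrs)
    dframe[["subject", "sentence_id", "word"]] = revised[
        ["subject", "sentence_id", "word"]
    ].to_numpy()
    if approach in (1, 2):
        sums = dframe.groupby(["subject", "sentence_id"])[attrs].transform("sum")
        counts = dframe.groupby(["subject", "sentence_id"])[attrs].transform(
            "count")
        if approach == 2:
            reference = sums.to_numpy(float) / counts.to_numpy(float)
        else:
            n = counts.to_numpy(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                reference = (sums.to_numpy(float) - delta) / (n - 1)
            reference = np.where(n <= 1, 0.0, reference)  # lone word: raw change
    else:
        reference = dframe.groupby(["subject", "word"])[attrs].transform(
            "mean").to_numpy(float)
    out[attrs] = delta - reference
    return out


def labels_from_scores(
    scores: np.ndarray, upper: float, lower: float | None = None
) -> np.ndarray:
    """Map scores to ratings: > upper is "more"; <= lower (if given) "less"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.where(scores > upper, 1, 0)
    if lower is not None:
        labels = np.where(scores <= lower, -1, labels)
    return labels


def fit_boundaries(
    scores: np.ndarray,
    human_labels: np.ndarray,
    two_boundary: bool = False,
    step: float = 0.01,
) -> BoundaryFit:
    """Sweep decision boundaries over [-1, 1] to maximize human matches.

    One-boundary mode merges "less" and "neutral": a prediction matches when
    the human label is +1 and the score exceeds the boundary, or the label
    is in {-1, 0} and it does not. Two-boundary mode first fits the upper
    boundary that way, then sweeps a lower boundary (initialized at the
    fitted upper one, moving down) for the three-way mapping. Ties go to the
    smallest boundary.
    """
    scores = np.asarray(scores, dtype=float)
    human_labels = np.asarray(human_labels)
    if scores.size == 0 or scores.shape != human_labels.shape:
        raise ValueError("scores and labels must be nonempty and aligned")
    grid = np.arange(-1.0, 1.0 + step / 2, step)
    merged = np.where(human_labels == 1, 1, 0)
    best_upper, best_matches = grid[0], -1
    for b in grid:
        matches = int(np.sum(merged == (scores > b)))
        if matches > best_matches:
            best_upper, best_matches = float(b), matches
    if not two_boundary:
        return BoundaryFit(best_upper, None, step, best_matches, scores.size)
    lower_grid = grid[grid <= best_upper][::-1]  # start where the upper ended
    best_lower, best3 = float(best_upper), -1
    for lo in lower_grid:
        pred = labels_from_scores(scores, best_upper, float(lo))
        matches = int(np.sum(pred == human_labels))
        if matches > best3 or (matches == best3 and lo < best_lower):
            best_lower, best3 = float(lo), matches
    return BoundaryFit(best_upper, best_lower, step, best3, scores.size)


def chance_model(
    n: int, score_range: tuple[float, float], seed: int
) -> np.ndarray:
    """Uniform random change scores over the model's empirical score range."""
    lo, hi = score_range
    if lo >= hi:
        raise ValueError("need lo < hi in score_range")
    return np.random.default_rng(seed).uniform(lo, hi, size=n)


def match_rate(
    model_labels: np.ndarray, human_labels: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Percent of questions matched, plus a 3x3 confusion table."""
    model_labels = np.asarray(model_labels)
    human_labels = np.asarray(human_labels)
    if model_labels.shape != human_labels.shape or model_labels.size == 0:
        raise ValueError("label arrays must be nonempty and aligned")
    percent = 100.0 * float(np.mean(model_labels == human_labels))
    confusion = pd.crosstab(
        pd.Series(human_labels, name="human"),
        pd.Series(model_labels, name="model"),
    ).reindex(index=list(VALID_RATINGS), columns=list(VALID_RATINGS),
              fill_value=0)
    return percent, confusion
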