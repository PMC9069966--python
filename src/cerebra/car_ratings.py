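"""Aggregate per-rater attribute ratings into generic CAR word vectors.

A CAR (Concept Attribute Representation) rating study asks many raters to
score, on a 0-6 scale, how strongly a word is associated with each of 66
experiential attributes ("Not Applicable" is allowed and coded as 0).
This module turns the long-format rating table into one generic
66-dimensional vector per word:

1. code "Not Applicable" responses as 0,
2. reject outlier raters whose 66-vector correlates < 0.5 (Pearson) with
   the mean vector for that word,
3. average the surviving raters per attribute,
4. normalize the averaged vector to unit Euclidean length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTES

RATING_MIN = 0.0
RATING_MAX = 6.0

REQUIRED_COLUMNS = ("word", "rater", "attribute", "rating")


def _validate_ratings(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"rating table is missing column {col!r}")
    ratings = pd.to_numeric(table["rating"], errors="coerce")
    numeric = ratings.notna()
    bad = numeric & ((ratings < RATING_MIN) | (ratings > RATING_MAX))
    if bad.any():
        idx = bad[bad].index[0]
        row = table.loc[idx]
        raise ValueError(
            f"rating outside [{RATING_MIN:g}, {RATING_MAX:g}] at row {idx}: "
            f"word={row['word']!r} rater={row['rater']!r} "
            f"attribute={row['attribute']!r} rating={row['rating']!r}"
        )


def load_rating_table(path, sep: str = ",") -> pd.DataFrame:
    """Read a long-format rating table; the literal ``NA`` marks not-applicable.

    Not-applicable entries are kept distinct (NaN in the ``rating`` column)
    until :func:`code_not_applicable` is applied.
    """
    table = pd.read_csv(path, sep=sep, keep_default_na=False, dtype=str)
    _validate_ratings_presence(table)
    rating = table["rating"].replace({"NA": None, "": None})
    table = table.assign(rating=pd.to_numeric(rating, errors="raise"))
    _validate_ratings(table)
    return table


def _validate_ratings_presence(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"rating table is missing column {col!r}")


def code_not_applicable(table: pd.DataFrame) -> pd.DataFrame:
    """Replace not-applicable (NaN) ratings with 0; numeric entries unchanged."""
    _validate_ratings(table)
    out = table.copy()
    out["rating"] = pd.to_numeric(out["rating"], errors="coerce").fillna(0.0)
    return out


def rater_matrix(
    table: pd.DataFrame, word, attributes: Sequence[str] = ATTRIBUTES
) -> pd.DataFrame:
    """Raters x attributes matrix for one word (after NA coding).

    Raises if any rater lacks a complete attribute vector.
    """
    sub = table[table["word"] == word]
    if sub.empty:
        raise ValueError(f"word {word!r} absent from rating table")
    mat = sub.pivot_table(
        index="rater", columns="attribute", values="rating", aggfunc="mean"
    )
    missing = [a for a in attributes if a not in mat.columns]
    if missing or mat.isna().any().any():
        raise ValueError(
            f"incomplete rating vectors for word {word!r}; "
            f"missing attributes: {missing[:5]}"
        )
    return mat.loc[:, list(attributes)]


def reject_outlier_raters(
    table: pd.DataFrame,
    word,
    threshold: float = 0.5,
    include_self: bool = True,
    attributes: Sequence[str] = ATTRIBUTES,
) -> tuple[set, set, dict]:
    """Single-pass outlier filter on a word's raters.

    A rater is rejected iff the Pearson correlation of its 66-vector against
    the mean vector over the word's raters is below ``threshold``. With
    ``include_self=True`` (default) the mean includes the rater being tested;
    set it to False to test each rater against the leave-one-out mean.
    Zero-variance rater vectors have undefined correlation and are rejected
    with the flag ``"degenerate"``.

    Returns ``(kept, rejected, flags)`` where flags maps rejected raters to
    ``"low_correlation"`` or ``"degenerate"``.
    """
    mat = rater_matrix(table, word, attributes)
    if len(mat) < 2:
        raise ValueError(f"need >=2 raters for word {word!r}, got {len(mat)}")
    values = mat.to_numpy(dtype=float)
    kept: set = set()
    rejected: set = set()
    flags: dict = {}
    grand_sum = values.sum(axis=0)
    n = len(values)
    for i, rater in enumerate(mat.index):
        v = values[i]
        if include_self:
            mean_vec = grand_sum / n
        else:
            mean_vec = (grand_sum - v) / (n - 1)
        if np.std(v) == 0.0 or np.std(mean_vec) == 0.0:
            rejected.add(rater)
            flags[rater] = "degenerate"
            continue
        r = np.corrcoef(v, mean_vec)[0, 1]
        if r < threshold:
            rejected.add(rater)
            flags[rater] = "low_correlation"
        else:
            kept.add(rater)
    return kept, rejected, flags


def aggregate_word(
    table: pd.DataFrame,
    word,
    kept: Iterable | None = None,
    attributes: Sequence[str] = ATTRIBUTES,
) -> np.ndarray:
    """Per-attribute arithmetic mean over kept raters (raw 0-6 scale)."""
    mat = rater_matrix(table, word, attributes)
    if kept is not None:
        mat = mat.loc[mat.index.isin(set(kept))]
    if mat.empty:
        raise ValueError(f"no raters survive for word {word!r}")
    return mat.to_numpy(dtype=float).mean(axis=0)


def to_unit_length(raw: np.ndarray) -> np.ndarray:
    """Scale a nonnegative attribute vector to unit Euclidean norm."""
    raw = np.asarray(raw, dtype=float)
    norm = np.linalg.norm(raw)
    if norm == 0.0:
        raise ValueError("cannot normalize zero vector")
    return raw / norm


def build_car_table(
    table: pd.DataFrame,
    threshold: float = 0.5,
    include_self: bool = True,
    attributes: Sequence[str] = ATTRIBUTES,
) -> pd.DataFrame:
    """Full pipeline: NA coding, outlier rejection, averaging, normalization.

    Returns a words x 66 DataFrame of unit-norm CAR vectors.
    """
    coded = code_not_applicable(table)
    rows = {}
    for word in pd.unique(coded["word"]):
        kept, _, _ = reject_outlier_raters(
            coded, word, threshold=threshold, include_self=include_self,
            attributes=attributes,
        )
        raw = aggregate_word(coded, word, kept=kept, attributes=attributes)
        rows[word] = to_unit_length(raw)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(attributes))
    out.index.name = "word"
    return out


def save_car_table(cars: pd.DataFrame, path, sep: str = ",") -> None:
    cars.to_csv(path, sep=sep, float_format="%.6f")


def load_car_table(path, sep: str = ",") -> pd.DataFrame:
    cars = pd.read_csv(path, sep=sep, index_col="word")
    if cars.shape[1] != len(ATTRIBUTES):
        raise ValueError(
            f"CAR table must have {len(ATTRIBUTES)} attribute columns, "
            f"found {cars.shape[1]}"
        )
    return cars
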