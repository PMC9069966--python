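"""Sentences, role-tagged tokens, and sentence fMRI containers.

A sentence is 2-5 content words, each tagged with one of three semantic
roles: Agent, Verb, or POLE (the combined Patient/Object/Location/Event
role). Sentence fMRI arrives as one 396-voxel vector per sentence and
subject, repetition-averaged and min-max scaled to [0.2, 0.8]. Word-level
fMRI proxies (SynthWords) are formed by averaging the fMRI of all sentences
containing the word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("Agent", "Verb", "POLE")
N_VOXELS = 396
VOXEL_LO = 0.2
VOXEL_HI = 0.8


@dataclass(frozen=True)
class Token:
    word: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass
class Sentence:
    id: int
    text: str
    tokens: list[Token]

    def __post_init__(self):
        if not 1 <= len(self.tokens) <= 6:
            raise ValueError(
                f"sentence {self.id} has {len(self.tokens)} tokens; expected 1-6"
            )

    @property
    def words(self) -> list[str]:
        return [t.word for t in self.tokens]


@dataclass
class SynthWord:
    """Word-level fMRI proxy: mean of the sentences containing the word."""

    word: str
    subject: str
    voxels: np.ndarray
    source_sentences: frozenset = field(default_factory=frozenset)


def parse_tokens(spec: str) -> list[Token]:
    """Parse ``"Agent:politician;Verb:celebrated;POLE:hotel"``."""
    tokens = []
    for part in spec.split(";"):
        part = part.strip()
        if not part:
            continue
        role, _, word = part.partition(":")
        tokens.append(Token(word=word.strip(), role=role.strip()))
    return tokens


def format_tokens(tokens: Sequence[Token]) -> str:
    return ";".join(f"{t.role}:{t.word}" for t in tokens)


def read_sentences(path, sep: str = "\t") -> list[Sentence]:
    frame = pd.read_csv(path, sep=sep, dtype={"sentence_id": int, "text": str})
    return [
        Sentence(id=int(r.sentence_id), text=str(r.text),
                 tokens=parse_tokens(str(r.tokens)))
        for r in frame.itertuples()
    ]


def write_sentences(sentences: Sequence[Sentence], path, sep: str = "\t") -> None:
    frame = pd.DataFrame(
        {
            "sentence_id": [s.id for s in sentences],
            "text": [s.text for s in sentences],
            "tokens": [format_tokens(s.tokens) for s in sentences],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


def average_repetitions(reps: Sequence[np.ndarray]) -> np.ndarray:
    """Voxel-wise mean over the repetitions of one sentence."""
    if len(reps) == 0:
        raise ValueError("no repetitions to average")
    arrays = [np.asarray(r, dtype=float) for r in reps]
    n = arrays[0].shape[0]
    for a in arrays:
        if a.shape != (n,):
            raise ValueError(f"repetition length mismatch: {a.shape} vs ({n},)")
    return np.mean(arrays, axis=0)


def scale_voxels(
    matrix: np.ndarray | pd.DataFrame,
    lo: float = VOXEL_LO,
    hi: float = VOXEL_HI,
    per_voxel: bool = True,
):
    """Linear min-max map of sentence x voxel activations onto [lo, hi].

    By default the map is computed per voxel across sentences (each voxel's
    minimum lands on ``lo`` and maximum on ``hi``); ``per_voxel=False``
    scales with the global min/max instead. Degenerate (constant) columns
    map to the interval midpoint.
    """
    if hi <= lo:
        raise ValueError(f"need hi > lo, got lo={lo} hi={hi}")
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("expected a 2-D matrix with >=1 row")
    if per_voxel:
        mn = values.min(axis=0, keepdims=True)
        mx = values.max(axis=0, keepdims=True)
    else:
        mn = np.full((1, values.shape[1]), values.min())
        mx = np.full((1, values.shape[1]), values.max())
    span = mx - mn
    mid = 0.5 * (lo + hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = lo + (values - mn) * (hi - lo) / span
    scaled = np.where(span == 0.0, mid, scaled)
    scaled = np.clip(scaled, lo, hi)  # guard float round-off at the endpoints
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    return scaled


def select_top_voxels(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k voxels with the largest across-sentence variance.

    Plumbing for users with real whole-brain data; the statistical criterion
    behind a study-specific voxel selection is outside this package.
    """
    if k < 1 or k > matrix.shape[1]:
        raise ValueError(f"k must be in [1, {matrix.shape[1]}], got {k}")
    variances = matrix.var(axis=0)
    keep = variances.sort_values(ascending=False).index[:k]
    return matrix.loc[:, sorted(keep, key=list(matrix.columns).index)]


def build_synthword(
    word: str,
    fmri_rows: Sequence[tuple[int, np.ndarray]],
    subject: str = "",
) -> SynthWord:
    """Average the fMRI of the sentences containing ``word`` into a SynthWord."""
    if len(fmri_rows) == 0:
        raise ValueError(f"word {word!r} absent from corpus")
    ids = frozenset(sid for sid, _ in fmri_rows)
    voxels = average_repetitions([vec for _, vec in fmri_rows])
    return SynthWord(word=word, subject=subject, voxels=voxels,
                     source_sentences=ids)


def build_synthwords(
    sentences: Sequence[Sentence],
    fmri: pd.DataFrame,
    subject: str = "",
) -> dict[str, SynthWord]:
    """SynthWords for every word of a corpus, one subject.

    ``fmri`` is a sentences x voxels DataFrame indexed by sentence_id.
    """
    membership: dict[str, list[tuple[int, np.ndarray]]] = {}
    for s in sentences:
        if s.id not in fmri.index:
            raise ValueError(f"sentence {s.id} missing from fMRI matrix")
        row = fmri.loc[s.id].to_numpy(dtype=float)
        for word in set(s.words):
            membership.setdefault(word, []).append((s.id, row))
    return {
        w: build_synthword(w, rows, subject=subject)
        for w, rows in membership.items()
    }


def dedupe_synthwords(
    words: Sequence[SynthWord],
) -> tuple[list[SynthWord], list[SynthWord], list[list[str]]]:
    """Drop SynthWords whose source-sentence sets coincide.

    Words occurring in exactly the same sentences average to identical
    vectors; among each such group one representative (first encountered)
    is kept. Returns ``(kept, excluded, duplicate_groups)``.
    """
    groups: dict[frozenset, list[SynthWord]] = {}
    for sw in words:
        groups.setdefault(sw.source_sentences, []).append(sw)
    kept: list[SynthWord] = []
    excluded: list[SynthWord] = []
    dup_groups: list[list[str]] = []
    for sw in words:
        group = groups[sw.source_sentences]
        if sw is group[0]:
            kept.append(sw)
            if len(group) > 1:
                dup_groups.append([g.word for g in group])
        else:
            # secondary numeric confirmation that the duplicates truly agree
            if not np.allclose(sw.voxels, group[0].voxels, atol=1e-12):
                kept.append(sw)
                continue
            excluded.append(sw)
    return kept, excluded, dup_groups


def assemble_synthsent(predicted: Sequence[np.ndarray]) -> np.ndarray:
    """Predicted sentence pattern: mean of the sentence's predicted words."""
    if len(predicted) == 0:
        raise ValueError("no predicted word vectors to assemble")
    return average_repetitions(predicted)


def read_fmri(path, sep: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, index_col="sentence_id")
    return frame.astype(float)


def write_fmri(fmri: pd.DataFrame, path, sep: str = ",") -> None:
    out = fmri.copy()
    out.index.name = "sentence_id"
    out.to_csv(path, sep=sep, float_format="%.6f")


def token_count(sentences: Iterable[Sentence]) -> int:
    """Total content tokens across the corpus (word occurrences, not types)."""
    return sum(len(s.tokens) for s in sentences)
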