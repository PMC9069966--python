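"""Seeded generators for CAR lexicons, corpora, fMRI, and simulated raters.

The study data this package analyzes (sentence fMRI under a restricted
license, crowd-sourced CAR ratings and survey streams) is emulated by a
generative surrogate with explicit ground truth:

* a lexicon of nonnegative sparse unit-norm CAR vectors with animate /
  object / action block structure,
* sentences of 2-5 role-tagged content words (one Agent, one Verb,
  optional POLE words),
* planted context shifts: each token's contextual CAR is the generic CAR
  mixed toward the mean CAR of the other words in the sentence with weight
  lambda (the conceptual-combination strength),
* sentence fMRI from a frozen random nonlinear CAR-to-voxel map per
  subject (affine -> tanh -> affine), token outputs averaged per sentence,
  Gaussian noise per repetition, repetitions averaged, then min-max scaled
  to [0.2, 0.8],
* noisy raters who threshold true change scores and flip labels at a fixed
  rate.

Everything is deterministic given (config, seed), and the planted shifts
are recorded so recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attributes import (
    ACTION_BLOCK, ANIMATE_BLOCK, ATTRIBUTES, OBJECT_BLOCK, block_indices,
)
from .corpus import Sentence, Token, scale_voxels


@dataclass
class SynthesisConfig:
    n_words: int = 40
    n_sentences: int = 30
    min_words: int = 2
    max_words: int = 5
    n_voxels: int = 396
    n_subjects: int = 2
    n_repetitions: int = 12
    lam: float = 0.3          # context-mixing strength, lambda in [0, 1]
    sigma: float = 0.01       # per-repetition Gaussian voxel noise
    hidden_dim: int = 96      # width of the frozen nonlinear map
    n_raters: int = 30        # CAR rating simulation
    rater_sigma: float = 0.8
    na_rate: float = 0.05
    n_outlier_raters: int = 1
    flip_rate: float = 0.2    # survey rater label flips
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 2 <= self.min_words <= self.max_words <= 5:
            raise ValueError("words per sentence must satisfy 2 <= min <= max <= 5")
        for name in ("n_words", "n_sentences", "n_voxels", "n_subjects",
                     "n_repetitions", "n_raters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.flip_rate < 1.0:
            raise ValueError("flip_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    config: SynthesisConfig
    lexicon: pd.DataFrame                 # words x 66 unit-norm CARs
    categories: dict                      # word -> animate | object | action
    sentences: list
    contextual: dict                      # (sentence_id, position) -> 66-vector
    fmri: dict = field(default_factory=dict)  # subject -> sentences x voxels


_CATEGORY_BLOCK = {
    "animate": ANIMATE_BLOCK,
    "object": OBJECT_BLOCK,
    "action": ACTION_BLOCK,
}


def gen_lexicon(config: SynthesisConfig) -> tuple[pd.DataFrame, dict]:
    """Sparse nonnegative unit-norm CAR vectors with category structure.

    Words split roughly evenly into animate / action / object categories;
    each word loads strongly on its category's attribute block and weakly
    and sparsely elsewhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_words
    n_animate = n // 3
    n_action = n // 3
    cats = (["animate"] * n_animate + ["action"] * n_action
            + ["object"] * (n - n_animate - n_action))
    names = {"animate": "agent", "action": "verb", "object": "object"}
    counters = {"animate": 0, "action": 0, "object": 0}
    rows, categories = {}, {}
    for cat in cats:
        word = f"{names[cat]}{counters[cat]:02d}"
        counters[cat] += 1
        v = rng.gamma(shape=1.0, scale=0.15, size=len(ATTRIBUTES))
        v[rng.random(len(ATTRIBUTES)) < 0.35] = 0.0  # off-block sparsity
        idx = block_indices(_CATEGORY_BLOCK[cat])
        v[idx] = rng.gamma(shape=2.0, scale=1.0, size=len(idx))
        if v.max() == 0.0:
            v[idx[0]] = 1.0
        rows[word] = v / np.linalg.norm(v)
        categories[word] = cat
    lexicon = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=list(ATTRIBUTES))
    lexicon.index.name = "word"
    return lexicon, categories


def gen_corpus(
    config: SynthesisConfig, lexicon: pd.DataFrame, categories: dict
) -> list[Sentence]:
    """Role-structured sentences: one Agent, one Verb, 0-3 POLE words.

    Every lexicon word is guaranteed to occur in at least one sentence
    (missing words are inserted into sentences with open slots).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pools = {cat: [w for w, c in categories.items() if c == cat]
             for cat in ("animate", "action", "object")}
    for cat, pool in pools.items():
        if not pool:
            raise ValueError(f"lexicon has no {cat} words")

    queues = {cat: list(rng.permutation(pool)) for cat, pool in pools.items()}

    def draw(cat: str) -> str:
        if queues[cat]:
            return queues[cat].pop()
        return str(rng.choice(pools[cat]))

    sentences = []
    for sid in range(config.n_sentences):
        n_tokens = int(rng.integers(config.min_words, config.max_words + 1))
        agent = draw("animate")
        verb = draw("action")
        tokens = [Token(agent, "Agent"), Token(verb, "Verb")]
        pole_pool = [w for w in pools["object"] if w not in (agent, verb)]
        n_pole = min(n_tokens - 2, len(pole_pool))
        fresh = [w for w in queues["object"] if w in pole_pool]
        picked = []
        for _ in range(n_pole):
            if fresh:
                w = fresh.pop()
                queues["object"].remove(w)
            else:
                w = str(rng.choice([p for p in pole_pool if p not in picked]))
            picked.append(w)
            tokens.append(Token(w, "POLE"))
        text = f"The {agent} {verb}" + (
            " the " + " and the ".join(picked) if picked else ""
        )
        sentences.append(Sentence(id=sid, text=text, tokens=tokens))
    # coverage: insert any unused word into a sentence with room (as a POLE
    # slot, the catch-all Patient/Object/Location/Event role)
    used = {t.word for s in sentences for t in s.tokens}
    for word in lexicon.index:
        if word in used:
            continue
        candidates = [s for s in sentences
                      if len(s.tokens) < config.max_words
                      and word not in s.words]
        if candidates:
            s = candidates[int(rng.integers(len(candidates)))]
            s.tokens.append(Token(word, "POLE"))
            s.text += f" {word}"
        else:
            sentences.append(Sentence(
                id=len(sentences),
                text=f"The {word}",
                tokens=[Token(draw('animate'), "Agent"), Token(word, "POLE")],
            ))
    return sentences


def gen_context_shifts(
    sentences: list[Sentence], lexicon: pd.DataFrame, lam: float
) -> dict[tuple[int, int], np.ndarray]:
    """Planted contextual CARs: clamp((1-lambda)*car + lambda*OWS-mean, 0, 1).

    Single-token sentences keep the generic CAR unchanged.
    """
    contextual = {}
    for s in sentences:
        cars = lexicon.loc[s.words].to_numpy(dtype=float)
        for pos in range(len(s.tokens)):
            if len(s.tokens) < 2:
                contextual[(s.id, pos)] = cars[pos].copy()
                continue
            ows = np.delete(cars, pos, axis=0).mean(axis=0)
            mixed = (1.0 - lam) * cars[pos] + lam * ows
            contextual[(s.id, pos)] = np.clip(mixed, 0.0, 1.0)
    return contextual


def _subject_map(rng: np.random.Generator, n_in: int, hidden: int, n_out: int):
    """Frozen random nonlinear CAR-to-voxel map: affine -> tanh -> affine."""
    A = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, hidden))
    a = rng.normal(0.0, 0.2, size=hidden)
    B = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, n_out))
    b = rng.normal(0.0, 0.2, size=n_out)

    def f(cars: np.ndarray) -> np.ndarray:
        return np.tanh(np.atleast_2d(cars) @ A + a) @ B + b

    return f


def gen_fmri(
    sentences: list[Sentence],
    contextual: dict,
    config: SynthesisConfig,
) -> dict[str, pd.DataFrame]:
    """Per-subject sentence fMRI matrices from the frozen nonlinear map.

    Each sentence's raw pattern is the mean of the map applied to its
    tokens' contextual CARs; per-repetition Gaussian noise is added, the
    repetitions are averaged, and the matrix is min-max scaled per voxel to
    [0.2, 0.8].
    """
    out = {}
    for subj_idx in range(config.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, subj_idx])
        )
        f = _subject_map(rng, len(ATTRIBUTES), config.hidden_dim,
                         config.n_voxels)
        raw = np.zeros((len(sentences), config.n_voxels))
        for i, s in enumerate(sentences):
            token_cars = np.stack([
                contextual[(s.id, pos)] for pos in range(len(s.tokens))
            ])
            raw[i] = f(token_cars).mean(axis=0)
        reps = raw[None, :, :] + rng.normal(
            0.0, config.sigma,
            size=(config.n_repetitions, *raw.shape),
        ) if config.sigma > 0 else np.broadcast_to(
            raw, (config.n_repetitions, *raw.shape)
        )
        averaged = reps.mean(axis=0)
        scaled = scale_voxels(averaged)
        frame = pd.DataFrame(
            scaled,
            index=pd.Index([s.id for s in sentences], name="sentence_id"),
            columns=[f"v{j:03d}" for j in range(config.n_voxels)],
        )
        out[f"S{subj_idx}"] = frame
    return out


def gen_rating_table(
    lexicon: pd.DataFrame, config: SynthesisConfig
) -> pd.DataFrame:
    """Simulated 0-6 rating study over the lexicon's true CAR profiles.

    Honest raters rate the word's true profile (rescaled to the 0-6 range)
    plus Gaussian noise, with occasional not-applicable answers (NaN);
    planted outlier raters rate a permuted profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    records = []
    for word in lexicon.index:
        car = lexicon.loc[word].to_numpy(dtype=float)
        profile = car * (6.0 / car.max())
        for r in range(config.n_raters):
            is_outlier = r < config.n_outlier_raters
            base = rng.permutation(profile) if is_outlier else profile
            noisy = np.clip(
                np.round(base + rng.normal(0.0, config.rater_sigma,
                                           size=len(base))),
                0.0, 6.0,
            )
            na_mask = rng.random(len(base)) < config.na_rate
            for attr, value, na in zip(ATTRIBUTES, noisy, na_mask):
                records.append({
                    "word": word,
                    "rater": f"{word}_r{r:02d}",
                    "attribute": attr,
                    "rating": np.nan if na else float(value),
                })
    return pd.DataFrame.from_records(records)


def gen_raters(
    true_scores: np.ndarray,
    flip_rate: float,
    n_raters: int,
    seed: int,
    thresholds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulated survey raters thresholding true change scores.

    The noiseless label is +1 above the upper threshold, -1 below the lower
    one, 0 between; with probability ``flip_rate`` each label is replaced by
    one of the two other labels uniformly. When ``thresholds`` is None the
    33rd/67th percentiles of the scores are used, giving roughly balanced
    categories. Returns a responses frame (question_id, participant, rating).
    """
    scores = np.asarray(true_scores, dtype=float)
    if thresholds is None:
        lower, upper = np.quantile(scores, [1 / 3, 2 / 3])
    else:
        lower, upper = thresholds
    if lower > upper:
        raise ValueError("need lower <= upper threshold")
    rng = np.random.default_rng(seed)
    base = np.where(scores > upper, 1, np.where(scores < lower, -1, 0))
    records = []
    for p in range(n_raters):
        labels = base.copy()
        flips = rng.random(scores.size) < flip_rate
        offsets = rng.integers(1, 3, size=scores.size)  # one of the 2 others
        others = np.array([-1, 0, 1])
        flipped = others[(np.searchsorted(others, labels) + offsets) % 3]
        labels = np.where(flips, flipped, labels)
        for qid, rating in enumerate(labels):
            records.append({
                "question_id": qid,
                "participant": f"P{p + 1}",
                "rating": int(rating),
            })
    return pd.DataFrame.from_records(records)


def make_dataset(config: SynthesisConfig | None = None) -> SyntheticDataset:
    """Generate the full bundle: lexicon, corpus, planted shifts, fMRI."""
    config = config or SynthesisConfig()
    lexicon, categories = gen_lexicon(config)
    sentences = gen_corpus(config, lexicon, categories)
    contextual = gen_context_shifts(sentences, lexicon, config.lam)
    fmri = gen_fmri(sentences, contextual, config)
    return SyntheticDataset(
        config=config, lexicon=lexicon, categories=categories,
        sentences=sentences, contextual=contextual, fmri=fmri,
    )
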