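"""End-to-end evaluation experiments on synthetic data.

These helpers wire the generator, the network+FGREP interpretation loop,
the aggregation statistics and the behavioral comparison into seeded,
desk-scale experiments:

* ``recovery_experiment``: how well the per-token revised-minus-original
  change vectors recover the planted context shifts, and whether revision
  increases the correlation with the Other Words in the Sentence (OWS).
* ``behavioral_surrogate``: whether boundaries fitted on the model's change
  scores match consensus labels of simulated raters (driven by the true
  change scores) better than boundaries fitted on random scores.

The desk-scale training/FGREP settings used by default (800-epoch budget,
1,500 FGREP iterations, one run, first subject) keep a 10-seed experiment
inside a few minutes on one CPU; they are package choices, configurable per
call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import behavior
from .aggregation import correlation_analysis
from .attributes import ATTRIBUTES
from .fgrep import FgrepConfig, revise_corpus
from .network import TrainingConfig
from .synthetic import SynthesisConfig, SyntheticDataset, gen_raters, make_dataset


def desk_training_config(seed: int = 0) -> TrainingConfig:
    """Reduced-epoch training budget for multi-seed experiments."""
    return TrainingConfig(max_epochs=800, target_mse=1e-4, seed=seed)


def desk_fgrep_config() -> FgrepConfig:
    """Bounded-iteration FGREP settings for multi-seed experiments."""
    return FgrepConfig(max_iters=1500, epsilon=1e-4)


def revise_first_subject(
    dataset: SyntheticDataset,
    train_config: TrainingConfig | None = None,
    fgrep_config: FgrepConfig | None = None,
    n_runs: int = 1,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Train + FGREP-revise the corpus for the dataset's first subject."""
    subject = next(iter(dataset.fmri))
    if base_seed is None:
        base_seed = dataset.config.seed
    return revise_corpus(
        dataset.sentences, dataset.lexicon,
        {subject: dataset.fmri[subject]},
        train_config=train_config or desk_training_config(base_seed),
        fgrep_config=fgrep_config or desk_fgrep_config(),
        n_runs=n_runs, base_seed=base_seed,
    )


def shift_recovery(
    dataset: SyntheticDataset, revised: pd.DataFrame
) -> tuple[float, int]:
    """Mean Pearson r between per-token change vectors and planted shifts.

    For every token, the change vector is the revised minus the generic CAR
    and the planted shift is the ground-truth contextual CAR minus the
    generic CAR. Tokens whose planted shift (or change) has zero variance
    (e.g. single-role degenerate cases, or lambda = 0 where no shift was
    planted) are excluded; returns (mean r, number of tokens scored).
    """
    attrs = list(ATTRIBUTES)
    rs = []
    for row in revised.itertuples():
        original = dataset.lexicon.loc[row.word].to_numpy(dtype=float)
        change = np.array([getattr(row, a) for a in attrs]) - original
        shift = dataset.contextual[(row.sentence_id, row.position)] - original
        if np.std(shift) > 0 and np.std(change) > 0:
            rs.append(pearsonr(shift, change).statistic)
    mean_r = float(np.mean(rs)) if rs else float("nan")
    return mean_r, len(rs)


def ows_gap(
    dataset: SyntheticDataset, revised: pd.DataFrame
) -> dict:
    """Token-weighted revised-vs-OWS minus original-vs-OWS correlation.

    Wraps :func:`cerebra.aggregation.correlation_analysis` and collapses its
    per-(subject, role) rows into overall means weighted by token count.
    """
    table = correlation_analysis(revised, dataset.lexicon, dataset.sentences)
    ok = table[table["n_tokens"] > 0]
    w = ok["n_tokens"].to_numpy(dtype=float)
    mean_rev = float(np.average(ok["mean_r_revised"], weights=w))
    mean_orig = float(np.average(ok["mean_r_original"], weights=w))
    return {
        "mean_r_revised": mean_rev,
        "mean_r_original": mean_orig,
        "gap": mean_rev - mean_orig,
        "n_tokens": int(w.sum()),
    }


def recovery_experiment(
    seed: int,
    lam: float = 0.3,
    sigma: float = 0.01,
    train_config: TrainingConfig | None = None,
    fgrep_config: FgrepConfig | None = None,
    n_runs: int = 1,
) -> dict:
    """One seed of the shift-recovery / OWS-gap experiment.

    Generates the default-size fixture at the given mixing strength, trains
    and revises the first subject, and reports the planted-shift recovery
    correlation plus the OWS correlation gap.
    """
    dataset = make_dataset(SynthesisConfig(seed=seed, lam=lam, sigma=sigma))
    revised = revise_first_subject(
        dataset, train_config=train_config, fgrep_config=fgrep_config,
        n_runs=n_runs, base_seed=seed,
    )
    mean_r, n_scored = shift_recovery(dataset, revised)
    gap = ows_gap(dataset, revised)
    return {
        "seed": seed, "lam": lam, "sigma": sigma,
        "recovery_r": mean_r, "n_tokens_scored": n_scored,
        **gap,
    }


def true_change_scores(
    dataset: SyntheticDataset, revised: pd.DataFrame, approach: int = 1
) -> np.ndarray:
    """Relative change scores computed from the planted contextual CARs.

    Uses the same token ordering as ``revised`` so the scores align
    question-for-question with the model's scores.
    """
    attrs = list(ATTRIBUTES)
    truth = revised.copy()
    truth[attrs] = np.stack([
        dataset.contextual[(row.sentence_id, row.position)]
        for row in revised.itertuples()
    ])
    frame = behavior.change_scores(
        truth, dataset.lexicon, dataset.sentences, approach=approach
    )
    return frame[attrs].to_numpy(dtype=float).ravel()


def behavioral_surrogate(
    dataset: SyntheticDataset,
    revised: pd.DataFrame,
    n_seeds: int = 20,
    flip_rate: float = 0.2,
    approach: int = 1,
    min_agree: int = 3,
) -> dict:
    """Fitted model-vs-rater match rate against a fitted chance baseline.

    Simulated raters label every (token, attribute) question from the TRUE
    (planted) change scores with the given flip rate; each seed draws fresh
    raters and a fresh random-score chance model. Boundaries are fitted in
    the two-boundary (three-label) mode so the chance fit converges to the
    majority-class fraction. Reports per-seed match rates, the win count
    (model beats chance), and the largest |chance - majority| deviation.
    """
    attrs = list(ATTRIBUTES)
    scores = behavior.change_scores(
        revised, dataset.lexicon, dataset.sentences, approach=approach
    )
    values = scores[attrs].to_numpy(dtype=float).ravel()
    truth = true_change_scores(dataset, revised, approach=approach)
    wins = 0
    model_rates, chance_rates, deviations = [], [], []
    for seed in range(n_seeds):
        responses = gen_raters(truth, flip_rate, n_raters=4, seed=seed)
        _, _, consensus = behavior.select_consensus_questions(
            responses, min_agree=min_agree
        )
        idx = consensus.index.to_numpy()
        labels = consensus.to_numpy()
        fit = behavior.fit_boundaries(values[idx], labels, two_boundary=True)
        predicted = behavior.labels_from_scores(
            values[idx], fit.boundary_upper, fit.boundary_lower
        )
        rate, _ = behavior.match_rate(predicted, labels)
        chance = behavior.chance_model(
            len(idx), (values.min(), values.max()), seed=seed
        )
        chance_fit = behavior.fit_boundaries(chance, labels, two_boundary=True)
        uniq, counts = np.unique(labels, return_counts=True)
        majority = behavior.majority_chance_rate(dict(zip(uniq, counts)))
        wins += int(rate > chance_fit.match_rate)
        model_rates.append(rate)
        chance_rates.append(chance_fit.match_rate)
        deviations.append(abs(chance_fit.match_rate - majority))
    return {
        "n_seeds": n_seeds,
        "wins": wins,
        "mean_model_rate": float(np.mean(model_rates)),
        "mean_chance_rate": float(np.mean(chance_rates)),
        "max_chance_majority_deviation": float(np.max(deviations)),
        "model_rates": model_rates,
        "chance_rates": chance_rates,
    }
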