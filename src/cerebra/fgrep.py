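"""Backpropagation-to-inputs (FGREP): context-revised CARs per sentence.

With the trained network's weights frozen, each sentence's predicted fMRI
(the mean of its words' predicted patterns) is compared with the observed
sentence fMRI, and the error is propagated back through the averaging and
both layers to the input CAR vectors. All of the sentence's word CARs
descend jointly on the sentence MSE; after every step the components are
clamped to [0, 1]. Iteration stops when the error is near zero, when the
clamped update can no longer move any component, or at an iteration cap.
Averaging the revised vectors over several train+revise runs (different
random seeds) gives the final context-specific CAR per word token.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import ATTRIBUTES
from .corpus import Sentence, assemble_synthsent, build_synthwords, dedupe_synthwords
from .network import NetworkParams, TrainingConfig, forward, train

TERM_CONVERGED = "converged"
TERM_CLAMPED = "clamped_stall"
TERM_MAX_ITERS = "max_iters"


@dataclass
class FgrepConfig:
    input_lr: float = 0.3
    epsilon: float = 1e-4       # sentence MSE regarded as "near zero"
    max_iters: int = 10_000
    clamp_lo: float = 0.0
    clamp_hi: float = 1.0
    stall_tol: float = 1e-9
    line_search: bool = True    # guarantee monotone descent of sentence MSE

    def __post_init__(self):
        if self.input_lr <= 0:
            raise ValueError("input_lr must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.clamp_lo >= self.clamp_hi:
            raise ValueError("need clamp_lo < clamp_hi")


def predict_sentence(
    params: NetworkParams,
    cars: np.ndarray,
    output_activation: str = "logistic",
) -> np.ndarray:
    """Forward every word CAR, then average the outputs into a SynthSent."""
    cars = np.atleast_2d(np.asarray(cars, dtype=float))
    if cars.shape[0] < 1:
        raise ValueError("need at least one word CAR")
    _, outputs = forward(params, cars, output_activation)
    return assemble_synthsent(list(outputs))


def sentence_error(
    predicted: np.ndarray, observed: np.ndarray
) -> tuple[np.ndarray, float]:
    """Error vector (observed - predicted) and its mean squared value."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs observed "
            f"{observed.shape}"
        )
    err = observed - predicted
    return err, float(np.mean(err ** 2))


def input_gradients(
    params: NetworkParams,
    cars: np.ndarray,
    observed: np.ndarray,
    output_activation: str = "logistic",
) -> tuple[np.ndarray, float]:
    """Gradient of 0.5*sum((pred - obs)^2) w.r.t. every word CAR.

    The gradient flows through the word-averaging step (each word receives
    1/m of the output error) and both network layers. Returns the (m, 66)
    gradient array and the current sentence MSE.
    """
    X = np.atleast_2d(np.asarray(cars, dtype=float))
    m = X.shape[0]
    hidden = 1.0 / (1.0 + np.exp(-(X @ params.w_in + params.b_hidden)))
    pre = hidden @ params.w_out + params.b_out
    if output_activation == "logistic":
        out = 1.0 / (1.0 + np.exp(-pre))
        act_deriv = out * (1.0 - out)
    else:
        out = pre
        act_deriv = np.ones_like(pre)
    pred = out.mean(axis=0)
    err = pred - np.asarray(observed, dtype=float)
    mse = float(np.mean(err ** 2))
    delta_out = (err / m) * act_deriv           # (m, n_out)
    delta_hidden = (delta_out @ params.w_out.T) * hidden * (1.0 - hidden)
    grads = delta_hidden @ params.w_in.T        # (m, n_in)
    return grads, mse


def fgrep_sentence(
    params: NetworkParams,
    cars: np.ndarray,
    observed: np.ndarray,
    config: FgrepConfig | None = None,
    output_activation: str = "logistic",
) -> tuple[np.ndarray, str, int, float]:
    """Jointly revise a sentence's word CARs under frozen network weights.

    Returns ``(revised, termination, n_iters, final_mse)``; ``revised`` has
    one row per word, every component in [clamp_lo, clamp_hi]. The network
    parameters are never modified.

    With ``line_search`` enabled (the default) the step size adapts so that
    the sentence MSE never increases: a step that would increase the error
    is retried at half the rate, and successful steps let the rate grow
    again (bounded by 100x ``input_lr``). A fixed step at exactly
    ``input_lr`` can orbit the attainable minimum instead of settling into
    it, which inflates the revised CARs with movement unrelated to the
    observed pattern; the safeguard removes that artifact. When no step
    size can reduce the error any further the error "cannot be modified"
    and the run terminates as a stall. ``line_search=False`` restores the
    plain fixed-step update.
    """
    config = config or FgrepConfig()
    X = np.atleast_2d(np.asarray(cars, dtype=float)).copy()
    observed = np.asarray(observed, dtype=float)
    termination = TERM_MAX_ITERS
    it = 0
    lr = config.input_lr
    lr_max = config.input_lr * 100.0
    lr_min = config.input_lr * 1e-12
    grads, mse = input_gradients(params, X, observed, output_activation)
    for it in range(config.max_iters):
        if mse <= config.epsilon:
            termination = TERM_CONVERGED
            break
        if not np.isfinite(mse):
            raise FloatingPointError(f"non-finite sentence error at iteration {it}")
        if config.line_search:
            stalled = False
            while True:
                X_new = np.clip(X - lr * grads, config.clamp_lo, config.clamp_hi)
                if np.max(np.abs(X_new - X)) <= config.stall_tol or lr < lr_min:
                    stalled = True
                    break
                grads_new, mse_new = input_gradients(
                    params, X_new, observed, output_activation
                )
                if mse_new <= mse:
                    break
                lr *= 0.5
            if stalled:
                termination = TERM_CLAMPED
                break
            X, grads, mse = X_new, grads_new, mse_new
            lr = min(lr * 1.5, lr_max)
        else:
            X_new = np.clip(
                X - config.input_lr * grads, config.clamp_lo, config.clamp_hi
            )
            if np.max(np.abs(X_new - X)) <= config.stall_tol:
                termination = TERM_CLAMPED
                break
            X = X_new
            grads, mse = input_gradients(params, X, observed, output_activation)
    else:
        if mse <= config.epsilon:
            termination = TERM_CONVERGED
    return X, termination, it, mse


def training_pairs(
    sentences: Sequence[Sentence],
    car_table: pd.DataFrame,
    fmri: pd.DataFrame,
    subject: str = "",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(CARWord, SynthWord) training pairs for one subject.

    SynthWords whose source-sentence sets coincide are identical and all but
    one representative are excluded before training.
    """
    synthwords = build_synthwords(sentences, fmri, subject=subject)
    kept, _, _ = dedupe_synthwords(list(synthwords.values()))
    words = [sw.word for sw in kept]
    missing = [w for w in words if w not in car_table.index]
    if missing:
        raise ValueError(f"words missing from CAR table: {missing[:5]}")
    X = car_table.loc[words].to_numpy(dtype=float)
    Y = np.stack([sw.voxels for sw in kept])
    return X, Y, words


def revise_corpus(
    sentences: Sequence[Sentence],
    car_table: pd.DataFrame,
    fmri_by_subject: Mapping[str, pd.DataFrame],
    train_config: TrainingConfig | None = None,
    fgrep_config: FgrepConfig | None = None,
    n_runs: int = 20,
    base_seed: int | None = None,
    output_activation: str = "logistic",
) -> pd.DataFrame:
    """Train + revise ``n_runs`` times per subject and average the runs.

    Each run trains the network from a fresh seed and revises every sentence
    with FGREP from that same run's network; the revised CAR reported per
    (subject, sentence, token) is the mean over runs. Subjects are processed
    independently. Returns a tidy frame with one row per token and columns
    subject, sentence_id, position, role, word, the 66 attributes,
    termination (modal across runs) and n_runs.
    """
    train_config = train_config or TrainingConfig()
    fgrep_config = fgrep_config or FgrepConfig()
    if base_seed is None:
        base_seed = train_config.seed
    records = []
    for subject, fmri in fmri_by_subject.items():
        X, Y, _ = training_pairs(sentences, car_table, fmri, subject=subject)
        terminations: dict[tuple, list[str]] = {}
        accum: dict[tuple, np.ndarray] = {}
        for run in range(n_runs):
            cfg = TrainingConfig(
                eta_init=train_config.eta_init,
                eta_floor=train_config.eta_floor,
                eta_decay=train_config.eta_decay,
                momentum=train_config.momentum,
                max_epochs=train_config.max_epochs,
                target_mse=train_config.target_mse,
                seed=base_seed + run,
                shuffle=train_config.shuffle,
            )
            params, _ = train(X, Y, cfg, output_activation=output_activation)
            for s in sentences:
                cars = car_table.loc[s.words].to_numpy(dtype=float)
                observed = fmri.loc[s.id].to_numpy(dtype=float)
                revised, term, _, _ = fgrep_sentence(
                    params, cars, observed, fgrep_config, output_activation
                )
                for pos, token in enumerate(s.tokens):
                    key = (s.id, pos)
                    accum[key] = accum.get(key, 0.0) + revised[pos]
                    terminations.setdefault(key, []).append(term)
        for s in sentences:
            for pos, token in enumerate(s.tokens):
                key = (s.id, pos)
                mean_rev = np.asarray(accum[key]) / n_runs
                terms = terminations[key]
                modal = max(set(terms), key=terms.count)
                rec = {
                    "subject": subject, "sentence_id": s.id, "position": pos,
                    "role": token.role, "word": token.word,
                    "termination": modal, "n_runs": n_runs,
                }
                rec.update(dict(zip(ATTRIBUTES, mean_rev)))
                records.append(rec)
    cols = ["subject", "sentence_id", "position", "role", "word",
            *ATTRIBUTES, "termination", "n_runs"]
    return pd.DataFrame.from_records(records)[cols]


def save_revised(revised: pd.DataFrame, path, sep: str = ",") -> None:
    revised.to_csv(path, sep=sep, index=False, float_format="%.6f")


def load_revised(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
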