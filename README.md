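# cerebra

Context-dependent word meanings from sentence fMRI.

Words mean different things in different sentences — *hurricane* in "The
hurricane destroyed the building" picks up destructive-event features it
does not carry in isolation. This package implements CEREBRA, a
neural-network analysis that makes that intuition measurable in brain data:

1. Each word starts as a 66-dimensional **CAR vector** (Concept Attribute
   Ratings: nonnegative, unit-norm semantic features such as *Vision*,
   *Loud*, *Dangerous*), aggregated from human 0–6 ratings with outlier
   rejection.
2. A small feed-forward network (66–66–396, logistic units, online SGD with
   momentum) learns to map each word's CAR to its **SynthWord** — the mean
   fMRI pattern of the sentences containing that word.
3. With the weights frozen, the error between a sentence's predicted
   pattern and its observed fMRI is **backpropagated to the word inputs**
   (FGREP). The words of the sentence move jointly, clamped to [0, 1],
   until the sentence error is near zero or cannot be reduced further. The
   moved inputs are the **context-revised CARs**: what the words mean *in
   that sentence*, according to the subject's brain.
4. The revised vectors are analyzed three ways: a **linear-regression
   baseline** (OLS voxel prediction with a closed-form minimum-norm
   inversion), **aggregation statistics** (Ward clustering of sentence
   representations, per-dimension t-tests, and correlations with the Other
   Words in the Sentence — OWS), and a **behavioral comparison** in which
   decision boundaries on the model's relative change scores are fitted to
   human more/same/less judgements and compared against a fitted chance
   model.

The original study's fMRI and survey data are restricted, so a seeded
**synthetic generator** (`cerebra.synthetic`) emulates the whole study with
explicit ground truth: planted context shifts of strength λ, a frozen
nonlinear CAR→voxel map per subject, noisy repetition-averaged voxels, and
simulated raters. Published survey summary counts ship as integer tables
(`cerebra.survey_tables`) for the exact-arithmetic analyses.

See [docs/methods.md](docs/methods.md) for models, parameters, numerical
choices, and the generator's known limitations — including why two
end-to-end recovery criteria fail honestly on synthetic data.

## Worked example

```python
import numpy as np
from cerebra import (
    FgrepConfig, SynthesisConfig, TrainingConfig, make_dataset, revise_corpus,
)
from cerebra.evaluation import ows_gap, shift_recovery

# A small synthetic study: 12 words, 8 sentences, one subject.
config = SynthesisConfig(n_words=12, n_sentences=8, n_voxels=50,
                         n_subjects=1, n_repetitions=4, hidden_dim=24,
                         lam=0.3, seed=0)
data = make_dataset(config)
print(f"{len(data.lexicon)} words, {len(data.sentences)} sentences, "
      f"{data.fmri['S0'].shape[1]} voxels")
print("example sentence:", data.sentences[0].text)

# Train the CAR -> voxel network and backpropagate sentence error to the
# word inputs (FGREP), giving one revised CAR per word token.
revised = revise_corpus(
    data.sentences, data.lexicon, data.fmri,
    train_config=TrainingConfig(max_epochs=800, target_mse=1e-4, seed=0),
    fgrep_config=FgrepConfig(max_iters=1500, epsilon=1e-4),
    n_runs=1, base_seed=0,
)
print(f"revised {len(revised)} word tokens "
      f"({revised['termination'].value_counts().to_dict()})")

# Does revision move tokens toward the other words in their sentence?
gap = ows_gap(data, revised)
print(f"OWS correlation: revised {gap['mean_r_revised']:+.3f} vs "
      f"original {gap['mean_r_original']:+.3f} (gap {gap['gap']:+.3f})")

# How well do the changes recover the planted context shifts?
mean_r, n = shift_recovery(data, revised)
print(f"planted-shift recovery: mean r = {mean_r:+.3f} over {n} tokens")
```

Output (about 15 seconds on one CPU):

```text
12 words, 8 sentences, 50 voxels
example sentence: The agent03 verb03
revised 24 word tokens ({'converged': 14, 'max_iters': 10})
OWS correlation: revised +0.693 vs original -0.081 (gap +0.774)
planted-shift recovery: mean r = +0.146 over 24 tokens
```

The two printed numbers illustrate both sides of the scientific story:
revision strongly increases within-sentence similarity (the OWS gap), but
the recovery of the *planted* shifts is weak — a structural property of
training on word-level mean targets, analyzed in
[docs/methods.md](docs/methods.md) under "Known limitations".

## Command line

The `cerebra` entry point wraps every stage; `cerebra pipeline` chains
them end to end and writes a digest manifest:

```bash
cerebra pipeline --seed 0 --out run0          # simulate ... behavior
cerebra simulate --seed 1 --out sim1          # synthetic dataset only
cerebra train --cars sim1/cars.csv --fmri sim1/fmri_S0.csv \
              --sentences sim1/sentences.tsv --out model.npz
cerebra validate --sentences sim1/sentences.tsv
cerebra report --run-dir run0
```

## Reproduction

Everything is deterministic given the seed.

```bash
# 1. Editable install (offline-friendly)
pip install --no-build-isolation --no-deps -e .

# 2. Test suite (about 10 minutes; two end-to-end acceptance tests fail
#    honestly on synthetic data — see docs/methods.md, "Known limitations")
python -m pytest -o addopts= -p no:cacheprovider -q tests/

# 3. Headline quantities, regenerated from scratch (about 5 minutes)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` writes `{"name": {"value": ..., "n": ...}}` for the
survey arithmetic (68/45% chance rates, 18/55% consensus shares, 47%
pairwise agreement), the gradient and pseudoinverse oracles, linear-model
exactness, the 10-seed planted-shift recovery and λ = 0 null experiments,
and the 20-seed behavioral surrogate.

## Layout

- `src/cerebra/` — the library: `attributes`, `car_ratings`, `corpus`,
  `network`, `fgrep`, `lreg`, `aggregation`, `behavior`, `synthetic`,
  `survey_tables`, `evaluation`, `pipeline`, `cli`
- `scripts/acceptance.py` — regenerates the headline quantities
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — models, parameters, limitations
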