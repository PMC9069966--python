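"""Configuration, validation, and the end-to-end pipeline runner.

The pipeline chains simulate -> ratings -> train -> interpret -> lreg ->
aggregate -> behavior into one seeded, reproducible run that writes its
artifacts plus a manifest (stage, input/output digests, seed, wall time).
All randomness flows from the declared seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, behavior, car_ratings, corpus, fgrep, lreg, synthetic
from .attributes import ATTRIBUTES
from .network import TrainingConfig


@dataclass
class RunConfig:
    out_dir: str = "cerebra_run"
    seed: int = 0
    n_runs: int = 1
    k_clusters: int = 30
    approach: int = 1
    two_boundary: bool = False
    synthesis: synthetic.SynthesisConfig = field(
        default_factory=synthetic.SynthesisConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    fgrep: fgrep.FgrepConfig = field(default_factory=fgrep.FgrepConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: v for k, v in raw.items()
                  if k in ("out_dir", "seed", "n_runs", "k_clusters",
                           "approach", "two_boundary")}
        cfg = cls(**kwargs)
        if "synthesis" in raw:
            cfg.synthesis = synthetic.SynthesisConfig(**raw["synthesis"])
        if "training" in raw:
            cfg.training = TrainingConfig(**raw["training"])
        if "fgrep" in raw:
            cfg.fgrep = fgrep.FgrepConfig(**raw["fgrep"])
        return cfg

    def digest(self) -> str:
        blob = json.dumps(
            {"out_dir": self.out_dir, "seed": self.seed,
             "n_runs": self.n_runs, "k_clusters": self.k_clusters,
             "approach": self.approach, "two_boundary": self.two_boundary,
             "synthesis": asdict(self.synthesis),
             "training": asdict(self.training),
             "fgrep": asdict(self.fgrep)},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


ALL_STAGES = ("simulate", "ratings", "train_interpret", "lreg", "aggregate",
              "behavior")


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "stages": []}
    state: dict = {}

    def record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"].append({
            "stage": stage,
            "outputs": {p.name: _file_digest(p) for p in outputs},
            "seed": config.seed,
            "wall_time_s": round(time.time() - t0, 3),
        })

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            cfg = synthetic.SynthesisConfig(
                **{**asdict(config.synthesis), "seed": config.seed})
            data = synthetic.make_dataset(cfg)
            state["data"] = data
            car_path = out / "cars.csv"
            car_ratings.save_car_table(data.lexicon, car_path)
            sent_path = out / "sentences.tsv"
            corpus.write_sentences(data.sentences, sent_path)
            fmri_paths = []
            for subject, frame in data.fmri.items():
                p = out / f"fmri_{subject}.csv"
                corpus.write_fmri(frame, p)
                fmri_paths.append(p)
            truth = pd.DataFrame.from_records([
                {"sentence_id": sid, "position": pos,
                 **dict(zip(ATTRIBUTES, vec))}
                for (sid, pos), vec in data.contextual.items()
            ])
            truth_path = out / "ground_truth_contextual.csv"
            truth.to_csv(truth_path, index=False, float_format="%.6f")
            record(stage, [car_path, sent_path, *fmri_paths, truth_path], t0)
        elif stage == "ratings":
            data = _require(state, "data", stage)
            table = synthetic.gen_rating_table(data.lexicon, data.config)
            coded = car_ratings.code_not_applicable(table)
            cars = car_ratings.build_car_table(coded)
            p = out / "cars_from_ratings.csv"
            car_ratings.save_car_table(cars, p)
            record(stage, [p], t0)
        elif stage == "train_interpret":
            data = _require(state, "data", stage)
            revised = fgrep.revise_corpus(
                data.sentences, data.lexicon, data.fmri,
                train_config=config.training, fgrep_config=config.fgrep,
                n_runs=config.n_runs, base_seed=config.seed,
            )
            state["revised"] = revised
            p = out / "revised_cars.csv"
            fgrep.save_revised(revised, p)
            record(stage, [p], t0)
        elif stage == "lreg":
            data = _require(state, "data", stage)
            rows = []
            for subject, fmri_frame in data.fmri.items():
                X, Y, _ = fgrep.training_pairs(
                    data.sentences, data.lexicon, fmri_frame, subject)
                model = lreg.fit_lreg(X, Y)
                for s in data.sentences:
                    cars = data.lexicon.loc[s.words].to_numpy(float)
                    observed = fmri_frame.loc[s.id].to_numpy(float)
                    revised, info = lreg.invert_lreg(model, cars, observed)
                    for pos, tok in enumerate(s.tokens):
                        rec = {"subject": subject, "sentence_id": s.id,
                               "position": pos, "role": tok.role,
                               "word": tok.word, "method": "lreg",
                               "exact": info["exact"]}
                        rec.update(dict(zip(ATTRIBUTES, revised[pos])))
                        rows.append(rec)
            frame = pd.DataFrame.from_records(rows)
            state["revised_lreg"] = frame
            p = out / "revised_cars_lreg.csv"
            frame.to_csv(p, index=False, float_format="%.6f")
            record(stage, [p], t0)
        elif stage == "aggregate":
            data = _require(state, "data", stage)
            revised = _require(state, "revised", stage)
            reports, clusters = [], {}
            for subject in data.fmri:
                sent_cars = aggregation.assemble_sentence_cars(revised, subject)
                clusters[subject] = aggregation.cluster_sentences(
                    sent_cars, k=config.k_clusters)
            changes = aggregation.dimension_change_tests(
                revised, data.lexicon,
                clusters=next(iter(clusters.values())))
            corr = aggregation.correlation_analysis(
                revised, data.lexicon, data.sentences, clusters=clusters)
            state["clusters"] = clusters
            p1 = out / "dimension_changes.csv"
            changes.to_csv(p1, index=False, float_format="%.6g")
            p2 = out / "ows_correlations.csv"
            corr.to_csv(p2, index=False, float_format="%.6g")
            summary = {
                "mean_r_original": float(corr["mean_r_original"].mean()),
                "mean_r_revised": float(corr["mean_r_revised"].mean()),
                "cluster_sizes": {
                    subject: pd.Series(list(cl.labels.values()))
                    .value_counts().to_dict()
                    for subject, cl in clusters.items()
                },
            }
            p3 = out / "aggregation_summary.json"
            p3.write_text(json.dumps(summary, indent=2, default=int))
            record(stage, [p1, p2, p3], t0)
        elif stage == "behavior":
            data = _require(state, "data", stage)
            revised = _require(state, "revised", stage)
            scores = behavior.change_scores(
                revised, data.lexicon, data.sentences,
                approach=config.approach)
            score_values = scores[list(ATTRIBUTES)].to_numpy(float).ravel()
            truth_frame = revised.copy()
            truth_frame[list(ATTRIBUTES)] = np.stack([
                data.contextual[(r.sentence_id, r.position)]
                for r in revised.itertuples()
            ])
            truth_scores = behavior.change_scores(
                truth_frame, data.lexicon, data.sentences,
                approach=config.approach)
            truth = truth_scores[list(ATTRIBUTES)].to_numpy(float).ravel()
            responses = synthetic.gen_raters(
                truth, data.config.flip_rate, n_raters=4, seed=config.seed)
            _, _, consensus = behavior.select_consensus_questions(
                responses, min_agree=3)
            idx = consensus.index.to_numpy()
            fit = behavior.fit_boundaries(
                score_values[idx], consensus.to_numpy(),
                two_boundary=config.two_boundary)
            labels = behavior.labels_from_scores(
                score_values[idx], fit.boundary_upper, fit.boundary_lower)
            rate, confusion = behavior.match_rate(labels, consensus.to_numpy())
            chance = behavior.chance_model(
                len(idx), (score_values.min(), score_values.max()),
                seed=config.seed)
            cfit = behavior.fit_boundaries(
                chance, consensus.to_numpy(),
                two_boundary=config.two_boundary)
            report = {
                "approach": config.approach,
                "boundary_upper": fit.boundary_upper,
                "boundary_lower": fit.boundary_lower,
                "match_rate_percent": rate,
                "chance_match_rate_percent": cfit.match_rate,
                "n_consensus_questions": int(len(idx)),
                "confusion": confusion.to_dict(),
            }
            p = out / "behavior_report.json"
            p.write_text(json.dumps(report, indent=2, default=int))
            record(stage, [p], t0)
        else:
            raise ValueError(f"unknown stage {stage!r}")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} needs upstream artifact {key!r}; "
            f"run the producing stage first"
        )
    return state[key]


def validate_inputs(paths: dict) -> list[dict]:
    """Machine-readable validation of input files; issues are data, not errors.

    ``paths`` may contain keys ``cars``, ``sentences``, ``fmri`` (a single
    path or list), ``ratings``. Checks dimensions (66 attributes, 396
    voxels), value ranges, and role vocabulary.
    """
    issues: list[dict] = []

    def issue(file, kind, detail):
        issues.append({"file": str(file), "kind": kind, "detail": detail})

    if "cars" in paths:
        try:
            cars = pd.read_csv(paths["cars"], index_col="word")
            if cars.shape[1] != len(ATTRIBUTES):
                issue(paths["cars"], "dimension",
                      f"expected 66 attribute columns, found {cars.shape[1]}")
            elif (cars.to_numpy(float) < 0).any():
                issue(paths["cars"], "range", "negative CAR values")
        except Exception as exc:  # malformed file is an issue, not a crash
            issue(paths["cars"], "parse", str(exc))
    if "sentences" in paths:
        try:
            sentences = corpus.read_sentences(paths["sentences"])
            for s in sentences:
                if not 2 <= len(s.tokens) <= 5:
                    issue(paths["sentences"], "token_count",
                          f"sentence {s.id} has {len(s.tokens)} tokens")
        except Exception as exc:
            issue(paths["sentences"], "parse", str(exc))
    fmri_paths = paths.get("fmri", [])
    if isinstance(fmri_paths, (str, Path)):
        fmri_paths = [fmri_paths]
    for p in fmri_paths:
        try:
            frame = corpus.read_fmri(p)
            if frame.shape[1] != corpus.N_VOXELS:
                issue(p, "dimension",
                      f"expected {corpus.N_VOXELS} voxels, found {frame.shape[1]}")
            values = frame.to_numpy(float)
            if values.min() < corpus.VOXEL_LO - 1e-9 or \
                    values.max() > corpus.VOXEL_HI + 1e-9:
                issue(p, "range", "voxel values outside [0.2, 0.8]")
        except Exception as exc:
            issue(p, "parse", str(exc))
    if "ratings" in paths:
        try:
            car_ratings.load_rating_table(paths["ratings"])
        except Exception as exc:
            issue(paths["ratings"], "range", str(exc))
    return issues
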