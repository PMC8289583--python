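"""End-to-end orchestration: data -> preprocess -> features -> model -> report.

A run is described by a :class:`RunConfig`; one seed drives the
generator, the train/test split and the boosted forests through
independently derived streams, so a single integer reproduces every
artifact.  The heavy lifting happens once in :func:`prepare_dataset`
(which extracts the full A–E feature superset); sweeps over feature
combinations or forest sizes then reuse the same features and split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from beatboost import __version__, ensemble, evaluate, features, io, preprocess, synth

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "RunConfig",
    "RunResult",
    "prepare_dataset",
    "run_pipeline",
    "sweep_combinations",
    "sweep_trees",
    "DEFAULT_TREE_GRID",
    "ALL_COMBINATIONS",
]

DEFAULT_TREE_GRID = (20, 30, 40, 50, 60, 70, 80, 90)

#: The 16 feature-set combinations of the experiment grid: all five
#: singletons, the six pairs containing B or C, the four triples and
#: the quadruple actually compared in the study design.
ALL_COMBINATIONS = (
    "A", "B", "C", "D", "E",
    "BC", "BD", "BE", "CD", "CE", "DE",
    "BCD", "BCE", "BDE", "CDE",
    "BCDE",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run."""

    source: str = "synthetic"  # "synthetic" | wfdb record path | feature CSV path
    active_sets: str = "BCDE"
    train_frac: float = 0.9
    seed: int = 0
    n_beats: int = 3000
    noise: synth.NoiseConfig = field(default_factory=synth.NoiseConfig)
    rounds: int = 10
    n_estimators: int = 70
    wavelet_level: int = 4
    use_detector: bool = False  # detect R peaks instead of annotations
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.active_sets:
            raise ValueError("active_sets must be nonempty")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class RunResult:
    report: evaluate.ClassMetricsReport
    train_idx: np.ndarray
    test_idx: np.ndarray
    matrix: features.FeatureMatrix
    model: ensemble.AdaBoostModel


def _derived_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {k: int(rng.integers(2**31 - 1)) for k in ("synth", "split", "model")}


def _load_record(config: RunConfig) -> io.ECGRecord:
    if config.source == "synthetic":
        sc = synth.SynthConfig(
            n_beats=config.n_beats,
            noise=config.noise,
            seed=_derived_seeds(config.seed)["synth"],
        )
        record, _ = synth.generate_record(sc)
        return record
    return io.read_wfdb(config.source)


def prepare_dataset(config: RunConfig) -> features.FeatureMatrix:
    """Generate/read a record and extract the full A–E feature superset.

    Beat labels and R positions come from the record's annotations
    (the reference positions), unless ``use_detector`` asks for the
    wavelet detector; fiducials always come from delineation of the
    denoised lead-A signal.
    """
    if config.source.endswith(".csv"):
        return features.FeatureMatrix.from_csv(config.source)
    try:
        record = _load_record(config)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        fs = record.sampling_rate
        lead_a = preprocess.denoise(record.lead(0), fs)
        lead_b = preprocess.denoise(record.lead(1), fs) if len(record.leads) > 1 else None
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    try:
        if config.use_detector:
            r_indices = preprocess.detect_r_peaks(lead_a, fs)
            ann = np.array([s for s, _ in record.annotations])
            ann_lab = [map_ for _, map_ in record.annotations]
            labels = []
            keep = []
            for r in r_indices:
                j = int(np.argmin(np.abs(ann - r))) if len(ann) else -1
                if j >= 0 and abs(int(ann[j]) - int(r)) <= int(0.05 * fs):
                    cls = io.map_to_aami(ann_lab[j])
                    if cls is not None:
                        keep.append(r)
                        labels.append(cls)
            r_indices = np.array(keep, dtype=int)
        else:
            pairs = [
                (s, io.map_to_aami(sym))
                for s, sym in sorted(record.annotations)
            ]
            pairs = [(s, c) for s, c in pairs if c is not None]
            r_indices = np.array([s for s, _ in pairs], dtype=int)
            labels = [c for _, c in pairs]

        signals = [lead_a] + ([lead_b] if lead_b is not None else [])
        beats = io.segment_beats(record, r_indices, labels, signals=signals)
        kept_r = np.array([b.r_sample for b in beats], dtype=int)
        fiducials = [preprocess.delineate(lead_a, int(r), fs) for r in kept_r]
        next_r = [int(kept_r[i + 1]) if i + 1 < len(kept_r) else None
                  for i in range(len(kept_r))]
    except Exception as exc:
        raise PipelineError("delineate", exc) from exc

    try:
        return features.assemble(
            beats,
            fiducials,
            "ABCDE" if lead_b is not None else "ACDE",
            sampling_rate=fs,
            next_r=next_r,
            signal=lead_a,
            wavelet_level=config.wavelet_level,
        )
    except Exception as exc:
        raise PipelineError("features", exc) from exc


def _train_eval(
    matrix: features.FeatureMatrix,
    active_sets: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model_cfg: ensemble.AdaBoostConfig,
) -> tuple[evaluate.ClassMetricsReport, ensemble.AdaBoostModel]:
    sub = matrix.subset(active_sets)
    model = ensemble.fit(sub.X[train_idx], sub.labels[train_idx], model_cfg)
    pred = ensemble.predict(model, sub.X[test_idx])
    cm = evaluate.confusion(sub.labels[test_idx], pred)
    return evaluate.metrics(cm), model


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) write artifacts."""
    seeds = _derived_seeds(config.seed)
    matrix = prepare_dataset(config)
    try:
        train_idx, test_idx = io.split_indices(
            matrix.labels, config.train_frac, seeds["split"]
        )
    except Exception as exc:
        raise PipelineError("split", exc) from exc
    model_cfg = ensemble.AdaBoostConfig(
        rounds=config.rounds, n_estimators=config.n_estimators, seed=seeds["model"]
    )
    try:
        report, model = _train_eval(
            matrix, config.active_sets, train_idx, test_idx, model_cfg
        )
    except Exception as exc:
        raise PipelineError("train", exc) from exc

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.subset(config.active_sets).to_csv(out / "features.csv")
        evaluate.report(report, out / "report")
        ensemble.save_model(model, out / "model.pkl")
        io.write_split_manifest(out / "split.json", config.seed, train_idx, test_idx)
        manifest = {
            "config": {
                **{k: v for k, v in dataclasses.asdict(config).items()
                   if k != "noise"},
                "noise": dataclasses.asdict(config.noise),
            },
            "derived_seeds": seeds,
            "version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return RunResult(
        report=report, train_idx=train_idx, test_idx=test_idx,
        matrix=matrix, model=model,
    )


def sweep_combinations(
    config: RunConfig,
    combo_list: tuple[str, ...] = ALL_COMBINATIONS,
) -> pd.DataFrame:
    """Accuracy per feature-set combination on a shared dataset + split."""
    seeds = _derived_seeds(config.seed)
    matrix = prepare_dataset(config)
    train_idx, test_idx = io.split_indices(
        matrix.labels, config.train_frac, seeds["split"]
    )
    model_cfg = ensemble.AdaBoostConfig(
        rounds=config.rounds, n_estimators=config.n_estimators, seed=seeds["model"]
    )
    rows = []
    for combo in combo_list:
        report, _ = _train_eval(matrix, combo, train_idx, test_idx, model_cfg)
        rows.append({"combination": combo, "accuracy_pct": report.overall_accuracy})
        logger.info("sets %-5s accuracy %.2f%%", combo, report.overall_accuracy)
    df = pd.DataFrame(rows)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep_sets.csv", index=False, float_format="%.2f")
    return df


def sweep_trees(
    config: RunConfig,
    tree_counts: tuple[int, ...] = DEFAULT_TREE_GRID,
) -> pd.DataFrame:
    """Accuracy per forest size, fixed data/split/feature combination."""
    if any(t < 1 for t in tree_counts):
        raise ValueError("tree counts must be positive")
    seeds = _derived_seeds(config.seed)
    matrix = prepare_dataset(config)
    train_idx, test_idx = io.split_indices(
        matrix.labels, config.train_frac, seeds["split"]
    )
    rows = []
    for n_trees in tree_counts:
        model_cfg = ensemble.AdaBoostConfig(
            rounds=config.rounds, n_estimators=n_trees, seed=seeds["model"]
        )
        report, _ = _train_eval(
            matrix, config.active_sets, train_idx, test_idx, model_cfg
        )
        rows.append({"n_estimators": n_trees, "accuracy_pct": report.overall_accuracy})
        logger.info("trees %3d accuracy %.2f%%", n_trees, report.overall_accuracy)
    df = pd.DataFrame(rows)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep_trees.csv", index=False, float_format="%.2f")
    return df
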