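"""Orchestration of the leakage-quantification study.

The core experiment runs the same preprocessing + nested-CV pipeline twice
per cohort and model — once with subject-level folds, once with
slice-level folds — and reports mean outer-fold train/test slice
accuracies together with the *inflation difference*: slice-level test
accuracy minus subject-level test accuracy.  On a cohort whose labels are
fully randomized (and carry no image signal), the subject-level arm is a
chance-level check (~50%) and the slice-level arm measures pure leakage.

Desk-scale presets mirror the small-cohort study condition: 34 subjects
(17 per class), 8 entropy-selected slices at 64x64, the small surrogate
CNN, fivefold outer CV and a reduced 2x2 hyperparameter grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .folds import SLICE_LEVEL, SUBJECT_LEVEL, FoldResult, HyperparameterGrid, nested_cv
from .models import ModelSpec, SmallCNNFactory, TrainConfig
from .preprocess import PreprocessConfig, preprocess_cohort
from .synthetic import SyntheticConfig, VolumeRecord, generate_cohort

__all__ = [
    "ExperimentRow",
    "ExperimentResult",
    "run_leakage_experiment",
    "random_label_experiment",
    "write_report",
    "desk_null_config",
    "desk_train_config",
    "desk_grid",
    "DESK_K",
    "DESK_INNER_K",
]

BOTH_STRATEGIES = (SUBJECT_LEVEL, SLICE_LEVEL)

# Desk-scale protocol constants: fivefold outer CV over 34 subjects, with a
# 2-fold inner loop and a 2x2 grid so a full two-strategy run stays in the
# minutes range on one CPU core.
DESK_K = 5
DESK_INNER_K = 2


def desk_null_config(seed: int = 0, slice_noise_sd: float = 0.2) -> SyntheticConfig:
    """Randomized-label null cohort at the small-cohort study size.

    34 subjects, no class effect, labels replaced by a random balanced
    permutation; ``slice_noise_sd`` defaults to 0.2 so same-subject slices
    stay near-duplicates, the regime in which slice-level splits leak
    hardest.  The balanced permutation (rather than coin flips) keeps the
    chance level at exactly 50%: with only 34 coin flips the majority
    class would average ~57%, and a classifier's prior would inflate the
    subject-level arm for a reason unrelated to leakage.
    """
    return SyntheticConfig(
        n_subjects_per_class=17,
        volume_shape=(12, 64, 64),
        template_smoothness=3.0,
        slice_noise_sd=slice_noise_sd,
        effect_size=0.0,
        randomize_labels=True,
        label_randomization="balanced_permutation",
        seed=seed,
    )


def desk_train_config() -> TrainConfig:
    """Reduced optimization budget for CPU runs of the surrogate CNN."""
    return TrainConfig(batch_size=32, epochs=16, learning_rate=1e-3, decay=0.0)


def desk_grid() -> HyperparameterGrid:
    return HyperparameterGrid.reduced()


@dataclass
class ExperimentRow:
    """One (cohort, model, strategy, seed) cell with its per-fold outcomes."""

    cohort_id: str
    model_family: str
    strategy: str
    seed: int
    fold_results: list[FoldResult]

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([r.train_accuracy for r in self.fold_results]))

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([r.test_accuracy for r in self.fold_results]))


@dataclass
class ExperimentResult:
    """All rows of a leakage experiment plus full provenance.

    ``provenance`` records every configuration and seed needed to
    recompute the numbers; ``summary()`` aggregates over seeds and folds,
    and ``differences()`` derives the leakage inflation per (cohort,
    model): slice-level minus subject-level mean test accuracy.
    """

    rows: list[ExperimentRow] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        records = [
            {
                "cohort_id": r.cohort_id,
                "model_family": r.model_family,
                "strategy": r.strategy,
                "seed": r.seed,
                "train_accuracy": r.mean_train_accuracy,
                "test_accuracy": r.mean_test_accuracy,
            }
            for r in self.rows
        ]
        frame = pd.DataFrame.from_records(records)
        return (
            frame.groupby(["cohort_id", "model_family", "strategy"], as_index=False)
            .agg(
                n_seeds=("seed", "nunique"),
                mean_train_accuracy=("train_accuracy", "mean"),
                mean_test_accuracy=("test_accuracy", "mean"),
            )
            .sort_values(["cohort_id", "model_family", "strategy"])
            .reset_index(drop=True)
        )

    def differences(self) -> pd.DataFrame:
        summary = self.summary()
        pivot = summary.pivot_table(
            index=["cohort_id", "model_family"],
            columns="strategy",
            values="mean_test_accuracy",
        )
        if SUBJECT_LEVEL not in pivot or SLICE_LEVEL not in pivot:
            return pd.DataFrame(
                columns=["cohort_id", "model_family", "difference"]
            )
        pivot = pivot.dropna(subset=[SUBJECT_LEVEL, SLICE_LEVEL])
        out = pivot.reset_index()[["cohort_id", "model_family"]]
        out["difference"] = (
            pivot[SLICE_LEVEL].to_numpy() - pivot[SUBJECT_LEVEL].to_numpy()
        )
        return out

    def mean_test_accuracy(self, strategy: str) -> float:
        """Pooled mean test accuracy for one strategy (mean of per-seed fold means)."""
        vals = [r.mean_test_accuracy for r in self.rows if r.strategy == strategy]
        if not vals:
            raise InputError(f"no rows with strategy {strategy!r}")
        return float(np.mean(vals))

    def test_slice_count(self, strategy: str) -> int:
        """Total number of test-slice evaluations behind one strategy's mean.

        Outer test folds partition the slices, so each replicate row
        contributes every preprocessed slice exactly once.
        """
        n_rows = sum(1 for r in self.rows if r.strategy == strategy)
        return n_rows * int(self.provenance.get("n_slices_per_run", 0))

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "provenance": self.provenance,
            "rows": [
                {
                    "cohort_id": r.cohort_id,
                    "model_family": r.model_family,
                    "strategy": r.strategy,
                    "seed": r.seed,
                    "fold_results": [asdict(fr) for fr in r.fold_results],
                }
                for r in self.rows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: Union[str, Path]) -> "ExperimentResult":
        payload = json.loads(Path(path).read_text())
        rows = [
            ExperimentRow(
                cohort_id=r["cohort_id"],
                model_family=r["model_family"],
                strategy=r["strategy"],
                seed=int(r["seed"]),
                fold_results=[FoldResult(**fr) for fr in r["fold_results"]],
            )
            for r in payload["rows"]
        ]
        return ExperimentResult(rows=rows, provenance=payload["provenance"])


ModelEntry = Union[ModelSpec, tuple[str, object]]


def _resolve_models(
    model_specs: Sequence[ModelEntry], train_config: TrainConfig
) -> list[tuple[str, object]]:
    resolved = []
    for entry in model_specs:
        if isinstance(entry, ModelSpec):
            resolved.append(
                (entry.family, SmallCNNFactory(spec=entry, base_config=train_config))
            )
        else:
            name, factory = entry
            resolved.append((name, factory))
    return resolved


def _derive_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0]
        % (2**31)
    )


def run_leakage_experiment(
    cohort: Sequence[VolumeRecord],
    model_specs: Sequence[ModelEntry],
    k: int = DESK_K,
    grid: Optional[HyperparameterGrid] = None,
    seeds: Sequence[int] = (0,),
    strategies: Sequence[str] = BOTH_STRATEGIES,
    preprocess_config: Optional[PreprocessConfig] = None,
    train_config: Optional[TrainConfig] = None,
    inner_k: Optional[int] = DESK_INNER_K,
    cohort_id: str = "cohort",
) -> ExperimentResult:
    """Run the two-strategy leakage experiment on one cohort.

    For every model and split strategy, the cohort is preprocessed (entropy
    slice selection, resize, per-image standardization) and pushed through
    nested CV; one row is produced per replicate seed (which controls fold
    dealing and weight initialization).  ``model_specs`` may mix
    :class:`ModelSpec` values with ``(name, factory)`` pairs for custom
    learners.
    """
    if len(model_specs) == 0:
        raise InputError("at least one model spec is required")
    grid = grid if grid is not None else desk_grid()
    preprocess_config = preprocess_config or PreprocessConfig()
    train_config = train_config or desk_train_config()
    slices = preprocess_cohort(cohort, preprocess_config)

    # normalize through JSON so stored and reloaded provenance compare equal
    result = ExperimentResult(
        provenance=json.loads(json.dumps({
            "cohort_id": cohort_id,
            "k": k,
            "inner_k": inner_k,
            "seeds": list(map(int, seeds)),
            "strategies": list(strategies),
            "grid": {
                "learning_rates": list(grid.learning_rates),
                "decays": list(grid.decays),
            },
            "preprocess": asdict(preprocess_config),
            "train": asdict(train_config),
            "n_subjects": len(cohort),
            "n_slices_per_run": len(slices),
        }))
    )
    for name, factory in _resolve_models(model_specs, train_config):
        for strategy in strategies:
            for seed in seeds:
                fold_results = nested_cv(
                    slices,
                    strategy,
                    k,
                    grid,
                    factory,
                    seed=_derive_seed(seed, 0 if strategy == SUBJECT_LEVEL else 1),
                    inner_k=inner_k,
                )
                result.rows.append(
                    ExperimentRow(
                        cohort_id=cohort_id,
                        model_family=name,
                        strategy=strategy,
                        seed=int(seed),
                        fold_results=fold_results,
                    )
                )
    return result


def random_label_experiment(
    config: SyntheticConfig,
    model_spec: ModelEntry = None,
    k: int = DESK_K,
    grid: Optional[HyperparameterGrid] = None,
    seeds: Sequence[int] = (0,),
    strategies: Sequence[str] = BOTH_STRATEGIES,
    preprocess_config: Optional[PreprocessConfig] = None,
    train_config: Optional[TrainConfig] = None,
    inner_k: Optional[int] = DESK_INNER_K,
) -> ExperimentResult:
    """Randomized-label control: both strategies on a null cohort.

    The config must describe a true null (``effect_size == 0`` and
    ``randomize_labels``); anything else is a configuration error, because
    the control's interpretation depends on the labels carrying no signal.
    A fresh cohort is generated per replicate seed, so the pooled means
    average over data, split and weight randomness.  Subject-level mean
    test accuracy is the chance-level check; slice-level is the leakage
    measurement.
    """
    if config.effect_size != 0:
        raise ConfigurationError(
            "the randomized-label control requires effect_size == 0"
        )
    if not config.randomize_labels:
        raise ConfigurationError(
            "the randomized-label control requires randomize_labels=True"
        )
    if model_spec is None:
        model_spec = ModelSpec.small_cnn()

    rows: list[ExperimentRow] = []
    merged: Optional[ExperimentResult] = None
    for seed in seeds:
        cohort = generate_cohort(replace(config, seed=_derive_seed(seed, 11)))
        part = run_leakage_experiment(
            cohort,
            [model_spec],
            k=k,
            grid=grid,
            seeds=(seed,),
            strategies=strategies,
            preprocess_config=preprocess_config,
            train_config=train_config,
            inner_k=inner_k,
            cohort_id="null-randomized",
        )
        rows.extend(part.rows)
        merged = part
    assert merged is not None
    merged.rows = rows
    merged.provenance["seeds"] = list(map(int, seeds))
    merged.provenance["synthetic"] = json.loads(json.dumps(asdict(config)))
    return merged


def write_report(result: ExperimentResult, path: Union[str, Path]) -> dict[str, Path]:
    """Write the tabular report: per-strategy means, inflation differences,
    and a JSON file with full per-fold detail and provenance."""
    if not result.rows:
        raise InputError("cannot report an empty experiment result")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "summary": path / "accuracy_by_strategy.csv",
        "differences": path / "leakage_inflation.csv",
        "detail": path / "experiment_detail.json",
    }
    result.summary().to_csv(files["summary"], index=False)
    result.differences().to_csv(files["differences"], index=False)
    result.to_json(files["detail"])
    return files
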