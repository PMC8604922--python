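"""Fold construction, leakage auditing, and nested cross-validation.

Two split strategies are contrasted:

* ``subject_level`` — whole subjects are dealt to folds, so all slices of
  one brain stay together.  This is the leakage-free design.
* ``slice_level`` — all slices of all subjects are pooled and dealt to
  folds individually.  Slices of one subject then appear in both training
  and test folds; because same-subject slices are highly correlated, a
  model can score a test slice by recognising its subject from training
  siblings.

``audit_leakage`` measures the exposure directly: for each test fold, the
fraction of its slices whose subject also has slices in the training side.
``nested_cv`` runs the full protocol — an outer k-fold loop for unbiased
performance estimation with an inner k-fold grid search over learning rate
and decay — applying the same split strategy at both levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np

from .errors import ConsistencyError, InputError, TrainingError
from .preprocess import SliceRecord

__all__ = [
    "SUBJECT_LEVEL",
    "SLICE_LEVEL",
    "FoldAssignment",
    "HyperparameterGrid",
    "FoldResult",
    "make_folds",
    "audit_leakage",
    "nested_cv",
    "ClassifierFactory",
]

SUBJECT_LEVEL = "subject_level"
SLICE_LEVEL = "slice_level"

Unit = object  # subject_id (str) or (subject_id, slice_index)


@dataclass(frozen=True)
class HyperparameterGrid:
    """Grid searched by the inner CV loop.

    Defaults are the full study grid: learning rates
    {1e-5, 3e-5, 1e-4, 3e-4, 1e-3} and learning-rate decays
    {0, 0.1, 0.3, 0.5}.  ``reduced()`` gives the 2x2 desk-scale grid,
    shifted one decade up because the from-scratch surrogate CNN needs
    larger Adam steps than grids tuned for fine-tuning pretrained nets.
    """

    learning_rates: tuple[float, ...] = (1e-5, 3e-5, 1e-4, 3e-4, 1e-3)
    decays: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5)

    def __post_init__(self) -> None:
        if not self.learning_rates or not self.decays:
            raise InputError("hyperparameter grid must be non-empty")
        if any(lr <= 0 or not np.isfinite(lr) for lr in self.learning_rates):
            raise InputError("learning rates must be positive and finite")
        if any(d < 0 or not np.isfinite(d) for d in self.decays):
            raise InputError("decays must be nonnegative and finite")

    def points(self) -> list[tuple[float, float]]:
        """All (learning_rate, decay) pairs in ascending (lr, decay) order."""
        return [
            (lr, d) for lr in sorted(self.learning_rates) for d in sorted(self.decays)
        ]

    @staticmethod
    def reduced() -> "HyperparameterGrid":
        return HyperparameterGrid(learning_rates=(1e-3, 1e-2), decays=(0.0, 0.3))


@dataclass
class FoldAssignment:
    """A k-fold partition of split units with its provenance.

    ``unit_to_fold`` maps each unit — a ``subject_id`` for subject-level
    splits, a ``(subject_id, slice_index)`` pair for slice-level splits —
    to its fold index in ``[0, k)``.
    """

    strategy: str
    k: int
    seed: int
    unit_to_fold: dict

    def fold_of(self, record: SliceRecord) -> int:
        unit = record.subject_id if self.strategy == SUBJECT_LEVEL else record.unit_id
        try:
            return self.unit_to_fold[unit]
        except KeyError:
            raise ConsistencyError(
                f"slice {record.unit_id} not covered by this fold assignment"
            ) from None

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.unit_to_fold.values():
            sizes[f] += 1
        return sizes

    def to_json(self, path: str | Path) -> None:
        table = [
            {"unit": list(u) if isinstance(u, tuple) else u, "fold": f}
            for u, f in sorted(self.unit_to_fold.items(), key=lambda kv: str(kv[0]))
        ]
        payload = {
            "strategy": self.strategy,
            "k": self.k,
            "seed": self.seed,
            "units": table,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "FoldAssignment":
        payload = json.loads(Path(path).read_text())
        unit_to_fold = {}
        for row in payload["units"]:
            unit = row["unit"]
            if isinstance(unit, list):
                unit = (unit[0], int(unit[1]))
            unit_to_fold[unit] = int(row["fold"])
        return FoldAssignment(
            strategy=payload["strategy"],
            k=int(payload["k"]),
            seed=int(payload["seed"]),
            unit_to_fold=unit_to_fold,
        )


@dataclass(frozen=True)
class FoldResult:
    """Outcome of one outer fold: chosen grid point and slice-level accuracies."""

    fold_index: int
    chosen_learning_rate: float
    chosen_decay: float
    train_accuracy: float
    test_accuracy: float


def _units_and_labels(
    slices: Sequence[SliceRecord], strategy: str
) -> tuple[list, list[int]]:
    if strategy == SUBJECT_LEVEL:
        seen: dict[str, int] = {}
        for s in slices:
            if s.subject_id in seen and seen[s.subject_id] != s.label:
                raise InputError(
                    f"subject {s.subject_id!r} carries inconsistent labels"
                )
            seen[s.subject_id] = s.label
        units = sorted(seen)
        return units, [seen[u] for u in units]
    if strategy == SLICE_LEVEL:
        units = sorted((s.unit_id for s in slices), key=lambda u: (u[0], u[1]))
        labels = {s.unit_id: s.label for s in slices}
        return list(units), [labels[u] for u in units]
    raise InputError(f"unknown split strategy {strategy!r}")


def make_folds(
    slices: Sequence[SliceRecord], strategy: str, k: int, seed: int
) -> FoldAssignment:
    """Deal split units into k folds, stratified by class.

    Units (subjects or pooled slices, depending on strategy) are shuffled
    within each class with a seeded RNG, concatenated class by class, and
    dealt round-robin to folds.  This keeps overall fold sizes within one
    unit of each other and per-fold class counts within one unit of the
    global proportion.  Deterministic given the seed.
    """
    if k < 2:
        raise InputError(f"k must be at least 2, got {k}")
    if len(slices) == 0:
        raise InputError("no slices to split")
    units, labels = _units_and_labels(slices, strategy)
    if len(units) < k:
        raise InputError(
            f"{len(units)} split units are fewer than k={k} folds"
        )
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise InputError("both classes must be present to build stratified folds")

    rng = np.random.default_rng(seed)
    deal_order: list = []
    for c in classes:
        members = [u for u, y in zip(units, labels) if y == c]
        rng.shuffle(members)
        deal_order.extend(members)
    unit_to_fold = {u: i % k for i, u in enumerate(deal_order)}
    return FoldAssignment(strategy=strategy, k=k, seed=seed, unit_to_fold=unit_to_fold)


def audit_leakage(
    assignment: FoldAssignment, slices: Sequence[SliceRecord]
) -> tuple[list[float], float]:
    """Fraction of test slices per fold whose subject leaks from training.

    For each fold ``f``, taken as the test fold, a slice counts as exposed
    when its subject owns at least one slice outside ``f`` (i.e. in that
    fold's training side).  Returns the per-fold fractions and their mean.
    Subject-level assignments audit to exactly 0 in every fold; slice-level
    assignments with several slices per subject audit to ~1.
    """
    folds_per_subject: dict[str, set[int]] = {}
    fold_of_slice: list[tuple[int, str]] = []
    for s in slices:
        f = assignment.fold_of(s)
        folds_per_subject.setdefault(s.subject_id, set()).add(f)
        fold_of_slice.append((f, s.subject_id))

    per_fold: list[float] = []
    for f in range(assignment.k):
        test = [subj for ff, subj in fold_of_slice if ff == f]
        if not test:
            per_fold.append(0.0)
            continue
        exposed = sum(1 for subj in test if folds_per_subject[subj] - {f})
        per_fold.append(exposed / len(test))
    return per_fold, float(np.mean(per_fold))


class SliceClassifier(Protocol):
    """Contract the CV engine requires of a classifier."""

    def fit(self, slices: Sequence[SliceRecord]) -> "SliceClassifier": ...

    def predict(self, slices: Sequence[SliceRecord]) -> np.ndarray: ...


class ClassifierFactory(Protocol):
    """Builds a fresh classifier for one (learning rate, decay, seed) triple."""

    def create(self, learning_rate: float, decay: float, seed: int) -> SliceClassifier: ...


def _accuracy(model: SliceClassifier, slices: Sequence[SliceRecord]) -> float:
    if len(slices) == 0:
        raise InputError("empty evaluation set")
    pred = np.asarray(model.predict(slices))
    truth = np.array([s.label for s in slices])
    return float((pred == truth).mean())


def _derive_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0] % (2**31))


def nested_cv(
    slices: Sequence[SliceRecord],
    strategy: str,
    k: int,
    grid: HyperparameterGrid,
    factory: ClassifierFactory,
    seed: int,
    inner_k: Optional[int] = None,
    standardizer_factory=None,
) -> list[FoldResult]:
    """Nested k-fold cross-validation with inner grid search.

    For each outer fold: the remaining ``k-1`` folds' slices are
    re-partitioned, with the same split strategy, into ``inner_k``
    (default ``k-1``) inner folds; every grid point is scored by its mean
    inner-validation slice accuracy; the best point (ties broken towards
    the lower learning rate, then the lower decay) is refit on the full
    outer-training data and evaluated on the held-out fold.  Slices of the
    outer test fold never reach the inner loop.

    ``standardizer_factory``, when given, must return an object with
    ``fit``/``transform`` (e.g. :class:`~sliceleak.preprocess.VoxelwiseStandardizer`);
    it is fitted on each training portion only and applied to both sides —
    the leakage-safe placement of dataset-level statistics.
    """
    assignment = make_folds(slices, strategy, k, seed)
    inner_k = (k - 1) if inner_k is None else inner_k
    if inner_k < 2:
        raise InputError(f"inner_k must be at least 2, got {inner_k}")
    grid_points = grid.points()

    slices = list(slices)
    outer_fold_of = [assignment.fold_of(s) for s in slices]
    results: list[FoldResult] = []
    for f in range(k):
        outer_train = [s for s, ff in zip(slices, outer_fold_of) if ff != f]
        outer_test = [s for s, ff in zip(slices, outer_fold_of) if ff == f]
        inner_assignment = make_folds(
            outer_train, strategy, inner_k, seed=_derive_seed(seed, f)
        )
        inner_fold_of = [inner_assignment.fold_of(s) for s in outer_train]

        scores: dict[tuple[float, float], float] = {}
        for lr, decay in grid_points:
            accs = []
            for g in range(inner_k):
                fit_set = [s for s, ff in zip(outer_train, inner_fold_of) if ff != g]
                val_set = [s for s, ff in zip(outer_train, inner_fold_of) if ff == g]
                fit_std, val_std = _maybe_standardize(
                    standardizer_factory, fit_set, val_set
                )
                model = factory.create(lr, decay, seed=_derive_seed(seed, f, 1))
                _fit_checked(model, fit_std, fold=f, grid_point=(lr, decay))
                accs.append(_accuracy(model, val_std))
            scores[(lr, decay)] = float(np.mean(accs))

        best = grid_points[0]
        for point in grid_points[1:]:  # points() is (lr, decay)-ascending: first max wins ties
            if scores[point] > scores[best]:
                best = point
        train_std, test_std = _maybe_standardize(
            standardizer_factory, outer_train, outer_test
        )
        model = factory.create(*best, seed=_derive_seed(seed, f, 2))
        _fit_checked(model, train_std, fold=f, grid_point=best)
        results.append(
            FoldResult(
                fold_index=f,
                chosen_learning_rate=best[0],
                chosen_decay=best[1],
                train_accuracy=_accuracy(model, train_std),
                test_accuracy=_accuracy(model, test_std),
            )
        )
    return results


def _maybe_standardize(standardizer_factory, train_set, eval_set):
    if standardizer_factory is None:
        return train_set, eval_set
    scaler = standardizer_factory().fit(train_set)
    return scaler.transform(train_set), scaler.transform(eval_set)


def _fit_checked(model, fit_set, fold: int, grid_point: tuple[float, float]) -> None:
    try:
        model.fit(fit_set)
    except TrainingError as exc:
        raise TrainingError(
            f"training failed in outer fold {fold} at grid point {grid_point}: {exc}"
        ) from exc
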