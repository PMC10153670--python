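"""Evaluation protocol: repeated k-fold cross-validation, accuracy /
generalization-gap summaries, and competition-rank aggregation of
test accuracies across datasets."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .data import Dataset
from .learning import LearningConfig
from .networks import TrainState, accuracy, train

__all__ = [
    "CVConfig",
    "CVResult",
    "cross_validate",
    "generalization_gap",
    "rank_approaches",
]


@dataclass(frozen=True)
class CVConfig:
    """Repeated k-fold protocol: ``repeats`` independent seeded splits."""

    folds: int = 5
    repeats: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.repeats < 1:
            raise ValueError("need at least 1 repeat")


@dataclass
class CVResult:
    """Mean (std) accuracies in percent over all repeats x folds."""

    train_acc: float
    train_std: float
    test_acc: float
    test_std: float
    mean_epochs: float
    per_fold_train: list = field(default_factory=list)
    per_fold_test: list = field(default_factory=list)
    histories: list = field(default_factory=list)

    def row(self) -> dict:
        return {
            "train_acc": self.train_acc, "train_std": self.train_std,
            "test_acc": self.test_acc, "test_std": self.test_std,
            "mean_epochs": self.mean_epochs,
        }


def cross_validate(build_model, ds: Dataset, cv: CVConfig = CVConfig(),
                   lcfg: LearningConfig = LearningConfig(),
                   state: TrainState = TrainState()) -> CVResult:
    """Repeated stratified k-fold CV of a model-builder callable.

    ``build_model(n_features, n_classes, rng)`` must return a fresh
    untrained model.  Each repeat draws a new seeded fold split; each fold
    trains on the remaining folds and evaluates on the held-out one.
    Accuracies are reported in percent, mean and std over repeats x folds.
    """
    rng = np.random.default_rng(cv.seed)
    tr_accs, te_accs, epochs, hists = [], [], [], []
    stratified = cv.stratified
    if stratified and np.bincount(ds.y).min() < cv.folds:
        warnings.warn("a class has fewer samples than folds; "
                      "falling back to unstratified folds", stacklevel=2)
        stratified = False
    for _ in range(cv.repeats):
        split_seed = int(rng.integers(2 ** 31))
        cls = StratifiedKFold if stratified else KFold
        splitter = cls(n_splits=cv.folds, shuffle=True,
                       random_state=split_seed)
        for tr_idx, te_idx in splitter.split(ds.X, ds.y):
            model = build_model(ds.n_features, ds.n_classes,
                                np.random.default_rng(int(rng.integers(2 ** 31))))
            st = TrainState(max_epoch=state.max_epoch, min_mse=state.min_mse,
                            shuffle=state.shuffle,
                            seed=int(rng.integers(2 ** 31)))
            hist = train(model, ds.X[tr_idx], ds.y[tr_idx], lcfg, st)
            tr_accs.append(100.0 * accuracy(ds.X[tr_idx], ds.y[tr_idx], model))
            te_accs.append(100.0 * accuracy(ds.X[te_idx], ds.y[te_idx], model))
            epochs.append(hist.epochs)
            hists.append(hist)
    return CVResult(
        train_acc=float(np.mean(tr_accs)), train_std=float(np.std(tr_accs)),
        test_acc=float(np.mean(te_accs)), test_std=float(np.std(te_accs)),
        mean_epochs=float(np.mean(epochs)),
        per_fold_train=tr_accs, per_fold_test=te_accs, histories=hists,
    )


def generalization_gap(train_acc: float, test_acc: float) -> float:
    """Training minus testing accuracy, in percentage points."""
    return train_acc - test_acc


def rank_approaches(test_acc: dict[str, dict[str, float]]):
    """Competition-rank approaches by test accuracy, per dataset and averaged.

    ``test_acc[dataset][approach]`` is a test accuracy in percent.  Within
    each dataset, approaches are ranked by descending accuracy with ties
    sharing the minimum rank (competition ranking).  Approaches missing
    from any dataset are excluded with a warning.  Returns
    ``(per_dataset_ranks, average_rank)`` keyed by approach name.
    """
    datasets = list(test_acc)
    if not datasets:
        raise ValueError("empty accuracy table")
    approaches = set(test_acc[datasets[0]])
    for d in datasets[1:]:
        approaches &= set(test_acc[d])
    dropped = set().union(*(set(test_acc[d]) for d in datasets)) - approaches
    if dropped:
        warnings.warn(f"approaches missing on some datasets excluded: "
                      f"{sorted(dropped)}", stacklevel=2)
    names = sorted(approaches)
    per_dataset: dict[str, dict[str, int]] = {}
    for d in datasets:
        accs = np.array([test_acc[d][a] for a in names])
        ranks = rankdata(-accs, method="min")
        per_dataset[d] = {a: int(r) for a, r in zip(names, ranks)}
    avg = {a: float(np.mean([per_dataset[d][a] for d in datasets]))
           for a in names}
    return per_dataset, avg
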