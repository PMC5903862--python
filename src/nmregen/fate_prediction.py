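"""Random-forest fate prediction with leave-one-experiment-out validation.

A bagged ensemble of decision trees is trained on the 32 predictors to
discriminate binary fate choices, at two levels: clone composition of a
sustentacular founder (SH vs SM, S vs SH, S vs SM) and division category of
a dividing sustentacular cell (HH vs SM/MM, SS vs HH, SS vs SM/MM; the two
mantle-producing categories are merged).  Validation is round-robin: with N
experiments the model is trained on N-1 and tested on the held-out one, for
each experiment in turn, so no cell ever contributes to both training and
test of a fold.

Row predictions are aggregated to the entity (clone or division) by
majority vote; exact ties count as incorrect.  Prediction quality is scored
with the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which compensates for class imbalance (e.g. 78% of divisions are SS);
whenever a factor of the denominator is zero the MCC is defined as 0.  The
spread of the score is estimated by resampling experiment-level test sets
with replacement (15 draws of 15 sets) and recomputing the pooled MCC.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .features import FEATURE_NAMES

__all__ = [
    "ConfusionMatrix",
    "mcc",
    "PredictionTask",
    "CLONE_TASKS",
    "DIVISION_TASKS",
    "TASKS",
    "ForestConfig",
    "train_forest",
    "round_robin_evaluate",
    "bootstrap_mcc",
    "feature_importance",
    "EvaluationReport",
]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 if undefined."""
    tp, tn, fp, fn = float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclasses.dataclass(frozen=True)
class PredictionTask:
    """A binary fate-choice task.

    ``positive`` / ``negative`` are the label sets mapped to class 1 / 0;
    rows with other labels are dropped.
    """

    name: str
    level: str  # "clone" or "division"
    positive: frozenset[str]
    negative: frozenset[str]

    def select(self, table: pd.DataFrame) -> pd.DataFrame:
        keep = table["label"].isin(self.positive | self.negative)
        out = table[keep].copy()
        out["y"] = out["label"].isin(self.positive).astype(int)
        return out


def _task(name: str, level: str, pos: Iterable[str], neg: Iterable[str]) -> PredictionTask:
    return PredictionTask(name, level, frozenset(pos), frozenset(neg))


CLONE_TASKS = {
    "SH-vs-SM": _task("SH-vs-SM", "clone", ["SH"], ["SM"]),
    "S-vs-SH": _task("S-vs-SH", "clone", ["S"], ["SH"]),
    "S-vs-SM": _task("S-vs-SM", "clone", ["S"], ["SM"]),
}
DIVISION_TASKS = {
    "HH-vs-SMMM": _task("HH-vs-SMMM", "division", ["HH"], ["SM", "MM"]),
    "SS-vs-HH": _task("SS-vs-HH", "division", ["SS"], ["HH"]),
    "SS-vs-SMMM": _task("SS-vs-SMMM", "division", ["SS"], ["SM", "MM"]),
}
TASKS = {**CLONE_TASKS, **DIVISION_TASKS}


@dataclasses.dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 200
    max_depth: int | None = None
    max_features: str | int | float = "sqrt"
    seed: int = 0
    bootstrap_replicates: int = 15
    bootstrap_sample_size: int | None = None  # default: number of experiments
    importance_repeats: int = 3


def train_forest(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    config: ForestConfig | None = None,
) -> RandomForestClassifier:
    """Fit the bagged-tree ensemble; reproducible for a fixed seed."""
    config = config or ForestConfig()
    if config.n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def feature_importance(
    model: RandomForestClassifier,
    X_val: np.ndarray | pd.DataFrame,
    y_val: np.ndarray,
    n_repeats: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance on held-out rows, ranked descending."""
    res = permutation_importance(
        model,
        np.asarray(X_val, dtype=float),
        np.asarray(y_val),
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    return pd.Series(res.importances_mean, index=FEATURE_NAMES).sort_values(
        ascending=False
    )


@dataclasses.dataclass
class EvaluationReport:
    """Round-robin evaluation result at the entity level."""

    task: PredictionTask
    entity_predictions: pd.DataFrame  # experiment_id, entity_id, y_true, y_pred, tie
    confusion: ConfusionMatrix
    mcc_pooled: float
    mcc_boot_mean: float
    mcc_boot_sd: float
    n_entities: int
    n_correct: int
    n_folds: int
    skipped_folds: list[str]
    importances: pd.Series | None

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_entities if self.n_entities else np.nan


def _vote(group: pd.DataFrame) -> tuple[int, int, bool]:
    votes = group["row_pred"].to_numpy(int)
    ones = int(votes.sum())
    zeros = votes.size - ones
    tie = ones == zeros
    pred = 1 if ones > zeros else 0
    return int(group["y"].iloc[0]), pred, tie


def round_robin_evaluate(
    feature_table: pd.DataFrame,
    task: PredictionTask,
    config: ForestConfig | None = None,
    compute_importance: bool = True,
) -> EvaluationReport:
    """Leave-one-experiment-out evaluation of one fate-choice task.

    ``feature_table`` is the output of
    :func:`nmregen.features.build_feature_table` for the task's level,
    covering all experiments.  Folds whose training data contain a single
    class are skipped with a warning and recorded in the report.
    """
    config = config or ForestConfig()
    rows = task.select(feature_table)
    exps = sorted(rows["experiment_id"].unique())
    if len(exps) < 3:
        raise ValueError(f"need >= 3 experiments with task rows, got {len(exps)}")

    ent_records = []
    skipped: list[str] = []
    importance_acc: list[pd.Series] = []
    for i, exp in enumerate(exps):
        train = rows[rows["experiment_id"] != exp]
        test = rows[rows["experiment_id"] == exp]
        assert not set(train["experiment_id"]) & set(test["experiment_id"])
        if train["y"].nunique() < 2:
            warnings.warn(f"fold {exp}: single-class training set, skipped")
            skipped.append(exp)
            continue
        if test.empty:
            continue
        model = train_forest(
            train[FEATURE_NAMES], train["y"].to_numpy(),
            dataclasses.replace(config, seed=config.seed + i),
        )
        test = test.copy()
        test["row_pred"] = model.predict(test[FEATURE_NAMES].to_numpy(float))
        if compute_importance and test["y"].nunique() == 2:
            importance_acc.append(
                feature_importance(
                    model,
                    test[FEATURE_NAMES],
                    test["y"].to_numpy(),
                    n_repeats=config.importance_repeats,
                    seed=config.seed + i,
                )
            )
        for entity, grp in test.groupby("entity_id", sort=True):
            y_true, y_pred, tie = _vote(grp)
            if tie:
                y_pred = 1 - y_true  # conservative: ties count as incorrect
            ent_records.append(
                {
                    "experiment_id": exp,
                    "entity_id": entity,
                    "y_true": y_true,
                    "y_pred": y_pred,
                    "tie": tie,
                }
            )

    ents = pd.DataFrame(ent_records)
    if ents.empty:
        raise ValueError("no fold produced predictions")
    confusion = _confusion_from_labels(ents["y_true"], ents["y_pred"])
    boot_mean, boot_sd = bootstrap_mcc(
        ents,
        n_replicates=config.bootstrap_replicates,
        sample_size=config.bootstrap_sample_size,
        seed=config.seed,
    )
    importances = None
    if importance_acc:
        importances = (
            pd.concat(importance_acc, axis=1).mean(axis=1).sort_values(ascending=False)
        )
    return EvaluationReport(
        task=task,
        entity_predictions=ents,
        confusion=confusion,
        mcc_pooled=mcc(confusion),
        mcc_boot_mean=boot_mean,
        mcc_boot_sd=boot_sd,
        n_entities=len(ents),
        n_correct=int((ents["y_true"] == ents["y_pred"]).sum()),
        n_folds=len(exps) - len(skipped),
        skipped_folds=skipped,
        importances=importances,
    )


def bootstrap_mcc(
    entity_predictions: pd.DataFrame,
    n_replicates: int = 15,
    sample_size: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of the MCC over resampled experiment-level test sets.

    Each replicate draws ``sample_size`` experiments (default: all of them)
    with replacement, pools their entity predictions and computes one MCC.
    Deterministic for a fixed seed.
    """
    if entity_predictions.empty:
        raise ValueError("no entity predictions to bootstrap")
    rng = np.random.default_rng(seed)
    exps = sorted(entity_predictions["experiment_id"].unique())
    k = sample_size if sample_size is not None else len(exps)
    groups = {e: g for e, g in entity_predictions.groupby("experiment_id")}
    scores = []
    for _ in range(n_replicates):
        chosen = rng.choice(exps, size=k, replace=True)
        pooled = pd.concat([groups[e] for e in chosen])
        cm = _confusion_from_labels(pooled["y_true"], pooled["y_pred"])
        scores.append(mcc(cm))
    scores = np.asarray(scores)
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    return float(scores.mean()), sd
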