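"""Training, cross-validation and the three-stage ion-channel cascade.

Backends are the standard estimators (RBF-kernel SVM a la LIBSVM, random
forest); this module owns what the estimators do not: the cascade decision
procedure, the leakage-free 10-fold cross-validation protocol, and the
Sn/OA/AA metrics computed on the pooled confusion matrix.

Metrics: per-class sensitivity Sn(i) = TP_i / (TP_i + FN_i), overall
accuracy OA = sum_i TP_i / N, and average accuracy AA = mean_i Sn(i), all
reported as percentages.

Cross-validation uses seeded stratified folds; min-max scaling and any MRMD
feature selection are refitted inside each training fold so no statistic of
the held-out part ever reaches the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from . import __version__
from .errors import ConfigurationError, InputDataError
from .features import encode_sequence, encoder_feature_names
from .seqio import LabeledDataset, ProteinSequence
from .skipgram import SkipGramConfig

logger = logging.getLogger(__name__)

BACKENDS = ("svm-rbf", "random-forest")

#: Coarse powers-of-two grids (steps of 2^2) spanning the LIBSVM-convention
#: ranges c in 2^-5..2^15 and g in 2^-15..2^3.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_G_GRID = tuple(2.0**e for e in range(-15, 4, 2))

MODEL_FORMAT_MAJOR = 0


# ---------------------------------------------------------------------------
# Confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise InputDataError(
                f"counts shape {self.counts.shape} does not match {n} classes"
            )
        if (self.counts < 0).any():
            raise InputDataError("confusion counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def _index(self, cls: int | str) -> int:
        return cls if isinstance(cls, int) else self.classes.index(cls)


def sensitivity(conf: ConfusionMatrix, cls: int | str) -> float:
    """Per-class sensitivity TP / (TP + FN) as a percentage.

    An empty true-class row has no defined sensitivity and returns NaN.
    """
    i = conf._index(cls)
    row_total = conf.counts[i].sum()
    if row_total == 0:
        logger.warning("class %s has no instances; sensitivity undefined", conf.classes[i])
        return float("nan")
    return float(conf.counts[i, i] / row_total * 100.0)


def overall_accuracy(conf: ConfusionMatrix) -> float:
    """Overall accuracy: trace / N as a percentage."""
    if conf.total == 0:
        raise InputDataError("empty confusion matrix")
    return float(np.trace(conf.counts) / conf.total * 100.0)


def average_accuracy(conf: ConfusionMatrix) -> float:
    """Mean per-class sensitivity (empty classes excluded with a warning)."""
    sns = [sensitivity(conf, i) for i in range(len(conf.classes))]
    sns = [s for s in sns if not np.isnan(s)]
    if not sns:
        raise InputDataError("no class has any instance")
    return float(np.mean(sns))


# ---------------------------------------------------------------------------
# Estimator construction and stage models


def _make_estimator(backend: str, params: Mapping, seed: int):
    if backend == "svm-rbf":
        return SVC(
            kernel="rbf",
            C=float(params.get("c", 1.0)),
            gamma=float(params.get("g", 1.0 / 8)),
            random_state=seed,
        )
    if backend == "random-forest":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_trees", 100)), random_state=seed
        )
    raise ConfigurationError(f"unknown backend {backend!r}; known: {BACKENDS}")


@dataclass
class StageModel:
    """One fitted cascade stage: scaler + optional selection + estimator.

    All preprocessing state was fitted on training data only and is captured
    for exact reapplication at predict time.
    """

    backend: str
    estimator: object
    scaler: MinMaxScaler
    feature_names: list[str]
    selected: list[str]
    classes: list[str]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def _prepare(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if list(features.columns) != self.feature_names:
                if set(features.columns) >= set(self.feature_names):
                    features = features[self.feature_names]
                else:
                    raise InputDataError(
                        f"feature mismatch: model expects {len(self.feature_names)} "
                        f"features, input has {features.shape[1]}"
                    )
            X = features.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
            if X.shape[1] != len(self.feature_names):
                raise InputDataError(
                    f"dimension mismatch: model expects {len(self.feature_names)} "
                    f"features, input has {X.shape[1]}"
                )
        X = self.scaler.transform(X)
        if self.selected != self.feature_names:
            idx = [self.feature_names.index(name) for name in self.selected]
            X = X[:, idx]
        return X

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._prepare(features))


def train_stage(
    features: pd.DataFrame,
    labels: Sequence[str],
    backend: str = "random-forest",
    params: Mapping | None = None,
    selection_m: int | None = None,
    seed: int = 0,
) -> StageModel:
    """Fit one stage: min-max scaling, optional MRMD selection, estimator."""
    params = dict(params or {})
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    for cls, count in zip(classes, counts):
        if count < 2:
            raise InputDataError(f"class {cls!r} has fewer than 2 training instances")
    feature_names = list(features.columns)
    scaler = MinMaxScaler().fit(features.to_numpy(dtype=float))
    X = scaler.transform(features.to_numpy(dtype=float))
    selected = feature_names
    if selection_m is not None:
        from .mrmd import select_subset

        scaled = pd.DataFrame(X, index=features.index, columns=feature_names)
        selected, _, _ = select_subset(scaled, list(y), m=selection_m, seed=seed)
        idx = [feature_names.index(name) for name in selected]
        X = X[:, idx]
    estimator = _make_estimator(backend, params, seed).fit(X, y)
    return StageModel(
        backend=backend,
        estimator=estimator,
        scaler=scaler,
        feature_names=feature_names,
        selected=list(selected),
        classes=list(classes),
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Pooled confusion matrix plus Sn/OA/AA and per-fold accuracies."""

    confusion: ConfusionMatrix
    fold_accuracies: list[float]

    @property
    def oa(self) -> float:
        return overall_accuracy(self.confusion)

    @property
    def aa(self) -> float:
        return average_accuracy(self.confusion)

    def sn(self) -> dict[str, float]:
        return {cls: sensitivity(self.confusion, cls) for cls in self.confusion.classes}


def _sorted_order(features: pd.DataFrame | np.ndarray, n: int) -> np.ndarray:
    # fold assignment is keyed on ids sorted lexicographically, so shuffling
    # instance order cannot change the pooled result
    if isinstance(features, pd.DataFrame):
        return np.argsort(features.index.astype(str).to_numpy(), kind="stable")
    return np.arange(n)


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    backend: str = "random-forest",
    params: Mapping | None = None,
    selection_m: int | None = None,
) -> CVResult:
    """Seeded stratified k-fold cross-validation with per-fold refitting.

    Scaling (and MRMD selection, if requested) is refitted on each training
    split; predictions on held-out folds are pooled into one confusion
    matrix from which Sn/OA/AA are computed.
    """
    if folds < 2:
        raise ConfigurationError(f"folds must be >= 2, got {folds}")
    y = np.asarray(list(labels))
    if len(y) != features.shape[0]:
        raise InputDataError("labels and feature rows differ in length")
    classes = sorted(np.unique(y))
    min_count = min(np.sum(y == c) for c in classes)
    if min_count < 2:
        raise InputDataError("every class needs at least 2 instances for CV")
    folds_eff = min(folds, int(min_count))
    if folds_eff < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, folds_eff)

    order = _sorted_order(features, len(y))
    feats = features.iloc[order] if isinstance(features, pd.DataFrame) else features[order]
    y_sorted = y[order]

    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    y_true_all: list[str] = []
    y_pred_all: list[str] = []
    fold_accs: list[float] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y_sorted)), y_sorted):
        model = train_stage(
            feats.iloc[train_idx],
            y_sorted[train_idx],
            backend=backend,
            params=params,
            selection_m=selection_m,
            seed=seed,
        )
        pred = model.predict(feats.iloc[test_idx])
        y_true_all.extend(y_sorted[test_idx])
        y_pred_all.extend(pred)
        fold_accs.append(float(np.mean(pred == y_sorted[test_idx]) * 100.0))
    counts = _sk_confusion(y_true_all, y_pred_all, labels=classes)
    return CVResult(ConfusionMatrix(counts, list(classes)), fold_accs)


def grid_search_svm(
    features: pd.DataFrame,
    labels: Sequence[str],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (c, g) grid search by cross-validated overall accuracy.

    The grid is scanned in ascending (c, g) order and only a strictly
    better OA replaces the incumbent, so ties resolve to the smallest c,
    then the smallest g.
    """
    if len(c_grid) == 0 or len(g_grid) == 0:
        raise ConfigurationError("empty (c, g) grid")
    best: tuple[float, float] | None = None
    best_oa = -np.inf
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            cv = cross_validate(
                features, labels, folds=folds, seed=seed,
                backend="svm-rbf", params={"c": c, "g": g},
            )
            oa = cv.oa
            if oa > best_oa:
                best_oa = oa
                best = (c, g)
    logger.info("grid search best (c, g) = %s with CV OA %.2f%%", best, best_oa)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# The three-stage cascade


#: Cascade stage names in decision order.
STAGES = ("ion", "gating", "subtype")

_VOLTAGE_SUBTYPES = ("K", "Ca", "Na", "anion")


@dataclass(frozen=True)
class StageConfig:
    """Feature and backend configuration of one cascade stage."""

    encoder: str = "ctd188"
    backend: str = "random-forest"
    params: tuple = ()
    selection_m: int | None = None
    skip_config: SkipGramConfig = SkipGramConfig()

    def params_dict(self) -> dict:
        return dict(self.params)


def stage_labels(six_class_labels: Sequence[str], stage: str) -> list[str | None]:
    """Map flat six-class labels to a stage's binary/4-way label (or None).

    ``None`` marks instances that the stage never sees (e.g. non-channels
    for the gating stage).
    """
    out: list[str | None] = []
    for label in six_class_labels:
        if stage == "ion":
            out.append("non-ion" if label == "non-ion" else "ion")
        elif stage == "gating":
            if label == "non-ion":
                out.append(None)
            else:
                out.append("voltage" if label in _VOLTAGE_SUBTYPES else "ligand")
        elif stage == "subtype":
            out.append(label if label in _VOLTAGE_SUBTYPES else None)
        else:
            raise ConfigurationError(f"unknown stage {stage!r}; known: {STAGES}")
    return out


@dataclass
class CascadeModel:
    """Three fitted stage models with their per-stage feature configuration."""

    stage1: StageModel
    stage2: StageModel
    stage3: StageModel
    configs: dict[str, StageConfig]
    package_version: str = __version__

    def stage_model(self, stage: str) -> StageModel:
        return {"ion": self.stage1, "gating": self.stage2, "subtype": self.stage3}[stage]

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_major": MODEL_FORMAT_MAJOR,
                "package_version": self.package_version,
                "model": self,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CascadeModel":
        payload = joblib.load(path)
        if payload.get("format_major") != MODEL_FORMAT_MAJOR:
            raise ConfigurationError(
                f"model bundle format {payload.get('format_major')} is incompatible "
                f"with this version (expects {MODEL_FORMAT_MAJOR})"
            )
        return payload["model"]


def train_cascade(
    dataset: LabeledDataset,
    configs: Mapping[str, StageConfig] | None = None,
    seed: int = 0,
) -> CascadeModel:
    """Train the three cascade stages from a flat six-class dataset.

    Each stage is trained only on the instances it would see at decision
    time: stage 1 on everything, stage 2 on channels, stage 3 on
    voltage-gated channels.
    """
    if dataset.scheme != "six":
        raise ConfigurationError("cascade training needs the flat six-class scheme")
    cfgs = {stage: StageConfig() for stage in STAGES}
    if configs:
        cfgs.update(configs)

    from .features import encode_dataset

    labels6 = dataset.labels
    models: dict[str, StageModel] = {}
    for stage in STAGES:
        cfg = cfgs[stage]
        ys = stage_labels(labels6, stage)
        keep = [i for i, y in enumerate(ys) if y is not None]
        seqs = [dataset.sequences[i] for i in keep]
        y = [ys[i] for i in keep]
        X = encode_dataset(seqs, cfg.encoder, cfg.skip_config)
        models[stage] = train_stage(
            X, y,
            backend=cfg.backend,
            params=cfg.params_dict(),
            selection_m=cfg.selection_m,
            seed=seed,
        )
    return CascadeModel(
        stage1=models["ion"],
        stage2=models["gating"],
        stage3=models["subtype"],
        configs=cfgs,
    )


def predict_cascade(
    item: ProteinSequence | pd.Series | Mapping[str, float],
    cascade: CascadeModel,
) -> tuple[str, list[tuple[str, str]]]:
    """Run the sequential decision procedure on one sequence.

    Returns the final label (one of non-ion, ligand, K, Ca, Na, anion) and
    the per-stage decision trail as (stage, decision) pairs.  Non-channels
    stop after stage 1; ligand-gated channels stop after stage 2.
    """

    def stage_features(stage: str):
        cfg = cascade.configs[stage]
        if isinstance(item, ProteinSequence):
            try:
                vec = encode_sequence(item, cfg.encoder, cfg.skip_config)
            except ValueError as exc:
                raise InputDataError(f"stage {stage!r}: {exc}") from exc
            return pd.DataFrame([vec], columns=list(encoder_feature_names(cfg.encoder)))
        if isinstance(item, pd.Series):
            return pd.DataFrame([item])
        return pd.DataFrame([dict(item)])

    trail: list[tuple[str, str]] = []
    decision = str(cascade.stage1.predict(stage_features("ion"))[0])
    trail.append(("ion", decision))
    if decision == "non-ion":
        return "non-ion", trail
    decision = str(cascade.stage2.predict(stage_features("gating"))[0])
    trail.append(("gating", decision))
    if decision == "ligand":
        return "ligand", trail
    decision = str(cascade.stage3.predict(stage_features("subtype"))[0])
    trail.append(("subtype", decision))
    return decision, trail
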