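"""Seeded training/evaluation orchestration.

Thin functional layer over :class:`~orchardvit.model.OAOMClassifier`:
directory-based training runs with history records, checkpoint
evaluation, stratified k-fold cross-validation, and the paired-seed
class-imbalance loss-comparison experiment.  Every run derives all of
its randomness from one integer seed, so a full
``generate_dataset -> train -> evaluate`` chain reproduces exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .losses import LOSS_KINDS, LossParams
from .metrics import ClassReport, confusion, report
from .model import OAOMClassifier, OAOMConfig
from .synthetic import DatasetDesign, default_class_specs, generate_dataset, load_dataset_arrays

__all__ = ["TrainConfig", "RunRecord", "train", "evaluate", "kfold_cv", "imbalance_experiment"]


@dataclass
class TrainConfig:
    """Training options.

    ``split`` is the overall (train, val, test) fraction triple; the
    generator emits train/test, so validation is carved out of the train
    split as ``val / (train + val)`` — (0.8, 0.1, 0.1) takes 1/9 of train.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    loss_kind: str = "mfce"
    loss_params: LossParams = field(default_factory=LossParams)
    seed: int = 0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    kfold: int | None = None

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def val_fraction_of_train(self) -> float:
        tr, va, _ = self.split
        return va / (tr + va) if va > 0 else 0.0


@dataclass
class RunRecord:
    """Everything one training run produced."""

    history: pd.DataFrame  # epoch, train_loss, train_acc[, val_loss, val_acc]
    test_report: ClassReport | None
    model_config: dict
    train_config: dict
    seed: int
    wall_seconds: float  # informational only
    class_names: list


def _make_estimator(model_config: OAOMConfig | dict, train_config: TrainConfig,
                    num_classes_hint: int | None = None) -> OAOMClassifier:
    if isinstance(model_config, OAOMConfig):
        cfg = model_config.to_dict()
    else:
        cfg = dict(model_config)
    declared = cfg.pop("num_classes", None)
    if declared is not None and num_classes_hint is not None and declared != num_classes_hint:
        raise ValueError(
            f"model config declares {declared} classes but the data has {num_classes_hint}"
        )
    cfg.pop("stride", None)
    lp = train_config.loss_params
    return OAOMClassifier(
        **cfg,
        loss_kind=train_config.loss_kind,
        gamma=lp.gamma,
        dv=lp.dv,
        learning_rate=train_config.learning_rate,
        batch_size=train_config.batch_size,
        epochs=train_config.epochs,
        validation_fraction=train_config.val_fraction_of_train,
        seed=train_config.seed,
    )


def _report_from_predictions(y_true, y_pred, class_names) -> ClassReport:
    cm = confusion(y_true, y_pred, m=len(class_names), labels=class_names)
    return report(cm)


def train(model_config, data_dir, train_config: TrainConfig,
          checkpoint_path=None) -> RunRecord:
    """Fit the classifier on a generated dataset directory.

    Trains on the ``train/`` split (with validation carved out per the
    config), evaluates on ``test/``, and optionally saves the fitted
    network.  Deterministic given ``train_config.seed``.
    """
    X_tr, y_tr, class_names = load_dataset_arrays(data_dir, "train")
    est = _make_estimator(model_config, train_config, num_classes_hint=len(class_names))
    t0 = time.perf_counter()
    est.fit(X_tr, y_tr)
    wall = time.perf_counter() - t0
    test_report = None
    try:
        X_te, y_te, te_names = load_dataset_arrays(data_dir, "test")
    except FileNotFoundError:
        X_te = None
    if X_te is not None:
        if te_names != class_names:
            raise ValueError(f"test split classes {te_names} differ from train {class_names}")
        y_pred = est.predict(X_te)
        test_report = _report_from_predictions(y_te, y_pred, class_names)
    if checkpoint_path is not None:
        est.save(checkpoint_path)
    record = RunRecord(
        history=pd.DataFrame(est.history_),
        test_report=test_report,
        model_config=est.config_.to_dict(),
        train_config={**asdict(train_config), "loss_params": asdict(train_config.loss_params)},
        seed=train_config.seed,
        wall_seconds=wall,
        class_names=list(class_names),
    )
    record.estimator = est  # convenience; not part of the dataclass contract
    return record


def evaluate(checkpoint, data_dir, split: str = "test") -> ClassReport:
    """Score a checkpoint (path or fitted estimator) on one dataset split."""
    est = checkpoint if isinstance(checkpoint, OAOMClassifier) else OAOMClassifier.load(checkpoint)
    X, y, class_names = load_dataset_arrays(data_dir, split)
    if len(class_names) != est.network_.config.num_classes:
        raise ValueError("checkpoint class count does not match the data")
    y_pred_labels = est.predict(X)
    # estimator classes_ may be labels; map predictions back to indices
    name_to_idx = {str(c): i for i, c in enumerate(class_names)}
    if set(map(str, est.classes_)) == set(name_to_idx):
        y_pred = np.array([name_to_idx[str(p)] for p in y_pred_labels])
    else:
        y_pred = np.asarray(y_pred_labels, dtype=int)
    return _report_from_predictions(y, y_pred, class_names)


def kfold_cv(model_config, data_dir, train_config: TrainConfig):
    """Stratified k-fold cross-validation over the pooled train+test images.

    Each sample lands in exactly one held-out fold; per-fold reports are
    averaged into a summary (mean and sd per metric).  Returns
    ``(records, summary_frame)``.
    """
    k = train_config.kfold
    if k is None or k < 2:
        raise ValueError("train_config.kfold must be an integer >= 2")
    X_tr, y_tr, class_names = load_dataset_arrays(data_dir, "train")
    try:
        X_te, y_te, _ = load_dataset_arrays(data_dir, "test")
        X = np.concatenate([X_tr, X_te])
        y = np.concatenate([y_tr, y_te])
    except FileNotFoundError:
        X, y = X_tr, y_tr
    counts = np.bincount(y, minlength=len(class_names))
    bad = [class_names[i] for i in np.nonzero(counts < k)[0]]
    if bad:
        raise ValueError(f"classes with fewer than k={k} samples: {bad}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=train_config.seed)
    records, rows = [], []
    for fold, (fit_idx, hold_idx) in enumerate(skf.split(X, y)):
        est = _make_estimator(model_config, train_config)
        est.set_params(seed=train_config.seed + fold, validation_fraction=0.0)
        est.fit(X[fit_idx], y[fit_idx])
        y_pred = est.predict(X[hold_idx])
        rep = _report_from_predictions(y[hold_idx], y_pred, class_names)
        records.append(RunRecord(
            history=pd.DataFrame(est.history_), test_report=rep,
            model_config=est.config_.to_dict(),
            train_config={**asdict(train_config), "loss_params": asdict(train_config.loss_params)},
            seed=train_config.seed + fold, wall_seconds=float("nan"),
            class_names=list(class_names),
        ))
        rows.append({
            "fold": fold, "accuracy": rep.accuracy,
            "macro_f1": rep.macro_avg["f1"], "weighted_f1": rep.weighted_avg["f1"],
        })
    frame = pd.DataFrame(rows)
    summary = frame.drop(columns="fold").agg(["mean", "std"])
    return records, summary


def imbalance_experiment(
    design: DatasetDesign,
    loss_kinds,
    seeds,
    data_dir=None,
    model_config: dict | OAOMConfig | None = None,
    train_config: TrainConfig | None = None,
    easy: bool = True,
    data_seed: int = 0,
) -> pd.DataFrame:
    """Paired-seed comparison of losses on an imbalanced design.

    One dataset is generated from ``design`` (shared by every run); for
    each (loss_kind, seed) pair a model is trained from the *same* seed —
    so initialisation is identical across loss kinds — and scored on the
    balanced test split.  Returns one row per run plus one ``seed="mean"``
    row per loss kind, with minority-class recall/F1, macro-F1 and
    accuracy.  The minority class is the one with the smallest training
    count.

    The default schedule (60 epochs) trains each run to convergence:
    shorter schedules sit mid-transition out of the all-majority plateau,
    where run-to-run variance swamps the loss comparison.
    """
    loss_kinds = list(loss_kinds)
    if len(loss_kinds) < 2:
        raise ValueError("need at least 2 loss kinds to compare")
    if min(design.per_class_train) == max(design.per_class_train):
        raise ValueError("design has no minority class")
    import tempfile

    tmp = None
    if data_dir is None:
        tmp = tempfile.TemporaryDirectory()
        data_dir = tmp.name
    data_dir = Path(data_dir)
    if not (data_dir / "train").exists():
        specs = default_class_specs(design, easy=easy)
        generate_dataset(design, specs, data_dir, master_seed=data_seed, overwrite=True)

    _, _, class_names = load_dataset_arrays(data_dir, "test")
    minority_label = design.classes[int(np.argmin(design.per_class_train))]

    base_tc = train_config or TrainConfig(epochs=60)
    rows = []
    try:
        for loss_kind in loss_kinds:
            for seed in seeds:
                tc = TrainConfig(**{**asdict(base_tc),
                                    "loss_params": base_tc.loss_params,
                                    "loss_kind": loss_kind, "seed": int(seed),
                                    "split": (sum(base_tc.split[:2]), 0.0, base_tc.split[2])})
                rec = train(model_config or {}, data_dir, tc)
                rep = rec.test_report
                mc = rep.per_class[str(minority_label)]
                rows.append({
                    "loss_kind": loss_kind, "seed": int(seed),
                    "minority_recall": mc["recall"], "minority_f1": mc["f1"],
                    "macro_f1": rep.macro_avg["f1"], "accuracy": rep.accuracy,
                })
    finally:
        if tmp is not None:
            tmp.cleanup()
    frame = pd.DataFrame(rows)
    means = (
        frame.groupby("loss_kind", sort=False)[["minority_recall", "minority_f1", "macro_f1", "accuracy"]]
        .mean()
        .reset_index()
    )
    means.insert(1, "seed", "mean")
    return pd.concat([frame, means], ignore_index=True)
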