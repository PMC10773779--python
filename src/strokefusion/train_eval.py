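"""Training protocol, classification metrics, cross-validation and the
four-arm ablation harness.

Metric definitions (positive class = poor prognosis):

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero-denominator metrics are reported as NaN and flagged, never silently
zeroed.  AUC uses the rank (Mann-Whitney) estimator with tie correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .metadata_encoder import fit_train_stats, vectorize_records
from .model import ArmFlags, PrognosisModel, build_model
from .nn import Adam, Tensor, softmax_cross_entropy
from .synthetic import CohortSample

__all__ = ["TrainConfig", "ConfusionCounts", "MetricReport", "Dataset",
           "confusion_counts", "compute_metrics", "roc_auc",
           "f1_from_precision_recall", "train", "evaluate",
           "patient_level_eval", "stratified_patient_folds",
           "cross_validate", "run_ablation", "prepare_dataset",
           "split_cohort"]


# ---------------------------------------------------------------------------
# configuration and data containers

@dataclass(frozen=True)
class TrainConfig:
    image_size: int = 224
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 0.001
    seed: int = 0
    profile: str = "paper"
    arms: ArmFlags = field(default_factory=ArmFlags)
    decision_threshold: float = 0.5

    def __post_init__(self):
        if min(self.image_size, self.batch_size, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


#: CPU-scale profile (reduced widths and epoch budget).
DESK_TRAIN = TrainConfig(image_size=64, epochs=30, profile="desk")


@dataclass
class Dataset:
    """Arrays ready for the model: replicated-channel images, encoded
    metadata, slice labels, patient ids."""

    images: np.ndarray            # (N, 3, H, W)
    meta: np.ndarray              # (N, Dm)
    labels: np.ndarray            # (N,)
    patient_ids: np.ndarray       # (N,) str
    masks: list | None = None     # per-slice lesion masks (synthetic only)

    def __len__(self):
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.images[idx], self.meta[idx], self.labels[idx],
                       self.patient_ids[idx],
                       [self.masks[i] for i in idx] if self.masks else None)


def prepare_dataset(samples: list[CohortSample],
                    train_samples: list[CohortSample] | None = None
                    ) -> Dataset:
    """Encode a cohort slice list into model-ready arrays.

    Continuous-field standardization uses statistics fitted on
    ``train_samples`` (defaults to ``samples`` itself, i.e. a training
    split).
    """
    stats_src = train_samples if train_samples is not None else samples
    by_pid = {}
    for s in stats_src:
        by_pid.setdefault(s.image.patient_id, s.metadata)
    stats = fit_train_stats(list(by_pid.values()))
    images = np.stack([np.repeat(s.image.pixels[None], 3, axis=0)
                       for s in samples])
    meta = vectorize_records([s.metadata for s in samples],
                             train_stats=stats)
    labels = np.array([s.label for s in samples], dtype=np.int64)
    pids = np.array([s.image.patient_id for s in samples])
    masks = [s.image.lesion_mask for s in samples]
    return Dataset(images, meta, labels, pids, masks)


def split_cohort(samples: list[CohortSample], test_fraction: float = 0.3,
                 seed: int = 0) -> tuple[list[CohortSample], list[CohortSample]]:
    """Patient-level stratified train/test split of a slice list."""
    by_pid: dict[str, int] = {}
    for s in samples:
        by_pid[s.image.patient_id] = s.label
    pids = np.array(sorted(by_pid))
    labels = np.array([by_pid[p] for p in pids])
    rng = np.random.default_rng(seed)
    test_pids: set[str] = set()
    for cls in (0, 1):
        cls_pids = pids[labels == cls]
        perm = rng.permutation(len(cls_pids))
        n_test = max(int(round(test_fraction * len(cls_pids))), 1)
        test_pids.update(cls_pids[perm[:n_test]])
    train = [s for s in samples if s.image.patient_id not in test_pids]
    test = [s for s in samples if s.image.patient_id in test_pids]
    return train, test


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally with positive class = 1 = poor prognosis."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()))


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float = math.nan
    undefined: tuple[str, ...] = ()
    per_fold: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "auc": self.auc}


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean; scale-free (works on fractions or percentages)."""
    if precision + recall == 0:
        return math.nan
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    precision = ratio(c.tp, c.tp + c.fp, "precision")
    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    if math.isnan(precision) or math.isnan(sensitivity) \
            or precision + sensitivity == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = f1_from_precision_recall(precision, sensitivity)
    return MetricReport(accuracy=(c.tp + c.tn) / c.total,
                        precision=precision, sensitivity=sensitivity,
                        specificity=specificity, f1=f1,
                        undefined=tuple(undefined))


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC with tie correction: the probability that
    a random positive outscores a random negative, ties counting 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# training

def _check_disjoint(train_pids, other_pids, other_name: str) -> None:
    overlap = sorted(set(train_pids) & set(other_pids))
    if overlap:
        raise ValueError(
            f"patient(s) {overlap} appear in both the training and "
            f"{other_name} splits")


def train(config: TrainConfig, train_set: Dataset,
          val_set: Dataset | None = None,
          model: PrognosisModel | None = None
          ) -> tuple[PrognosisModel, dict]:
    """Minimise cross-entropy with Adam for a fixed epoch budget.

    Deterministic given (config, seed). Returns the trained model and a
    history dict with per-epoch mean loss (and validation accuracy when
    a validation set is given).
    """
    if val_set is not None:
        _check_disjoint(train_set.patient_ids, val_set.patient_ids,
                        "validation")
    if model is None:
        model = build_model(config.profile, config.arms,
                            train_set.meta.shape[1], seed=config.seed,
                            image_size=config.image_size)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(train_set)
    history: dict = {"loss": [], "val_accuracy": []}
    needs_meta = model.flags.mlp
    for _ in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            if len(idx) < 2:
                continue        # BN needs batch statistics
            imgs = Tensor(train_set.images[idx])
            meta = Tensor(train_set.meta[idx]) if needs_meta else None
            logits = model(imgs, meta)
            loss = softmax_cross_entropy(logits, train_set.labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["loss"].append(float(np.mean(losses)))
        if val_set is not None:
            probs = model.predict_proba(
                val_set.images, val_set.meta if needs_meta else None)
            preds = (probs >= config.decision_threshold).astype(int)
            history["val_accuracy"].append(
                float((preds == val_set.labels).mean()))
    return model, history


def evaluate(model: PrognosisModel, dataset: Dataset,
             threshold: float = 0.5) -> tuple[MetricReport, np.ndarray]:
    """Slice-level metric report and per-slice scores."""
    meta = dataset.meta if model.flags.mlp else None
    probs = model.predict_proba(dataset.images, meta)
    preds = (probs >= threshold).astype(int)
    report = compute_metrics(confusion_counts(dataset.labels, preds))
    if len(set(dataset.labels.tolist())) == 2:
        report.auc = roc_auc(probs, dataset.labels)
    return report, probs


def patient_level_eval(model: PrognosisModel, dataset: Dataset,
                       threshold: float = 0.5
                       ) -> tuple[MetricReport, dict[str, float]]:
    """Aggregate slice probabilities to patient level by their mean."""
    meta = dataset.meta if model.flags.mlp else None
    probs = model.predict_proba(dataset.images, meta)
    by_pid: dict[str, list[float]] = {}
    pid_label: dict[str, int] = {}
    for pid, p, y in zip(dataset.patient_ids, probs, dataset.labels):
        by_pid.setdefault(pid, []).append(float(p))
        pid_label[pid] = int(y)
    pids = sorted(by_pid)
    pat_probs = {p: float(np.mean(by_pid[p])) for p in pids}
    y_true = np.array([pid_label[p] for p in pids])
    y_pred = np.array([int(pat_probs[p] >= threshold) for p in pids])
    report = compute_metrics(confusion_counts(y_true, y_pred))
    if len(set(y_true.tolist())) == 2:
        report.auc = roc_auc([pat_probs[p] for p in pids], y_true)
    return report, pat_probs


# ---------------------------------------------------------------------------
# cross-validation and ablation

def stratified_patient_folds(patient_ids, labels, k: int, seed: int
                             ) -> list[np.ndarray]:
    """Partition unique patients into k label-stratified folds.

    Depends only on (patient_ids, k, seed); returns per-fold arrays of
    patient ids.
    """
    pid_label: dict[str, int] = {}
    for pid, y in zip(patient_ids, labels):
        pid_label[str(pid)] = int(y)
    pids = np.array(sorted(pid_label))
    ys = np.array([pid_label[p] for p in pids])
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for cls in (0, 1):
        cls_pids = pids[ys == cls]
        if len(cls_pids) < k:
            raise ValueError(
                f"need at least {k} patients of class {cls} for {k}-fold "
                f"stratified cross-validation, got {len(cls_pids)}")
        perm = rng.permutation(len(cls_pids))
        for i, j in enumerate(perm):
            folds[i % k].append(cls_pids[j])
    return [np.array(sorted(f)) for f in folds]


def _fold_summary(per_fold: list[dict]) -> tuple[dict, dict]:
    keys = ("accuracy", "precision", "sensitivity", "specificity", "f1",
            "auc")
    mean, std = {}, {}
    for k in keys:
        vals = np.array([f[k] for f in per_fold], dtype=float)
        vals = vals[~np.isnan(vals)]
        mean[k] = float(vals.mean()) if vals.size else math.nan
        std[k] = float(vals.std()) if vals.size else math.nan
    return mean, std


def cross_validate(config: TrainConfig, cohort: list[CohortSample],
                   k: int = 5, seed: int = 0,
                   patient_level: bool = True) -> MetricReport:
    """k-fold patient-level stratified cross-validation; reports
    per-fold metrics and their mean +/- std."""
    pids = [s.image.patient_id for s in cohort]
    labels = [s.label for s in cohort]
    folds = stratified_patient_folds(pids, labels, k, seed)
    per_fold = []
    for fi, test_pids in enumerate(folds):
        test_set_pids = set(test_pids.tolist())
        tr = [s for s in cohort if s.image.patient_id not in test_set_pids]
        te = [s for s in cohort if s.image.patient_id in test_set_pids]
        train_ds = prepare_dataset(tr)
        test_ds = prepare_dataset(te, train_samples=tr)
        model, _ = train(config, train_ds)
        if patient_level:
            report, _ = patient_level_eval(model, test_ds,
                                           config.decision_threshold)
        else:
            report, _ = evaluate(model, test_ds, config.decision_threshold)
        per_fold.append(report.as_dict())
    mean, std = _fold_summary(per_fold)
    out = MetricReport(**{k_: mean[k_] for k_ in
                          ("accuracy", "precision", "sensitivity",
                           "specificity", "f1")}, auc=mean["auc"])
    out.per_fold, out.mean, out.std = per_fold, mean, std
    return out


ABLATION_ARMS = (1, 2, 3, 4)


def run_ablation(cohort: list[CohortSample], base_config: TrainConfig,
                 seeds: tuple[int, ...] = (0, 1, 2),
                 test_fraction: float = 0.3,
                 patient_level: bool = True,
                 arms: tuple[int, ...] = ABLATION_ARMS,
                 return_models: bool = False):
    """Train/evaluate the nested arm configurations on identical splits
    and seeds; one row per arm with mean +/- std over seeds.

    With ``return_models`` the trained models are returned as a second
    value keyed by (arm, seed)."""
    rows = []
    models: dict[tuple[int, int], PrognosisModel] = {}
    for arm in arms:
        per_seed = []
        for seed in seeds:
            tr, te = split_cohort(cohort, test_fraction, seed=seed)
            train_ds = prepare_dataset(tr)
            test_ds = prepare_dataset(te, train_samples=tr)
            cfg = TrainConfig(
                image_size=base_config.image_size,
                batch_size=base_config.batch_size,
                epochs=base_config.epochs,
                learning_rate=base_config.learning_rate,
                seed=seed, profile=base_config.profile,
                arms=ArmFlags.for_arm(arm),
                decision_threshold=base_config.decision_threshold)
            model, _ = train(cfg, train_ds)
            models[(arm, seed)] = model
            if patient_level:
                report, _ = patient_level_eval(model, test_ds)
            else:
                report, _ = evaluate(model, test_ds)
            per_seed.append(report.as_dict())
        mean, std = _fold_summary(per_seed)
        flags = ArmFlags.for_arm(arm)
        rows.append({"arm": arm, "ms": flags.ms, "glam": flags.glam,
                     "mlp": flags.mlp, "mean": mean, "std": std,
                     "per_seed": per_seed,
                     "n_parameters": models[(arm, seeds[0])].n_parameters()})
    if return_models:
        return rows, models
    return rows
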