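"""Training loop, K-fold cross-validation, metrics and model comparison.

Training uses Adam with categorical cross-entropy (150 epochs, batch 32 by
default, matching the architecture's published regimen). Evaluation derives
accuracy, macro/micro precision, recall and F1 from the confusion matrix;
macro averages exclude classes absent from the evaluated data (their
precision/recall is undefined rather than zero). Cross-validation is
stratified 5-fold by default. Model comparison follows the normality-then-
paired-t protocol: a Shapiro-Wilk test on the paired differences, then a
paired t-test, with the t-test explicitly flagged unreliable when normality
is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .model import MultiStreamModel, build_msacnn_rm
from .nn.losses import softmax, softmax_cross_entropy
from .nn.optim import Adam
from .preprocess import WindowedDataset, triplicate_inputs


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    track_best: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    micro: dict = field(default_factory=dict)
    per_class: dict = field(default_factory=dict)
    per_fold: list | None = None
    std_range: tuple | None = None

    @classmethod
    def from_confusion(cls, confusion) -> "EvalReport":
        cm = np.asarray(confusion, dtype=float)
        total = cm.sum()
        if total <= 0:
            raise ValueError("empty confusion matrix")
        tp = np.diag(cm)
        row = cm.sum(axis=1)  # true-class counts
        col = cm.sum(axis=0)  # predicted-class counts
        accuracy = tp.sum() / total
        present = row > 0  # classes absent from the data are excluded from macro
        with np.errstate(divide="ignore", invalid="ignore"):
            prec_c = np.where(col > 0, tp / np.maximum(col, 1e-300), np.nan)
            rec_c = np.where(row > 0, tp / np.maximum(row, 1e-300), np.nan)
            f1_c = np.where(
                np.nan_to_num(prec_c) + np.nan_to_num(rec_c) > 0,
                2 * np.nan_to_num(prec_c) * np.nan_to_num(rec_c)
                / (np.nan_to_num(prec_c) + np.nan_to_num(rec_c)), 0.0)
        macro_prec = float(np.nanmean(np.where(present, prec_c, np.nan)))
        macro_rec = float(np.nanmean(np.where(present, rec_c, np.nan)))
        macro_f1 = float(np.mean(f1_c[present]))
        micro = {
            # single-label micro precision == micro recall == accuracy
            "precision": float(accuracy),
            "recall": float(accuracy),
            "f1": float(accuracy),
        }
        return cls(
            accuracy=float(accuracy), precision=macro_prec, recall=macro_rec,
            f1=macro_f1, confusion=np.asarray(confusion), micro=micro,
            per_class={"precision": prec_c, "recall": rec_c, "f1": f1_c})

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _check_label_width(model: MultiStreamModel, ds: WindowedDataset):
    if ds.onehot_labels.shape[1] != model.cfg.num_classes:
        raise ValueError(
            f"label width {ds.onehot_labels.shape[1]} != model output width "
            f"{model.cfg.num_classes}")


def _accuracy(model, x, y_onehot):
    pred = model.predict(x)
    return float(np.mean(pred == y_onehot.argmax(axis=1)))


def train(model: MultiStreamModel, train_ds: WindowedDataset,
          val_ds: WindowedDataset | None, cfg: TrainConfig):
    """Train in place; returns a per-epoch history dict.

    The three streams receive identical copies of every batch. With
    ``track_best`` and a validation set, the parameters of the best
    validation-accuracy epoch are restored at the end and the winning epoch
    index is recorded in ``history["best_epoch"]``.
    """
    _check_label_width(model, train_ds)
    if val_ds is not None:
        _check_label_width(model, val_ds)
    rng = np.random.default_rng(cfg.seed)
    for leaf in model.leaves():
        if hasattr(leaf, "rate"):  # reseed dropout for reproducible runs
            leaf.rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.leaves(), lr=cfg.learning_rate)
    x_all = train_ds.windows
    y_all = train_ds.onehot_labels
    n = x_all.shape[0]
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_weights, best_epoch = -np.inf, None, -1
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            views = (xb.copy(), xb.copy(), xb.copy())
            logits = model.forward(views, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb.argmax(axis=1)).sum())
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(hits / n)
        if val_ds is not None:
            vlogits = model.forward(triplicate_inputs(val_ds), train=False)
            vloss, _ = softmax_cross_entropy(vlogits, val_ds.onehot_labels)
            vacc = float(np.mean(vlogits.argmax(axis=1)
                                 == val_ds.class_ids))
            history["val_loss"].append(float(vloss))
            history["val_acc"].append(vacc)
            if cfg.track_best and vacc > best_acc:
                best_acc, best_epoch = vacc, epoch
                best_weights = model.get_weights()
    if cfg.track_best and best_weights is not None:
        model.set_weights(best_weights)
        history["best_epoch"] = best_epoch
    return history


def evaluate(model: MultiStreamModel, ds: WindowedDataset) -> EvalReport:
    """Predict by per-row argmax of the softmax output and score from the
    confusion matrix (rows = true class, columns = predicted)."""
    if ds.n == 0:
        raise ValueError("cannot evaluate on empty data")
    pred = model.predict(triplicate_inputs(ds))
    g = ds.onehot_labels.shape[1]
    cm = _sk_confusion(ds.class_ids, pred, labels=np.arange(g))
    return EvalReport.from_confusion(cm)


@dataclass
class FoldPlan:
    K: int
    fold_assignments: np.ndarray
    seed: int

    def __post_init__(self):
        sizes = np.bincount(self.fold_assignments, minlength=self.K)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


def make_fold_plan(class_ids, K: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment: each window lands in exactly one fold."""
    if K < 2:
        raise ValueError("K must be >= 2")
    y = np.asarray(class_ids)
    if len(y) < K:
        raise ValueError(f"need at least K={K} samples, got {len(y)}")
    counts = np.bincount(y)
    if counts[counts > 0].min() >= K:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        assignments = np.empty(len(y), dtype=int)
        for k, (_tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
            assignments[te] = k
    else:  # too few samples in some class for stratification
        perm = np.random.default_rng(seed).permutation(len(y))
        assignments = np.empty(len(y), dtype=int)
        assignments[perm] = np.arange(len(y)) % K
    return FoldPlan(K=K, fold_assignments=assignments, seed=seed)


def kfold_cv(ds: WindowedDataset, K: int, model_factory, cfg: TrainConfig,
             seed: int = 0) -> EvalReport:
    """K seeded train/test rounds; every window is tested exactly once.

    ``model_factory(fold_index)`` must return a fresh untrained model.
    Returns the pooled confusion-matrix report with ``per_fold`` metric
    dicts and ``std_range`` = (min, max) of the across-fold standard
    deviations of the four headline metrics.
    """
    plan = make_fold_plan(ds.class_ids, K=K, seed=seed)
    per_fold = []
    pooled = None
    for k in range(K):
        test_mask = plan.fold_assignments == k
        train_sub = ds.subset(~test_mask)
        test_sub = ds.subset(test_mask)
        model = model_factory(k)
        fold_cfg = TrainConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, seed=cfg.seed + k,
            track_best=False)
        train(model, train_sub, None, fold_cfg)
        rep = evaluate(model, test_sub)
        per_fold.append(rep.as_dict())
        pooled = rep.confusion if pooled is None else pooled + rep.confusion
    agg = EvalReport.from_confusion(pooled)
    metric_names = ("accuracy", "precision", "recall", "f1")
    means = {m: float(np.mean([f[m] for f in per_fold])) for m in metric_names}
    stds = [float(np.std([f[m] for f in per_fold], ddof=1)) for m in metric_names]
    agg.accuracy, agg.precision = means["accuracy"], means["precision"]
    agg.recall, agg.f1 = means["recall"], means["f1"]
    agg.per_fold = per_fold
    agg.std_range = (min(stds), max(stds))
    return agg


@dataclass
class ComparisonReport:
    n: int
    mean_diff: float
    shapiro_p: float | None
    t_stat: float | None
    t_p: float | None
    significant: bool
    normality_rejected: bool
    note: str


def paired_t(a, b):
    """Closed-form paired t-test: t = mean(d) / (sd(d) / sqrt(n)).

    Returns (t, two-sided p) with the p-value from the t distribution with
    n-1 degrees of freedom. A zero-variance nonzero difference yields
    t = +/-inf and p = 0.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def compare_models(acc_a, acc_b, alpha: float = 0.05) -> ComparisonReport:
    """Shapiro-Wilk normality check on the paired differences, then a paired
    t-test; the verdict is flagged unreliable if normality is rejected."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 paired folds")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return ComparisonReport(
                n=len(d), mean_diff=0.0, shapiro_p=None, t_stat=0.0, t_p=1.0,
                significant=False, normality_rejected=False,
                note="no difference: all paired values identical")
        t, p = paired_t(a, b)
        return ComparisonReport(
            n=len(d), mean_diff=float(d.mean()), shapiro_p=None,
            t_stat=t, t_p=p, significant=True, normality_rejected=False,
            note="degenerate: constant nonzero difference (zero variance)")
    shapiro_p = float(stats.shapiro(d).pvalue)
    t, p = paired_t(a, b)
    rejected = shapiro_p < alpha
    note = ("normality rejected: paired t-test unreliable" if rejected
            else "normality not rejected")
    return ComparisonReport(
        n=len(d), mean_diff=float(d.mean()), shapiro_p=shapiro_p,
        t_stat=t, t_p=p, significant=bool(p < alpha and not rejected),
        normality_rejected=rejected, note=note)


def save_report(report: EvalReport, out_dir, history: dict | None = None):
    """Write an EvalReport (and optional history) as JSON + CSV + heatmap."""
    import json
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(
        {**report.as_dict(), "micro": report.micro,
         "std_range": report.std_range}, indent=2))
    pd.DataFrame(report.confusion).to_csv(out / "confusion.csv", index=False)
    if history is not None:
        pd.DataFrame({k: v for k, v in history.items()
                      if isinstance(v, list)}).to_csv(
            out / "history.csv", index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion, cmap="viridis")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out / "confusion.png", dpi=120)
    plt.close(fig)
    return out


def run_ablation(ds: WindowedDataset, cfg_factory, train_cfg: TrainConfig,
                 test_ids=("test1", "test7"), seed: int = 0, K: int = 5):
    """Cross-validate several ablation variants on the same fold plan."""
    from .model import build_ablation_variant

    results = {}
    for tid in test_ids:
        results[tid] = kfold_cv(
            ds, K,
            lambda k, _tid=tid: build_ablation_variant(
                _tid, cfg_factory(), seed=seed + 100 * k),
            train_cfg, seed=seed)
    return results
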