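"""Training, evaluation and comparison protocol.

Within-subject evaluation is the default regime: each subject's windows are
randomly split 80/20 stratified by class (optionally grouped by trial so no
trial contributes windows to both sides), the model is trained for a fixed
number of epochs with Adam at lr 1e-3 (60 epochs for the 3-class n-back
task, 70 for word generation), and accuracy / precision / recall / F1 are
computed from the confusion matrix.  Whole-dataset 5-fold cross-validation
and the ablation comparison (full model vs concatenation fusion vs the two
unimodal variants, paired t-tests across seeds or subjects) complete the
protocol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold, train_test_split
from threadpoolctl import threadpool_limits

from .model import MBCATT, ModelConfig, build_variant
from .nn import Adam, softmax_cross_entropy
from .signal_store import WindowSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol: Adam, lr 1e-3, fixed epoch count, no early
    stopping.  Batch size and shuffle policy are implementation defaults."""

    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be > 0")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


DEFAULT_EPOCHS = {"nback": 60, "wg": 70}


# --------------------------------------------------------------------- splits

def split_within_subject(ws: WindowSet, ratio: float = 0.8, seed: int = 0,
                         grouping: str = "window") -> tuple[WindowSet, WindowSet]:
    """Stratified train/test partition of one subject's windows.

    grouping='window' samples windows independently (the default protocol;
    note overlapping windows from one trial can then land on both sides).
    grouping='trial' keeps every window of a trial block on one side,
    removing that leakage.
    """
    labels = ws.labels()
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 windows to split")
    if grouping == "window":
        idx = np.arange(len(ws))
        tr, te = train_test_split(idx, train_size=ratio, random_state=seed,
                                  stratify=labels, shuffle=True)
        return ws.subset(np.sort(tr)), ws.subset(np.sort(te))
    if grouping != "trial":
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    trials = ws.trial_ids()
    # trials are atomic; stratify at the trial level by each trial's label
    trial_label = {t: labels[trials == t][0] for t in np.unique(trials)}
    train_trials: set = set()
    for c in np.unique(list(trial_label.values())):
        c_trials = np.array([t for t, lab in trial_label.items() if lab == c])
        rng.shuffle(c_trials)
        n_train = int(round(ratio * len(c_trials)))
        n_train = min(max(n_train, 1), len(c_trials) - 1) if len(c_trials) > 1 else 1
        train_trials.update(c_trials[:n_train].tolist())
    train_idx = [i for i in range(len(ws)) if trials[i] in train_trials]
    test_idx = [i for i in range(len(ws)) if trials[i] not in train_trials]
    if not test_idx:
        raise ValueError("trial grouping left the test side empty; need >= 2 "
                         "trials in some class")
    return ws.subset(np.sort(train_idx)), ws.subset(np.sort(test_idx))


def kfold(ws_or_labels, k: int = 5, seed: int = 0, stratified: bool = True):
    """k disjoint test folds covering every window exactly once; fold sizes
    differ by at most one."""
    labels = (ws_or_labels.labels() if isinstance(ws_or_labels, WindowSet)
              else np.asarray(ws_or_labels))
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if stratified and np.unique(labels, return_counts=True)[1].min() < k:
        log.warning("a class has fewer than %d members; falling back to "
                    "unstratified folds", k)
        stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n), labels)]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    return [(np.sort(np.concatenate(folds[:i] + folds[i + 1:])), np.sort(folds[i]))
            for i in range(k)]


# ------------------------------------------------------------------- training

def train(model: MBCATT, train_windows: WindowSet, spec: TrainSpec) -> MBCATT:
    """Fixed-epoch Adam training with per-epoch reshuffling.

    Deterministic given the spec seed and the model's build seed (single
    threaded).  Records per-epoch mean loss and training accuracy in
    ``model.training_history``.  Aborts on non-finite loss.
    """
    if len(train_windows) == 0:
        raise ValueError("empty training set")
    eeg, fnirs, y = train_windows.stacked()
    opt = Adam(model.parameters(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed)
    n = len(y)
    with threadpool_limits(1):
        _run_epochs(model, opt, spec, rng, eeg, fnirs, y, n)
    return model


def _run_epochs(model, opt, spec, rng, eeg, fnirs, y, n):
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, spec.batch_size):
            sel = order[start:start + spec.batch_size]
            logits = model.forward(eeg[sel], fnirs[sel], training=True)
            loss, grad, probs = softmax_cross_entropy(logits, y[sel])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // spec.batch_size}"
                    f" (lr={spec.learning_rate}, batch={len(sel)})")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss * len(sel))
            correct += int((probs.argmax(axis=1) == y[sel]).sum())
        model.training_history.append({
            "epoch": epoch, "loss": float(np.sum(losses) / n),
            "train_accuracy": correct / n})


# -------------------------------------------------------------------- metrics

@dataclass
class ConfusionMatrix:
    """Integer counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class ``c`` under one-vs-rest reduction."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum()) - tp
        fn = int(self.counts[c, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def plot(self, path, title: str = "Confusion matrix"):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(self.counts, cmap="Blues")
        names = self.class_names or [str(i) for i in range(self.n_classes)]
        ax.set_xticks(range(self.n_classes), names)
        ax.set_yticks(range(self.n_classes), names)
        ax.set_xlabel("Predicted")
        ax.set_ylabel("True")
        ax.set_title(title)
        for i in range(self.n_classes):
            for j in range(self.n_classes):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center",
                        color="black", fontsize=9)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def confusion(y_true, y_pred, n_classes: int,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if ((y_true < 0) | (y_true >= n_classes) | (y_pred < 0)
            | (y_pred >= n_classes)).any():
        raise ValueError("label out of range")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names)


@dataclass
class MetricsReport:
    """Accuracy, precision, recall, F1 from one confusion matrix.

    accuracy = (TP+TN)/(TP+TN+FP+FN) reduces to trace/total for multi-class;
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R).  The
    headline numbers use the requested averaging (macro by default; micro
    collapses to accuracy for single-label problems); per-class values are
    always included.  Zero-denominator classes contribute 0 with a warning.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: dict = field(default_factory=dict)
    confusion: ConfusionMatrix | None = None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "averaging": self.averaging}


def _safe_div(num, den, what, cls):
    if den == 0:
        log.warning("%s undefined for class %s (zero denominator); using 0", what, cls)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix, averaging: str = "macro") -> MetricsReport:
    if averaging not in ("macro", "micro", "binary"):
        raise ValueError(f"unknown averaging {averaging!r}")
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / total
    per = {"precision": [], "recall": [], "f1": []}
    for c in range(cm.n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(c)
        p = _safe_div(tp, tp + fp, "precision", c)
        r = _safe_div(tp, tp + fn, "recall", c)
        f1 = _safe_div(2 * p * r, p + r, "f1", c) if (p + r) else 0.0
        per["precision"].append(p)
        per["recall"].append(r)
        per["f1"].append(f1)
    if averaging == "macro":
        prec = float(np.mean(per["precision"]))
        rec = float(np.mean(per["recall"]))
        f1 = float(np.mean(per["f1"]))
    elif averaging == "micro":
        # pooled one-vs-rest counts; collapses to accuracy for single-label
        tps = sum(cm.one_vs_rest(c)[0] for c in range(cm.n_classes))
        fps = sum(cm.one_vs_rest(c)[2] for c in range(cm.n_classes))
        fns = sum(cm.one_vs_rest(c)[3] for c in range(cm.n_classes))
        prec = _safe_div(tps, tps + fps, "micro precision", "*")
        rec = _safe_div(tps, tps + fns, "micro recall", "*")
        f1 = _safe_div(2 * prec * rec, prec + rec, "micro f1", "*") if prec + rec else 0.0
    else:
        if cm.n_classes != 2:
            raise ValueError("binary averaging requires 2 classes")
        prec, rec, f1 = per["precision"][1], per["recall"][1], per["f1"][1]
    return MetricsReport(accuracy=acc, precision=prec, recall=rec, f1=f1,
                         averaging=averaging, per_class=per, confusion=cm)


def evaluate(model: MBCATT, test_windows: WindowSet, averaging: str = "macro",
             batch_size: int = 64) -> MetricsReport:
    """Window-level metrics of a trained model on held-out windows."""
    if len(test_windows) == 0:
        raise ValueError("empty test set")
    eeg, fnirs, y = test_windows.stacked()
    preds = []
    with threadpool_limits(1):
        for start in range(0, len(y), batch_size):
            sl = slice(start, start + batch_size)
            preds.append(model.predict(eeg[sl], fnirs[sl]))
    y_pred = np.concatenate(preds)
    cm = confusion(y, y_pred, len(test_windows.class_names),
                   test_windows.class_names)
    return metrics_from_confusion(cm, averaging)


# ---------------------------------------------------------------- statistics

@dataclass
class TTestResult:
    t: float
    p: float
    mean_diff: float
    df: int
    zero_variance: bool = False


def paired_ttest(scores_a, scores_b) -> TTestResult:
    """Two-sided paired t-test on per-pair differences (df = n-1).

    Zero-variance differences are degenerate: identical vectors give
    (t=0, p=1); a constant non-zero difference has an undefined p and is
    flagged.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, 0.0, n - 1, zero_variance=True)
        return TTestResult(math.copysign(math.inf, mean), math.nan, mean,
                           n - 1, zero_variance=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), float(p), mean, n - 1)


# ------------------------------------------------------------------ protocol

def _fit_eval(variant, cfg, train_ws, test_ws, spec, averaging="macro"):
    model = build_variant(variant, cfg, seed=spec.seed)
    train(model, train_ws, spec)
    return model, evaluate(model, test_ws, averaging)


def run_experiment(window_sets: dict[str, WindowSet], model_config: ModelConfig,
                   spec: TrainSpec, protocol: str = "split8020_cv5train",
                   variants: tuple[str, ...] = ("full",), ratio: float = 0.8,
                   grouping: str = "window", k: int = 5,
                   inner_cv: bool = False, averaging: str = "macro") -> dict:
    """Run the evaluation protocol over per-subject window sets.

    protocol='split8020_cv5train': per-subject stratified 80/20 split, with
    optional 5-fold cross-validation inside the training subset
    (``inner_cv``), then a final fit on the whole training subset evaluated
    on the held-out 20%.  protocol='cv5full': windows are pooled across
    subjects and evaluated by stratified 5-fold cross-validation (per-fold
    rows plus the average row).  Returns a plain-dict report with every
    seed/config needed for an exact rerun.
    """
    if protocol not in ("split8020_cv5train", "cv5full"):
        raise ValueError(f"unknown protocol {protocol!r}")
    report = {"protocol": protocol, "train_spec": asdict(spec),
              "model_config": model_config.to_dict(), "variants": {}}
    from .preprocess import merge_window_sets
    for variant in variants:
        vrep = {}
        if protocol == "split8020_cv5train":
            per_subject = {}
            for sid, ws in window_sets.items():
                tr, te = split_within_subject(ws, ratio, spec.seed, grouping)
                entry = {}
                if inner_cv:
                    fold_accs = []
                    for fi, (ftr, fte) in enumerate(kfold(tr, k, spec.seed)):
                        _, rep = _fit_eval(variant, model_config, tr.subset(ftr),
                                           tr.subset(fte), spec, averaging)
                        fold_accs.append(rep.accuracy)
                    entry["train_cv_accuracy"] = fold_accs
                _, rep = _fit_eval(variant, model_config, tr, te, spec, averaging)
                entry["test"] = rep.as_dict()
                entry["per_class"] = rep.per_class
                per_subject[sid] = entry
            vrep["per_subject"] = per_subject
            tests = [e["test"] for e in per_subject.values()]
            vrep["average"] = {m: float(np.mean([t[m] for t in tests]))
                               for m in ("accuracy", "precision", "recall", "f1")}
        else:
            pooled = merge_window_sets(list(window_sets.values()))
            folds = []
            for fi, (ftr, fte) in enumerate(kfold(pooled, k, spec.seed)):
                _, rep = _fit_eval(variant, model_config, pooled.subset(ftr),
                                   pooled.subset(fte), spec, averaging)
                folds.append(rep.as_dict())
            vrep["folds"] = folds
            vrep["average"] = {m: float(np.mean([f[m] for f in folds]))
                               for m in ("accuracy", "precision", "recall", "f1")}
        report["variants"][variant] = vrep
    if "full" in report["variants"] and len(report["variants"]) > 1:
        report["ablation"] = _ablation_summary(report, protocol)
    return report


def _scores(vrep, protocol):
    if protocol == "split8020_cv5train":
        return [e["test"]["accuracy"] for e in vrep["per_subject"].values()]
    return [f["accuracy"] for f in vrep["folds"]]


def _ablation_summary(report, protocol):
    full = _scores(report["variants"]["full"], protocol)
    out = {}
    for name, vrep in report["variants"].items():
        if name == "full":
            continue
        base = _scores(vrep, protocol)
        entry = {"mean_accuracy_drop": float(np.mean(full) - np.mean(base))}
        if len(full) >= 2:
            tt = paired_ttest(full, base)
            entry["paired_t"] = {"t": tt.t, "p": tt.p, "mean_diff": tt.mean_diff,
                                 "df": tt.df, "zero_variance": tt.zero_variance}
        out[name] = entry
    return out


def ablation_study(make_window_set, model_config: ModelConfig, spec: TrainSpec,
                   seeds, variants=("full", "concat_ablation", "eeg_only",
                                    "fnirs_only"),
                   ratio: float = 0.8, grouping: str = "trial") -> dict:
    """Variant comparison over independent seeds.

    ``make_window_set(seed)`` must return a fresh WindowSet (typically from
    the synthetic generator).  Each seed gets its own data, split, and model
    initialization; the paired t-test then compares the full model with each
    baseline across seeds.
    """
    accs = {v: [] for v in variants}
    for seed in seeds:
        ws = make_window_set(seed)
        sspec = TrainSpec(learning_rate=spec.learning_rate, epochs=spec.epochs,
                          batch_size=spec.batch_size, seed=seed)
        tr, te = split_within_subject(ws, ratio, seed, grouping)
        for v in variants:
            _, rep = _fit_eval(v, model_config, tr, te, sspec)
            accs[v].append(rep.accuracy)
    result = {"seeds": list(seeds), "accuracy": {v: list(a) for v, a in accs.items()},
              "mean_accuracy": {v: float(np.mean(a)) for v, a in accs.items()},
              "comparisons": {}}
    for v in variants:
        if v == "full":
            continue
        tt = paired_ttest(accs["full"], accs[v])
        result["comparisons"][f"full_vs_{v}"] = {
            "t": tt.t, "p": tt.p, "mean_diff": tt.mean_diff, "df": tt.df,
            "zero_variance": tt.zero_variance}
    return result
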