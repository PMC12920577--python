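"""Training, cross-validation, metrics, significance tests and alert-rate
mitigation for the segment classifier.

The metric suite reports, per class (one-vs-rest), precision, sensitivity
(recall), specificity, F1, FNR and FPR from the confusion counts

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)        sensitivity = TP / (TP + FN)
    F1 = 2 * precision * sensitivity / (precision + sensitivity)

together with macro / micro / support-weighted aggregates and one-vs-rest
ROC-AUC computed from the Mann-Whitney rank statistic with tie correction.
Mitigation utilities implement per-class decision-threshold optimization,
class-weighted loss (through :func:`graphecg.model.cross_entropy_loss`) and
temporal alert aggregation (alert only after k consecutive abnormal
segments).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .features import FEATURE_NAMES, FeatureTensor
from .model import (LeadGraphTransformer, LeadGraph, ModelConfig, build_lead_graph,
                    cross_entropy_loss)
from .nn import Adam

logger = logging.getLogger(__name__)

ABNORMAL = ("S", "V", "E")
_SEVERITY = ("V", "S", "E")

__all__ = [
    "FoldSplit", "MetricsReport", "TrainResult", "make_folds", "patient_holdout",
    "train", "grid_search", "compute_metrics", "roc_auc_ovr", "paired_t_test",
    "temporal_alert_aggregation", "optimize_thresholds", "ablation_run",
    "mask_feature_subset",
]


# ---------------------------------------------------------------------------
# folds and splits
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    folds: list[np.ndarray]
    level: str
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_val(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        val = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return np.sort(train), np.sort(val)


def make_folds(labels: np.ndarray, k: int, level: str = "segment", seed: int = 0,
               patient_ids: np.ndarray | None = None) -> FoldSplit:
    """Disjoint k folds: class-stratified at segment level, grouped at patient level."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if level == "segment":
        counts = pd.Series(labels).value_counts()
        if (counts < k).any():
            warnings.warn("some class has fewer members than k: fold sizes will be uneven")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [np.sort(val) for _, val in skf.split(np.zeros(len(labels)), labels)]
    elif level == "patient":
        if patient_ids is None:
            raise ValidationError("patient-level folds require patient ids")
        patient_ids = np.asarray(patient_ids)
        patients = np.unique(patient_ids)
        rng = np.random.default_rng(seed)
        rng.shuffle(patients)
        assign = {p: i % k for i, p in enumerate(patients)}
        folds = [np.flatnonzero([assign[p] == i for p in patient_ids]) for i in range(k)]
    else:
        raise ValidationError(f"unknown split level {level!r}")
    return FoldSplit(folds=folds, level=level, seed=seed)


def patient_holdout(patient_ids: np.ndarray, test_frac: float = 0.25, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Whole-patient train/test split; returns (train_idx, test_idx)."""
    patient_ids = np.asarray(patient_ids)
    patients = np.unique(patient_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    n_test = max(1, int(round(test_frac * len(patients))))
    test_set = set(patients[:n_test])
    mask = np.array([p in test_set for p in patient_ids])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: LeadGraphTransformer
    history: pd.DataFrame
    best_epoch: int


def _accuracy(model: LeadGraphTransformer, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(x)
    loss = float(cross_entropy_loss(probs, y).data)
    return float(np.mean(np.argmax(probs, axis=1) == y)), loss


def train(features: FeatureTensor, train_idx: np.ndarray,
          config: ModelConfig | None = None, seed: int = 0,
          val_idx: np.ndarray | None = None, max_epochs: int = 15,
          patience: int = 5, graph: LeadGraph | None = None,
          class_weights: np.ndarray | None = None) -> TrainResult:
    """Train the classifier with Adam and early stopping on validation loss.

    Deterministic for fixed arguments: shuffling, initialization and dropout
    all derive from ``seed``.  Returns the parameters of the best-validation
    -loss epoch (final epoch when no validation set is given).
    """
    if len(train_idx) == 0:
        raise ValidationError("empty training set")
    config = config or ModelConfig()
    x_all = features.model_input
    y_all = features.labels
    if y_all is None:
        raise ValidationError("features carry no labels")
    n_leads = x_all.shape[2]
    graph = graph or build_lead_graph(n_leads, "full")
    model = LeadGraphTransformer(d_feat=x_all.shape[-1], T=x_all.shape[1], graph=graph,
                          config=config, seed=seed)
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    model.fit_standardizer(x_tr)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2)

    rows = []
    best_loss, best_epoch, best_params, bad_epochs = math.inf, -1, None, 0
    for epoch in range(max_epochs):
        order = shuffle_rng.permutation(len(x_tr))
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            probs = model.forward(x_tr[sel], train=True, rng=drop_rng)
            loss = cross_entropy_loss(probs, y_tr[sel], class_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
        tr_acc, tr_loss = _accuracy(model, x_tr, y_tr)
        row = {"epoch": epoch, "train_loss": tr_loss, "train_acc": tr_acc}
        monitor = tr_loss
        if val_idx is not None and len(val_idx):
            va_acc, va_loss = _accuracy(model, x_all[val_idx], y_all[val_idx])
            row.update(val_loss=va_loss, val_acc=va_acc)
            monitor = va_loss
        rows.append(row)
        if monitor < best_loss - 1e-9:
            best_loss, best_epoch, bad_epochs = monitor, epoch, 0
            best_params = [p.data.copy() for p in model.parameters()]
        else:
            bad_epochs += 1
            if val_idx is not None and bad_epochs >= patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
    if best_params is not None:
        for p, saved in zip(model.parameters(), best_params):
            p.data[...] = saved
    return TrainResult(model=model, history=pd.DataFrame(rows), best_epoch=best_epoch)


def grid_search(features: FeatureTensor, grid: dict[str, list], folds: FoldSplit,
                base_config: ModelConfig | None = None, seed: int = 0,
                max_epochs: int = 10) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive search over the hyperparameter lattice.

    Every combination is trained and evaluated on each fold; the winner has
    the lowest mean validation cross-entropy (ties: higher mean accuracy,
    then first in enumeration order).  Returns (best config, results table).
    """
    base_config = base_config or ModelConfig()
    axes = list(grid.keys())
    if any(len(v) == 0 for v in grid.values()):
        raise ValidationError("grid axes must be non-empty")
    rows = []
    best = None
    for combo_id, values in enumerate(itertools.product(*(grid[a] for a in axes))):
        cfg = replace(base_config, **dict(zip(axes, values)))
        losses, accs = [], []
        for i in range(folds.k):
            tr, va = folds.train_val(i)
            result = train(features, tr, cfg, seed=seed, val_idx=va,
                           max_epochs=max_epochs)
            acc, loss = _accuracy(result.model, features.model_input[va],
                                  features.labels[va])
            losses.append(loss)
            accs.append(acc)
        row = dict(zip(axes, values))
        row.update(combo_id=combo_id, mean_val_loss=float(np.mean(losses)),
                   mean_val_acc=float(np.mean(accs)))
        rows.append(row)
        key = (row["mean_val_loss"], -row["mean_val_acc"], combo_id)
        if best is None or key < best[0]:
            best = (key, cfg)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    confusion: np.ndarray                 # K x K, rows true, cols predicted
    accuracy: float
    per_class: pd.DataFrame               # precision/sensitivity/specificity/f1/fnr/fpr/support
    macro: dict[str, float]
    micro: dict[str, float]
    weighted: dict[str, float]
    auc: dict[str, float] | None = None   # per-class + macro, when probs given

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "macro": self.macro, "micro": self.micro, "weighted": self.weighted,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None,
                    class_names: list[str] | None = None) -> MetricsReport:
    """Confusion counts and the full derived metric suite (one-vs-rest).

    Zero-denominator metrics are reported as 0 (flagged by a support column
    of 0 in ``per_class``); macro averages run over all classes.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    K = n_classes or int(max(y_true.max(initial=0), y_pred.max(initial=0)) + 1)
    if (y_true < 0).any() or (y_true >= K).any() or (y_pred < 0).any() or (y_pred >= K).any():
        raise ValidationError("codes must lie in [0, n_classes)")
    conf = np.zeros((K, K), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    total = conf.sum()
    accuracy = _safe_div(np.trace(conf), total)

    rows = {}
    tps = fps = fns = 0
    names = class_names or [str(i) for i in range(K)]
    for c in range(K):
        tp = conf[c, c]
        fn = conf[c].sum() - tp
        fp = conf[:, c].sum() - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp)
        sensitivity = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity)
        rows[names[c]] = {
            "precision": precision, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1,
            "fnr": 1.0 - sensitivity, "fpr": 1.0 - specificity,
            "support": int(tp + fn),
        }
        tps += tp
        fps += fp
        fns += fn
    per_class = pd.DataFrame(rows).T
    support = per_class["support"].to_numpy()
    metric_cols = ["precision", "sensitivity", "specificity", "f1", "fnr", "fpr"]
    macro = {m: float(per_class[m].mean()) for m in metric_cols}
    weighted = {m: float(np.average(per_class[m], weights=support)) if support.sum()
                else 0.0 for m in metric_cols}
    micro_p = _safe_div(tps, tps + fps)
    micro_r = _safe_div(tps, tps + fns)
    micro = {"precision": micro_p, "sensitivity": micro_r,
             "f1": _safe_div(2 * micro_p * micro_r, micro_p + micro_r)}
    return MetricsReport(confusion=conf, accuracy=float(accuracy), per_class=per_class,
                         macro=macro, micro=micro, weighted=weighted)


def binary_counts_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Closed-form binary metrics straight from the four confusion counts."""
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": _safe_div(2 * precision * sensitivity, precision + sensitivity),
        "fnr": 1.0 - sensitivity,
        "fpr": 1.0 - specificity,
    }


def roc_auc_ovr(y_true: np.ndarray, probs: np.ndarray,
                class_names: list[str] | None = None) -> dict[str, float]:
    """One-vs-rest ROC-AUC per class from the Mann-Whitney rank statistic.

    AUC_c = (R_pos - n_pos (n_pos + 1)/2) / (n_pos n_neg) with midranks for
    ties.  Classes absent from ``y_true`` get NaN; macro averages the rest.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    probs = np.asarray(probs, dtype=np.float64)
    K = probs.shape[1]
    names = class_names or [str(i) for i in range(K)]
    out: dict[str, float] = {}
    aucs = []
    for c in range(K):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[names[c]] = math.nan
            continue
        ranks = sstats.rankdata(probs[:, c])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        out[names[c]] = float(auc)
        aucs.append(auc)
    out["macro"] = float(np.mean(aucs)) if aucs else math.nan
    return out


def auc_bruteforce(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Concordant-pair counting oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in scores_pos:
        for n in scores_neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


def paired_t_test(scores_a: np.ndarray, scores_b: np.ndarray
                  ) -> tuple[float, int, float]:
    """Paired two-sided t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need equal-length score vectors with n >= 2")
    d = a - b
    n = d.size
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if abs(d.mean()) < 1e-300:
            return 0.0, n - 1, 1.0
        warnings.warn("zero-variance nonzero-mean differences: t is infinite")
        return math.copysign(math.inf, d.mean()), n - 1, 0.0
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
    return t, n - 1, p


# ---------------------------------------------------------------------------
# mitigation strategies
# ---------------------------------------------------------------------------

def temporal_alert_aggregation(stream, k_consecutive: int) -> list[tuple[int, str]]:
    """Alert events from a stream of per-segment class symbols.

    An alert fires at the index of the k-th consecutive abnormal (non-N)
    segment; the run's majority abnormal class is reported (severity V > S >
    E breaks ties).  The consecutive counter resets on every N segment and
    after each alert, so k = 1 alerts at every abnormal segment and a long
    abnormal run re-alerts every k segments.
    """
    if k_consecutive < 1:
        raise ValidationError("k_consecutive must be >= 1")
    alerts: list[tuple[int, str]] = []
    run: list[str] = []
    for i, sym in enumerate(stream):
        if sym == "N":
            run = []
            continue
        run.append(sym)
        if len(run) >= k_consecutive:
            counts = {s: run.count(s) for s in set(run)}
            best = max(counts.values())
            cls = next(s for s in _SEVERITY if counts.get(s) == best)
            alerts.append((i, cls))
            run = []
    return alerts


def _veto_predictions(probs: np.ndarray, class_idx: int, thr: float,
                      n_idx: int) -> np.ndarray:
    """Argmax predictions with a veto threshold on one abnormal class."""
    pred = np.argmax(probs, axis=1)
    veto = (pred == class_idx) & (probs[:, class_idx] < thr)
    pred = pred.copy()
    pred[veto] = n_idx
    return pred


def optimize_thresholds(val_probs: np.ndarray, val_labels: np.ndarray,
                        objective: str = "min_fpr_at_sensitivity",
                        sensitivity_target: float = 0.9,
                        class_names: list[str] | None = None) -> dict[str, float]:
    """Per-abnormal-class veto thresholds scanned over {0.00, ..., 0.99}.

    ``min_fpr_at_sensitivity`` picks, per class, the highest threshold whose
    class sensitivity still reaches ``sensitivity_target`` (FPR never rises
    with the threshold); when no threshold satisfies the constraint the class
    keeps threshold 0 (flagged in the log).  ``max_f1`` maximizes the class
    F1 instead.
    """
    probs = np.asarray(val_probs, dtype=np.float64)
    y = np.asarray(val_labels, dtype=np.int64)
    if probs.size == 0:
        raise ValidationError("empty validation set")
    K = probs.shape[1]
    if class_names is not None:
        names = class_names
    elif K == 4:
        names = ["E", "N", "S", "V"]  # alphabetical LabelMap order
    else:
        raise ValidationError("class_names required when n_classes != 4")
    if "N" not in names:
        raise ValidationError("threshold optimization needs an N class")
    n_idx = names.index("N")
    grid = np.round(np.arange(0.0, 1.0, 0.01), 2)
    thresholds: dict[str, float] = {}
    for c, name in enumerate(names):
        if name == "N":
            continue
        best_thr = 0.0
        if objective == "min_fpr_at_sensitivity":
            feasible = False
            for thr in grid:
                pred = _veto_predictions(probs, c, thr, n_idx)
                m = compute_metrics(y, pred, n_classes=K, class_names=names)
                if m.per_class.loc[name, "sensitivity"] >= sensitivity_target:
                    best_thr, feasible = float(thr), True
            if not feasible:
                logger.warning("sensitivity target %.2f infeasible for class %s; "
                               "threshold left at 0", sensitivity_target, name)
                best_thr = 0.0
        elif objective == "max_f1":
            best_f1 = -1.0
            for thr in grid:
                pred = _veto_predictions(probs, c, thr, n_idx)
                m = compute_metrics(y, pred, n_classes=K, class_names=names)
                f1 = m.per_class.loc[name, "f1"]
                if f1 > best_f1:
                    best_f1, best_thr = f1, float(thr)
        else:
            raise ValidationError(f"unknown objective {objective!r}")
        thresholds[name] = best_thr
    return thresholds


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

NONLINEAR_COLS = tuple(FEATURE_NAMES.index(n) for n in ("apen", "sd1", "sd2"))

VARIANTS = ("hybrid", "gnn_only", "transformer_only", "no_attention",
            "no_tuning", "time_frequency", "nonlinear_only")


def mask_feature_subset(features: FeatureTensor, keep: str) -> FeatureTensor:
    """Zero (and mask) feature columns outside the requested group.

    ``time_frequency`` removes the non-linear columns (ApEn, SD1, SD2);
    ``nonlinear_only`` keeps only those three.
    """
    if keep == "time_frequency":
        drop = list(NONLINEAR_COLS)
    elif keep == "nonlinear_only":
        drop = [i for i in range(len(features.feature_names)) if i not in NONLINEAR_COLS]
    else:
        raise ValidationError(f"unknown feature subset {keep!r}")
    values = features.values.copy()
    mask = features.mask.copy()
    values[..., drop] = 0.0
    mask[..., drop] = 1.0
    return FeatureTensor(values=values, mask=mask, labels=features.labels,
                         feature_names=features.feature_names,
                         patient_ids=features.patient_ids)


def ablation_run(features: FeatureTensor, train_idx: np.ndarray, test_idx: np.ndarray,
                 variants=("hybrid", "gnn_only", "transformer_only"),
                 config: ModelConfig | None = None, seed: int = 0,
                 max_epochs: int = 15, class_names: list[str] | None = None
                 ) -> pd.DataFrame:
    """Train and evaluate architecture / feature variants on a fixed split.

    ``gnn_only`` drops the transformer stack (temporal mean-pool remains);
    ``transformer_only`` uses the identity lead graph; ``no_attention``
    replaces attention weights with uniform averaging; ``no_tuning`` uses a
    deliberately untuned configuration (learning rate 1e-2, no dropout);
    ``time_frequency`` / ``nonlinear_only`` mask feature groups.
    """
    config = config or ModelConfig()
    rows = []
    for variant in variants:
        if variant not in VARIANTS:
            raise ValidationError(f"unknown ablation variant {variant!r}")
        cfg, feats, graph = config, features, None
        if variant == "gnn_only":
            cfg = replace(config, n_transformer_layers=0)
        elif variant == "transformer_only":
            graph = build_lead_graph(features.values.shape[2], "identity")
        elif variant == "no_attention":
            cfg = replace(config, uniform_attention=True)
        elif variant == "no_tuning":
            cfg = replace(config, learning_rate=1e-2, dropout=0.0)
        elif variant in ("time_frequency", "nonlinear_only"):
            feats = mask_feature_subset(features, variant)
        result = train(feats, train_idx, cfg, seed=seed, max_epochs=max_epochs)
        probs = result.model.predict_proba(feats.model_input[test_idx])
        y_test = feats.labels[test_idx]
        report = compute_metrics(y_test, np.argmax(probs, axis=1),
                                 n_classes=cfg.n_classes, class_names=class_names)
        rows.append({
            "variant": variant,
            "accuracy": report.accuracy,
            "macro_f1": report.macro["f1"],
            "macro_precision": report.macro["precision"],
            "macro_sensitivity": report.macro["sensitivity"],
        })
    return pd.DataFrame(rows)
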