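"""Training, evaluation and comparison protocol.

Splits are epoch-wise and stratified by class at the published fractions
(70% train / 20% validation / 10% test).  The default hyperparameters follow
the emulated study's tuning table: SGD, learning rate 1e-4, batch size 16,
cross-entropy loss, weight decay 6e-6, dropout 0.2, 150 epochs.  FT2
activation parameters are updated by their own momentum rule (see
:mod:`dfcgn.ft2`), decoupled from the weight optimiser.

Evaluation reports the confusion matrix (positive = class 1), accuracy,
sensitivity, precision, specificity, Cohen's kappa, and a ROC curve with
trapezoidal AUC over the score-threshold sweep.

Noise robustness is probed in the signal domain: additive white Gaussian
noise is scaled per epoch to a stated SNR and the clean-trained model is
evaluated on the noisy copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import EpochSet
from .ft2 import ft2_update
from .model import DFCGN, DFCGNConfig, reduced_config
from .graph import SpectralGraph, graph_from_epochs


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainConfig:
    optimizer: str = "sgd"          # sgd | adam | adadelta | adamax
    lr: float = 1e-4
    batch_size: int = 16
    loss: str = "cross_entropy"     # cross_entropy | mse
    weight_decay: float = 6e-6
    momentum: float = 0.0           # SGD weight momentum
    ft2_rho: float = 0.9            # FT2 momentum coefficient
    ft2_xi: float = 1e-4            # FT2 learning rate
    grad_clip: Optional[float] = 1.0  # global weight-gradient norm cap (None = off)
    lr_decay: float = 1.0           # per-epoch multiplicative lr decay
    epochs: int = 150
    split: Tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("sgd", "adam", "adadelta", "adamax"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("cross_entropy", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# splitting


def _allocate(counts: np.ndarray, total: int, frac: float) -> np.ndarray:
    """Largest-remainder apportionment of ``floor(frac * total)`` across classes."""
    want = int(np.floor(frac * total))
    exact = frac * counts
    base = np.floor(exact).astype(int)
    short = want - base.sum()
    if short > 0:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(exact - base, kind="stable")
        base[order[:-short]] -= 1
    return base


def split_epochs(eset: EpochSet, cfg: TrainConfig):
    """Stratified train/val/test split at cfg.split fractions.

    Validation and test sizes are floored globally (``floor(frac * n)``) and
    apportioned across classes by largest remainder; the remainder goes to
    train.  Deterministic under cfg.seed.  Raises if the training or
    validation split would miss a class entirely.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = np.array([0, 1])
    counts = np.array([(eset.labels == c).sum() for c in classes])
    if (counts == 0).any():
        raise ValueError("both classes must be present in the epoch set")
    n = eset.n_epochs
    te_per = _allocate(counts, n, cfg.split[2])
    va_per = _allocate(counts, n, cfg.split[1])
    tr_per = counts - te_per - va_per
    if (tr_per <= 0).any() or (va_per <= 0).any():
        raise ValueError(
            f"a class would be missing from the train or validation split at "
            f"n={n}; use more epochs (e.g. enable sub-epoch windowing)"
        )
    tr_idx, va_idx, te_idx = [], [], []
    for c, nt, nv in zip(classes, te_per, va_per):
        idx = rng.permutation(np.where(eset.labels == c)[0])
        te_idx.extend(idx[:nt])
        va_idx.extend(idx[nt:nt + nv])
        tr_idx.extend(idx[nt + nv:])
    return (eset.subset(np.sort(tr_idx)),
            eset.subset(np.sort(va_idx)),
            eset.subset(np.sort(te_idx)))


# ---------------------------------------------------------------------------
# optimisers (weights only; FT2 params have their own rule)


class _Optimizer:
    def __init__(self, params: Dict[str, np.ndarray], cfg: TrainConfig):
        self.params = params
        self.lr = cfg.lr
        self.wd = cfg.weight_decay
        self.momentum = cfg.momentum
        self.kind = cfg.optimizer
        self.grad_clip = cfg.grad_clip
        self.t = 0
        self.state = {
            k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
            for k, v in params.items()
        }

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        if self.grad_clip is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > self.grad_clip:
                grads = {k: v * (self.grad_clip / total) for k, v in grads.items()}
        for name, p in self.params.items():
            g = grads[name] + self.wd * p
            st = self.state[name]
            if self.kind == "sgd":
                if self.momentum:
                    st["m"] = self.momentum * st["m"] + g
                    g = st["m"]
                p -= self.lr * g
            elif self.kind == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g * g
                mhat = st["m"] / (1 - b1 ** self.t)
                vhat = st["v"] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            elif self.kind == "adamax":
                b1, b2, eps = 0.9, 0.999, 1e-8
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = np.maximum(b2 * st["v"], np.abs(g))
                p -= self.lr / (1 - b1 ** self.t) * st["m"] / (st["v"] + eps)
            elif self.kind == "adadelta":
                rho, eps = 0.95, 1e-6
                st["m"] = rho * st["m"] + (1 - rho) * g * g
                dx = np.sqrt(st["v"] + eps) / np.sqrt(st["m"] + eps) * g
                st["v"] = rho * st["v"] + (1 - rho) * dx * dx
                p -= self.lr * dx


def _loss_value(probs: np.ndarray, y: np.ndarray, loss: str) -> float:
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), y] = 1.0
    if loss == "cross_entropy":
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))
    return float(np.mean((probs - onehot) ** 2))


# ---------------------------------------------------------------------------
# training loop


def train(
    model: DFCGN,
    train_set: EpochSet,
    val_set: Optional[EpochSet],
    cfg: TrainConfig,
) -> Tuple[DFCGN, pd.DataFrame]:
    """Train ``model`` in place; returns it with the best-validation weights.

    History is one row per epoch with train/val loss and accuracy.  The
    checkpoint with the highest validation accuracy (earliest epoch on ties)
    is restored at the end; with no validation set the final weights stand.
    Aborts with diagnostics if the loss turns non-finite.
    """
    if train_set.n_epochs == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    Xtr, ytr = train_set.epochs, train_set.labels
    model.fit_scaler(Xtr)
    model.calibrate_scales(Xtr)
    for layer in model.layers:
        layer["ft2"].rho = cfg.ft2_rho
        layer["ft2"].xi = cfg.ft2_xi
    opt = _Optimizer(model.weight_params(), cfg)

    history = {k: [] for k in ("epoch", "train_loss", "train_acc", "val_loss", "val_acc")}
    best = (-1.0, None)  # (val acc, state arrays)

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_set.n_epochs)
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            probs, cache = model.forward(Xtr[sel], training=True, rng=rng)
            loss_val = _loss_value(probs, ytr[sel], cfg.loss)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size} "
                    f"(lr={cfg.lr}, optimizer={cfg.optimizer})"
                )
            grads, ft2_grads = model.backward(cache, ytr[sel], loss=cfg.loss)
            if cfg.lr > 0:
                opt.step(grads)
            for layer, fg in zip(model.layers, ft2_grads):
                if cfg.ft2_xi > 0:
                    ft2_update(layer["ft2"], fg)
        opt.lr *= cfg.lr_decay
        for layer in model.layers:
            layer["ft2"].xi *= cfg.lr_decay

        tr_probs = model.predict_proba(Xtr)
        history["epoch"].append(epoch)
        history["train_loss"].append(_loss_value(tr_probs, ytr, cfg.loss))
        history["train_acc"].append(float((tr_probs.argmax(1) == ytr).mean()))
        if val_set is not None and val_set.n_epochs:
            va_probs = model.predict_proba(val_set.epochs)
            va_acc = float((va_probs.argmax(1) == val_set.labels).mean())
            history["val_loss"].append(_loss_value(va_probs, val_set.labels, cfg.loss))
            history["val_acc"].append(va_acc)
            if va_acc > best[0]:
                best = (va_acc, model.state_arrays())
        else:
            history["val_loss"].append(np.nan)
            history["val_acc"].append(np.nan)

    if best[1] is not None:
        model.load_state(best[1])
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Confusion counts and derived metrics; positive class = 1."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    kappa: float
    roc_fpr: Optional[np.ndarray] = None
    roc_tpr: Optional[np.ndarray] = None
    auc: Optional[float] = None
    history: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dict(self) -> Dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "precision": self.precision, "specificity": self.specificity,
            "kappa": self.kappa, "auc": self.auc,
        }
        return d


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> Dict[str, float]:
    """Accuracy, sensitivity, precision, specificity and Cohen's kappa."""
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = (tp + tn) / total
    # chance agreement from the marginals
    p_yes = ((tp + fn) / total) * ((tp + fp) / total)
    p_no = ((tn + fp) / total) * ((tn + fn) / total)
    p_e = p_yes + p_no
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return {
        "accuracy": p_o,
        "sensitivity": _safe_div(tp, tp + fn),
        "precision": _safe_div(tp, tp + fp),
        "specificity": _safe_div(tn, tn + fp),
        "kappa": kappa,
    }


def roc_points(scores: np.ndarray, labels: np.ndarray):
    """ROC curve over the score-threshold sweep, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: Optional[np.ndarray] = None,
) -> EvalReport:
    """Build an :class:`EvalReport` from labels, predictions and scores."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    m = metrics_from_counts(tp, fp, tn, fn)
    report = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, **m)
    if scores is not None:
        try:
            report.roc_fpr, report.roc_tpr, report.auc = roc_points(scores, y_true)
        except ValueError:
            warnings.warn("single-class test set: ROC/AUC undefined", RuntimeWarning)
    return report


def evaluate(model: DFCGN, test_set: EpochSet) -> EvalReport:
    """Confusion metrics + ROC of a trained model on a test epoch set."""
    if test_set.n_epochs == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(test_set.epochs)
    return evaluate_predictions(test_set.labels, probs.argmax(1), probs[:, 1])


# ---------------------------------------------------------------------------
# handcrafted features & baselines


FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis", "crest", "power")


def handcrafted_features(
    eset: EpochSet, peak_to_peak: bool = False
) -> pd.DataFrame:
    """Six classical statistics per epoch per channel.

    mean, variance, skewness, kurtosis (Fisher), crest factor (peak/RMS; the
    ``peak_to_peak`` flag swaps in max−min instead of the peak), and mean
    signal power.  Zero-variance channels get 0 for the scale-free statistics
    with a warning.
    """
    if eset.n_epochs == 0:
        raise ValueError("empty epoch set")
    X = eset.epochs
    names = list(eset.channel_names) or [f"ch{i}" for i in range(eset.n_channels)]
    cols, data = [], []
    mean = X.mean(axis=2)
    var = X.var(axis=2)
    power = np.mean(X ** 2, axis=2)
    dead = var == 0
    if dead.any():
        warnings.warn("zero-variance channel(s): degenerate statistics set to 0",
                      RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(dead, 0.0, stats.skew(X, axis=2))
        kurt = np.where(dead, 0.0, stats.kurtosis(X, axis=2))
        peak = (X.max(axis=2) - X.min(axis=2)) if peak_to_peak else np.abs(X).max(axis=2)
        rms = np.sqrt(power)
        crest = np.where(rms > 0, peak / np.where(rms > 0, rms, 1.0), 0.0)
        crest = np.where(dead, 0.0, crest)
    per_feature = {"mean": mean, "variance": var, "skewness": skew,
                   "kurtosis": kurt, "crest": crest, "power": power}
    for ci, ch in enumerate(names):
        for feat in FEATURE_NAMES:
            cols.append(f"{ch}_{feat}")
            data.append(per_feature[feat][:, ci])
    df = pd.DataFrame(np.column_stack(data), columns=cols)
    df["label"] = eset.labels
    return df


def _sklearn_baselines(seed: int):
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return {
        "KNN": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5)),
        "SVM": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
        "MLP": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=500, random_state=seed),
        ),
    }


def _fit_dfcgn(
    train_set: EpochSet, val_set: EpochSet, cfg: TrainConfig,
    model_cfg: DFCGNConfig, G: SpectralGraph,
) -> DFCGN:
    model = DFCGN(model_cfg, G, seed=cfg.seed)
    model, _ = train(model, train_set, val_set, cfg)
    return model


def _features_as_epochset(feats: pd.DataFrame, eset: EpochSet) -> EpochSet:
    """Reshape the handcrafted feature table into (epochs, channels, 6)."""
    n_ch = eset.n_channels
    vals = feats.drop(columns="label").to_numpy()
    arr = vals.reshape(eset.n_epochs, n_ch, len(FEATURE_NAMES))
    return EpochSet(arr, eset.labels, eset.fs,
                    channel_names=list(eset.channel_names),
                    provenance=list(eset.provenance))


def baseline_compare(
    eset: EpochSet,
    cfg: TrainConfig,
    model_cfg: Optional[DFCGNConfig] = None,
    G: Optional[SpectralGraph] = None,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Accuracy of KNN/SVM/MLP and DFCGN on raw epochs vs handcrafted features.

    Returns a table with one row per method and columns ``feature_learning``
    (raw waveform input) and ``handcrafted`` (six statistics per channel).
    All methods share the same stratified split and seed.
    """
    tr, va, te = split_epochs(eset, cfg)
    if G is None:
        G = graph_from_epochs(tr, tau=tau)
    if model_cfg is None:
        model_cfg = reduced_config(n_nodes=eset.n_channels)

    feats = handcrafted_features(eset)
    f_all = _features_as_epochset(feats, eset)
    # split indices must match: rebuild subsets by provenance-free position
    def flat(s: EpochSet):
        return s.epochs.reshape(s.n_epochs, -1), s.labels

    results = {}
    for name, clf in _sklearn_baselines(cfg.seed).items():
        row = {}
        for col, (a, b, c) in (
            ("feature_learning", (tr, va, te)),
            ("handcrafted", tuple(split_epochs(f_all, cfg))),
        ):
            Xtr, ytr = flat(a)
            Xte, yte = flat(c)
            clf.fit(np.vstack([Xtr, flat(b)[0]]), np.r_[ytr, flat(b)[1]])
            row[col] = float(clf.score(Xte, yte))
        results[name] = row

    # DFCGN on raw epochs
    model = _fit_dfcgn(tr, va, cfg, model_cfg, G)
    raw_acc = evaluate(model, te).accuracy
    # DFCGN on the 6-feature table: shallow ledger on width 6
    f_tr, f_va, f_te = split_epochs(f_all, cfg)
    f_cfg = DFCGNConfig(
        layer_widths=(6, 6, 3), cheb_orders=(3, 3),
        n_nodes=eset.n_channels, dropout_rate=model_cfg.dropout_rate,
        ft2_as_leaky=model_cfg.ft2_as_leaky,
    )
    f_model = _fit_dfcgn(f_tr, f_va, cfg, f_cfg, G)
    hc_acc = evaluate(f_model, f_te).accuracy
    results["DFCGN"] = {"feature_learning": raw_acc, "handcrafted": hc_acc}

    return pd.DataFrame(results).T[["feature_learning", "handcrafted"]]


# ---------------------------------------------------------------------------
# SNR robustness


def add_noise_at_snr(
    epochs: np.ndarray, snr_db: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive white Gaussian noise scaled per epoch to the stated SNR."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    X = np.asarray(epochs, dtype=float)
    p_sig = np.mean(X ** 2, axis=(1, 2), keepdims=True)
    p_noise = p_sig / 10.0 ** (snr_db / 10.0)
    return X + np.sqrt(p_noise) * rng.standard_normal(X.shape)


def snr_sweep(
    model: DFCGN,
    test_set: EpochSet,
    snr_db_list: Sequence[Optional[float]],
    seed: int = 0,
    n_noise_seeds: int = 5,
) -> pd.DataFrame:
    """Accuracy of a clean-trained model on noise-corrupted test epochs.

    Each SNR is averaged over ``n_noise_seeds`` independent noise draws;
    ``None`` (or +inf) in the list means no added noise and reproduces the
    clean accuracy exactly.
    """
    if not len(snr_db_list):
        raise ValueError("snr_db_list must be non-empty")
    rows = []
    for snr in snr_db_list:
        if snr is None or (isinstance(snr, float) and np.isinf(snr)):
            acc = evaluate(model, test_set).accuracy
            rows.append({"snr_db": np.inf, "accuracy": acc, "accuracy_sd": 0.0})
            continue
        accs = []
        for k in range(n_noise_seeds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, int(1e6 + k)]))
            noisy = add_noise_at_snr(test_set.epochs, float(snr), rng)
            probs = model.predict_proba(noisy)
            accs.append(float((probs.argmax(1) == test_set.labels).mean()))
        rows.append({"snr_db": float(snr), "accuracy": float(np.mean(accs)),
                     "accuracy_sd": float(np.std(accs))})
    return pd.DataFrame(rows)
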