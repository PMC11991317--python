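"""Training protocol, metrics, cross-validation, ablations, noise sweeps.

Metrics follow the standard confusion-table definitions (accuracy,
sensitivity, specificity, precision, F1) plus the kappa coefficient in two
forms: the uniform-chance form (N*p - 1)/(N - 1) and the marginal (Cohen)
form computed from the confusion-table marginals. The marginal form is the
default reported column.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import (StratifiedGroupKFold, StratifiedKFold,
                                     train_test_split)

from .model import MSDSANet, ModelConfig
from .layers import SGD
from .preprocessing import inject_noise, preprocess_trials, stack_samples


# ------------------------------------------------------------------- metrics
@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts; positive class is 1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> dict:
    """acc, SN (recall), SP, P (precision) and F1 from confusion counts."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / counts.total
    sn = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    sp = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    p = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    if np.isnan(p) or np.isnan(sn) or (p + sn) == 0:
        warnings.warn("F1 undefined; reported as NaN")
        f1 = float("nan")
    else:
        f1 = 2 * p * sn / (p + sn)
    return {"acc": acc, "sn": sn, "sp": sp, "precision": p, "f1": f1}


def kappa(p: float, n_classes: int = 2) -> float:
    """Uniform-chance kappa (N*p - 1)/(N - 1); for N = 2 this is 2p - 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {p}")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return (n_classes * p - 1.0) / (n_classes - 1.0)


def kappa_marginal(counts: ConfusionCounts) -> float:
    """Cohen's kappa with chance agreement from the table marginals."""
    n = counts.total
    if n == 0:
        raise ValueError("empty confusion table")
    po = (counts.tp + counts.tn) / n
    pe = ((counts.tp + counts.fn) * (counts.tp + counts.fp)
          + (counts.tn + counts.fp) * (counts.tn + counts.fn)) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


# ------------------------------------------------------------------- training
@dataclass
class TrainingConfig:
    """SGD hyperparameters. Defaults follow the full-scale protocol
    (lr 1e-5, batch 64, 40 epochs; 30 epochs for DREAMER-style data).
    reduced() is the preset for the small synthetic-data models, where the
    tiny widths tolerate — and the short budget needs — a much larger step.
    """

    lr: float = 1e-5
    batch_size: int = 64
    epochs: int = 40
    seed: int = 0
    shuffle: bool = True

    @classmethod
    def dreamer(cls, **kw) -> "TrainingConfig":
        kw.setdefault("epochs", 30)
        return cls(**kw)

    @classmethod
    def reduced(cls, **kw) -> "TrainingConfig":
        kw.setdefault("lr", 0.02)
        kw.setdefault("batch_size", 32)
        kw.setdefault("epochs", 20)
        return cls(**kw)


def _model_inputs(model: MSDSANet, arrays: dict, idx=None) -> dict:
    """Only the inputs of enabled streams; disabled inputs are never read."""
    cfg = model.cfg
    sel = (lambda a: a if idx is None else a[idx])
    out = {}
    if cfg.use_temporal_stream:
        out["eeg"] = sel(arrays["eeg"])
    if cfg.use_grid_stream:
        out["grid"] = sel(arrays["grid"])
    if cfg.use_dsanet:
        out["periph"] = sel(arrays["periph"])
    return out


def train(model: MSDSANet, arrays: dict, hyper: TrainingConfig) -> list[float]:
    """Mini-batch SGD on the cross-entropy loss; returns the per-epoch loss trace.

    Samples are reshuffled every epoch; with a fixed seed the run is
    bit-reproducible.
    """
    labels = np.asarray(arrays["label"], dtype=int)
    n = labels.size
    if n < 1:
        raise ValueError("empty training set")
    onehot = np.eye(model.cfg.n_classes)[labels]
    rng = np.random.default_rng(hyper.seed)
    opt = SGD(model.parameters(), hyper.lr)
    model.train()
    trace = []
    for _ in range(hyper.epochs):
        order = rng.permutation(n) if hyper.shuffle else np.arange(n)
        total = 0.0
        for a in range(0, n, hyper.batch_size):
            b = order[a:a + hyper.batch_size]
            loss = model.loss(onehot[b], **_model_inputs(model, arrays, b))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * b.size
        trace.append(total / n)
    model.eval()
    return trace


def predict(model: MSDSANet, arrays: dict, batch_size: int = 256) -> np.ndarray:
    n = len(arrays["label"])
    preds = []
    for a in range(0, n, batch_size):
        idx = np.arange(a, min(a + batch_size, n))
        preds.append(model.predict(**_model_inputs(model, arrays, idx)))
    return np.concatenate(preds)


def _fold_row(y_true, y_pred) -> dict:
    counts = confusion(y_true, y_pred)
    row = metrics(counts)
    row["kappa"] = kappa_marginal(counts)
    row["kappa_uniform"] = kappa(row["acc"], 2)
    return row


# ------------------------------------------------------------------ reporting
@dataclass
class EvalReport:
    """Per-fold metric rows plus mean +/- sd aggregates."""

    affect_dimension: str
    folds: list = field(default_factory=list)      # list of dicts
    config_fingerprint: str = ""
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def aggregate(self) -> dict:
        df = pd.DataFrame(self.folds)
        return {c: {"mean": float(df[c].mean()), "sd": float(df[c].std(ddof=0))}
                for c in df.columns}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def to_json(self, path=None):
        payload = {"affect_dimension": self.affect_dimension,
                   "config_fingerprint": self.config_fingerprint,
                   "seed": self.seed, "folds": self.folds,
                   "aggregate": self.aggregate(), "extra": self.extra}
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="fold")


def config_fingerprint(cfg: ModelConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------------ evaluation runs
def _grouped_holdout_indices(labels, groups, test_frac: float, seed: int):
    """Class-stratified holdout of whole trials (groups)."""
    rng = np.random.default_rng(seed)
    group_label = {g: int(round(labels[groups == g].mean()))
                   for g in np.unique(groups)}
    test_groups = []
    for cls in sorted(set(group_label.values())):
        gs = sorted(g for g, lab in group_label.items() if lab == cls)
        gs = [gs[i] for i in rng.permutation(len(gs))]
        n_te = max(int(round(test_frac * len(gs))), 1)
        test_groups.extend(gs[:n_te])
    te_mask = np.isin(groups, test_groups)
    return np.flatnonzero(~te_mask), np.flatnonzero(te_mask)


def run_subject_cv(samples, model_cfg: ModelConfig, hyper: TrainingConfig,
                   k: int = 10, affect_dimension: str = "",
                   split: str = "window") -> EvalReport:
    """Stratified k-fold cross-validation for one subject.

    The default split is a seeded stratified shuffle of windows, mirroring
    protocols that shuffle samples before folding. Window-level splitting can
    place windows of the same trial in both train and test folds, which
    inflates accuracy whenever trials carry identifiable signatures;
    split="trial" keeps each trial's windows in a single fold instead.
    """
    arrays = samples if isinstance(samples, dict) else stack_samples(samples)
    labels = arrays["label"]
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2 or counts.min() < k:
        raise ValueError(f"need >= {k} samples of each class for {k}-fold CV")
    if split == "trial":
        skf = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                   random_state=hyper.seed)
        fold_iter = skf.split(np.zeros(labels.size), labels,
                              groups=arrays["trial"])
    elif split == "window":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=hyper.seed)
        fold_iter = skf.split(np.zeros(labels.size), labels)
    else:
        raise ValueError(f"split must be 'window' or 'trial', got {split!r}")
    report = EvalReport(affect_dimension=affect_dimension, seed=hyper.seed,
                        config_fingerprint=config_fingerprint(model_cfg))
    for fold, (tr, te) in enumerate(fold_iter):
        if np.unique(labels[tr]).size < 2:
            raise ValueError(f"fold {fold}: a class is absent from the training split")
        model = MSDSANet(model_cfg)
        sub = {key: val[tr] for key, val in arrays.items()}
        train(model, sub, hyper)
        y_pred = predict(model, {key: val[te] for key, val in arrays.items()})
        report.folds.append(_fold_row(labels[te], y_pred))
    return report


def evaluate_holdout(samples, model_cfg: ModelConfig, hyper: TrainingConfig,
                     test_frac: float = 0.25, affect_dimension: str = "",
                     split: str = "window") -> tuple[EvalReport, MSDSANet]:
    """Single stratified train/test split; returns the report and the model.

    split="window" shuffles windows; split="trial" holds out whole trials
    (no window of a test trial is seen in training).
    """
    arrays = samples if isinstance(samples, dict) else stack_samples(samples)
    labels = arrays["label"]
    if split == "trial":
        if "trial" not in arrays:
            raise ValueError("trial-grouped split needs the 'trial' array")
        tr, te = _grouped_holdout_indices(labels, arrays["trial"], test_frac,
                                          hyper.seed)
    elif split == "window":
        idx = np.arange(labels.size)
        tr, te = train_test_split(idx, test_size=test_frac, stratify=labels,
                                  random_state=hyper.seed)
    else:
        raise ValueError(f"split must be 'window' or 'trial', got {split!r}")
    model = MSDSANet(model_cfg)
    trace = train(model, {key: val[tr] for key, val in arrays.items()}, hyper)
    y_pred = predict(model, {key: val[te] for key, val in arrays.items()})
    report = EvalReport(affect_dimension=affect_dimension, seed=hyper.seed,
                        config_fingerprint=config_fingerprint(model_cfg),
                        folds=[_fold_row(labels[te], y_pred)],
                        extra={"loss_trace": trace, "n_train": int(tr.size),
                               "n_test": int(te.size), "split": split})
    return report, model


def noise_sweep(trials, dimension: str, threshold: float,
                model_cfg: ModelConfig, hyper: TrainingConfig,
                snr_list=(10.0, 0.0, -5.0), layout=None, seed: int = 0,
                include_peripheral: bool = False, test_frac: float = 0.25,
                split: str = "window") -> list[tuple[float, EvalReport]]:
    """Accuracy under additive Gaussian noise at several SNRs.

    For each SNR (the no-noise reference first) the EEG channels of every
    trial — train and test alike — are corrupted, the standard preprocessing
    and holdout protocol is re-run, and the report collected.
    """
    results = []
    for i, snr in enumerate([np.inf, *snr_list]):
        rng = np.random.default_rng(seed + i)
        noisy = [inject_noise(t, snr, seed=rng,
                              include_peripheral=include_peripheral)
                 for t in trials]
        samples = preprocess_trials(noisy, dimension, threshold, layout=layout)
        report, _ = evaluate_holdout(samples, model_cfg, hyper,
                                     test_frac=test_frac,
                                     affect_dimension=dimension, split=split)
        report.extra["snr_db"] = None if np.isinf(snr) else float(snr)
        results.append((float(snr), report))
    return results


# ---------------------------------------------------------------- embeddings
def embed_features(features: np.ndarray, seed: int = 0,
                   perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE embedding of an [n, d] feature matrix; seeded."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 feature vectors, got {n}")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(features)


def plot_embedding(coords: np.ndarray, labels, path, title: str = "") -> None:
    """Scatter plot of a 2-D embedding colored by binary label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color, name in ((0, "tab:green", "low"), (1, "tab:red", "high")):
        m = labels == cls
        ax.scatter(coords[m, 0], coords[m, 1], s=8, c=color, label=name, alpha=0.7)
    ax.legend(frameon=False)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
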