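"""Subject-dependent training and evaluation.

The central objects follow the model/results convention of statistical
modelling packages:

* :class:`EmotionClassifier` — a model bound to one subject's feature
  tensors and a :class:`~eegemotion.labels.LabelScheme`; constructed from a
  feature store (:meth:`EmotionClassifier.from_hdf5`) or directly from a
  recording (:meth:`EmotionClassifier.from_recording`).
* :meth:`EmotionClassifier.fit` — runs the subject-dependent k-fold
  protocol (segment-level shuffled 5-fold by default; trial-level split
  available), trains a fresh network per fold with AdamW / cross-entropy,
  evaluates the held-out fold, and returns an
  :class:`EmotionClassifierResults` carrying per-fold confusion matrices,
  macro metrics and a ``summary()`` table.
* :class:`MetricsReport` — the aggregate over subjects (mean +- std over
  subjects of per-subject fold means), as produced by
  :func:`run_experiment`.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from . import nn
from .features import (ChannelLayout, assemble_tensors, compute_de_features,
                       load_feature_tensors, normalize_de)
from .io import EEGRecording
from .labels import LabelScheme
from .metrics import METRIC_NAMES, confusion_matrix, macro_metrics
from .network import GridTransformerNet, ModelConfig

__all__ = [
    "TrainConfig",
    "EmotionClassifier",
    "EmotionClassifierResults",
    "MetricsReport",
    "kfold_split",
    "run_experiment",
]


@dataclass
class TrainConfig:
    """Optimisation settings (AdamW, cross-entropy, fixed epoch count)."""

    batch_size: int = 240
    learning_rate: float = 1e-3
    epochs: int = 100
    folds: int = 5
    seed: int = 0
    weight_decay: float = 0.01

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.learning_rate) <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def kfold_split(n_samples: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold test-index sets partitioning range(n_samples)."""
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n_samples))]


def _train_network(net: GridTransformerNet, X: np.ndarray, y: np.ndarray,
                   cfg: TrainConfig, rng: np.random.Generator) -> list[float]:
    params = net.parameters()
    opt = nn.AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history = []
    n = len(X)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward(X[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return history


def _predict(net: GridTransformerNet, X: np.ndarray, batch_size: int) -> np.ndarray:
    preds = []
    for start in range(0, len(X), batch_size):
        logits = net.forward(X[start:start + batch_size])
        preds.append(np.argmax(logits, axis=-1))
    return np.concatenate(preds)


class EmotionClassifier:
    """One subject's grid-feature classifier under a label scheme."""

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 scheme: LabelScheme, model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 subject_id: str = "subject", trial_ids: np.ndarray | None = None):
        features = np.asarray(features, dtype=np.float32)
        labels = np.asarray(labels, dtype=np.int64)
        if features.ndim != 4:
            raise ValueError("features must be (n, C, H, W)")
        if len(features) != len(labels):
            raise ValueError("features and labels differ in length")
        self.scheme = scheme
        if model_config is None:
            model_config = ModelConfig(n_classes=scheme.n_classes,
                                       C=features.shape[1],
                                       H=features.shape[2], W=features.shape[3])
        if model_config.n_classes != scheme.n_classes:
            raise ValueError(
                f"model head has {model_config.n_classes} classes but the label "
                f"scheme produces {scheme.n_classes}")
        if features.shape[1:] != (model_config.C, model_config.H, model_config.W):
            raise ValueError(
                f"feature shape {features.shape[1:]} does not match model config "
                f"{(model_config.C, model_config.H, model_config.W)}")
        self.features = features
        self.labels = labels
        self.model_config = model_config
        self.train_config = train_config or TrainConfig()
        self.subject_id = subject_id
        self.trial_ids = (np.asarray(trial_ids, dtype=np.int64)
                          if trial_ids is not None else None)
        # populated only under the fold-strict normalisation protocol
        self._strict: tuple | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_hdf5(cls, path, scheme: LabelScheme,
                  model_config: ModelConfig | None = None,
                  train_config: TrainConfig | None = None) -> "EmotionClassifier":
        feats, ratings, prov, meta = load_feature_tensors(path)
        labels = scheme.labels(ratings)
        return cls(feats, labels, scheme, model_config, train_config,
                   subject_id=str(meta.get("subject_id", Path(path).stem)),
                   trial_ids=prov[:, 0])

    @classmethod
    def from_recording(cls, rec: EEGRecording, layout: ChannelLayout,
                       scheme: LabelScheme, feature_set: str = "both",
                       model_config: ModelConfig | None = None,
                       train_config: TrainConfig | None = None,
                       enhancement: str = "inside",
                       strict_normalization: bool = False) -> "EmotionClassifier":
        """Extract features in memory and bind them to the scheme.

        With ``strict_normalization`` the per channel x band min/max are
        recomputed from the training folds only inside :meth:`fit` (held-out
        values are clipped to [0, 1]); the default uses the subject's whole
        session, mirroring the usual whole-session protocol.
        """
        de, segments = compute_de_features(rec)
        ratings = np.array([[seg.ratings.get(d, np.nan)
                             for d in ("valence", "arousal", "dominance")]
                            for seg in segments])
        labels = scheme.labels(ratings)
        trial_ids = np.array([seg.trial_id for seg in segments])
        norm = normalize_de(de)
        tensors = assemble_tensors(norm, segments, rec.channel_names, layout,
                                   feature_set=feature_set, enhancement=enhancement)
        feats = np.stack([t.values for t in tensors])
        obj = cls(feats, labels, scheme, model_config, train_config,
                  subject_id=rec.subject_id, trial_ids=trial_ids)
        if strict_normalization:
            obj._strict = (de, segments, tuple(rec.channel_names), layout,
                           feature_set, enhancement)
        return obj

    # -- fitting -----------------------------------------------------------
    def _fold_features(self, train_idx: np.ndarray) -> np.ndarray:
        if self._strict is None:
            return self.features
        de, segments, names, layout, feature_set, enhancement = self._strict
        norm = normalize_de(de, stats_de=de[train_idx])
        tensors = assemble_tensors(norm, segments, names, layout,
                                   feature_set=feature_set,
                                   enhancement=enhancement)
        return np.stack([t.values for t in tensors]).astype(np.float32)

    def _splits(self) -> list[np.ndarray]:
        cfg = self.train_config
        return kfold_split(len(self.features), k=cfg.folds, seed=cfg.seed)

    def fit(self, split_by: str = "segment", verbose: bool = False
            ) -> "EmotionClassifierResults":
        """Run k-fold cross-validated training and score held-out folds.

        ``split_by='trial'`` shuffles whole trials into folds instead of
        individual segments (the stricter protocol).
        """
        cfg = self.train_config
        k = cfg.folds
        n = len(self.features)
        if split_by == "segment":
            test_sets = self._splits()
        elif split_by == "trial":
            if self.trial_ids is None:
                raise ValueError("trial-level split needs trial provenance")
            uniq = np.unique(self.trial_ids)
            trial_folds = kfold_split(len(uniq), k=k, seed=cfg.seed)
            test_sets = [np.flatnonzero(np.isin(self.trial_ids, uniq[f]))
                         for f in trial_folds]
        else:
            raise ValueError("split_by must be 'segment' or 'trial'")

        confusions, histories, fold_seconds = [], [], []
        nets = []
        for fold, test_idx in enumerate(test_sets):
            t0 = time.perf_counter()
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            X = self._fold_features(train_idx)
            net = GridTransformerNet(
                ModelConfig(**{**asdict(self.model_config),
                               "seed": self.model_config.seed + fold}))
            rng = np.random.default_rng(cfg.seed + 7919 * (fold + 1))
            hist = _train_network(net, X[train_idx], self.labels[train_idx],
                                  cfg, rng)
            y_pred = _predict(net, X[test_idx], cfg.batch_size)
            cm = confusion_matrix(self.labels[test_idx], y_pred,
                                  self.scheme.n_classes)
            confusions.append(cm)
            histories.append(hist)
            nets.append(net)
            fold_seconds.append(time.perf_counter() - t0)
            if verbose:
                acc = macro_metrics(cm)["macro"]["accuracy"]
                print(f"[{self.subject_id}] fold {fold + 1}/{k}: "
                      f"macro accuracy {acc:.4f} "
                      f"({fold_seconds[-1]:.1f} s)")
        return EmotionClassifierResults(
            subject_id=self.subject_id, scheme=self.scheme,
            model_config=self.model_config, train_config=cfg,
            confusions=confusions, loss_histories=histories,
            fold_seconds=fold_seconds, nets=nets)


class EmotionClassifierResults:
    """Per-fold confusions and macro metrics for one subject."""

    def __init__(self, subject_id, scheme, model_config, train_config,
                 confusions, loss_histories, fold_seconds, nets=None):
        self.subject_id = subject_id
        self.scheme = scheme
        self.model_config = model_config
        self.train_config = train_config
        self.confusions = [np.asarray(c) for c in confusions]
        self.loss_histories = loss_histories
        self.fold_seconds = fold_seconds
        self.nets = nets or []
        self.fold_metrics = [macro_metrics(c) for c in self.confusions]

    # -- aggregates --------------------------------------------------------
    def metric(self, name: str) -> np.ndarray:
        """Per-fold values of one macro metric."""
        return np.array([m["macro"][name] for m in self.fold_metrics])

    @property
    def mean_metrics(self) -> dict[str, float]:
        return {m: float(self.metric(m).mean()) for m in METRIC_NAMES}

    @property
    def std_metrics(self) -> dict[str, float]:
        return {m: float(self.metric(m).std(ddof=0)) for m in METRIC_NAMES}

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(self.confusions, axis=0)

    def degenerate_classes(self) -> list[int]:
        flagged = set()
        for m in self.fold_metrics:
            flagged.update(m["degenerate_classes"])
        return sorted(flagged)

    def summary(self) -> str:
        lines = [
            f"Subject-dependent results: {self.subject_id}",
            f"scheme={self.scheme.mode} dims={'/'.join(self.scheme.dimensions)} "
            f"classes={self.scheme.n_classes} "
            f"variant={self.model_config.encoder_variant} "
            f"folds={self.train_config.folds} epochs={self.train_config.epochs}",
            "-" * 64,
            f"{'metric':<14}" + "".join(f"{'fold ' + str(i + 1):>9}"
                                        for i in range(len(self.confusions)))
            + f"{'mean':>9}{'std':>8}",
        ]
        for m in METRIC_NAMES:
            vals = self.metric(m)
            lines.append(f"{m:<14}" + "".join(f"{v:>9.4f}" for v in vals)
                         + f"{vals.mean():>9.4f}{vals.std(ddof=0):>8.4f}")
        deg = self.degenerate_classes()
        if deg:
            lines.append(f"degenerate classes (no support in some fold): {deg}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "scheme": {"mode": self.scheme.mode,
                       "dimensions": list(self.scheme.dimensions),
                       "n_classes": self.scheme.n_classes},
            "per_fold": [{"confusion": c.tolist(),
                          "macro": m["macro"],
                          "test_size": int(c.sum())}
                         for c, m in zip(self.confusions, self.fold_metrics)],
            "mean": self.mean_metrics,
            "std": self.std_metrics,
            "degenerate_classes": self.degenerate_classes(),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{self.subject_id}_report.json").write_text(
            json.dumps(self.to_dict(), indent=2))
        for i, cm in enumerate(self.confusions):
            np.savetxt(out / f"{self.subject_id}_fold{i + 1}_confusion.csv",
                       cm, fmt="%d", delimiter=",")

    def plot_confusion(self, fold: int | None = None, ax=None):
        """Heatmap of one fold's (or the pooled) confusion matrix."""
        import matplotlib.pyplot as plt

        cm = self.pooled_confusion if fold is None else self.confusions[fold]
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xlabel("predicted class")
        ax.set_ylabel("true class")
        ax.figure.colorbar(im, ax=ax)
        return ax


class MetricsReport:
    """Aggregate over subjects: mean +- std of per-subject fold means."""

    def __init__(self, subject_results: list[EmotionClassifierResults]):
        if not subject_results:
            raise ValueError("no subject results to aggregate")
        self.subject_results = subject_results

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for m in METRIC_NAMES:
            per_subject = np.array([r.mean_metrics[m] for r in self.subject_results])
            out[m] = (float(per_subject.mean()), float(per_subject.std(ddof=0)))
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"Aggregate over {len(self.subject_results)} subject(s) "
                 f"(mean +- std of per-subject fold means)", "-" * 48]
        for m, (mu, sd) in agg.items():
            lines.append(f"{m:<14}{100 * mu:>8.2f} +- {100 * sd:.2f} %")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"subjects": [r.to_dict() for r in self.subject_results],
                "aggregate": {m: {"mean": mu, "std": sd}
                              for m, (mu, sd) in self.aggregate().items()}}

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2))
        import csv
        with open(out / "summary.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "mean", "std"])
            for m, (mu, sd) in self.aggregate().items():
                w.writerow([m, f"{mu:.6f}", f"{sd:.6f}"])


def run_experiment(feature_paths, scheme: LabelScheme,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   split_by: str = "segment", verbose: bool = False) -> MetricsReport:
    """Fit one classifier per subject feature store and aggregate."""
    if isinstance(feature_paths, (str, Path)):
        feature_paths = [feature_paths]
    results = []
    for path in feature_paths:
        model = EmotionClassifier.from_hdf5(path, scheme,
                                            model_config=model_config,
                                            train_config=train_config)
        results.append(model.fit(split_by=split_by, verbose=verbose))
    return MetricsReport(results)
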