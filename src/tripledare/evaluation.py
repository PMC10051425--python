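"""Target-domain metrics and benchmark reporting.

Multi-label predictions are scored as N x L independent binary decisions:
accuracy is the pooled fraction of correct decisions, micro-F1 pools
TP/FP/FN over all decisions, and per-label F1 is computed per column (0 by
convention when a label has neither positive truth nor positive
predictions).  Embedding quality is summarized by a silhouette compactness
score: for each binary label, instances are clustered into {positive,
negative} and the mean silhouette s_i = (b_i - a_i) / max(a_i, b_i) is
computed; the final score averages over labels with at least two members in
each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import f1_score

from .datasets import DomainDataset
from .features import handcrafted_features_batch, zscore_apply


@dataclass
class MetricsReport:
    accuracy: float
    f1_micro: float
    per_label_f1: dict[str, float]
    silhouette_mean: float | None = None
    method: str = ""
    seed: int = 0
    config_hash: str = ""
    extras: dict = field(default_factory=dict)


def multilabel_metrics(pred: np.ndarray, truth: np.ndarray,
                       label_names: list[str] | None = None) -> MetricsReport:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for arr in (pred, truth):
        if np.any((arr != 0) & (arr != 1)):
            raise ValueError("predictions and truth must be binary")
    accuracy = float((pred == truth).mean())
    f1_micro = float(f1_score(truth, pred, average="micro", zero_division=0))
    per_label = f1_score(truth, pred, average=None, zero_division=0)
    per_label = np.atleast_1d(per_label)
    names = label_names or [f"label_{i}" for i in range(truth.shape[1])]
    return MetricsReport(
        accuracy=accuracy, f1_micro=f1_micro,
        per_label_f1={n: float(v) for n, v in zip(names, per_label)})


def silhouette_compactness(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean per-label binary-cluster silhouette of an embedding set.

    Labels whose positive or negative cluster has fewer than two members are
    skipped; identical points score 0 (the 0/0 convention).
    """
    X = np.asarray(embeddings, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(labels))
    if Y.shape[0] == 1 and X.shape[0] > 1:
        Y = Y.T
    if X.shape[0] < 4:
        raise ValueError("silhouette needs at least four instances")
    D = cdist(X, X)
    scores = []
    for l in range(Y.shape[1]):
        y = Y[:, l].astype(bool)
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos < 2 or n_neg < 2:
            continue
        s = np.empty(len(X))
        for cluster, other, n_c in ((y, ~y, n_pos), (~y, y, n_neg)):
            a = D[np.ix_(cluster, cluster)].sum(axis=1) / (n_c - 1)  # excl. self
            b = D[np.ix_(cluster, other)].mean(axis=1)
            denom = np.maximum(a, b)
            s[cluster] = np.where(denom > 0, (b - a) / np.maximum(denom, 1e-300), 0.0)
        scores.append(float(s.mean()))
    if not scores:
        raise ValueError("no label has two members in both clusters")
    return float(np.mean(scores))


def evaluate_model(model, dataset: DomainDataset, method: str = "", seed: int = 0,
                   threshold: float = 0.5, silhouette_subsample: int = 1000) -> MetricsReport:
    """Score a trained dual-view model on every sample of a labeled dataset.

    Features are normalized with the model's stored source-fitted statistics;
    the caller's dataset is not mutated.  Silhouette is computed on the fused
    embeddings over a seeded subsample (for tractable pairwise distances).
    """
    feats = dataset.features
    if feats is None:
        feats = handcrafted_features_batch(dataset.raw, dataset.aux)
    feats = zscore_apply(feats, model.norm_stats)
    probs, fused = model.predict_numpy(feats.astype(np.float32),
                                       dataset.raw.astype(np.float32))
    pred = (probs >= threshold).astype(np.int8)
    truth = dataset.labels
    report = multilabel_metrics(pred, truth, dataset.label_names)
    idx = np.arange(len(fused))
    if len(idx) > silhouette_subsample:
        rng = np.random.default_rng([seed % (2 ** 31), 31])
        idx = np.sort(rng.choice(idx, silhouette_subsample, replace=False))
    try:
        report.silhouette_mean = silhouette_compactness(fused[idx], truth[idx])
    except ValueError:
        report.silhouette_mean = None
    report.method = method
    report.seed = seed
    return report


def benchmark_report(runs: list[MetricsReport]) -> dict[str, pd.DataFrame]:
    """Aggregate per-run metrics into per-seed and mean tables."""
    if not runs:
        raise ValueError("benchmark_report needs at least one run")
    rows = [dict(method=r.method, seed=r.seed, accuracy=r.accuracy,
                 f1_micro=r.f1_micro, silhouette=r.silhouette_mean)
            for r in runs]
    per_seed = pd.DataFrame(rows)
    mean = (per_seed.drop(columns="seed")
            .groupby("method", sort=False).mean(numeric_only=True).reset_index())
    return {"per_seed": per_seed, "mean": mean}


def write_report(tables: dict[str, pd.DataFrame], out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        df.to_json(out / f"{name}.json", orient="records", indent=2)
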