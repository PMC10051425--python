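"""Joint-fusion online triplet mining over source + pseudo-labeled target batches.

A triplet (a, p, n) over the concatenated mini-batch is *mined* when

    d(x_a, x_p) + alpha > d(x_a, x_n)   and   c(y_a, y_p) > c(y_a, y_n)

with pairwise-distinct indices, Euclidean distance on the joint-fusion
embedding, and c the multi-label compatibility score (count of shared
positive labels; the condition implies c(y_a, y_p) >= 1).  Target rows carry
pseudo-labels from the current classifier, source rows their true labels.

Two implementations are provided: :func:`mine_triplets` enumerates the exact
triplet set (used for analysis and small batches), while
:func:`triplet_loss_terms` computes the mined-triplet mean hinge loss and its
gradient coefficients over pairwise distances without materializing the
triplet list, which keeps large training batches cheap.  The two agree by
construction and are cross-checked in the test suite.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class Triplet(NamedTuple):
    a: int
    p: int
    n: int


def assign_pseudo_labels(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold classifier probabilities into binary pseudo-labels (>= rule)."""
    return (np.asarray(probs) >= threshold).astype(np.int8)


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    return D


def compatibility_matrix(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must be binary")
    return labels.astype(np.int64) @ labels.astype(np.int64).T


def _mined_mask(D: np.ndarray, C: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean [B, B, B] tensor over (a, p, n) of the mining condition."""
    B = D.shape[0]
    cond = (D[:, :, None] + alpha > D[:, None, :]) & (C[:, :, None] > C[:, None, :])
    cond &= C[:, :, None] >= 1
    eye = np.eye(B, dtype=bool)
    cond &= ~eye[:, :, None]   # p != a
    cond &= ~eye[:, None, :]   # n != a
    cond &= ~eye[None, :, :]   # n != p
    return cond


def mine_triplets(embeddings: np.ndarray, labels: np.ndarray, alpha: float,
                  per_anchor_cap: int | None = None,
                  rng: np.random.Generator | None = None,
                  distances: np.ndarray | None = None) -> list[Triplet]:
    """Exact mined-triplet set, in lexicographic (a, p, n) order.

    ``per_anchor_cap`` uniformly subsamples each anchor's triplets (seeded
    ``rng`` required); order stays lexicographic after subsampling.
    """
    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels)
    if embeddings.shape[0] != labels.shape[0]:
        raise ValueError("embeddings and labels must have the same batch size")
    if not np.all(np.isfinite(embeddings)):
        raise ValueError("embeddings must be finite")
    if alpha < 0:
        raise ValueError("margin must be non-negative")
    D = pairwise_distances(embeddings) if distances is None else distances
    C = compatibility_matrix(labels)
    mask = _mined_mask(D, C, alpha)
    idx = np.argwhere(mask)  # row-major => lexicographic in (a, p, n)
    if per_anchor_cap is not None:
        if rng is None:
            raise ValueError("per_anchor_cap requires a seeded rng")
        keep: list[np.ndarray] = []
        for a in np.unique(idx[:, 0]):
            rows = np.flatnonzero(idx[:, 0] == a)
            if rows.size > per_anchor_cap:
                rows = np.sort(rng.choice(rows, per_anchor_cap, replace=False))
            keep.append(rows)
        idx = idx[np.concatenate(keep)] if keep else idx
    return [Triplet(int(a), int(p), int(n)) for a, p, n in idx]


def triplet_loss_terms(d_fused: np.ndarray, compat: np.ndarray, alpha: float,
                       layer_distances: list[np.ndarray],
                       block: int = 64) -> tuple[list[np.ndarray], list[float], int]:
    """Per-layer gradient coefficients of the mined-triplet mean hinge loss.

    Mining runs on the fused distances ``d_fused``; the loss of layer l is
    ``mean over mined triplets of [D_l(a,p) - D_l(a,n) + alpha]_+``, i.e.
    ``sum(W_l * D_l) + alpha * n_active_l / n_mined`` where ``W_l`` counts
    (+1/n_mined) active (a,p) pairs and (-1/n_mined) active (a,n) pairs.

    Returns ``(W_layers, const_layers, n_mined)``; the loss of layer l is
    ``(W_layers[l] * D_l).sum() + const_layers[l]``.  Anchors are processed in
    blocks to bound the [block, B, B] working set.
    """
    B = d_fused.shape[0]
    C = np.ascontiguousarray(compat, dtype=np.int16)
    not_eye = ~np.eye(B, dtype=bool)
    n_layers = len(layer_distances)
    W = [np.zeros((B, B)) for _ in range(n_layers)]
    active_counts = [0] * n_layers
    n_mined = 0
    fused_is_layer = [Dl is d_fused for Dl in layer_distances]
    for start in range(0, B, block):
        sl = slice(start, min(start + block, B))
        dF = d_fused[sl]
        mined = (dF[:, :, None] + alpha) > dF[:, None, :]
        mined &= C[sl][:, :, None] > C[sl][:, None, :]
        mined &= not_eye[sl][:, :, None]   # p != a
        mined &= not_eye[sl][:, None, :]   # n != a
        mined &= not_eye[None, :, :]       # n != p
        n_mined += int(mined.sum())
        for li, Dl in enumerate(layer_distances):
            if fused_is_layer[li]:
                active = mined  # the hinge condition *is* the fused mining condition
            else:
                dl = Dl[sl]
                active = mined & ((dl[:, :, None] + alpha) > dl[:, None, :])
            cnt_p = active.sum(axis=2)
            cnt_n = active.sum(axis=1)
            W[li][sl] += cnt_p
            W[li][sl] -= cnt_n
            active_counts[li] += int(cnt_p.sum())
    if n_mined == 0:
        return [np.zeros((B, B)) for _ in range(n_layers)], [0.0] * n_layers, 0
    consts = [alpha * ac / n_mined for ac in active_counts]
    return [w / n_mined for w in W], consts, n_mined


def build_joint_batch(source_batch: tuple[np.ndarray, np.ndarray, np.ndarray],
                      target_batch: tuple[np.ndarray, np.ndarray],
                      classifier, threshold: float = 0.5):
    """Concatenate a labeled source batch with a pseudo-labeled target batch.

    ``source_batch`` is (features, raw, labels); ``target_batch`` is
    (features, raw).  ``classifier`` maps (features, raw) to fused embeddings
    and label probabilities (the dual-view model's ``predict`` contract).
    Returns (fused embeddings [2m, D], labels [2m, L], source mask [2m]).
    """
    feat_s, raw_s, y_s = source_batch
    feat_t, raw_t = target_batch
    if len(feat_s) == 0 or len(feat_t) == 0:
        raise ValueError("batches must be non-empty")
    emb_s, probs_s = classifier(feat_s, raw_s)
    emb_t, probs_t = classifier(feat_t, raw_t)
    y_t = assign_pseudo_labels(probs_t, threshold)
    embeddings = np.concatenate([emb_s, emb_t], axis=0)
    labels = np.concatenate([np.asarray(y_s, dtype=np.int8), y_t], axis=0)
    mask = np.zeros(len(embeddings), dtype=bool)
    mask[:len(emb_s)] = True
    return embeddings, labels, mask
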