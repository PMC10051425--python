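"""The three training objectives plus the CORAL baseline loss.

Total cost: C = lambda1 * L_cls + lambda2 * L_d + lambda3 * L_tri, where

* ``L_cls`` is class-frequency-weighted binary cross-entropy on labeled
  source windows (one independent binary decision per context label);
* ``L_d`` is the domain alignment loss: the squared multi-kernel maximum
  mean discrepancy (MK-MMD, biased V-statistic) between source and target
  embeddings, summed over the MLP, CNN and joint-fusion encodings;
* ``L_tri`` is the joint-fusion triplet loss with margin ``alpha``, averaged
  over mined triplets.

Every loss accepts either plain numpy arrays (analysis) or autodiff
``Tensor`` objects (training); the two paths share formulas and are pinned
against each other and against brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import KernelBankConfig


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _value(x):
    return x.data if _is_tensor(x) else np.asarray(x)


# -- kernel bank -----------------------------------------------------------

@dataclass
class KernelBank:
    """A weighted bank of Gaussian kernels k(x,y) = sum_u beta_u exp(-||x-y||^2 / 2 sigma_u^2)."""

    betas: np.ndarray
    bandwidths: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        if self.betas.shape != self.bandwidths.shape or self.betas.size < 1:
            raise ValueError("betas and bandwidths must be equal-length, non-empty")
        if np.any(self.betas < 0) or np.any(self.bandwidths <= 0):
            raise ValueError("betas must be >= 0 and bandwidths > 0")

    @property
    def n_kernels(self) -> int:
        return self.betas.size


def median_bandwidth(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pooled sample (the classic
    median heuristic); falls back to 1.0 when all points coincide."""
    X = np.asarray(X, dtype=np.float64)
    sq = (X ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    iu = np.triu_indices(len(X), k=1)
    med = float(np.median(np.sqrt(d2[iu]))) if iu[0].size else 0.0
    return med if med > 0 else 1.0


def resolve_kernel_bank(config: KernelBankConfig, pooled=None) -> KernelBank:
    """Turn a kernel-bank config into concrete bandwidths.

    With ``bandwidths=None`` the median heuristic on ``pooled`` data is
    scaled by the configured multipliers (recomputed per batch in training).
    """
    if config.bandwidths is not None:
        sigmas = np.asarray(config.bandwidths, dtype=float)
    else:
        if pooled is None:
            raise ValueError("median-heuristic bank needs pooled data to resolve")
        sigmas = median_bandwidth(_value(pooled)) * np.asarray(
            config.median_multipliers, dtype=float)
    betas = (np.asarray(config.betas, dtype=float) if config.betas is not None
             else np.full(sigmas.size, 1.0 / sigmas.size))
    return KernelBank(betas=betas, bandwidths=sigmas)


def _kernel_matrix(A, B, bank: KernelBank):
    """Gram matrix of the multi-kernel between rows of A and rows of B."""
    if _is_tensor(A) or _is_tensor(B):
        d2 = ad.pairwise_sq_dists(ad.constant(A), ad.constant(B))
        out = None
        for beta, sigma in zip(bank.betas, bank.bandwidths):
            term = ad.mul(ad.exp(ad.mul(d2, -1.0 / (2.0 * sigma ** 2))), float(beta))
            out = term if out is None else ad.add(out, term)
        return out
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    sq_a = (A ** 2).sum(axis=1)
    sq_b = (B ** 2).sum(axis=1)
    d2 = np.maximum(sq_a[:, None] + sq_b[None, :] - 2.0 * A @ B.T, 0.0)
    out = np.zeros_like(d2)
    for beta, sigma in zip(bank.betas, bank.bandwidths):
        out += beta * np.exp(-d2 / (2.0 * sigma ** 2))
    return out


def multi_kernel(x, y, bank: KernelBank) -> float:
    """k(x, y) for two single vectors."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("multi_kernel requires equal-dimension vectors")
    d2 = float(((x - y) ** 2).sum())
    return float(np.sum(bank.betas * np.exp(-d2 / (2.0 * bank.bandwidths ** 2))))


def mk_mmd_sq(Xs, Xt, bank: KernelBank):
    """Squared MK-MMD, biased V-statistic:
    mean k(s,s') + mean k(t,t') - 2 mean k(s,t).  Non-negative; zero when the
    two batches are the same multiset."""
    ns, nt = _value(Xs).shape[0], _value(Xt).shape[0]
    if ns < 1 or nt < 1:
        raise ValueError("mk_mmd_sq requires non-empty batches")
    if _is_tensor(Xs) or _is_tensor(Xt):
        # one joint Gram matrix; block weights turn its weighted sum into
        # mean(Kss) + mean(Ktt) - 2 mean(Kst)
        joint = ad.concat([ad.constant(Xs), ad.constant(Xt)], axis=0)
        K = _kernel_matrix(joint, joint, bank)
        M = np.empty((ns + nt, ns + nt), dtype=K.data.dtype)
        M[:ns, :ns] = 1.0 / (ns * ns)
        M[ns:, ns:] = 1.0 / (nt * nt)
        M[:ns, ns:] = -1.0 / (ns * nt)
        M[ns:, :ns] = -1.0 / (ns * nt)
        return ad.weighted_sum(K, M)
    Kss = _kernel_matrix(Xs, Xs, bank)
    Ktt = _kernel_matrix(Xt, Xt, bank)
    Kst = _kernel_matrix(Xs, Xt, bank)
    return float(Kss.mean() + Ktt.mean() - 2.0 * Kst.mean())


def domain_alignment_loss(layer_pairs, bank_config: KernelBankConfig | KernelBank):
    """Sum of squared MK-MMD over network layers (MLP, CNN, fusion encodings).

    With a median-heuristic bank config the bandwidths are resolved per layer
    on the pooled (source + target) batch.
    """
    layer_pairs = list(layer_pairs)
    if not layer_pairs:
        raise ValueError("domain_alignment_loss needs at least one layer pair")
    total = None
    for Xs, Xt in layer_pairs:
        if isinstance(bank_config, KernelBank):
            bank = bank_config
        else:
            pooled = np.concatenate([_value(Xs), _value(Xt)], axis=0)
            bank = resolve_kernel_bank(bank_config, pooled)
        term = mk_mmd_sq(Xs, Xt, bank)
        if total is None:
            total = term
        elif _is_tensor(term) or _is_tensor(total):
            total = ad.add(total, term)
        else:
            total = total + term
    return total


def mmd_sq_from_joint(d2_joint: Tensor, ns: int, nt: int,
                      bank_config: KernelBankConfig | KernelBank) -> Tensor:
    """Squared MK-MMD from a precomputed joint squared-distance matrix.

    ``d2_joint`` is the [ns+nt, ns+nt] pairwise squared-distance Tensor of
    the concatenated (source, target) batch; the median-heuristic bank is
    resolved from its off-diagonal entries.  Equivalent to :func:`mk_mmd_sq`
    on the two slices — the training loop uses this form so the distance
    matrix can be shared with triplet mining.
    """
    if isinstance(bank_config, KernelBank):
        bank = bank_config
    else:
        if bank_config.bandwidths is not None:
            bank = resolve_kernel_bank(bank_config)
        else:
            iu = np.triu_indices(ns + nt, k=1)
            med = float(np.median(np.sqrt(d2_joint.data[iu])))
            sigmas = (med if med > 0 else 1.0) * np.asarray(
                bank_config.median_multipliers, dtype=float)
            betas = (np.asarray(bank_config.betas, dtype=float)
                     if bank_config.betas is not None
                     else np.full(sigmas.size, 1.0 / sigmas.size))
            bank = KernelBank(betas=betas, bandwidths=sigmas)
    K = None
    for beta, sigma in zip(bank.betas, bank.bandwidths):
        term = ad.mul(ad.exp(ad.mul(d2_joint, -1.0 / (2.0 * sigma ** 2))), float(beta))
        K = term if K is None else ad.add(K, term)
    M = np.empty((ns + nt, ns + nt), dtype=K.data.dtype)
    M[:ns, :ns] = 1.0 / (ns * ns)
    M[ns:, ns:] = 1.0 / (nt * nt)
    M[:ns, ns:] = -1.0 / (ns * nt)
    M[ns:, :ns] = -1.0 / (ns * nt)
    return ad.weighted_sum(K, M)


# -- classification --------------------------------------------------------

def class_weights(labels: np.ndarray, cap: float = 100.0) -> np.ndarray:
    """Inverse class-frequency positive weights w_l = (#neg_l / #pos_l), capped."""
    labels = np.asarray(labels)
    pos = labels.sum(axis=0).astype(float)
    neg = labels.shape[0] - pos
    with np.errstate(divide="ignore"):
        w = np.where(pos > 0, neg / np.maximum(pos, 1e-12), cap)
    return np.minimum(w, cap)


def classification_loss(probs, labels, weights: np.ndarray | None = None,
                        eps: float = 1e-7):
    """Mean over samples x labels of class-weighted binary cross-entropy.

    Positive decisions carry weight ``weights[l]``; negatives weight 1.
    """
    y = _value(labels).astype(float)
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be binary")
    L = y.shape[-1]
    w = np.ones(L) if weights is None else np.asarray(weights, dtype=float)
    if _is_tensor(probs):
        p = probs
        wpos = np.broadcast_to(w, y.shape)
        term = ad.add(
            ad.mul(ad.mul(ad.log(p, eps=eps), -1.0), y * wpos),
            ad.mul(ad.mul(ad.log(ad.add(ad.mul(p, -1.0), 1.0), eps=eps), -1.0), 1.0 - y))
        return ad.mean(term)
    p = np.clip(np.asarray(probs, dtype=float), eps, 1.0 - eps)
    term = -(w * y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(term.mean())


def classification_loss_logits(logits: Tensor, labels: np.ndarray,
                               weights: np.ndarray | None = None) -> Tensor:
    """Numerically stable weighted BCE from logits (training path):
    w*y*softplus(-z) + (1-y)*softplus(z), averaged over samples x labels."""
    y = np.asarray(labels, dtype=logits.data.dtype)
    L = y.shape[-1]
    w = np.ones(L) if weights is None else np.asarray(weights, dtype=float)
    wpos = (w * y).astype(logits.data.dtype)
    pos_term = ad.mul(ad.softplus(ad.mul(logits, -1.0)), wpos)
    neg_term = ad.mul(ad.softplus(logits), 1.0 - y)
    return ad.mean(ad.add(pos_term, neg_term))


# -- triplet ---------------------------------------------------------------

def compatibility(y1: np.ndarray, y2: np.ndarray) -> int:
    """Number of shared positive labels (dot product of binary vectors)."""
    y1, y2 = np.asarray(y1), np.asarray(y2)
    if y1.shape != y2.shape:
        raise ValueError("label vectors must have equal length")
    if np.any((y1 != 0) & (y1 != 1)) or np.any((y2 != 0) & (y2 != 1)):
        raise ValueError("label vectors must be binary")
    return int(y1 @ y2)


def triplet_loss(embeddings: np.ndarray, triplets, alpha: float,
                 distances: np.ndarray | None = None) -> float:
    """Mean over triplets of [d(a,p) - d(a,n) + alpha]_+ (Euclidean d).

    An empty triplet list yields 0 (a batch may contain no valid triplets).
    """
    if alpha < 0:
        raise ValueError("margin must be non-negative")
    triplets = list(triplets)
    if not triplets:
        return 0.0
    X = np.asarray(embeddings, dtype=float)
    if distances is None:
        sq = (X ** 2).sum(axis=1)
        distances = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0))
    idx = np.asarray([(t.a, t.p, t.n) if hasattr(t, "a") else tuple(t)
                      for t in triplets], dtype=int)
    hinge = np.maximum(
        distances[idx[:, 0], idx[:, 1]] - distances[idx[:, 0], idx[:, 2]] + alpha, 0.0)
    return float(hinge.mean())


def total_cost(l_cls, l_d, l_tri, weights):
    """C = lambda1 * L_cls + lambda2 * L_d + lambda3 * L_tri."""
    lam1, lam2, lam3 = weights
    terms = [(lam1, l_cls), (lam2, l_d), (lam3, l_tri)]
    if any(_is_tensor(t) for _, t in terms):
        out = None
        for lam, t in terms:
            piece = ad.mul(ad.constant(t), float(lam))
            out = piece if out is None else ad.add(out, piece)
        return out
    return float(lam1 * l_cls + lam2 * l_d + lam3 * l_tri)


# -- CORAL baseline --------------------------------------------------------

def coral_loss(Xs, Xt):
    """Correlation alignment: ||Cov(Xs) - Cov(Xt)||_F^2 / (4 d^2), with the
    unbiased (n-1) covariance."""
    ns, nt = _value(Xs).shape[0], _value(Xt).shape[0]
    d = _value(Xs).shape[1]
    if _value(Xt).shape[1] != d:
        raise ValueError("CORAL batches must share the feature dimension")
    if ns < 2 or nt < 2:
        raise ValueError("CORAL needs at least two samples per batch")
    if _is_tensor(Xs) or _is_tensor(Xt):
        Xs, Xt = ad.constant(Xs), ad.constant(Xt)

        def cov(X, n):
            mu = ad.mean(X, axis=0, keepdims=True)
            Xc = ad.add(X, ad.mul(mu, -1.0))
            return ad.mul(ad.matmul(ad.transpose(Xc), Xc), 1.0 / (n - 1))

        diff = ad.add(cov(Xs, ns), ad.mul(cov(Xt, nt), -1.0))
        return ad.mul(ad.sum_(ad.mul(diff, diff)), 1.0 / (4.0 * d * d))
    Cs = np.cov(np.asarray(Xs, dtype=float), rowvar=False).reshape(d, d)
    Ct = np.cov(np.asarray(Xt, dtype=float), rowvar=False).reshape(d, d)
    return float(((Cs - Ct) ** 2).sum() / (4.0 * d * d))
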