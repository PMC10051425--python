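"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (loops, direct formulas)
and never calls into the package's optimized implementations.
"""

import numpy as np


def naive_window_features(window: np.ndarray, bands) -> np.ndarray:
    """Direct per-channel evaluation of the handcrafted feature formulas."""
    feats = []
    for s in range(3):
        axes = [window[s, ax].astype(float) for ax in range(3)]
        mag = np.sqrt(sum(a ** 2 for a in axes))
        channels = axes + [mag]
        for sig in channels:
            n = len(sig)
            mean = sum(sig) / n
            m2 = sum((sig - mean) ** 2) / n
            m3 = sum((sig - mean) ** 3) / n
            m4 = sum((sig - mean) ** 4) / n
            sd = np.sqrt(m2)
            skew = m3 / sd ** 3 if m2 > 0 else 0.0
            kurt = m4 / m2 ** 2 if m2 > 0 else 0.0
            feats += [mean, sd, skew, kurt]
            spectrum = np.fft.rfft(sig)
            for a, b in bands:
                total = 0.0
                for i in range(a, b + 1):
                    total += abs(spectrum[i]) ** 2
                feats.append(total / (b - a + 1))
        sma = sum(np.abs(window[s, ax]).sum() for ax in range(3)) / 3.0
        feats.append(sma)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            si, sj = channels[i], channels[j]
            ci = si - si.mean()
            cj = sj - sj.mean()
            denom = np.sqrt((ci ** 2).mean() * (cj ** 2).mean())
            feats.append((ci * cj).mean() / denom if denom > 0 else 0.0)
    return np.array(feats)


def naive_mmd_sq(Xs: np.ndarray, Xt: np.ndarray, betas, sigmas) -> float:
    """O(n^2) double-sum estimator of the squared multi-kernel MMD."""
    def k(x, y):
        d2 = float(((x - y) ** 2).sum())
        return sum(b * np.exp(-d2 / (2.0 * s ** 2)) for b, s in zip(betas, sigmas))

    ns, nt = len(Xs), len(Xt)
    kss = sum(k(Xs[i], Xs[j]) for i in range(ns) for j in range(ns)) / ns ** 2
    ktt = sum(k(Xt[i], Xt[j]) for i in range(nt) for j in range(nt)) / nt ** 2
    kst = sum(k(Xs[i], Xt[j]) for i in range(ns) for j in range(nt)) / (ns * nt)
    return kss + ktt - 2.0 * kst


def naive_mine_triplets(embeddings: np.ndarray, labels: np.ndarray,
                        alpha: float) -> list[tuple[int, int, int]]:
    """Exhaustive O(n^3) filter of the triplet mining conjunction."""
    n = len(embeddings)
    d = np.array([[np.sqrt(((embeddings[i] - embeddings[j]) ** 2).sum())
                   for j in range(n)] for i in range(n)])
    c = np.array([[int(labels[i] @ labels[j]) for j in range(n)] for i in range(n)])
    out = []
    for a in range(n):
        for p in range(n):
            for neg in range(n):
                if a == p or a == neg or p == neg:
                    continue
                if c[a, p] < 1:
                    continue
                if not (d[a, p] + alpha > d[a, neg]):
                    continue
                if not (c[a, p] > c[a, neg]):
                    continue
                out.append((a, p, neg))
    return out


def naive_silhouette(embeddings: np.ndarray, cluster: np.ndarray) -> float:
    """Per-point a_i / b_i loop for a binary clustering."""
    n = len(embeddings)
    d = np.array([[np.sqrt(((embeddings[i] - embeddings[j]) ** 2).sum())
                   for j in range(n)] for i in range(n)])
    scores = []
    for i in range(n):
        same = [j for j in range(n) if cluster[j] == cluster[i] and j != i]
        other = [j for j in range(n) if cluster[j] != cluster[i]]
        a = np.mean([d[i, j] for j in same])
        b = np.mean([d[i, j] for j in other])
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def naive_multilabel_counts(pred: np.ndarray, truth: np.ndarray):
    """Pooled confusion counts over all N x L binary decisions."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for l in range(pred.shape[1]):
            if pred[i, l] == 1 and truth[i, l] == 1:
                tp += 1
            elif pred[i, l] == 1:
                fp += 1
            elif truth[i, l] == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
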