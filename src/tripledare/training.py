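"""The unsupervised domain adaptation training loop.

Each optimization step draws a labeled source mini-batch (sequential over a
per-epoch shuffle) and a randomly sampled unlabeled target mini-batch,
forwards both through the dual-view network, and minimizes

    C = lambda1 * L_cls + lambda2 * L_d + lambda3 * L_tri

where L_cls is class-weighted BCE on source labels only, L_d is the MK-MMD
domain alignment loss summed over the three encodings (MLP, CNN, fusion),
and L_tri is the joint-fusion triplet loss on triplets mined over the
concatenated batch with pseudo-labeled target rows.  The loss weights
follow a warm-up schedule: lambda2 = lambda3 = 0 at the start of training
(classifier-first, so early pseudo-labels do not mislead mining) and ramp up
as lambda(p) = lambda_max * (2 / (1 + e^(-gamma p)) - 1); the learning rate
anneals as lr(p) = lr0 / (1 + a p)^b with progress p in [0, 1].

Method switch: ``dan`` keeps only the alignment loss (lambda3 = 0),
``coral`` swaps MK-MMD for correlation alignment, ``source_only`` trains the
classifier alone, and ``ablation-cls[+dom][+tri]`` masks arbitrary terms.

Target labels are never read: the loop operates on a label-hidden view of
the target dataset, so any leak raises ``LabelsHiddenError``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .config import RunConfig
from .datasets import DomainDataset
from .encoders import DualViewNet, fuse
from .evaluation import multilabel_metrics
from .features import featurize_dataset, zscore_apply, zscore_fit
from .losses import (class_weights, classification_loss_logits, coral_loss,
                     mmd_sq_from_joint, total_cost)
from .mining import assign_pseudo_labels, compatibility_matrix, triplet_loss_terms
from .nn import Adam


def schedule(p: float, config) -> tuple[float, float, float]:
    """(learning rate, lambda2, lambda3) at training progress p in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("progress must lie in [0, 1]")
    lam = config.lambda_max * (2.0 / (1.0 + np.exp(-config.gamma * p)) - 1.0)
    lr = config.lr0 / (1.0 + config.lr_decay_a * p) ** config.lr_decay_b
    return float(lr), float(lam), float(lam)


def split_subjectwise(dataset: DomainDataset, val_frac: float = 0.1,
                      seed: int = 0) -> tuple[DomainDataset, DomainDataset]:
    """Split by subject so no subject appears in both train and validation."""
    subjects = np.unique(dataset.subject_ids)
    if subjects.size < 2:
        raise ValueError("subject-wise split needs at least two subjects")
    rng = np.random.default_rng([seed % (2 ** 31), 11])
    order = rng.permutation(subjects)
    n_val = max(1, int(round(val_frac * subjects.size)))
    if n_val >= subjects.size:
        n_val = subjects.size - 1
    val_subjects = set(order[:n_val].tolist())
    val_mask = np.isin(dataset.subject_ids, list(val_subjects))
    return dataset.subset(np.flatnonzero(~val_mask)), dataset.subset(np.flatnonzero(val_mask))


def _parse_method(method: str) -> tuple[bool, bool, bool]:
    """-> (use_domain_mmd, use_domain_coral, use_triplet)."""
    if method == "tripledare":
        return True, False, True
    if method == "dan":
        return True, False, False
    if method == "coral":
        return False, True, False
    if method == "source_only":
        return False, False, False
    if method.startswith("ablation-"):
        parts = set(method[len("ablation-"):].split("+"))
        unknown = parts - {"cls", "dom", "tri"}
        if unknown:
            raise ValueError(f"unknown ablation mask components {sorted(unknown)}")
        return "dom" in parts, False, "tri" in parts
    raise ValueError(f"unknown method {method!r}")


@dataclass
class StepRecord:
    step: int
    epoch: int
    lr: float
    lambda2: float
    lambda3: float
    loss_cls: float
    loss_domain: float
    loss_triplet: float
    loss_total: float
    n_triplets: int


@dataclass
class TrainHistory:
    steps: list[StepRecord] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = -1.0

    def as_arrays(self) -> dict[str, np.ndarray]:
        keys = ("step", "epoch", "lr", "lambda2", "lambda3", "loss_cls",
                "loss_domain", "loss_triplet", "loss_total", "n_triplets")
        return {k: np.array([getattr(r, k) for r in self.steps]) for k in keys}


def prepare_features(source: DomainDataset, target: DomainDataset,
                     val_frac: float, seed: int):
    """Featurize both domains; z-score with *source-train* statistics only."""
    if source.features is None:
        featurize_dataset(source)
    if target.features is None:
        featurize_dataset(target)
    train_ds, val_ds = split_subjectwise(source, val_frac, seed)
    stats = zscore_fit(train_ds.features)
    for ds in (train_ds, val_ds, target):
        ds.features = zscore_apply(ds.features, stats)
    return train_ds, val_ds, stats


def train(source: DomainDataset, target: DomainDataset,
          config: RunConfig) -> tuple[DualViewNet, TrainHistory]:
    """Run the UDA loop; returns the best-on-source-validation model."""
    tcfg, mcfg = config.train, config.mining
    target = target.without_labels()  # hard no-leak guarantee
    train_ds, val_ds, stats = prepare_features(source, target, tcfg.val_frac, tcfg.seed)

    use_mmd, use_coral, use_triplet = _parse_method(tcfg.method)
    weights = class_weights(train_ds.labels)
    n_labels = train_ds.n_labels
    T = train_ds.raw.shape[-1]
    model = DualViewNet(train_ds.features.shape[1], n_labels, T,
                        config.model, seed=tcfg.seed)
    optimizer = Adam(model.parameters(), lr=tcfg.lr0)
    rng = np.random.default_rng([tcfg.seed % (2 ** 31), 23])

    m = min(tcfg.batch_size, train_ds.n, target.n)
    steps_per_epoch = max(1, train_ds.n // m)
    total_steps = steps_per_epoch * tcfg.epochs
    feat_t = target.features.astype(np.float32)
    raw_t = target.raw.astype(np.float32)
    feat_s = train_ds.features.astype(np.float32)
    raw_s = train_ds.raw.astype(np.float32)
    labels_s = np.asarray(train_ds.labels)

    history = TrainHistory()
    best_params: list[np.ndarray] | None = None
    step = 0
    pseudo_t: np.ndarray | None = None
    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_ds.n)
        for b in range(steps_per_epoch):
            p = step / max(total_steps - 1, 1)
            lr, lam2, lam3 = schedule(p, tcfg)
            idx_s = order[b * m:(b + 1) * m]
            idx_t = rng.choice(target.n, size=m, replace=target.n < m)

            y_s = labels_s[idx_s]
            needs_target = use_mmd or use_coral or use_triplet
            keys = ("e_mlp", "e_cnn", "e_fused")
            if needs_target:
                # one joint forward keeps the network pass shared between
                # the source and target halves of the step
                out = model.forward(
                    np.concatenate([feat_s[idx_s], feat_t[idx_t]]),
                    np.concatenate([raw_s[idx_s], raw_t[idx_t]]))
                logits_s = ad.take(out["logits"], slice(0, m))
                d2 = {k: ad.pairwise_sq_dists(out[k], out[k]) for k in keys}
            else:
                out = model.forward(feat_s[idx_s], raw_s[idx_s])
                logits_s = out["logits"]
                d2 = {}

            l_cls = classification_loss_logits(logits_s, y_s, weights)

            if use_mmd:
                l_dom = None
                for k in keys:
                    term = mmd_sq_from_joint(d2[k], m, m, config.kernels)
                    l_dom = term if l_dom is None else ad.add(l_dom, term)
            elif use_coral:
                l_dom = None
                for k in keys:
                    term = coral_loss(ad.take(out[k], slice(0, m)),
                                      ad.take(out[k], slice(m, 2 * m)))
                    l_dom = term if l_dom is None else ad.add(l_dom, term)
            else:
                l_dom = ad.constant(0.0)

            n_triplets = 0
            if use_triplet:
                if pseudo_t is None or step % mcfg.refresh_every == 0:
                    probs_t = ad.sigmoid(ad.take(out["logits"], slice(m, 2 * m))).data
                    pseudo_t = assign_pseudo_labels(probs_t, mcfg.pseudo_threshold)
                joint_labels = np.concatenate([y_s, pseudo_t], axis=0)
                compat = compatibility_matrix(joint_labels)
                D = {k: ad.sqrt(d2[k], eps=1e-12) for k in keys}
                Ws, consts, n_triplets = triplet_loss_terms(
                    D["e_fused"].data, compat, mcfg.margin,
                    [D[k].data for k in keys])
                if n_triplets:
                    l_tri = None
                    for k, W, c in zip(keys, Ws, consts):
                        term = ad.add(ad.weighted_sum(D[k], W.astype(D[k].data.dtype)),
                                      float(c))
                        l_tri = term if l_tri is None else ad.add(l_tri, term)
                else:
                    l_tri = ad.constant(0.0)
            else:
                l_tri = ad.constant(0.0)

            lam2_eff = lam2 if (use_mmd or use_coral) else 0.0
            lam3_eff = lam3 if use_triplet else 0.0
            cost = total_cost(l_cls, l_dom, l_tri, (tcfg.lambda1, lam2_eff, lam3_eff))
            if not np.isfinite(cost.data):
                raise RuntimeError(
                    f"non-finite training cost at step {step} "
                    f"(cls={l_cls.data}, dom={ad.constant(l_dom).data}, "
                    f"tri={ad.constant(l_tri).data})")
            model.zero_grad()
            cost.backward()
            optimizer.lr = lr
            optimizer.step()

            history.steps.append(StepRecord(
                step=step, epoch=epoch, lr=lr, lambda2=lam2_eff, lambda3=lam3_eff,
                loss_cls=float(l_cls.data), loss_domain=float(ad.constant(l_dom).data),
                loss_triplet=float(ad.constant(l_tri).data),
                loss_total=float(cost.data), n_triplets=int(n_triplets)))
            step += 1

        probs_val, _ = model.predict_numpy(
            val_ds.features.astype(np.float32), val_ds.raw.astype(np.float32))
        report = multilabel_metrics(assign_pseudo_labels(probs_val, 0.5), val_ds.labels)
        history.val_f1.append(report.f1_micro)
        if report.f1_micro > history.best_val_f1:
            history.best_val_f1 = report.f1_micro
            history.best_epoch = epoch
            best_params = [a.copy() for a in model.state_arrays()]

    if best_params is not None:
        model.load_state_arrays(best_params)
    model.norm_stats = stats  # carried for downstream evaluation
    return model, history


def run_ablation(source: DomainDataset, target: DomainDataset,
                 config: RunConfig, seeds: list[int] | None = None):
    """Train the four loss masks with shared seeds; returns a metrics table.

    Masks: cls only, cls+dom (alignment only), cls+tri (triplet only), and
    the full objective.  Each mask sees identical data, initialization seed
    and batch order, so differences isolate the loss components.
    """
    from .evaluation import evaluate_model  # local import avoids a cycle
    seeds = seeds if seeds is not None else [config.train.seed]
    masks = ("ablation-cls", "ablation-cls+dom", "ablation-cls+tri",
             "ablation-cls+dom+tri")
    rows = []
    for seed in seeds:
        for mask in masks:
            cfg = copy.deepcopy(config)
            cfg.train.seed = seed
            cfg.train.method = mask
            model, _ = train(source, target, cfg)
            report = evaluate_model(model, target, method=mask, seed=seed)
            rows.append(report)
    return rows
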