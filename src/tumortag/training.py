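"""Risk-extrapolation (VREx) training for domain generalization.

Each tissue (or spatial slide) is a source domain e = 1..m. The empirical
risk of a domain is the mean cross-entropy of the softmax class probabilities
against its labels,

    R_e(theta) = CrossEntropy(f_theta(x_e), y_e),

and training minimizes

    L(theta) = beta * R_var(theta) + R_avg(theta),

where R_avg = (1/m) sum_e R_e is the mean risk, R_var = (1/m) sum_e
(R_e - R_avg)^2 is the population variance of the per-domain risks, and beta
balances the two terms (beta -> 0 recovers ERM; large beta forces equal
risks across domains). Each optimization step draws an equal-size minibatch
from every domain so all m risks are defined at every step.

Early stopping uses an extra-domain validation set held fully outside the
training domains: the returned model is the state at the epoch where
extra-domain accuracy is maximal (first maximizer on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    MALIGNANT,
    ModelState,
    _as_matrix,
    _backward,
    _forward,
    softmax_matrix,
)

# ---------------------------------------------------------------------------
# risks and the VREx objective
# ---------------------------------------------------------------------------


@dataclass
class RiskVector:
    """Per-domain empirical risks R_1..R_m for one step or epoch."""

    risks: np.ndarray
    domain_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.risks = np.asarray(self.risks, dtype=np.float64)
        if self.risks.ndim != 1 or self.risks.size < 1:
            raise ValueError("risks must be a non-empty 1-D vector")
        if not np.isfinite(self.risks).all() or (self.risks < 0).any():
            raise ValueError("risks must be finite and non-negative")
        if self.domain_names is not None and len(self.domain_names) != self.risks.size:
            raise ValueError("domain_names length mismatch")

    @property
    def m(self) -> int:
        return int(self.risks.size)


def _risks_of(rv) -> np.ndarray:
    risks = rv.risks if isinstance(rv, RiskVector) else np.asarray(rv, dtype=np.float64)
    if risks.size < 1:
        raise ValueError("empty risk vector")
    return risks


def average_risk(rv) -> float:
    """Mean of the per-domain risks, R_avg = (1/m) sum_e R_e."""
    return float(np.mean(_risks_of(rv)))


def variance_risk(rv) -> float:
    """Population variance of the per-domain risks,
    R_var = (1/m) sum_e (R_e - R_avg)^2; zero for a single domain."""
    return float(np.var(_risks_of(rv), ddof=0))


def rex_loss(rv, beta: float) -> float:
    """The risk-extrapolation objective L = beta * R_var + R_avg (beta >= 0);
    beta = 0 is exactly the ERM mean risk."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return beta * variance_risk(rv) + average_risk(rv)


def cross_entropy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean natural-log cross-entropy of softmax class probabilities against
    integer labels, computed via a numerically stable log-sum-exp."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores/labels length mismatch")
    if scores.shape[0] == 0:
        raise ValueError("empty batch")
    shifted = scores - scores.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=1))
    return float(np.mean(logZ - shifted[np.arange(len(labels)), labels]))


def domain_risk(model: ModelState, X_e, y_e, mode: str = "infer", rng=None) -> float:
    """Empirical risk of one domain: mean cross-entropy of the model's softmax
    probabilities against the domain's 0/1 labels."""
    X = _as_matrix(X_e)
    y = np.asarray(y_e, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty domain batch")
    if mode == "train":
        g, _ = _forward(model.params, X, model.spec.dropout_p, rng)
    else:
        g, _ = _forward(model.params, X)
    return cross_entropy(g, y)


# ---------------------------------------------------------------------------
# loss + gradient of one step (all domains)
# ---------------------------------------------------------------------------

def rex_loss_and_grad(params, spec, batches, beta, rng=None):
    """Loss L = beta*R_var + R_avg over per-domain batches [(X_e, y_e), ...]
    and its gradient with respect to every parameter.

    d L / d R_e = 1/m + 2*beta*(R_e - R_avg)/m, so the parameter gradient is
    the weighted sum of per-domain cross-entropy gradients. Dropout masks are
    drawn from ``rng`` when given (train mode); pass None for a deterministic
    check.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    m = len(batches)
    risks = np.empty(m)
    caches = []
    softmaxes = []
    for e, (X_e, y_e) in enumerate(batches):
        X = _as_matrix(X_e)
        g, cache = _forward(params, X, spec.dropout_p if rng is not None else 0.0, rng)
        p = softmax_matrix(g)
        y = np.asarray(y_e, dtype=np.int64)
        risks[e] = cross_entropy(g, y)
        caches.append((cache, p, y))
        softmaxes.append(p)
    r_avg = risks.mean()
    r_var = risks.var(ddof=0)
    loss = beta * r_var + r_avg
    coeff = 1.0 / m + 2.0 * beta * (risks - r_avg) / m
    grads = None
    for (cache, p, y), c_e in zip(caches, coeff):
        dg = p.copy()
        dg[np.arange(len(y)), y] -= 1.0
        dg *= c_e / len(y)
        g_e, _ = _backward(params, cache, dg)
        if grads is None:
            grads = g_e
        else:
            for k in grads:
                grads[k] += g_e[k]
    return loss, grads, RiskVector(risks)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyper-parameters.

    beta defaults to 1 (equal weight on variance and average risk);
    learning_rate / batch_per_domain / max_epochs default to a stable
    configuration for small affine networks (adaptive-moment gradient
    descent, no weight decay).
    """

    beta: float = 1.0
    learning_rate: float = 1e-4
    batch_per_domain: int = 128
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_per_domain < 1 or self.max_epochs < 1:
            raise ValueError("batch_per_domain and max_epochs must be >= 1")


@dataclass
class TrainTrace:
    """Per-epoch training record: mean risks, loss, per-domain and
    extra-domain accuracy, and the checkpoint flag (exactly one epoch, the
    first maximizer of extra-domain accuracy)."""

    domain_names: list[str]
    r_avg: list[float] = field(default_factory=list)
    r_var: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    domain_accuracy: list[dict[str, float]] = field(default_factory=list)
    extra_accuracy: list[float] = field(default_factory=list)
    checkpoint_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_epochs):
            row = {
                "epoch": i,
                "R_avg": self.r_avg[i],
                "R_var": self.r_var[i],
                "loss": self.loss[i],
                "extra_domain_accuracy": self.extra_accuracy[i],
                "checkpoint": int(i == self.checkpoint_epoch),
            }
            for d in self.domain_names:
                row[f"acc_{d}"] = self.domain_accuracy[i][d]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _accuracy(model: ModelState, X, y, threshold: float = 0.5) -> float:
    g, _ = _forward(model.params, _as_matrix(X))
    sm = softmax_matrix(g)[:, MALIGNANT]
    calls = (sm > threshold).astype(np.int64)
    return float(np.mean(calls == np.asarray(y, dtype=np.int64)))


def train(
    model: ModelState,
    data,
    extra_domain,
    cfg: TrainConfig,
) -> tuple[ModelState, TrainTrace]:
    """Train with the VREx objective and extra-domain early stopping.

    ``data`` is (X, ann, partition): an aligned matrix (cells x features in
    the model's feature order), an AnnotationTable, and a domain partition
    mapping domain name -> row indices. ``extra_domain`` is (X_extra,
    y_extra), a labeled set from outside every training domain, used solely
    to pick the checkpoint epoch.

    Every step draws ``batch_per_domain`` cells from each domain, computes
    the m per-domain cross-entropy risks, forms L = beta*R_var + R_avg, and
    updates the parameters; an epoch is enough steps to cover the largest
    domain once. Returns the model state from the first epoch maximizing
    extra-domain accuracy, plus the full trace. Fully determined by cfg.seed.
    """
    X, ann, partition = data
    X = _as_matrix(X)
    domain_names = list(partition.keys())
    m = len(domain_names)
    if m < 1:
        raise ValueError("at least one training domain is required")
    if m == 1 and cfg.beta > 0:
        warnings.warn(
            "single training domain: the variance risk is identically zero "
            "and beta has no effect"
        )
    X_extra, y_extra = extra_domain
    X_extra = _as_matrix(X_extra)
    y_extra = np.asarray(y_extra, dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    params = model.copy_params()
    opt = _Adam(params, cfg.learning_rate)
    labels = ann.labels
    largest = max(len(ix) for ix in partition.values())
    steps_per_epoch = max(1, int(np.ceil(largest / cfg.batch_per_domain)))

    trace = TrainTrace(domain_names=domain_names)
    best_acc = -np.inf
    best_params = model.copy_params()
    best_epoch = -1

    for epoch in range(cfg.max_epochs):
        # per-epoch shuffled index streams, one per domain, cycled as needed
        streams = {
            d: np.concatenate(
                [
                    rng.permutation(partition[d])
                    for _ in range(
                        int(
                            np.ceil(
                                steps_per_epoch
                                * cfg.batch_per_domain
                                / len(partition[d])
                            )
                        )
                    )
                ]
            )
            for d in domain_names
        }
        epoch_losses, epoch_ravg, epoch_rvar = [], [], []
        for step in range(steps_per_epoch):
            lo = step * cfg.batch_per_domain
            hi = lo + cfg.batch_per_domain
            batches = []
            for d in domain_names:
                ix = streams[d][lo:hi]
                batches.append((X[ix], labels[ix]))
            loss, grads, rv = rex_loss_and_grad(
                params, model.spec, batches, cfg.beta, rng
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}"
                )
            opt.step(params, grads)
            epoch_losses.append(loss)
            epoch_ravg.append(average_risk(rv))
            epoch_rvar.append(variance_risk(rv))

        snapshot = ModelState(
            spec=model.spec,
            params=params,
            feature_list=model.feature_list,
            preprocess=model.preprocess,
            threshold=model.threshold,
            metadata=model.metadata,
        )
        dom_acc = {
            d: _accuracy(snapshot, X[partition[d]], labels[partition[d]])
            for d in domain_names
        }
        extra_acc = _accuracy(snapshot, X_extra, y_extra)
        trace.r_avg.append(float(np.mean(epoch_ravg)))
        trace.r_var.append(float(np.mean(epoch_rvar)))
        trace.loss.append(float(np.mean(epoch_losses)))
        trace.domain_accuracy.append(dom_acc)
        trace.extra_accuracy.append(extra_acc)
        if extra_acc > best_acc:  # strict: first maximizer wins ties
            best_acc = extra_acc
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch

    trace.checkpoint_epoch = best_epoch
    checkpoint = ModelState(
        spec=model.spec,
        params=best_params,
        feature_list=model.feature_list,
        preprocess=model.preprocess,
        threshold=model.threshold,
        metadata={
            **model.metadata,
            "n_domains": m,
            "beta": cfg.beta,
            "seed": cfg.seed,
            "epochs_trained": cfg.max_epochs,
            "checkpoint_epoch": best_epoch,
        },
    )
    return checkpoint, trace


# ---------------------------------------------------------------------------
# end-to-end fit from raw counts
# ---------------------------------------------------------------------------

def fit_malignancy_model(
    raw,
    ann,
    pre_cfg=None,
    train_cfg=None,
    extra_raw=None,
    extra_labels=None,
    bottleneck_dim: int = 512,
    dropout_p: float = 0.5,
):
    """Full training pipeline from raw counts: normalize -> balance classes
    per domain -> 4:1 stratified split -> HVG selection on the training split
    -> VREx training with extra-domain early stopping.

    When no extra-domain set is supplied, the within-distribution validation
    split stands in for checkpoint selection (with a warning, since it cannot
    measure generalization to unseen domains). Returns (checkpoint model,
    trace, info dict with the validation ids and accuracy).
    """
    from .model import ModelSpec, init_model
    from .preprocessing import (
        PreprocessConfig,
        align_features,
        balance_classes_per_domain,
        domain_partition,
        normalize_cells,
        select_hvgs,
        split_train_val,
    )

    pre_cfg = pre_cfg or PreprocessConfig()
    train_cfg = train_cfg or TrainConfig()

    normalized = normalize_cells(raw, pre_cfg.scale_factor)
    balanced = balance_classes_per_domain(ann, seed=pre_cfg.seed)
    train_ids, val_ids = split_train_val(
        balanced, pre_cfg.split_fraction, pre_cfg.seed
    )
    row = {c: i for i, c in enumerate(normalized.cell_ids)}
    ann_by_id = {c: i for i, c in enumerate(balanced.cell_ids)}

    train_matrix = normalized.subset_cells([row[c] for c in train_ids])
    n_hvgs = min(pre_cfg.n_hvgs, train_matrix.n_genes)
    features = select_hvgs(train_matrix, n_hvgs)
    train_matrix = train_matrix.subset_genes(features)
    train_ann = balanced.subset([ann_by_id[c] for c in train_ids])
    partition = domain_partition(train_ann)

    val_matrix = normalized.subset_cells([row[c] for c in val_ids]).subset_genes(
        features
    )
    val_labels = balanced.labels[[ann_by_id[c] for c in val_ids]]

    if extra_raw is not None:
        extra_norm = normalize_cells(extra_raw, pre_cfg.scale_factor)
        extra_aligned, _ = align_features(extra_norm, features)
        extra = (extra_aligned.values, np.asarray(extra_labels, dtype=np.int64))
    else:
        warnings.warn(
            "no extra-domain validation set supplied; using the internal "
            "validation split for checkpoint selection"
        )
        extra = (val_matrix.values, val_labels)

    spec = ModelSpec(
        input_dim=len(features),
        bottleneck_dim=min(bottleneck_dim, 512),
        dropout_p=dropout_p,
    )
    model = init_model(spec, train_cfg.seed)
    model.feature_list = features
    model.preprocess = {"scale_factor": pre_cfg.scale_factor, "log_applied": True}
    checkpoint, trace = train(
        model, (train_matrix.values, train_ann, partition), extra, train_cfg
    )
    info = {
        "features": features,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "internal_validation_accuracy": _accuracy(
            checkpoint, val_matrix.values, val_labels
        ),
        "n_validation_cells": int(len(val_labels)),
    }
    return checkpoint, trace, info
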