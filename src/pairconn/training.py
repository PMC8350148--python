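"""Training objective and loop: dual masked BCE, imbalance weighting, Adam.

The objective evaluates the shared classifier twice per batch -- once on
the first connectivity matrix K (loss L1) and once on the attention-
updated matrix K' (loss L2) -- and minimizes L = lambda*L1 + (1-lambda)*L2.
Inference always uses the K' path.  Class imbalance at each time-point
is handled by weighting the positive-label term of the BCE by the
observed negative/positive count ratio, so the two classes carry equal
total mass.  Missing follow-up labels are excluded coordinate-wise by
0/1 masks; a masked entry never contributes to loss or gradient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import ShuffleSplit

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig, TrainConfig
from .model import PairwiseAttentionNet

log = logging.getLogger(__name__)

__all__ = [
    "LossBundle",
    "class_weights",
    "masked_weighted_bce",
    "combined_loss",
    "make_cv_splits",
    "train_model",
]


@dataclass
class LossBundle:
    L1: float
    L2: float
    L: float


def class_weights(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Positive-class weight per head coordinate: (#negative / #positive).

    With a 72%-positive time-point this yields 28/72, so that weighted
    positive mass equals negative mass.  A coordinate with no observed
    positives (or no negatives) gets weight 1 with a warning.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask)
    if labels.shape != mask.shape:
        raise ValueError("labels and mask shapes differ")
    n_pos = ((labels == 1) & (mask == 1)).sum(axis=0).astype(float)
    n_neg = ((labels == 0) & (mask == 1)).sum(axis=0).astype(float)
    w = np.ones_like(n_pos)
    ok = (n_pos > 0) & (n_neg > 0)
    w[ok] = n_neg[ok] / n_pos[ok]
    if not ok.all():
        warnings.warn(
            f"heads {np.where(~ok)[0].tolist()} have a single observed class; "
            "using weight 1", stacklevel=2,
        )
    return w


def masked_weighted_bce(logits, labels, mask, weights) -> float:
    """Scalar masked, class-weighted BCE-with-logits (mean over observed)."""
    t = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=float))
    return float(ad.masked_weighted_bce_with_logits(t, labels, mask, weights).data)


def combined_loss(loss_K: float, loss_Kprime: float, lam: float) -> LossBundle:
    """L = lambda * L1 + (1 - lambda) * L2 (L1: K path, L2: K' path)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0,1], got {lam}")
    return LossBundle(L1=loss_K, L2=loss_Kprime,
                      L=lam * loss_K + (1.0 - lam) * loss_Kprime)


def make_cv_splits(subject_ids, n_splits: int, train_fraction: float, seed: int):
    """Random subject-level train/test resampling splits (deterministic)."""
    ids = list(subject_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 subjects for cross-validation")
    n_test = int(round(len(ids) * (1.0 - train_fraction)))
    if n_test < 1 or n_test >= len(ids):
        raise ValueError(f"train_fraction {train_fraction} infeasible for {len(ids)} subjects")
    ss = ShuffleSplit(n_splits=n_splits, test_size=n_test, random_state=seed)
    splits = []
    for tr, te in ss.split(ids):
        splits.append(([ids[i] for i in tr], [ids[i] for i in te]))
    return splits


class _Adam:
    """Adam with optional decoupled weight decay on weight matrices."""

    def __init__(self, named_params, beta1, beta2, weight_decay=0.0, eps=1e-8):
        items = list(named_params.items())
        self.names = [k for k, _ in items]
        self.params = [p for _, p in items]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay and self.names[i].endswith(".w"):
                p.data -= lr * self.weight_decay * p.data


def _batch_losses(model, Xb, Yb, Mb, pos_w, rng):
    """Graph + loss tensors for one batch; returns (loss_tensor, L1, L2)."""
    cfg = model.config
    out = model.forward_graph(Xb, train=True, rng=rng)
    if cfg.regression_mode:
        loss_fn = lambda t: ad.masked_mse(t, Yb, Mb)
    else:
        loss_fn = lambda t: ad.masked_weighted_bce_with_logits(t, Yb, Mb, pos_w)
    L1 = loss_fn(out["logits_K"])
    if cfg.no_reweighting:
        return L1, L1, L1
    L2 = loss_fn(out["logits_Kprime"])
    lam = cfg.lam
    total = L1.affine(lam, 0.0) + L2.affine(1.0 - lam, 0.0)
    return total, L1, L2


def _similarity_warm_start(model, X, train_config, rng):
    """Self-supervised warm-start: fit K to each subject's sample
    correlation matrix (mapped to [0,1]) before any label is seen.

    Grounds the similarity network F in its intended semantics -- a
    pairwise correlation score -- so supervised training starts from an
    informative connectivity map instead of a near-constant one.  Uses
    the time series only; no label information enters.
    """
    from .autodiff import Tensor

    n = X.shape[0]
    targets = np.empty((n, X.shape[1], X.shape[1]))
    for i in range(n):
        targets[i] = 0.5 * (np.corrcoef(X[i]) + 1.0)   # map [-1,1] -> [0,1]
    opt = _Adam(model.params, train_config.adam_beta1, train_config.adam_beta2)
    ones = np.ones_like(targets[:1])
    for _ in range(train_config.pretrain_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            emb = model.embed(Tensor(X[idx].astype(model.dtype)))
            K = model.connectivity(emb)
            loss = ad.masked_mse(K, targets[idx], np.ones_like(targets[idx]))
            opt.zero_grad()
            loss.backward()
            opt.step(train_config.pretrain_lr)


def train_model(
    X: np.ndarray,
    Y: np.ndarray,
    M: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    pos_weight: np.ndarray | None = None,
    validation: tuple | None = None,
) -> tuple[PairwiseAttentionNet, pd.DataFrame]:
    """Fit the network on (X, Y, M) = signals (n,N,T), labels and masks (n,l).

    Returns the fitted model and a per-epoch history of L, L1, L2 (and
    held-out AUC/accuracy when a ``validation=(Xv, Yv, Mv)`` triple is
    given and ``train_config.eval_every > 0``).  Fully deterministic
    given the configs and seed.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    n = X.shape[0]
    if Y.ndim == 1:
        Y, M = Y[:, None], M[:, None]
    if M.sum() == 0:
        raise ValueError("no observed labels in the training set")
    if pos_weight is None:
        pos_weight = (np.ones(Y.shape[1]) if model_config.regression_mode
                      else class_weights(Y, M))
    pos_weight = np.asarray(pos_weight, dtype=np.float64)

    model = PairwiseAttentionNet(model_config, seed=train_config.seed)
    rng = np.random.default_rng(train_config.seed + 1)
    if train_config.pretrain_epochs > 0 and not model_config.pearson_F:
        _similarity_warm_start(model, X, train_config, rng)
    opt = _Adam(model.params, train_config.adam_beta1, train_config.adam_beta2,
                weight_decay=train_config.weight_decay)

    rows = []
    for epoch in range(train_config.epochs):
        lr = train_config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        ep = {"L": 0.0, "L1": 0.0, "L2": 0.0}
        n_batches = 0
        for lo in range(0, n, train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            if M[idx].sum() == 0:
                continue
            total, L1, L2 = _batch_losses(model, X[idx], Y[idx], M[idx], pos_weight, rng)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: "
                    f"L={total.data}, L1={L1.data}, L2={L2.data}, lr={lr}"
                )
            opt.zero_grad()
            total.backward()
            opt.step(lr)
            ep["L"] += float(total.data)
            ep["L1"] += float(L1.data)
            ep["L2"] += float(L2.data)
            n_batches += 1
        row = {"epoch": epoch, "lr": lr,
               **{k: v / max(n_batches, 1) for k, v in ep.items()}}
        if (validation is not None and train_config.eval_every
                and (epoch + 1) % train_config.eval_every == 0):
            row.update(_validation_metrics(model, validation))
        rows.append(row)

    model.fitted = True
    history = pd.DataFrame(rows)
    if validation is not None and train_config.epochs and not train_config.eval_every:
        final = _validation_metrics(model, validation)
        for k, v in final.items():
            history.loc[history.index[-1], k] = v
    return model, history


def _validation_metrics(model, validation) -> dict:
    from .evaluation import evaluate  # local import to avoid a cycle

    Xv, Yv, Mv = validation
    res = model.predict(np.asarray(Xv, dtype=np.float64))
    if model.config.regression_mode:
        err = (res.logits - Yv) ** 2
        mv = np.asarray(Mv, dtype=float)
        return {"val_mse": float((err * mv).sum() / max(mv.sum(), 1.0))}
    rep = evaluate(res.logits, Yv, Mv)
    out = {}
    for h in range(rep.n_heads):
        out[f"val_acc_h{h}"] = rep.accuracy[h]
        out[f"val_auc_h{h}"] = rep.auc[h]
    return out
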