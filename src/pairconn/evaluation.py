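"""Cross-validated evaluation: accuracy, AUC, average precision, CAPS MSE.

Classification metrics are computed per head coordinate over observed
(mask = 1) entries only, with the decision threshold at 0.5 on the
sigmoid of the logit.  AUC and average precision are rank statistics and
are reported as NaN ("undefined") when a head sees a single class.
Cross-validation metrics are summarized as the per-split mean and SD
(mean of per-split values, not subject-pooled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import average_precision_score, balanced_accuracy_score, roc_auc_score

from .config import ModelConfig, TrainConfig
from .data import Dataset
from .training import class_weights, make_cv_splits, train_model

log = logging.getLogger(__name__)

__all__ = ["HeadMetrics", "MetricReport", "evaluate", "cross_validate", "sensitivity_sweep"]


@dataclass
class HeadMetrics:
    """Per-head metric vectors for one evaluation set."""

    accuracy: np.ndarray
    auc: np.ndarray
    average_precision: np.ndarray
    balanced_accuracy: np.ndarray
    mse: np.ndarray | None = None

    @property
    def n_heads(self) -> int:
        return len(self.accuracy)


def evaluate(scores, labels, mask=None, threshold: float = 0.5,
             from_logits: bool = True, regression: bool = False) -> HeadMetrics:
    """Score an (n, l) prediction matrix against binary (or continuous) labels."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if mask is None:
        mask = np.ones_like(labels)
    mask = np.atleast_2d(np.asarray(mask))
    n, l = scores.shape
    if regression:
        mse = np.full(l, np.nan)
        for h in range(l):
            obs = mask[:, h] == 1
            if obs.any():
                mse[h] = float(np.mean((scores[obs, h] - labels[obs, h]) ** 2))
        nanv = np.full(l, np.nan)
        return HeadMetrics(nanv, nanv, nanv, nanv, mse=mse)

    prob = expit(scores) if from_logits else scores
    acc = np.full(l, np.nan)
    auc = np.full(l, np.nan)
    ap = np.full(l, np.nan)
    bacc = np.full(l, np.nan)
    for h in range(l):
        obs = mask[:, h] == 1
        if not obs.any():
            continue
        y = labels[obs, h].astype(int)
        p = prob[obs, h]
        acc[h] = float(np.mean((p >= threshold).astype(int) == y))
        if len(np.unique(y)) == 2:
            auc[h] = float(roc_auc_score(y, p))
            ap[h] = float(average_precision_score(y, p))
            bacc[h] = float(balanced_accuracy_score(y, (p >= threshold).astype(int)))
    return HeadMetrics(acc, auc, ap, bacc)


@dataclass
class MetricReport:
    """Per-split metrics plus mean/SD summary across splits."""

    per_split: pd.DataFrame      # columns: split, head, accuracy, auc, ap, ...
    head_names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        g = self.per_split.drop(columns=["split"]).groupby("head")
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()

    def mean(self, metric: str) -> np.ndarray:
        """Per-head across-split mean of one metric column."""
        return (self.per_split.groupby("head")[metric].mean()
                .sort_index().to_numpy())


def _split_rows(split: int, hm: HeadMetrics, head_names) -> list[dict]:
    rows = []
    for h in range(hm.n_heads):
        row = {"split": split, "head": head_names[h],
               "accuracy": hm.accuracy[h], "auc": hm.auc[h],
               "average_precision": hm.average_precision[h],
               "balanced_accuracy": hm.balanced_accuracy[h]}
        if hm.mse is not None:
            row["mse"] = hm.mse[h]
        rows.append(row)
    return rows


def _head_targets(dataset: Dataset, head: str, timepoint=None):
    """(Y, M, head_names) for a prediction head."""
    if head == "dx":
        y, m = dataset.dx_arrays()
        return y, m, ["t1", "t2", "t3"]
    if head == "caps":
        y, m = dataset.caps_arrays()
        return y, m, ["t1", "t2", "t3"]
    if head == "symptoms":
        if timepoint is None:
            raise ValueError("symptom head needs a time-point index (0, 1 or 2)")
        from .data import SYMPTOM_NAMES
        y, m = dataset.symptom_arrays(timepoint)
        return y, m, list(SYMPTOM_NAMES)
    if head == "survival":
        from .clusters_survival import build_survival_task
        sub, y = build_survival_task(dataset)
        ds = dataset.subset(sub)
        return y[:, None], np.ones((len(y), 1), dtype=int), ["persists_t3"], ds
    raise ValueError(f"unknown head {head!r}")


@dataclass
class CVResult:
    report: MetricReport
    models: list
    splits: list
    histories: list
    predictions: list        # per split: dict(ids, scores, labels, mask)


def cross_validate(
    dataset: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    head: str = "dx",
    timepoint=None,
    independent_timepoints: bool = False,
) -> CVResult:
    """Train/evaluate over random 80/20 subject splits.

    ``independent_timepoints`` is the ablation that fits one single-
    label (l=1) model per diagnosis time-point instead of one joint l=3
    model; its metrics come from the identical evaluation path.
    """
    if head == "survival":
        got = _head_targets(dataset, head)
        Y, M, head_names, dataset = got
    else:
        Y, M, head_names = _head_targets(dataset, head, timepoint)
    X = dataset.signal_array()
    ids = dataset.subject_ids
    if head == "caps":
        model_config = _with(model_config, regression_mode=True)

    splits = make_cv_splits(ids, train_config.n_splits, train_config.train_fraction,
                            train_config.seed)
    id_index = {s: i for i, s in enumerate(ids)}
    rows, models, hists, preds = [], [], [], []
    for si, (tr_ids, te_ids) in enumerate(splits):
        tr = np.array([id_index[i] for i in tr_ids])
        te = np.array([id_index[i] for i in te_ids])
        Ytr, Mtr = Y[tr], M[tr]
        Yte, Mte = Y[te], M[te]
        scaler = None
        if head == "caps":
            # z-score targets on observed training entries, per time-point
            mu = np.array([Ytr[Mtr[:, h] == 1, h].mean() for h in range(Y.shape[1])])
            sd = np.array([Ytr[Mtr[:, h] == 1, h].std() or 1.0 for h in range(Y.shape[1])])
            scaler = (mu, sd)
            Ytr = (Ytr - mu) / sd
            Yte = (Yte - mu) / sd

        if independent_timepoints:
            if head != "dx":
                raise ValueError("independent-time-point ablation applies to the dx head")
            split_models, scores_cols, hist_list = [], [], []
            for h in range(Y.shape[1]):
                mc = _with(model_config, head_size=1)
                model, hist = train_model(X[tr], Ytr[:, h], Mtr[:, h], mc, train_config)
                split_models.append(model)
                hist_list.append(hist)
                scores_cols.append(model.predict(X[te]).logits[:, 0])
            scores = np.column_stack(scores_cols)
            models.append(split_models)
            hists.append(hist_list)
        else:
            model, hist = train_model(X[tr], Ytr, Mtr, model_config, train_config)
            model.scaler = scaler
            scores = model.predict(X[te]).logits
            models.append(model)
            hists.append(hist)

        hm = evaluate(scores, Yte, Mte, regression=(head == "caps"))
        rows.extend(_split_rows(si, hm, head_names))
        preds.append({"ids": te_ids, "scores": scores, "labels": Yte, "mask": Mte})

    report = MetricReport(pd.DataFrame(rows), head_names)
    return CVResult(report, models, splits, hists, preds)


def sensitivity_sweep(
    dataset: Dataset,
    param: str,
    grid,
    model_config: ModelConfig,
    train_config: TrainConfig,
    head: str = "dx",
) -> pd.DataFrame:
    """One full cross-validation per grid value of beta or lambda.

    Returns a table with one row per grid point and the across-split
    mean accuracy (and AUC) per time-point head.
    """
    if param not in ("beta", "lambda"):
        raise ValueError("param must be 'beta' or 'lambda'")
    rows = []
    for v in grid:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{param}={v} outside [0,1]")
        mc = _with(model_config, **{"beta" if param == "beta" else "lam": float(v)})
        res = cross_validate(dataset, mc, train_config, head=head)
        row = {param: float(v)}
        for hname, acc, auc in zip(
            res.report.head_names,
            res.report.mean("accuracy"),
            res.report.mean("auc"),
        ):
            row[f"acc_{hname}"] = acc
            row[f"auc_{hname}"] = auc
        rows.append(row)
        log.info("sweep %s=%s done", param, v)
    return pd.DataFrame(rows)


def _with(cfg: ModelConfig, **kw) -> ModelConfig:
    from dataclasses import replace

    return replace(cfg, **kw)
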