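"""Edge-wise group statistics on the learned connectivity matrices.

For each unordered region pair (i, j), i < j, the attention-updated
connectivity k'_ij is symmetrized as (k'_ij + k'_ji)/2 per subject and
compared between diagnosed and non-diagnosed subjects with a two-sample
t-test (pooled-variance by default, Welch optional).  P-values are
corrected across all N(N-1)/2 pairs with the Benjamini-Hochberg step-up
procedure; pairs with adjusted p below alpha are flagged significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import Dataset

__all__ = ["collect_edges", "edge_ttests", "edge_report_for_dataset", "upper_pairs"]


def upper_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Unordered region pairs (i, j), i < j, in row-major order."""
    return [(i, j) for i in range(n_regions) for j in range(i + 1, n_regions)]


def collect_edges(model, subjects, batch_size: int = 32) -> np.ndarray:
    """Per-subject symmetrized upper-triangle of K' -> (n, N(N-1)/2).

    Under the no-reweighting ablation the first connectivity matrix K is
    used (no K' exists).
    """
    if not getattr(model, "fitted", False):
        raise ValueError("model is not trained; fit or load a bundle first")
    res = model.predict(subjects, batch_size=batch_size)
    K = res.K_prime if res.K_prime is not None else res.K
    sym = 0.5 * (K + K.transpose(0, 2, 1))
    iu = np.triu_indices(K.shape[1], k=1)
    return sym[:, iu[0], iu[1]]


def edge_ttests(
    edges: np.ndarray,
    group: np.ndarray,
    alpha: float = 0.05,
    region_names=None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per edge with BH-FDR across all pairs.

    ``edges`` is (n_subjects, n_pairs) as produced by `collect_edges`;
    ``group`` is a binary vector (1 = diagnosed).  Returns a report
    sorted by adjusted p with columns: region_i, region_j (index and
    name), mean_diff, t, df, p, p_adj, significant.
    """
    edges = np.asarray(edges, dtype=float)
    group = np.asarray(group).astype(int)
    if edges.shape[0] != group.shape[0]:
        raise ValueError("one group label per subject required")
    g1, g0 = edges[group == 1], edges[group == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both groups need at least 2 subjects")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=0, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edges with degenerate variance; p set to 1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    if equal_var:
        df = len(g1) + len(g0) - 2
        dfs = np.full(edges.shape[1], float(df))
    else:  # Welch-Satterthwaite
        v1, v0 = g1.var(ddof=1, axis=0), g0.var(ddof=1, axis=0)
        n1, n0 = len(g1), len(g0)
        num = (v1 / n1 + v0 / n0) ** 2
        den = (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dfs = np.where(den > 0, num / den, float(n1 + n0 - 2))

    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    n_regions = int(round((1 + np.sqrt(1 + 8 * edges.shape[1])) / 2))
    if n_regions * (n_regions - 1) // 2 != edges.shape[1]:
        raise ValueError(
            f"{edges.shape[1]} columns is not a triangular pair count N(N-1)/2"
        )
    pairs = upper_pairs(n_regions)
    rows = []
    for k, (i, j) in enumerate(pairs):
        rows.append({
            "region_i": i, "region_j": j,
            "name_i": region_names[i] if region_names else f"region_{i}",
            "name_j": region_names[j] if region_names else f"region_{j}",
            "mean_diff": float(g1[:, k].mean() - g0[:, k].mean()),
            "t": float(t[k]), "df": float(dfs[k]),
            "p": float(p[k]), "p_adj": float(p_adj[k]),
            "significant": bool(reject[k]),
        })
    rep = pd.DataFrame(rows).sort_values(["p_adj", "p"], kind="stable")
    return rep.reset_index(drop=True)


def edge_report_for_dataset(
    model,
    dataset: Dataset,
    timepoint: int = 0,
    alpha: float = 0.05,
    equal_var: bool = True,
    subjects: str = "all",
) -> pd.DataFrame:
    """Edge report grouping subjects by diagnosis at one time-point.

    All subjects with an observed diagnosis at the time-point are pooled
    by default, mirroring a whole-cohort association analysis.
    """
    if subjects != "all":
        dataset = dataset.subset(subjects)
    keep, group = [], []
    for sid in dataset.subject_ids:
        rec = dataset.labels[sid]
        if rec.dx_mask[timepoint] == 1:
            keep.append(sid)
            group.append(int(rec.dx[timepoint]))
    ds = dataset.subset(keep)
    edges = collect_edges(model, ds.subjects)
    return edge_ttests(edges, np.array(group), alpha=alpha,
                       region_names=ds.region_names, equal_var=equal_var)
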