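"""DSM-5 symptom clusters, dominant-cluster assignment and persistence.

The 20 PTSD symptoms partition into four DSM-5 clusters with per-cluster
minimum counts for the criterion to be met:

==========  =======================================  =======  ========
cluster     name                                     indices  minimum
==========  =======================================  =======  ========
B           Intrusion                                0-4      1
C           Avoidance                                5-6      1
D           Negative alterations in mood/cognition   7-13     2
E           Hyperarousal                             14-19    2
==========  =======================================  =======  ========

A subject's *dominant* cluster is found by scoring each cluster as the
fraction of its symptoms met, converting scores to within-cohort
percentiles (mid-rank convention) and picking the cluster whose
percentile strictly exceeds all others by at least ``margin``; ties (or
margins not met) yield no dominant cluster and such subjects are
skipped in visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset, N_SYMPTOMS

__all__ = [
    "CLUSTERS",
    "ClusterCriteria",
    "symptoms_to_clusters",
    "dominant_cluster",
    "DominanceResult",
    "extract_hidden_features",
    "embed_2d",
    "build_survival_task",
]


@dataclass(frozen=True)
class ClusterCriteria:
    cluster_id: str
    start: int
    stop: int            # exclusive
    minimum: int

    @property
    def size(self) -> int:
        return self.stop - self.start


CLUSTERS = (
    ClusterCriteria("B", 0, 5, 1),
    ClusterCriteria("C", 5, 7, 1),
    ClusterCriteria("D", 7, 14, 2),
    ClusterCriteria("E", 14, 20, 2),
)


def symptoms_to_clusters(symptom_vector) -> np.ndarray:
    """Map a 20-bit symptom vector to the four cluster criteria bits (B,C,D,E)."""
    v = np.asarray(symptom_vector)
    if v.shape[-1] != N_SYMPTOMS:
        raise ValueError(f"expected {N_SYMPTOMS} symptoms, got {v.shape[-1]}")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("symptom values must be 0/1")
    out = np.stack(
        [v[..., c.start:c.stop].sum(axis=-1) >= c.minimum for c in CLUSTERS],
        axis=-1,
    )
    return out.astype(int)


@dataclass
class DominanceResult:
    scores: np.ndarray        # (n, 4) fraction of cluster symptoms met
    percentiles: np.ndarray   # (n, 4) mid-rank percentile within the cohort
    dominant: list            # per subject: 'B'/'C'/'D'/'E' or None


def _midrank_percentiles(col: np.ndarray) -> np.ndarray:
    """Mid-rank percentile of each value within its column (ties averaged)."""
    n = len(col)
    less = (col[:, None] > col[None, :]).sum(axis=1)
    equal = (col[:, None] == col[None, :]).sum(axis=1)
    return 100.0 * (less + 0.5 * equal) / n


def dominant_cluster(symptom_matrix, margin: float = 0.0) -> DominanceResult:
    """Per-subject dominant DSM-5 cluster over a cohort's symptom vectors.

    ``margin`` is the minimum percentile gap (in points) the top cluster
    must hold over the runner-up; the default 0 demands a strict unique
    maximum.
    """
    S = np.atleast_2d(np.asarray(symptom_matrix))
    if S.shape[0] < 2:
        raise ValueError("dominance needs at least two subjects")
    scores = np.stack(
        [S[:, c.start:c.stop].sum(axis=1) / c.size for c in CLUSTERS], axis=1
    )
    pct = np.column_stack([_midrank_percentiles(scores[:, k]) for k in range(4)])
    dominant = []
    names = [c.cluster_id for c in CLUSTERS]
    for row in pct:
        order = np.argsort(row)[::-1]
        if row[order[0]] - row[order[1]] > margin:
            dominant.append(names[order[0]])
        else:
            dominant.append(None)
    return DominanceResult(scores, pct, dominant)


def extract_hidden_features(model, subjects) -> np.ndarray:
    """First classifier-layer activations (n x 100) for trained models."""
    if not getattr(model, "fitted", False):
        raise ValueError("model is not trained; fit or load a bundle first")
    return model.predict(subjects).hidden_features


def embed_2d(features: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """t-SNE embedding of the 100-dim features to the plane (seeded)."""
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return ts.fit_transform(X)


def build_survival_task(dataset: Dataset, cluster: str | None = None):
    """Persistence task: T1-positive subjects with observed T3 diagnosis.

    Returns (subject_ids, labels) where the label is 1 when the subject
    still meets the diagnosis at T3.  With ``cluster`` set, positivity
    is judged on that DSM-5 cluster criterion instead of the overall
    diagnosis (requires observed symptoms at T1 and T3).
    """
    ids, labels = [], []
    for sid in dataset.subject_ids:
        rec = dataset.labels[sid]
        if cluster is None:
            if rec.dx_mask[0] == 1 and rec.dx[0] == 1 and rec.dx_mask[2] == 1:
                ids.append(sid)
                labels.append(int(rec.dx[2]))
        else:
            if rec.symptoms_mask[0] == 1 and rec.symptoms_mask[2] == 1:
                c1 = symptoms_to_clusters(rec.symptoms[0])
                c3 = symptoms_to_clusters(rec.symptoms[2])
                k = [c.cluster_id for c in CLUSTERS].index(cluster)
                if c1[k] == 1:
                    ids.append(sid)
                    labels.append(int(c3[k]))
    if not ids:
        raise ValueError("no eligible subjects for the persistence task")
    return ids, np.asarray(labels, dtype=int)
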