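"""Synthetic longitudinal cohort generator.

Produces desk-scale cohorts with the statistical structure the
connectivity network and the edge statistics assume.  Every regional
signal is an AR(1) process; subjects whose latent chronic-case
indicator is set additionally receive, on each planted region pair, a
shared latent AR(1) signal injected into both regions, so the
group-discriminating information lives purely in pairwise coupling and
not in marginal amplitude (each series is z-scored before use by
default).  Diagnosis follows the cohort's remission pattern: chronic
cases stay positive at all three time-points, transient cases are
positive at T1 and remit, controls are negative throughout.  Symptom
vectors of diagnosed subjects always satisfy the four DSM-5 cluster
criteria; non-diagnosed subjects carry sub-threshold symptom noise.
Longitudinal dropout is monotone (a subject lost at T2 stays lost).

All distributional choices beyond the reference prevalences
(72%/29%/23% positive at the three time-points) are stand-ins chosen
for plausibility; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .data import Dataset, LabelRecord, SubjectTimeSeries, N_SYMPTOMS
from .clusters_survival import CLUSTERS

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "write_cohort"]


@dataclass
class CohortConfig:
    n_subjects: int = 160
    n_regions: int = 20
    n_timepoints_signal: int = 120
    prevalence_t1: float = 0.72
    prevalence_t2: float = 0.29
    prevalence_t3: float = 0.23
    planted_pairs: list = field(default_factory=lambda: [(0, 1), (2, 3), (4, 5)])
    effect_strength: float = 1.5
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    dropout_t2: float = 25 / 160          # study attrition T1 -> T2
    dropout_t3: float = 5 / 135           # additional attrition T2 -> T3
    enforce_remission: bool = True        # nested positives: T3+ within T2+ within T1+
    zscore: bool = True                   # z-score each regional series
    amplitude_confound: float = 0.0       # optional per-group amplitude gain
    symptom_rate_case: float = 0.55       # per-symptom rate for diagnosed subjects
    symptom_rate_control: float = 0.08    # sub-threshold noise rate
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("prevalence_t1", "prevalence_t2", "prevalence_t3",
                     "dropout_t2", "dropout_t3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.enforce_remission and not (
            self.prevalence_t3 <= self.prevalence_t2 <= self.prevalence_t1
        ):
            raise ValueError(
                "remission pattern requires prevalence_t3 <= prevalence_t2 <= "
                "prevalence_t1 (set enforce_remission=False to lift this)"
            )
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in (-1,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_strength < 0:
            raise ValueError("effect_strength must be >= 0")
        seen = set()
        for p in self.planted_pairs:
            i, j = p
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"planted pair {p} invalid for {self.n_regions} regions")
            if (i, j) in seen:
                raise ValueError(f"duplicate planted pair {p}")
            seen.add((i, j))

    def region_names(self) -> list[str]:
        width = max(3, len(str(self.n_regions - 1)))
        return [f"roi_{i:0{width}d}" for i in range(self.n_regions)]


@dataclass
class SyntheticCohort:
    time_series: list
    labels: list
    config: CohortConfig
    chronic: np.ndarray            # latent chronic-case indicator per subject
    planted_pairs: list

    def to_dataset(self) -> Dataset:
        return Dataset(self.time_series, {r.subject_id: r for r in self.labels})


def _ar1(rng, shape, phi, sd):
    """Stationary AR(1) noise along the last axis."""
    eps = rng.normal(0.0, sd, size=shape)
    x0 = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi), size=shape[:-1])
    zi = (phi * np.asarray(x0))[..., None]
    rest, _ = lfilter([1.0], [1.0, -phi], eps[..., 1:], axis=-1, zi=zi)
    return np.concatenate([np.asarray(x0)[..., None], rest], axis=-1)


def _symptoms_case(rng, rate) -> np.ndarray:
    """Symptom vector guaranteed to satisfy all four DSM-5 cluster criteria."""
    v = (rng.random(N_SYMPTOMS) < rate).astype(int)
    for c in CLUSTERS:
        have = int(v[c.start:c.stop].sum())
        need = c.minimum - have
        if need > 0:
            zeros = c.start + np.flatnonzero(v[c.start:c.stop] == 0)
            add = rng.choice(zeros, size=need, replace=False)
            v[add] = 1
    return v


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; deterministic given the config (including its seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, N, T = cfg.n_subjects, cfg.n_regions, cfg.n_timepoints_signal
    p1, p2, p3 = cfg.prevalence_t1, cfg.prevalence_t2, cfg.prevalence_t3

    dx = np.zeros((n, 3), dtype=int)
    dx[:, 0] = rng.random(n) < p1
    if cfg.enforce_remission:
        # nested persistence: a single latent uniform drives remission timing
        u = rng.random(n)
        q2 = p2 / p1 if p1 > 0 else 0.0
        q3 = p3 / p1 if p1 > 0 else 0.0
        dx[:, 1] = (dx[:, 0] == 1) & (u < q2)
        dx[:, 2] = (dx[:, 0] == 1) & (u < q3)
    else:
        dx[:, 1] = rng.random(n) < p2
        dx[:, 2] = rng.random(n) < p3
    chronic = (dx.sum(axis=1) == 3).astype(int)

    # monotone attrition
    lost2 = rng.random(n) < cfg.dropout_t2
    lost3 = lost2 | (rng.random(n) < cfg.dropout_t3)
    obs = np.column_stack([np.ones(n, dtype=int), (~lost2).astype(int), (~lost3).astype(int)])

    width = max(3, len(str(n - 1)))
    names = cfg.region_names()
    series, labels = [], []
    for s in range(n):
        X = _ar1(rng, (N, T), cfg.ar_coefficient, cfg.noise_sd)
        if chronic[s]:
            for (i, j) in cfg.planted_pairs:
                latent = _ar1(rng, (T,), cfg.ar_coefficient, cfg.noise_sd)
                X[i] += cfg.effect_strength * latent
                X[j] += cfg.effect_strength * latent
            if cfg.amplitude_confound:
                X *= 1.0 + cfg.amplitude_confound
        if cfg.zscore:
            X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        sid = f"sub_{s:0{width}d}"
        series.append(SubjectTimeSeries(sid, X, list(names), tr_seconds=cfg.tr_seconds))

        caps = 20.0 + 30.0 * dx[s] + 10.0 * chronic[s] + rng.normal(0.0, 5.0, size=3)
        caps = np.maximum(caps, 0.0)
        sym = np.zeros((3, N_SYMPTOMS), dtype=int)
        for t in range(3):
            if dx[s, t] == 1:
                sym[t] = _symptoms_case(rng, cfg.symptom_rate_case)
            else:
                sym[t] = (rng.random(N_SYMPTOMS) < cfg.symptom_rate_control).astype(int)
        persists_mask = int(dx[s, 0] == 1 and obs[s, 2] == 1)
        labels.append(LabelRecord(
            subject_id=sid,
            dx=dx[s] * obs[s],          # masked entries zeroed (never read)
            dx_mask=obs[s],
            caps=caps * obs[s],
            caps_mask=obs[s].copy(),
            symptoms=sym * obs[s][:, None],
            symptoms_mask=obs[s].copy(),
            persists_t3=int(dx[s, 2]) if persists_mask else 0,
            persists_mask=persists_mask,
        ))

    return SyntheticCohort(series, labels, cfg, chronic, list(cfg.planted_pairs))


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write one time-series file per subject, a label table, the region
    list and a manifest; returns the manifest dict."""
    from . import io as pcio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for sts in cohort.time_series:
        fname = f"ts_{sts.subject_id}.tsv"
        pcio.write_timeseries(sts, directory / fname)
        files.append(fname)
    pcio.write_labels(cohort.labels, directory / "labels.csv")
    pcio.write_regions(cohort.config.region_names(), directory / "regions.txt")
    manifest = {
        "format": "pairconn-cohort-v1",
        "seed": cohort.config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_regions": cohort.config.n_regions,
        "n_timepoints": cohort.config.n_timepoints_signal,
        "planted_pairs": [list(p) for p in cohort.planted_pairs],
        "labels": "labels.csv",
        "regions": "regions.txt",
        "timeseries": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
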