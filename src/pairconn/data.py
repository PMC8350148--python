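"""In-memory containers for parcellated time series and longitudinal labels.

Orientation convention: in memory a subject's matrix has rows = regions
and columns = timepoints (region i's signal is ``matrix[i]``); on disk
the transpose is stored (rows = timepoints) for human inspection.

Missing labels are carried by explicit 0/1 mask arrays, never by
sentinel values: masked entries are undefined and must not be read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: symptom column order: DSM-5 criteria B (intrusion, 5), C (avoidance, 2),
#: D (negative mood/cognition, 7), E (hyperarousal, 6)
SYMPTOM_NAMES = (
    ["b1", "b2", "b3", "b4", "b5"]
    + ["c1", "c2"]
    + [f"d{i}" for i in range(1, 8)]
    + [f"e{i}" for i in range(1, 7)]
)
N_SYMPTOMS = 20
TIMEPOINTS = ("t1", "t2", "t3")


@dataclass
class SubjectTimeSeries:
    """One subject's regional BOLD signals: an N x T matrix plus names."""

    subject_id: str
    matrix: np.ndarray                   # (N, T), rows = regions
    region_names: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"{self.subject_id}: expected 2-D matrix")
        n, t = self.matrix.shape
        if n < 2:
            raise ValueError(f"{self.subject_id}: need at least 2 regions, got {n}")
        if t < 16:
            raise ValueError(
                f"{self.subject_id}: need at least 16 timepoints for the "
                f"four-pool extractor, got {t}"
            )
        if len(self.region_names) != n:
            raise ValueError(f"{self.subject_id}: {len(self.region_names)} names for {n} regions")
        if len(set(self.region_names)) != n:
            raise ValueError(f"{self.subject_id}: duplicate region names")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.subject_id}: non-finite values in time series")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LabelRecord:
    """Longitudinal outcomes for one subject, with per-entry observation masks.

    ``dx`` is the binary diagnosis at the three follow-up time-points,
    ``caps`` the continuous severity score, ``symptoms`` a 3x20 binary
    matrix (columns ordered B1..B5, C1, C2, D1..D7, E1..E6) and
    ``persists_t3`` whether a subject positive at T1 still meets the
    diagnosis at the last time-point.
    """

    subject_id: str
    dx: np.ndarray                       # (3,) {0,1}
    dx_mask: np.ndarray                  # (3,) {0,1}
    caps: np.ndarray = None              # (3,) float
    caps_mask: np.ndarray = None
    symptoms: np.ndarray = None          # (3, 20) {0,1}
    symptoms_mask: np.ndarray = None     # (3,) per-time-point
    persists_t3: int = 0
    persists_mask: int = 0

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=np.int64)
        self.dx_mask = np.asarray(self.dx_mask, dtype=np.int64)
        if self.caps is None:
            self.caps = np.zeros(3)
        if self.caps_mask is None:
            self.caps_mask = np.zeros(3, dtype=np.int64)
        if self.symptoms is None:
            self.symptoms = np.zeros((3, N_SYMPTOMS), dtype=np.int64)
        if self.symptoms_mask is None:
            self.symptoms_mask = np.zeros(3, dtype=np.int64)
        self.caps = np.asarray(self.caps, dtype=np.float64)
        self.caps_mask = np.asarray(self.caps_mask, dtype=np.int64)
        self.symptoms = np.asarray(self.symptoms, dtype=np.int64)
        self.symptoms_mask = np.asarray(self.symptoms_mask, dtype=np.int64)
        if self.dx.shape != (3,) or self.dx_mask.shape != (3,):
            raise ValueError(f"{self.subject_id}: dx and dx_mask must have shape (3,)")
        if self.symptoms.shape != (3, N_SYMPTOMS):
            raise ValueError(f"{self.subject_id}: symptoms must be 3x{N_SYMPTOMS}")
        bad = set(np.unique(self.symptoms)) - {0, 1}
        if bad:
            raise ValueError(f"{self.subject_id}: symptom values outside {{0,1}}: {sorted(bad)}")
        # symptoms observed at a time-point implies the diagnosis there is observed
        if np.any((self.symptoms_mask == 1) & (self.dx_mask == 0)):
            raise ValueError(f"{self.subject_id}: symptoms observed where diagnosis is not")


@dataclass
class Dataset:
    """A cohort: aligned time series and labels sharing one region list."""

    subjects: list[SubjectTimeSeries]
    labels: dict[str, LabelRecord]
    region_names: list[str] = field(default=None)

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("empty dataset")
        if self.region_names is None:
            self.region_names = list(self.subjects[0].region_names)
        for s in self.subjects:
            if s.region_names != self.region_names:
                raise ValueError(f"{s.subject_id}: region names differ from the canonical list")
            if s.subject_id not in self.labels:
                raise ValueError(f"{s.subject_id}: no label record")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def signal_array(self) -> np.ndarray:
        """Stack all subjects into a (n, N, T) array (requires equal T)."""
        return np.stack([s.matrix for s in self.subjects])

    def dx_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n,3) diagnosis labels and masks, subject order preserved."""
        y = np.stack([self.labels[i].dx for i in self.subject_ids])
        m = np.stack([self.labels[i].dx_mask for i in self.subject_ids])
        return y, m

    def caps_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        y = np.stack([self.labels[i].caps for i in self.subject_ids])
        m = np.stack([self.labels[i].caps_mask for i in self.subject_ids])
        return y, m

    def symptom_arrays(self, timepoint: int) -> tuple[np.ndarray, np.ndarray]:
        """(n,20) symptom bits and (n,20) masks for one time-point index."""
        y = np.stack([self.labels[i].symptoms[timepoint] for i in self.subject_ids])
        m = np.repeat(
            np.array([[self.labels[i].symptoms_mask[timepoint]] for i in self.subject_ids]),
            N_SYMPTOMS, axis=1,
        )
        return y, m

    def subset(self, ids) -> "Dataset":
        keep = set(ids)
        subs = [s for s in self.subjects if s.subject_id in keep]
        labs = {s.subject_id: self.labels[s.subject_id] for s in subs}
        return Dataset(subs, labs, list(self.region_names))
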