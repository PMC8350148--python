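"""Readers and writers for time series, label tables and model bundles.

On-disk orientation: a time-series file has one row per timepoint and
one column per region (header row = region names); in memory the matrix
is transposed to regions x timepoints.  Values are written with 17
significant digits so that a write/read round trip is bit-exact.

The label table is a single CSV keyed by ``subject_id`` with columns
``dx_t1..dx_t3``, ``caps_t1..caps_t3``, ``sym_<tp>_<symptom>`` for the
20 DSM-5 symptoms per time-point (b1..b5, c1, c2, d1..d7, e1..e6) and
``persists_t3``.  An empty cell means "missing" and sets the mask.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .data import Dataset, LabelRecord, SubjectTimeSeries, SYMPTOM_NAMES, TIMEPOINTS
from .model import PairwiseAttentionNet

log = logging.getLogger(__name__)

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_labels", "write_labels",
    "read_regions", "write_regions",
    "read_cohort", "save_model", "load_model",
]

BUNDLE_VERSION = 1


class ParseError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def write_timeseries(sts: SubjectTimeSeries, path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(sts.region_names) + "\n")
        # rows = timepoints on disk
        for row in sts.matrix.T:
            fh.write(sep.join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(path, subject_id: str | None = None,
                    tr_seconds: float = 2.0) -> SubjectTimeSeries:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    with open(path) as fh:
        names = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"{path}: duplicate region names {dupes}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ParseError(f"{path}: malformed table ({e})") from e
    df.columns = names
    mat = df.to_numpy()
    if mat.dtype == object or not np.issubdtype(mat.dtype, np.number):
        for r in range(len(df)):
            for c, col in enumerate(names):
                try:
                    float(df.iloc[r, c])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell at data row {r + 1}, column {col!r}"
                    ) from None
        mat = mat.astype(float)
    bad = np.argwhere(~np.isfinite(mat.astype(float)))
    if len(bad):
        r, c = bad[0]
        raise ParseError(
            f"{path}: missing/non-finite value at data row {r + 1}, column {names[c]!r}"
        )
    if subject_id is None:
        subject_id = path.stem.removeprefix("ts_")
    return SubjectTimeSeries(subject_id, mat.astype(float).T, names, tr_seconds)


def write_regions(names, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(names) + "\n")


def read_regions(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _label_columns() -> list[str]:
    cols = ["subject_id"]
    cols += [f"dx_{t}" for t in TIMEPOINTS]
    cols += [f"caps_{t}" for t in TIMEPOINTS]
    for t in TIMEPOINTS:
        cols += [f"sym_{t}_{s}" for s in SYMPTOM_NAMES]
    cols.append("persists_t3")
    return cols


def write_labels(records, path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        for k, t in enumerate(TIMEPOINTS):
            row[f"dx_{t}"] = int(r.dx[k]) if r.dx_mask[k] else None
            row[f"caps_{t}"] = float(r.caps[k]) if r.caps_mask[k] else None
            for si, s in enumerate(SYMPTOM_NAMES):
                row[f"sym_{t}_{s}"] = (int(r.symptoms[k, si])
                                       if r.symptoms_mask[k] else None)
        row["persists_t3"] = int(r.persists_t3) if r.persists_mask else None
        rows.append(row)
    pd.DataFrame(rows, columns=_label_columns()).to_csv(path, index=False,
                                                        float_format="%.17g")


def read_labels(path) -> dict[str, LabelRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    known = set(_label_columns())
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("%s: ignoring unknown columns %s", path, unknown)
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: missing subject_id column")
    out: dict[str, LabelRecord] = {}
    for _, row in df.iterrows():
        sid = row["subject_id"]
        dx = np.zeros(3, dtype=int)
        dxm = np.zeros(3, dtype=int)
        caps = np.zeros(3)
        capsm = np.zeros(3, dtype=int)
        sym = np.zeros((3, len(SYMPTOM_NAMES)), dtype=int)
        symm = np.zeros(3, dtype=int)
        for k, t in enumerate(TIMEPOINTS):
            v = row.get(f"dx_{t}")
            if v is not None and not pd.isna(v):
                dx[k], dxm[k] = int(v), 1
            v = row.get(f"caps_{t}")
            if v is not None and not pd.isna(v):
                caps[k], capsm[k] = float(v), 1
            svals = [row.get(f"sym_{t}_{s}") for s in SYMPTOM_NAMES]
            present = [v is not None and not pd.isna(v) for v in svals]
            if all(present):
                for si, v in enumerate(svals):
                    iv = int(v)
                    if iv not in (0, 1):
                        raise ParseError(
                            f"{path}: subject {sid}: symptom sym_{t}_"
                            f"{SYMPTOM_NAMES[si]} = {v!r} outside {{0,1}}"
                        )
                    sym[k, si] = iv
                symm[k] = 1
            elif any(present):
                raise ParseError(
                    f"{path}: subject {sid}: partially observed symptoms at {t}"
                )
        pv = row.get("persists_t3")
        pm = int(pv is not None and not pd.isna(pv))
        out[sid] = LabelRecord(
            subject_id=sid, dx=dx, dx_mask=dxm, caps=caps, caps_mask=capsm,
            symptoms=sym, symptoms_mask=symm,
            persists_t3=int(pv) if pm else 0, persists_mask=pm,
        )
    return out


def read_cohort(directory) -> Dataset:
    """Load a cohort directory written by `simulate.write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    regions = read_regions(directory / manifest["regions"])
    labels = read_labels(directory / manifest["labels"])
    subjects = []
    for fname in manifest["timeseries"]:
        sts = read_timeseries(directory / fname)
        if sts.region_names != regions:
            raise ParseError(
                f"{fname}: header region names disagree with {manifest['regions']}"
            )
        subjects.append(sts)
    return Dataset(subjects, labels, regions)


def save_model(model: PairwiseAttentionNet, directory, extra: dict | None = None) -> None:
    """Model bundle: config JSON + parameter arrays + metadata."""
    from .config import config_to_dict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "seed": model.seed,
        "fitted": bool(model.fitted),
        "config": config_to_dict(model.config),
    }
    if extra:
        meta.update(extra)
    with open(directory / "model.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    np.savez(directory / "params.npz", **model.state_dict())


def load_model(directory) -> PairwiseAttentionNet:
    directory = Path(directory)
    meta_path = directory / "model.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no model bundle in {directory}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    cfg = dict(meta["config"])
    for k in ("conv_filters", "similarity_hidden", "classifier_hidden"):
        cfg[k] = tuple(cfg[k])
    model = PairwiseAttentionNet(ModelConfig(**cfg), seed=meta.get("seed", 0))
    with np.load(directory / "params.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.fitted = bool(meta.get("fitted", True))
    return model
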