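"""Readers and writers for the pipeline's file formats.

Tabular data are TSV (time series with a region-ID header; manifests;
region tables; edge lists), volumes are NIfTI via nibabel, motion traces
are 6-column whitespace text with the rotation unit declared in a header
comment, and reports/truth files are JSON. Region IDs are 1-based
everywhere, matching atlas label conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, FeatureVector
from .preproc import MotionTrace, RoiTimeSeries

__all__ = [
    "ManifestRow",
    "StudyManifest",
    "RegionTable",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_motion_txt",
    "write_motion_txt",
    "read_manifest",
    "write_manifest",
    "read_region_table",
    "write_region_table",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_feature_vector_tsv",
    "write_edge_list_tsv",
    "write_region_weights_tsv",
    "read_truth_json",
    "write_truth_json",
    "write_json",
]

SESSIONS = ("pre", "post")
SESSION_LABEL = {"pre": -1, "post": 1}


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    session: str  # "pre" | "post"
    label: int  # -1 | +1
    path: str
    motion_path: str | None = None


@dataclass(frozen=True)
class StudyManifest:
    """Per-sample file listing with pairing validation.

    Invariants: label is -1 iff session is "pre"; every subject appears
    once per session; referenced paths exist (checked when requested).
    """

    rows: tuple  # of ManifestRow
    kind: str = "timeseries"  # or "features"

    def __post_init__(self) -> None:
        seen = set()
        subjects: dict[str, set] = {}
        for r in self.rows:
            if r.session not in SESSIONS:
                raise ValueError(f"manifest: bad session {r.session!r} for {r.subject_id}")
            if r.label != SESSION_LABEL[r.session]:
                raise ValueError(
                    f"manifest: subject {r.subject_id} session {r.session} must carry "
                    f"label {SESSION_LABEL[r.session]}, got {r.label}"
                )
            key = (r.subject_id, r.session)
            if key in seen:
                raise ValueError(f"manifest: duplicate entry {key}")
            seen.add(key)
            subjects.setdefault(r.subject_id, set()).add(r.session)
        for s, sess in subjects.items():
            if sess != set(SESSIONS):
                raise ValueError(f"manifest: subject {s} is unpaired (has only {sorted(sess)})")

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.rows})

    def check_paths(self, root: Path | None = None) -> None:
        root = Path(root) if root else Path(".")
        for r in self.rows:
            p = root / r.path
            if not p.exists():
                raise FileNotFoundError(f"manifest path does not exist: {p}")


@dataclass(frozen=True)
class RegionTable:
    """Atlas label IDs with region names (and optional category)."""

    ids: np.ndarray
    names: tuple
    categories: tuple = ()

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        if np.unique(ids).size != ids.size:
            raise ValueError("region table has duplicate label IDs")
        if len(self.names) != ids.size:
            raise ValueError("region table needs one name per ID")
        object.__setattr__(self, "ids", ids)

    def name_of(self, label: int) -> str:
        pos = np.flatnonzero(self.ids == label)
        if pos.size == 0:
            raise KeyError(f"label {label} not in region table")
        return self.names[int(pos[0])]

    def check_covers(self, labels) -> None:
        missing = np.setdiff1d(np.asarray(labels, dtype=int), self.ids)
        if missing.size:
            raise ValueError(f"region table is missing label(s) {missing.tolist()}")


# ---------------------------------------------------------------- time series


def write_timeseries_tsv(ts: RoiTimeSeries, path) -> None:
    df = pd.DataFrame(ts.data, columns=[str(i) for i in ts.region_ids])
    with open(path, "w") as fh:
        fh.write(f"# tr_seconds={ts.tr}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path, tr: float | None = None) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# tr_seconds="):
            file_tr = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            file_tr = None
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    use_tr = tr if tr is not None else file_tr
    if use_tr is None:
        raise ValueError(f"{path}: TR not in file header and not supplied")
    try:
        ids = np.array([int(c) for c in df.columns])
    except ValueError as e:
        raise ValueError(f"{path}: header must be integer region IDs ({e})") from None
    return RoiTimeSeries(data=df.to_numpy(dtype=float), tr=use_tr, region_ids=ids)


# -------------------------------------------------------------------- motion


def write_motion_txt(m: MotionTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# columns: tx_mm ty_mm tz_mm rx ry rz; rotation_unit={m.unit}\n")
        np.savetxt(fh, m.params, fmt="%.10g")


def read_motion_txt(path, unit: str | None = None) -> MotionTrace:
    path = Path(path)
    file_unit = None
    with open(path) as fh:
        first = fh.readline()
        if "rotation_unit=" in first:
            file_unit = first.rsplit("rotation_unit=", 1)[1].strip()
    params = np.loadtxt(path, comments="#")
    use_unit = unit if unit is not None else file_unit
    if use_unit is None:
        raise ValueError(
            f"{path}: rotation unit not declared (no header comment and no --unit)"
        )
    return MotionTrace(params=np.atleast_2d(params), unit=use_unit)


# ----------------------------------------------------------------- manifests


def write_manifest(m: StudyManifest, path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "session": r.session,
            "label": r.label,
            "path": r.path,
            "motion_path": r.motion_path or "",
        }
        for r in m.rows
    ]
    df = pd.DataFrame(rows)
    df.attrs["kind"] = m.kind
    with open(path, "w") as fh:
        fh.write(f"# kind={m.kind}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_manifest(path) -> StudyManifest:
    path = Path(path)
    kind = "timeseries"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# kind="):
            kind = first.split("=", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t", dtype={"subject_id": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "session", "label", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    rows = []
    for i, rec in df.iterrows():
        motion = rec.get("motion_path", "")
        motion = None if (pd.isna(motion) or motion == "") else str(motion)
        try:
            rows.append(
                ManifestRow(
                    subject_id=str(rec["subject_id"]),
                    session=str(rec["session"]),
                    label=int(rec["label"]),
                    path=str(rec["path"]),
                    motion_path=motion,
                )
            )
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path}, line {i + 3}: {e}") from None
    try:
        return StudyManifest(rows=tuple(rows), kind=kind)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


# ------------------------------------------------------------- region tables


def write_region_table(t: RegionTable, path) -> None:
    df = pd.DataFrame({"label": t.ids, "name": t.names})
    if t.categories:
        df["category"] = t.categories
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path) -> RegionTable:
    df = pd.read_csv(path, sep="\t")
    if not {"label", "name"} <= set(df.columns):
        raise ValueError(f"{path}: region table needs 'label' and 'name' columns")
    cats = tuple(df["category"]) if "category" in df.columns else ()
    return RegionTable(
        ids=df["label"].to_numpy(dtype=int), names=tuple(df["name"]), categories=cats
    )


# ------------------------------------------------------- matrices & features


def write_matrix_tsv(m: ConnectivityMatrix, path) -> None:
    pd.DataFrame(
        m.values, columns=[str(i) for i in m.region_ids], index=m.region_ids
    ).to_csv(path, sep="\t", float_format="%.10g", index_label="region")


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region")
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), region_ids=np.array([int(c) for c in df.columns])
    )


def write_feature_vector_tsv(fv: FeatureVector, path, names: RegionTable | None = None) -> None:
    df = pd.DataFrame(
        {"i": fv.edges[:, 0], "j": fv.edges[:, 1], "z": fv.z}
    )
    if names is not None:
        df.insert(2, "name_i", [names.name_of(int(i)) for i in fv.edges[:, 0]])
        df.insert(3, "name_j", [names.name_of(int(j)) for j in fv.edges[:, 1]])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_edge_list_tsv(edge_rows: list[dict], path) -> None:
    pd.DataFrame(edge_rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_region_weights_tsv(weights: np.ndarray, region_ids, path, names=None) -> None:
    df = pd.DataFrame({"region": region_ids, "weight": weights})
    if names is not None:
        df.insert(1, "name", [names.name_of(int(r)) for r in region_ids])
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- JSON


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_truth_json(effect, path) -> None:
    write_json(
        {
            "edges": [list(e) for e in effect.edges],
            "delta_r": list(effect.delta_r),
            "direction": list(effect.direction),
        },
        path,
    )


def read_truth_json(path):
    from .synthetic import PlantedEffect

    with open(path) as fh:
        d = json.load(fh)
    return PlantedEffect(
        edges=[tuple(e) for e in d["edges"]],
        delta_r=d["delta_r"],
        direction=d.get("direction"),
    )
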