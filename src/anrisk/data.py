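"""Data model and I/O for morphometric feature tables and connectomes.

The central container is :class:`FeatureTable`: an ordered set of scans
(rows) by an ordered set of regional morphometric features (columns), plus
per-scan metadata (group, age, estimated intracranial volume, BMI-SDS,
optional outcome score) and per-feature descriptors.  Feature *kind*
(cortical thickness vs. subcortical gray-matter volume vs. CSF-space volume)
is carried explicitly because it determines which confounds apply to a
feature: volumetric kinds are adjusted for head size (eTIV), thickness is
not.

File dialect: comma-separated UTF-8, one row per scan, with a sidecar
descriptor CSV (feature name, kind, hemisphere, region label).  Connectivity
matrices are dense square CSV with region labels as header; they are
symmetrized and their diagonal zeroed on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "GROUPS",
    "HC",
    "ACAN_TP1",
    "ACAN_TP2",
    "RECAN",
    "FeatureKind",
    "FeatureDescriptor",
    "SubjectRecord",
    "FeatureTable",
    "ConnectivityMatrix",
    "read_feature_table",
    "write_feature_table",
    "validate_table",
    "read_connectivity_matrix",
    "write_connectivity_matrix",
]

# Canonical group labels: healthy controls, acutely underweight patients at
# treatment start (TP1), the same patients after partial weight-restoration
# (TP2), and long-term weight-recovered former patients.
HC = "HC"
ACAN_TP1 = "acAN_TP1"
ACAN_TP2 = "acAN_TP2"
RECAN = "recAN"
GROUPS = (HC, ACAN_TP1, ACAN_TP2, RECAN)


class FeatureKind:
    """Feature kinds; volumetric kinds receive eTIV adjustment."""

    CORTICAL_THICKNESS = "cortical_thickness"
    SUBCORTICAL_GM_VOLUME = "subcortical_gm_volume"
    CSF_VOLUME = "csf_volume"

    ALL = (CORTICAL_THICKNESS, SUBCORTICAL_GM_VOLUME, CSF_VOLUME)
    # CSF-space measures are volumes, hence head-size dependent.
    VOLUMETRIC = (SUBCORTICAL_GM_VOLUME, CSF_VOLUME)


HEMISPHERES = ("left", "right", "bilateral", "none")

#: Canonical metadata column names, in file order.
METADATA_COLUMNS = ("scan_id", "subject_id", "group", "age", "etiv", "bmi_sds", "outcome")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One morphometric feature: name, kind, hemisphere and region label."""

    name: str
    kind: str
    hemisphere: str = "none"
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FeatureKind.ALL:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r} for {self.name!r}")

    @property
    def is_volumetric(self) -> bool:
        return self.kind in FeatureKind.VOLUMETRIC


@dataclass
class SubjectRecord:
    """Metadata for one scan (a subject may contribute scans at several timepoints)."""

    scan_id: str
    subject_id: str
    group: str
    age: float
    etiv: float
    bmi_sds: float
    outcome: float | None = None


@dataclass
class FeatureTable:
    """Scans-by-features matrix with aligned metadata and descriptors."""

    records: list[SubjectRecord]
    descriptors: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise IntegrityError("values must be a 2-D matrix")
        if self.values.shape != (len(self.records), len(self.descriptors)):
            raise IntegrityError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.records)} records x {len(self.descriptors)} descriptors"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def n_scans(self) -> int:
        return len(self.records)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    @property
    def feature_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def scan_ids(self) -> list[str]:
        return [r.scan_id for r in self.records]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def groups(self) -> np.ndarray:
        return np.asarray([r.group for r in self.records], dtype=object)

    def metadata(self, name: str) -> np.ndarray:
        """Per-scan metadata vector (``age``, ``etiv``, ``bmi_sds``, ``outcome``)."""
        vals = [getattr(r, name) for r in self.records]
        if name == "outcome":
            return np.asarray([np.nan if v is None else v for v in vals], dtype=float)
        return np.asarray(vals, dtype=float)

    def group_mask(self, *groups: str) -> np.ndarray:
        g = self.groups
        mask = np.zeros(self.n_scans, dtype=bool)
        for grp in groups:
            mask |= g == grp
        return mask

    def subset(self, rows: np.ndarray | Sequence[int]) -> "FeatureTable":
        """A new table restricted to the given row indices or boolean mask."""
        idx = np.asarray(rows)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            records=[replace(self.records[i]) for i in idx],
            descriptors=list(self.descriptors),
            values=self.values[idx].copy(),
        )

    def copy(self) -> "FeatureTable":
        return self.subset(np.arange(self.n_scans))

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        """Same metadata/descriptors with a replaced value matrix."""
        return FeatureTable(
            records=[replace(r) for r in self.records],
            descriptors=list(self.descriptors),
            values=np.asarray(values, dtype=float).copy(),
        )

    def assert_same_features(self, names: Sequence[str]) -> None:
        if list(names) != self.feature_names:
            raise SchemaError("feature schema mismatch between table and model")


# ---------------------------------------------------------------------------
# Feature-table I/O
# ---------------------------------------------------------------------------


def _infer_kind(name: str) -> FeatureDescriptor:
    """Fallback descriptor inference from FreeSurfer-style naming conventions."""
    low = name.lower()
    hemi = "none"
    region = name
    if low.startswith(("lh_", "left")):
        hemi = "left"
    elif low.startswith(("rh_", "right")):
        hemi = "right"
    if low.endswith("_thickness"):
        kind = FeatureKind.CORTICAL_THICKNESS
        region = name[3:-len("_thickness")] if name[:3] in ("lh_", "rh_") else name
    elif any(tok in low for tok in ("vent", "csf", "choroid")):
        kind = FeatureKind.CSF_VOLUME
    else:
        kind = FeatureKind.SUBCORTICAL_GM_VOLUME
    return FeatureDescriptor(name=name, kind=kind, hemisphere=hemi, region_label=region)


def _descriptor_sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_descriptors.csv")


def read_descriptors(path: str | Path) -> list[FeatureDescriptor]:
    """Read a descriptor CSV (columns: name, kind, hemisphere, region_label)."""
    df = pd.read_csv(path, dtype=str)
    required = {"name", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"descriptor file {path} is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureDescriptor(
                name=row["name"],
                kind=row["kind"],
                hemisphere=row.get("hemisphere", "none") or "none",
                region_label=row.get("region_label", "") or "",
            )
        )
    return out


def write_descriptors(descriptors: Iterable[FeatureDescriptor], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": d.name,
                "kind": d.kind,
                "hemisphere": d.hemisphere,
                "region_label": d.region_label,
            }
            for d in descriptors
        ]
    )
    df.to_csv(path, index=False)


def read_feature_table(
    path: str | Path,
    metadata_columns: Mapping[str, str] | None = None,
    descriptor_path: str | Path | None = None,
) -> FeatureTable:
    """Read a feature table from CSV.

    Parameters
    ----------
    path
        Delimited text file with one header row; metadata columns plus at
        least one feature column.
    metadata_columns
        Optional mapping from canonical metadata names (``scan_id``,
        ``subject_id``, ``group``, ``age``, ``etiv``, ``bmi_sds``,
        ``outcome``) to the column names used in the file.
    descriptor_path
        Sidecar descriptor CSV.  Defaults to ``<stem>_descriptors.csv`` next
        to ``path``; if absent, kinds are inferred from naming conventions.
    """
    path = Path(path)
    colmap = {c: c for c in METADATA_COLUMNS}
    if metadata_columns:
        colmap.update(metadata_columns)
    df = pd.read_csv(path, float_precision="round_trip")

    mandatory = [colmap[c] for c in METADATA_COLUMNS if c != "outcome"]
    for col in mandatory:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    meta_cols = [colmap[c] for c in METADATA_COLUMNS if colmap[c] in df.columns]
    feature_cols = [c for c in df.columns if c not in meta_cols]
    if not feature_cols:
        raise FormatError(f"no feature columns found in {path}")

    # Parse feature cells strictly, naming the offending cell on failure.
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy() & df[col].notna().to_numpy())
        if bad.size:
            raise ParseError(
                f"non-numeric value {df[col].iloc[bad[0]]!r} at row {bad[0]}, "
                f"column {col!r} in {path}"
            )
        if parsed.isna().any():
            i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise ParseError(f"missing value at row {i}, column {col!r} in {path}")
        values[:, j] = parsed.to_numpy(dtype=float)

    scan_ids = df[colmap["scan_id"]].astype(str)
    if scan_ids.duplicated().any():
        dup = scan_ids[scan_ids.duplicated()].iloc[0]
        raise IntegrityError(f"duplicate scan_id {dup!r} in {path}")

    has_outcome = colmap["outcome"] in df.columns
    records = []
    for i in range(len(df)):
        outcome = None
        if has_outcome:
            v = df[colmap["outcome"]].iloc[i]
            outcome = None if pd.isna(v) else float(v)
        records.append(
            SubjectRecord(
                scan_id=str(scan_ids.iloc[i]),
                subject_id=str(df[colmap["subject_id"]].iloc[i]),
                group=str(df[colmap["group"]].iloc[i]),
                age=float(df[colmap["age"]].iloc[i]),
                etiv=float(df[colmap["etiv"]].iloc[i]),
                bmi_sds=float(df[colmap["bmi_sds"]].iloc[i]),
                outcome=outcome,
            )
        )

    if descriptor_path is None and _descriptor_sidecar_path(path).exists():
        descriptor_path = _descriptor_sidecar_path(path)
    if descriptor_path is not None:
        descriptors = read_descriptors(descriptor_path)
        by_name = {d.name: d for d in descriptors}
        missing = [c for c in feature_cols if c not in by_name]
        if missing:
            raise FormatError(f"descriptor file lacks entries for features: {missing[:5]}")
        descriptors = [by_name[c] for c in feature_cols]
    else:
        descriptors = [_infer_kind(c) for c in feature_cols]

    return FeatureTable(records=records, descriptors=descriptors, values=values)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    descriptor_path: str | Path | None = None,
) -> None:
    """Write a table (and its descriptor sidecar) as CSV, re-readable by
    :func:`read_feature_table`."""
    path = Path(path)
    meta = {
        "scan_id": table.scan_ids,
        "subject_id": table.subject_ids,
        "group": list(table.groups),
        "age": table.metadata("age"),
        "etiv": table.metadata("etiv"),
        "bmi_sds": table.metadata("bmi_sds"),
        "outcome": table.metadata("outcome"),
    }
    df = pd.DataFrame(meta)
    feat = pd.DataFrame(table.values, columns=table.feature_names)
    df = pd.concat([df, feat], axis=1)
    # Full round-trip precision for feature values and float metadata.
    df.to_csv(path, index=False, float_format="%.17g")
    if descriptor_path is None:
        descriptor_path = _descriptor_sidecar_path(path)
    write_descriptors(table.descriptors, descriptor_path)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_table(table: FeatureTable) -> list[str]:
    """Return a list of invariant violations (empty iff the table is valid).

    Pure: repeated calls on the same table give identical output.  Violations
    name the offending record or descriptor and the rule violated.
    """
    violations: list[str] = []
    n, p = table.values.shape
    if n != len(table.records):
        violations.append("matrix row count does not equal record count")
    if p != len(table.descriptors):
        violations.append("matrix column count does not equal descriptor count")

    seen_names: set[str] = set()
    for d in table.descriptors:
        if d.name in seen_names:
            violations.append(f"descriptor {d.name!r}: duplicate feature name")
        seen_names.add(d.name)

    seen_scans: set[str] = set()
    for r in table.records:
        if r.scan_id in seen_scans:
            violations.append(f"record {r.scan_id!r}: duplicate scan_id")
        seen_scans.add(r.scan_id)
        if not r.age > 0:
            violations.append(f"record {r.scan_id!r}: age must be > 0 (got {r.age})")
        if not r.etiv > 0:
            violations.append(f"record {r.scan_id!r}: etiv must be > 0 (got {r.etiv})")
        if r.group not in GROUPS:
            violations.append(f"record {r.scan_id!r}: unknown group {r.group!r}")

    bad = ~np.isfinite(table.values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        violations.append(
            f"record {table.records[int(i)].scan_id!r}, feature "
            f"{table.descriptors[int(j)].name!r}: non-finite value"
        )
    return violations


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative region-by-region connectivity with zero diagonal."""

    region_labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.region_labels)
        if self.weights.shape != (n, n):
            raise IntegrityError("weights must be square and match region_labels")
        if not np.allclose(self.weights, self.weights.T, atol=1e-9):
            raise IntegrityError("weights must be symmetric within 1e-9")
        if np.any(np.diag(self.weights) != 0.0):
            raise IntegrityError("diagonal must be exactly zero")
        if np.any(self.weights < 0):
            raise IntegrityError("weights must be nonnegative")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


def _normalize_weights(w: np.ndarray) -> tuple[np.ndarray, int]:
    """Symmetrize, clip negatives (returning the clipped count), zero the diagonal."""
    w = np.asarray(w, dtype=float)
    w = 0.5 * (w + w.T)
    n_neg = int(np.sum(w < 0))
    if n_neg:
        w = np.clip(w, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w, n_neg


def connectivity_from_raw(labels: Sequence[str], weights: np.ndarray) -> ConnectivityMatrix:
    """Build a valid matrix from possibly asymmetric/negative raw weights.

    Functional connectomes may contain negative entries; the weighted-degree
    centrality definition assumes nonnegative ties, so negatives are clipped
    to zero (count logged).
    """
    w, n_neg = _normalize_weights(weights)
    if n_neg:
        logger.info("clipped %d negative connectivity entries to zero", n_neg)
    return ConnectivityMatrix(region_labels=list(labels), weights=w)


def read_connectivity_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a dense square CSV (header row = region labels)."""
    df = pd.read_csv(path, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise FormatError(
            f"connectivity matrix in {path} is {w.shape[0]}x{w.shape[1]}, expected square"
        )
    return connectivity_from_raw(labels, w)


def write_connectivity_matrix(conn: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(conn.weights, columns=conn.region_labels).to_csv(
        path, index=False, float_format="%.17g"
    )
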