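"""Dataset input, integrity checking, exploratory summaries, and run manifests.

Chemical structures arrive as SDF (V2000), SMILES (one per line, optional
tab-separated id), CSV, or XLSX (the latter two must carry a SMILES column).
Labels, when present, are binary, multiclass, or continuous. Rows whose
structure cannot be parsed, or whose label is missing in a labeled run, are
removed by :func:`integrity_check` and enumerated in a removed-rows report.

The :class:`RunManifest` is the complete machine-readable record of a run:
every chosen option, hyperparameter, seed, and stage result. It round-trips
losslessly through JSON and is sufficient to replay a run on a new dataset or
re-render past results without recomputation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

LABEL_KINDS = ("none", "binary", "multiclass", "continuous")
REMOVAL_REASONS = (
    "unreadable_structure",
    "missing_value",
    "conflicting_duplicate",
    "duplicate",
)

MANIFEST_SCHEMA_VERSION = 1


@dataclass
class MoleculeRecord:
    """One input structure with its parse status and optional raw label."""

    record_id: str
    source_index: int
    structure_text: str
    label: Any = None
    parse_ok: bool = True


@dataclass
class Dataset:
    records: list[MoleculeRecord]
    label_kind: str = "none"
    label_column: str | None = None
    #: how raw label values were mapped to integer codes (binary/multiclass)
    label_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"unknown label_kind {self.label_kind!r}")

    @property
    def n(self) -> int:
        return len(self.records)

    def retained(self) -> list[MoleculeRecord]:
        return [r for r in self.records if r.parse_ok]

    def labels(self) -> np.ndarray | None:
        """Label vector aligned with the records, or None for unlabeled data."""
        if self.label_kind == "none":
            return None
        vals = [r.label for r in self.records]
        dtype = float if self.label_kind == "continuous" else int
        return np.asarray(vals, dtype=dtype)


@dataclass
class RemovedRowsReport:
    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, source_index: int, reason: str) -> None:
        if reason not in REMOVAL_REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        self.rows.append((int(source_index), reason))

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["source_index", "reason"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ExploratorySummary:
    n_retained: int
    n_unreadable: int
    n_missing: int
    class_counts: dict[int, int] | None = None
    histogram: tuple[list[float], list[int]] | None = None  # (bin_edges, counts)


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def _coerce_labels(records: list[MoleculeRecord], label_kind: str) -> dict[str, int] | None:
    """Coerce raw labels in place to the declared kind; return the value map used.

    Binary labels are accepted as {0,1} or as exactly two distinct strings
    mapped by sorted order. Multiclass string labels are mapped to 0..C-1 by
    sorted order. Missing labels are left as None (removed later by the
    integrity check, not here).
    """
    if label_kind == "none":
        for r in records:
            r.label = None
        return None

    present = [(r, r.label) for r in records if not _is_missing(r.label)]
    for r in records:
        if _is_missing(r.label):
            r.label = None

    if label_kind == "continuous":
        for r, v in present:
            try:
                r.label = float(v)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"label {v!r} (row {r.source_index}) not coercible to continuous"
                ) from exc
        return None

    # binary / multiclass: try numeric codes first
    def _as_int(v: Any) -> int | None:
        try:
            f = float(v)
        except (TypeError, ValueError):
            return None
        return int(f) if f == int(f) else None

    ints = [_as_int(v) for _, v in present]
    if all(i is not None for i in ints):
        distinct = sorted(set(ints))
        if label_kind == "binary" and not set(distinct) <= {0, 1}:
            raise ValueError(f"binary labels must be 0/1, got values {distinct}")
        for (r, _), i in zip(present, ints):
            r.label = i
        return None

    # string labels: map distinct values by sorted order
    distinct_str = sorted({str(v) for _, v in present})
    if label_kind == "binary" and len(distinct_str) != 2:
        raise ValueError(
            f"binary labels need exactly two distinct values, got {distinct_str}"
        )
    mapping = {v: i for i, v in enumerate(distinct_str)}
    for r, v in present:
        r.label = mapping[str(v)]
    return mapping


# ---------------------------------------------------------------------------
# readers


def _split_sdf_blocks(text: str) -> list[str]:
    blocks = []
    for block in text.split("$$$$"):
        if block.strip():
            blocks.append(block.strip("\n") + "\n")
    return blocks


def _read_sdf(path: Path, label_column: str | None) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    blocks = _split_sdf_blocks(path.read_text())
    records: list[MoleculeRecord] = []
    for i, mol in enumerate(supplier):
        text = blocks[i] if i < len(blocks) else ""
        label = None
        if mol is not None and label_column and mol.HasProp(label_column):
            label = mol.GetProp(label_column)
        records.append(
            MoleculeRecord(
                record_id=f"rec{i}",
                source_index=i,
                structure_text=text,
                label=label,
                parse_ok=mol is not None,
            )
        )
    return records


def _read_smiles(path: Path) -> list[MoleculeRecord]:
    records = []
    i = 0
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smi = parts[0].strip()
        rid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"rec{i}"
        mol = Chem.MolFromSmiles(smi)
        records.append(
            MoleculeRecord(
                record_id=rid,
                source_index=i,
                structure_text=smi,
                parse_ok=mol is not None,
            )
        )
        i += 1
    return records


def _find_smiles_column(df: pd.DataFrame, explicit: str | None = None) -> str:
    if explicit is not None:
        if explicit not in df.columns:
            raise ValueError(f"no structure column: {explicit!r} not in file")
        return explicit
    for col in df.columns:
        if str(col).strip().lower() == "smiles":
            return col
    raise ValueError(
        "no structure column: expected a column named 'SMILES' "
        "(case-insensitive); pass smiles_column to override"
    )


def _read_table(
    df: pd.DataFrame, label_column: str | None, smiles_column: str | None
) -> list[MoleculeRecord]:
    smi_col = _find_smiles_column(df, smiles_column)
    if label_column is not None and label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not in file")
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        smi = row[smi_col]
        smi = "" if _is_missing(smi) else str(smi).strip()
        mol = Chem.MolFromSmiles(smi) if smi else None
        records.append(
            MoleculeRecord(
                record_id=f"rec{i}",
                source_index=i,
                structure_text=smi,
                label=row[label_column] if label_column else None,
                parse_ok=mol is not None,
            )
        )
    return records


def read_dataset(
    path: str | Path,
    format: str,
    label_column: str | None = None,
    label_kind: str = "none",
    smiles_column: str | None = None,
) -> Dataset:
    """Read a chemical dataset from SDF, SMILES, CSV, or XLSX.

    One :class:`MoleculeRecord` is produced per input record; parse status is
    assigned by attempting to parse each structure with RDKit. Labels are
    read from ``label_column`` (an SD property for SDF, a column otherwise)
    and coerced to the declared ``label_kind``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if label_kind not in LABEL_KINDS:
        raise ValueError(f"unknown label_kind {label_kind!r}")
    if label_kind != "none" and label_column is None:
        raise ValueError("label_column is required when label_kind != 'none'")

    if format == "sdf":
        records = _read_sdf(path, label_column)
    elif format == "smiles":
        records = _read_smiles(path)
        if label_column is not None:
            raise ValueError("SMILES files carry no label column; use csv/sdf")
    elif format == "csv":
        records = _read_table(pd.read_csv(path), label_column, smiles_column)
    elif format == "xlsx":
        records = _read_table(pd.read_excel(path), label_column, smiles_column)
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records:
        raise ValueError(f"empty file: {path}")

    label_map = _coerce_labels(records, label_kind)
    return Dataset(
        records=records,
        label_kind=label_kind,
        label_column=label_column,
        label_map=label_map,
    )


# ---------------------------------------------------------------------------
# integrity check and exploratory summary


def integrity_check(ds: Dataset) -> tuple[Dataset, RemovedRowsReport]:
    """Remove unreadable structures and (for labeled data) missing labels.

    Returns the cleaned dataset and a report enumerating every removal with
    its reason. Conservation holds: n_input = n_retained + n_removed.
    """
    report = RemovedRowsReport()
    kept: list[MoleculeRecord] = []
    for rec in ds.records:
        if not rec.parse_ok:
            report.add(rec.source_index, "unreadable_structure")
        elif ds.label_kind != "none" and rec.label is None:
            report.add(rec.source_index, "missing_value")
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("empty dataset after integrity check")
    clean = Dataset(
        records=kept,
        label_kind=ds.label_kind,
        label_column=ds.label_column,
        label_map=ds.label_map,
    )
    return clean, report


def summarize_dataset(ds: Dataset, report: RemovedRowsReport | None = None) -> ExploratorySummary:
    """Exploratory summary: retained/removed counts plus class balance or a histogram.

    Continuous labels are binned into 10 equal-width bins between the
    observed min and max (a single bin when min == max).
    """
    n_unreadable = n_missing = 0
    if report is not None:
        for _, reason in report.rows:
            if reason == "unreadable_structure":
                n_unreadable += 1
            elif reason == "missing_value":
                n_missing += 1
    summary = ExploratorySummary(
        n_retained=len(ds.retained()),
        n_unreadable=n_unreadable,
        n_missing=n_missing,
    )
    labels = ds.labels()
    if labels is None or len(labels) == 0:
        return summary
    if ds.label_kind in ("binary", "multiclass"):
        vals, counts = np.unique(labels.astype(int), return_counts=True)
        summary.class_counts = {int(v): int(c) for v, c in zip(vals, counts)}
    else:
        lo, hi = float(labels.min()), float(labels.max())
        if lo == hi:
            edges = np.array([lo, hi])
        else:
            edges = np.linspace(lo, hi, 11)
        counts, edges = np.histogram(labels, bins=edges)
        summary.histogram = ([float(e) for e in edges], [int(c) for c in counts])
    return summary


# ---------------------------------------------------------------------------
# run manifest


def _jsonable(obj: Any) -> Any:
    """Convert numpy/tuple containers to plain JSON-native structures."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class RunManifest:
    """Replayable record of a complete run: options, seeds, and stage results.

    Content is held as JSON-native structures so that save → load is an exact
    field-by-field round trip.
    """

    schema_version: int = MANIFEST_SCHEMA_VERSION
    input: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def set_input(self, **kwargs: Any) -> None:
        self.input.update(_jsonable(kwargs))

    def set_option(self, key: str, value: Any) -> None:
        self.options[key] = _jsonable(value)

    def set_seed(self, key: str, value: int) -> None:
        self.seeds[key] = int(value)

    def set_stage(self, name: str, **payload: Any) -> None:
        self.stages[name] = _jsonable(payload)

    def get_stage(self, name: str) -> dict:
        if name not in self.stages:
            raise KeyError(f"manifest has no stage {name!r}")
        return self.stages[name]

    def has_stage(self, name: str) -> bool:
        return name in self.stages

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "input": self.input,
            "options": self.options,
            "seeds": self.seeds,
            "stages": self.stages,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunManifest":
        if not isinstance(d, dict) or "schema_version" not in d:
            raise ValueError("malformed manifest: missing schema_version")
        if d["schema_version"] != MANIFEST_SCHEMA_VERSION:
            raise ValueError(
                f"incompatible manifest schema {d['schema_version']!r}; "
                f"this version reads schema {MANIFEST_SCHEMA_VERSION}"
            )
        return cls(
            schema_version=d["schema_version"],
            input=d.get("input", {}),
            options=d.get("options", {}),
            seeds=d.get("seeds", {}),
            stages=d.get("stages", {}),
        )


def save_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n"
    )


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest file {path}: {exc}") from exc
    return RunManifest.from_dict(data)
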