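"""Binary fingerprints, continuous 2-D descriptors, and feature scaling.

Fingerprints: Morgan (circular, atom-type invariants), FeatMorgan (circular
with pharmacophoric feature invariants), and MACCS (166 substructure keys;
the implementation's padding bit 0 is stripped).

Continuous descriptors come from the RDKit 2-D descriptor engine in two
tiers: ``compact`` (physico-chemical descriptors, fragment counts excluded)
and ``extended`` (the full RDKit 2-D list). Columns containing any non-finite
value across the dataset are dropped and recorded.

Scaling methods: min–max to [0, 1]; z-score to mean 0 / sd 1; decimal scaling
that divides each column by the smallest power of ten bringing its maximum
absolute value to at most 1. Scaling parameters are stored per column so the
identical transform can be replayed on new data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem import MACCSkeys

from chemgroup.dataio import Dataset

FINGERPRINT_FAMILIES = ("morgan", "feat_morgan", "maccs")
DESCRIPTOR_SETS = ("compact", "extended")
SCALING_METHODS = ("minmax", "zscore", "decimal")


@dataclass
class FingerprintSpec:
    family: str = "morgan"
    radius: int = 3
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.family not in FINGERPRINT_FAMILIES:
            raise ValueError(f"unknown fingerprint family {self.family!r}")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits < 1:
            raise ValueError("n_bits must be positive")


@dataclass
class FeatureMatrix:
    """n×p named feature table with scaling provenance."""

    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    column_kind: str = "continuous"  # binary | continuous
    scaling: dict = field(default_factory=lambda: {"method": "none"})
    #: columns dropped at construction because of non-finite values
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows / {len(self.column_names)} columns"
            )
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique")

    @property
    def n(self) -> int:
        return len(self.row_ids)

    @property
    def p(self) -> int:
        return len(self.column_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.column_names.index(c) for c in names]
        return FeatureMatrix(
            row_ids=list(self.row_ids),
            column_names=list(names),
            values=self.values[:, idx],
            column_kind=self.column_kind,
            scaling=dict(self.scaling),
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "row_id", df.index)
        df.to_csv(path, index=False)

    def apply_scaling(self, values: np.ndarray) -> np.ndarray:
        """Apply this matrix's stored scaling parameters to new raw data."""
        method = self.scaling.get("method", "none")
        values = np.asarray(values, dtype=float)
        if method == "none":
            return values
        params = self.scaling["params"]
        out = np.empty_like(values)
        for j in range(values.shape[1]):
            out[:, j] = _apply_column_scaling(values[:, j], method, params[j])
        return out


def _apply_column_scaling(col: np.ndarray, method: str, p: dict) -> np.ndarray:
    if method == "minmax":
        span = p["max"] - p["min"]
        return np.zeros_like(col) if span == 0 else (col - p["min"]) / span
    if method == "zscore":
        return np.zeros_like(col) if p["sd"] == 0 else (col - p["mean"]) / p["sd"]
    if method == "decimal":
        return col / (10.0 ** p["j"])
    raise ValueError(f"unknown scaling method {method!r}")


# ---------------------------------------------------------------------------
# fingerprints


def _mols_from_dataset(ds: Dataset) -> list[tuple[str, Chem.Mol]]:
    mols = []
    for rec in ds.retained():
        mol = Chem.MolFromSmiles(rec.structure_text)
        if mol is None and "M  END" in (rec.structure_text or ""):
            mol = Chem.MolFromMolBlock(rec.structure_text)
        if mol is None:
            continue  # reported upstream; dropped here
        mols.append((rec.record_id, mol))
    if not mols:
        raise ValueError("no parseable structures for descriptor calculation")
    return mols


def compute_fingerprints(ds: Dataset, spec: FingerprintSpec) -> FeatureMatrix:
    """Binary fingerprint matrix, one row per (parseable) retained record."""
    mols = _mols_from_dataset(ds)
    if spec.family == "maccs":
        # RDKit emits 167 bits with bit 0 as padding; strip it → 166 keys
        rows = []
        for _, mol in mols:
            bv = MACCSkeys.GenMACCSKeys(mol)
            rows.append(np.array(bv.ToList()[1:], dtype=float))
        names = [f"maccs_{i}" for i in range(1, 167)]
    else:
        if spec.family == "feat_morgan":
            inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=spec.radius, fpSize=spec.n_bits, atomInvariantsGenerator=inv
            )
        else:
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=spec.radius, fpSize=spec.n_bits
            )
        rows = [np.array(gen.GetFingerprint(m).ToList(), dtype=float) for _, m in mols]
        names = [f"{spec.family}_{i}" for i in range(spec.n_bits)]
    return FeatureMatrix(
        row_ids=[rid for rid, _ in mols],
        column_names=names,
        values=np.vstack(rows),
        column_kind="binary",
    )


# ---------------------------------------------------------------------------
# continuous descriptors


def _descriptor_functions(set_name: str) -> list[tuple[str, callable]]:
    if set_name not in DESCRIPTOR_SETS:
        raise ValueError(f"unknown descriptor set {set_name!r}")
    funcs = list(Descriptors.descList)
    if set_name == "compact":
        funcs = [(n, f) for n, f in funcs if not n.startswith("fr_")]
    return funcs


def descriptor_set_version(set_name: str) -> dict:
    """Backend + version string recorded in the manifest (counts are version-sensitive)."""
    import rdkit

    return {
        "backend": "rdkit-2d",
        "set": set_name,
        "rdkit_version": rdkit.__version__,
        "n_descriptors": len(_descriptor_functions(set_name)),
    }


def compute_descriptors(ds: Dataset, set_name: str = "compact") -> FeatureMatrix:
    """Continuous 2-D descriptor matrix.

    Columns with any non-finite or missing value across the dataset are
    dropped; the drop list is kept on the returned matrix (and recorded in
    the manifest by the pipeline).
    """
    funcs = _descriptor_functions(set_name)
    mols = _mols_from_dataset(ds)
    rows = []
    for _, mol in mols:
        vals = []
        for _, fn in funcs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    v = float(fn(mol))
                except Exception:
                    v = np.nan
            vals.append(v)
        rows.append(vals)
    values = np.asarray(rows, dtype=float)
    names = [n for n, _ in funcs]

    finite = np.isfinite(values).all(axis=0)
    dropped = [n for n, ok in zip(names, finite) if not ok]
    return FeatureMatrix(
        row_ids=[rid for rid, _ in mols],
        column_names=[n for n, ok in zip(names, finite) if ok],
        values=values[:, finite],
        column_kind="continuous",
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# scaling


def scale_features(fm: FeatureMatrix, method: str) -> FeatureMatrix:
    """Scale a continuous feature matrix column-wise.

    minmax → [0, 1]; zscore → mean 0, sd 1 (population sd); decimal → divide
    by 10^j with j the smallest non-negative integer making max|x| ≤ 1.
    Constant columns map to all zeros under minmax/zscore. Binary matrices
    pass through unchanged with a warning.
    """
    if method not in SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}")
    if fm.column_kind == "binary":
        warnings.warn("binary matrix passed to scale_features; returned unchanged")
        return fm

    values = fm.values
    out = np.empty_like(values)
    params: list[dict] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        if method == "minmax":
            p = {"min": float(col.min()), "max": float(col.max())}
        elif method == "zscore":
            p = {"mean": float(col.mean()), "sd": float(col.std(ddof=0))}
        else:  # decimal
            m = float(np.abs(col).max())
            jexp = 0
            while m / (10.0**jexp) > 1.0:
                jexp += 1
            p = {"j": jexp}
        out[:, j] = _apply_column_scaling(col, method, p)
        params.append(p)

    return FeatureMatrix(
        row_ids=list(fm.row_ids),
        column_names=list(fm.column_names),
        values=out,
        column_kind="continuous",
        scaling={"method": method, "params": params},
        dropped_columns=list(fm.dropped_columns),
    )
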