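"""Synthetic data generators for exercising every pipeline stage.

Three generators, all pure functions of their parameters and seed:

- :func:`make_feature_blobs` — separable Gaussian blobs for clustering and
  tuning checks, with ground-truth labels for recovery scoring;
- :func:`make_labeled_features` — labeled feature tables with a small
  planted informative subset among independent noise columns, for the
  filter-search and selector-recovery checks;
- :func:`make_smiles_families` — valid SMILES built by decorating scaffold
  cores (benzene, cyclohexane, pyridine, ...) with substituents, optionally
  injecting counterion-bearing salts and duplicated entries, for
  standardization and end-to-end tests.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from chemgroup.dataio import Dataset, MoleculeRecord

SCAFFOLDS = [
    "c1ccccc1",        # benzene
    "C1CCCCC1",        # cyclohexane
    "c1ccncc1",        # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCOC1",         # tetrahydrofuran
    "c1ccsc1",         # thiophene
]

SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C(=O)O", "C(=O)N", "C#N", "S", "OCC", "C(C)C", "CO", "CN",
]

COUNTERIONS = ["Cl", "Br", "[Na+].[Cl-]", "OS(=O)(=O)O"]


def make_feature_blobs(
    n: int, k: int, p: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k isotropic Gaussian blobs (unit sd) with centers ``separation``
    standard deviations apart along random orthogonal directions."""
    if not n >= k >= 2:
        raise ValueError("need n >= k >= 2")
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    # random orthonormal center directions so centers are `separation` apart
    raw = rng.normal(size=(p, k))
    q, _ = np.linalg.qr(raw)
    centers = q[:, :k].T * separation / math.sqrt(2)
    labels = np.repeat(np.arange(k), math.ceil(n / k))[:n]
    X = centers[labels] + rng.normal(size=(n, p))
    return X, labels


def make_labeled_features(
    n: int,
    p_informative: int,
    p_noise: int,
    effect: float,
    label_kind: str = "binary",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature table with a planted informative subset.

    The first ``p_informative`` columns carry the signal with coefficient
    magnitude ``effect`` (alternating sign); labels come from a logistic
    model (binary), a softmax over 3 classes (multiclass), or a linear
    model with unit noise (continuous). Noise columns are independent
    standard normals.
    """
    if min(n, p_informative, p_noise) < 1:
        raise ValueError("counts must be positive")
    if label_kind not in ("binary", "multiclass", "continuous"):
        raise ValueError(f"invalid label_kind {label_kind!r}")
    rng = np.random.default_rng(seed)
    p = p_informative + p_noise
    X = rng.normal(size=(n, p))
    coefs = effect * np.array([(-1) ** i for i in range(p_informative)], dtype=float)
    signal = X[:, :p_informative] @ coefs
    if label_kind == "binary":
        prob = 1.0 / (1.0 + np.exp(-signal))
        y = (rng.random(n) < prob).astype(int)
    elif label_kind == "multiclass":
        shift = np.array([-1.0, 0.0, 1.0])
        logits = signal[:, None] * shift[None, :]
        prob = np.exp(logits - logits.max(axis=1, keepdims=True))
        prob /= prob.sum(axis=1, keepdims=True)
        y = np.array([rng.choice(3, p=pi) for pi in prob])
    else:
        y = signal + rng.normal(size=n)
    return X, y


def _decorations() -> list[tuple[str, str]]:
    """(scaffold, decorated SMILES) pairs in a deterministic enumeration order."""
    out = []
    for core in SCAFFOLDS:
        out.append((core, core))
        # substituents attach through their first atom, written after the
        # ring closure so the SMILES stays valence-correct
        for sub in SUBSTITUENTS:
            out.append((core, f"{core}{sub}"))
        for s1 in SUBSTITUENTS[:6]:
            for s2 in SUBSTITUENTS[:6]:
                out.append((core, f"{core}C({s1}){s2}"))
    return out


def make_smiles_families(
    n_families: int,
    n_per_family: int,
    salt_fraction: float = 0.0,
    duplicate_fraction: float = 0.0,
    seed: int = 0,
) -> Dataset:
    """Dataset of valid SMILES from decorated scaffold families.

    The family index is attached as a multiclass label. ``salt_fraction``
    of the records get a counterion fragment appended;
    ``duplicate_fraction`` additional records duplicate earlier entries.
    """
    if not 0 <= salt_fraction <= 1 or not 0 <= duplicate_fraction <= 1:
        raise ValueError("fractions must be in [0, 1]")
    if n_families > len(SCAFFOLDS):
        raise ValueError(f"at most {len(SCAFFOLDS)} families available")
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    for core, smi in _decorations():
        by_family.setdefault(core, []).append(smi)

    records: list[MoleculeRecord] = []
    idx = 0
    base: list[tuple[str, int]] = []
    for fam, core in enumerate(SCAFFOLDS[:n_families]):
        pool = by_family[core]
        if n_per_family > len(pool):
            raise ValueError(
                f"requested {n_per_family} > {len(pool)} enumerable decorations"
            )
        chosen = rng.choice(len(pool), size=n_per_family, replace=False)
        for c in chosen:
            base.append((pool[c], fam))

    n_base = len(base)
    n_salts = round(salt_fraction * n_base)
    salt_rows = set(rng.choice(n_base, size=n_salts, replace=False)) if n_salts else set()
    for i, (smi, fam) in enumerate(base):
        text = smi
        if i in salt_rows:
            text = f"{smi}.{COUNTERIONS[int(rng.integers(len(COUNTERIONS)))]}"
        records.append(
            MoleculeRecord(
                record_id=f"rec{idx}", source_index=idx, structure_text=text,
                label=fam, parse_ok=True,
            )
        )
        idx += 1

    n_dups = round(duplicate_fraction * n_base)
    if n_dups:
        dup_sources = rng.integers(n_base, size=n_dups)
        for s in dup_sources:
            smi, fam = base[int(s)]
            records.append(
                MoleculeRecord(
                    record_id=f"rec{idx}", source_index=idx, structure_text=smi,
                    label=fam, parse_ok=True,
                )
            )
            idx += 1

    return Dataset(records=records, label_kind="multiclass", label_column="family")


def write_smiles_file(ds: Dataset, path) -> None:
    """Write a dataset as a SMILES file (structure<TAB>id per line)."""
    lines = [f"{r.structure_text}\t{r.record_id}" for r in ds.records]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_csv_file(ds: Dataset, path) -> None:
    """Write a dataset as a CSV with SMILES and label columns."""
    pd.DataFrame(
        {
            "SMILES": [r.structure_text for r in ds.records],
            "label": [r.label for r in ds.records],
        }
    ).to_csv(path, index=False)
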