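"""QSAR-ready-style structure standardization.

Applied before descriptor calculation so that salts, charge states, nitro
drawing conventions, tautomers, and stereochemistry do not split identical
parent structures into distinct feature rows. The rule order is fixed:

1. normalize     — functional-group normalization (nitro groups rewritten to
                   the charge-separated canonical form, valence corrections)
2. salt_removal  — keep the largest organic fragment, dropping counterions
3. neutralization — remove charges where chemically valid (zwitterions whose
                   charges cancel, e.g. nitro, are left alone)
4. tautomer_canonicalization — RDKit canonical-tautomer scheme
5. stereo_removal — wipe tetrahedral and double-bond stereo marks
6. valence_check + canonicalization — final sanitization and canonical SMILES

Exact duplicates after standardization are collapsed; labeled duplicates with
conflicting labels are removed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from chemgroup.dataio import Dataset, MoleculeRecord, RemovedRowsReport

RULE_NAMES = (
    "normalize",
    "salt_removal",
    "neutralization",
    "tautomer_canonicalization",
    "stereo_removal",
    "canonicalization",
)


@dataclass
class StandardizationOutcome:
    input_id: str
    canonical_smiles: str | None = None
    applied_rules: list[str] = field(default_factory=list)
    failed: bool = False
    reason: str | None = None


def _parse(structure_text: str) -> Chem.Mol | None:
    text = structure_text or ""
    if "M  END" in text or "\n" in text.strip():
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=False)
    return mol


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize_structure(structure_text: str, input_id: str = "") -> StandardizationOutcome:
    """Standardize one structure (SMILES or mol-block) to a canonical SMILES.

    Returns a :class:`StandardizationOutcome` whose ``applied_rules`` lists,
    in order, the rules that actually changed the structure;
    ``canonicalization`` is always recorded on success.
    """
    out = StandardizationOutcome(input_id=input_id)

    mol = _parse(structure_text)
    if mol is None:
        out.failed, out.reason = True, "unparseable structure"
        return out

    def smi(m: Chem.Mol) -> str:
        return Chem.MolToSmiles(m)

    try:
        mol.UpdatePropertyCache(strict=False)
        before = Chem.MolToSmiles(mol, canonical=True)

        # functional-group normalization (incl. nitro) + initial sanitization
        mol = rdMolStandardize.Cleanup(mol)
        if smi(mol) != before:
            out.applied_rules.append("normalize")

        # largest organic fragment
        before = smi(mol)
        chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
        mol = chooser.choose(mol)
        if smi(mol) != before:
            out.applied_rules.append("salt_removal")
        if not _has_carbon(mol):
            out.failed, out.reason = True, "no organic fragment"
            return out

        # neutralization where chemically valid
        before = smi(mol)
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        Chem.SanitizeMol(mol)
        if smi(mol) != before:
            out.applied_rules.append("neutralization")

        # canonical tautomer
        before = smi(mol)
        enumerator = rdMolStandardize.TautomerEnumerator()
        mol = enumerator.Canonicalize(mol)
        if smi(mol) != before:
            out.applied_rules.append("tautomer_canonicalization")

        # stereochemistry removal
        before = smi(mol)
        Chem.RemoveStereochemistry(mol)
        if smi(mol) != before:
            out.applied_rules.append("stereo_removal")

        # final valence check + canonical SMILES
        Chem.SanitizeMol(mol)
        out.canonical_smiles = Chem.MolToSmiles(mol)
        out.applied_rules.append("canonicalization")
    except Exception as exc:  # rdkit raises bare Exceptions for valence errors
        out.failed, out.reason = True, f"standardization error: {exc}"
        out.applied_rules = []
        out.canonical_smiles = None
    return out


def standardize_dataset(
    ds: Dataset, verbose_log: list | None = None
) -> tuple[Dataset, RemovedRowsReport]:
    """Standardize every record and collapse duplicates.

    Exact duplicates (identical canonical SMILES) with consistent labels are
    collapsed to the first occurrence; duplicates with conflicting labels are
    all removed and reported as ``conflicting_duplicate``. Records that fail
    standardization are reported as ``unreadable_structure``.
    """
    report = RemovedRowsReport()
    outcomes: list[tuple[MoleculeRecord, StandardizationOutcome]] = []
    for rec in ds.retained():
        out = standardize_structure(rec.structure_text, input_id=rec.record_id)
        if verbose_log is not None:
            verbose_log.append(out)
        if out.failed:
            report.add(rec.source_index, "unreadable_structure")
        else:
            outcomes.append((rec, out))

    # group by canonical SMILES
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec, out in outcomes:
        rec = MoleculeRecord(
            record_id=rec.record_id,
            source_index=rec.source_index,
            structure_text=out.canonical_smiles,
            label=rec.label,
            parse_ok=True,
        )
        groups.setdefault(out.canonical_smiles, []).append(rec)

    kept: list[MoleculeRecord] = []
    labeled = ds.label_kind != "none"
    for _, members in groups.items():
        if len(members) == 1:
            kept.append(members[0])
            continue
        label_values = {m.label for m in members}
        if labeled and len(label_values) > 1:
            for m in members:
                report.add(m.source_index, "conflicting_duplicate")
        else:
            kept.append(members[0])
            for m in members[1:]:
                report.add(m.source_index, "duplicate")

    if not kept:
        raise ValueError("empty dataset after standardization")

    kept.sort(key=lambda r: r.source_index)
    clean = Dataset(
        records=kept,
        label_kind=ds.label_kind,
        label_column=ds.label_column,
        label_map=ds.label_map,
    )
    return clean, report
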