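import json

import numpy as np
import pytest
from rdkit import Chem

from chemgroup.dataio import (
    Dataset,
    MoleculeRecord,
    RunManifest,
    integrity_check,
    load_manifest,
    read_dataset,
    save_manifest,
    summarize_dataset,
)


def _molblock(smiles: str) -> str:
    return Chem.MolToMolBlock(Chem.MolFromSmiles(smiles))


def _sdf_text(entries) -> str:
    """entries: list of (smiles or raw block, {prop: value})."""
    chunks = []
    for smi, props in entries:
        block = _molblock(smi) if "M  END" not in smi else smi
        for k, v in props.items():
            block += f"\n>  <{k}>\n{v}\n"
        chunks.append(block + "\n$$$$\n")
    return "".join(chunks)


CORRUPT_BLOCK = "garbage\n\n\n  3  2  0\nnot atoms\nM  END"


class TestReadDataset:
    def test_sdf_with_corrupt_block_flags_record(self, tmp_path):
        text = _sdf_text(
            [("CCO", {"Outcome": "1"}), (CORRUPT_BLOCK, {}), ("c1ccccc1", {"Outcome": "0"})]
        )
        path = tmp_path / "in.sdf"
        path.write_text(text)
        ds = read_dataset(path, "sdf", label_column="Outcome", label_kind="binary")
        assert ds.n == 3
        assert [r.parse_ok for r in ds.records] == [True, False, True]
        assert [r.label for r in ds.records if r.parse_ok] == [1, 0]

    def test_csv_without_smiles_column_errors(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("structure,activity\nCCO,1\n")
        with pytest.raises(ValueError, match="no structure column"):
            read_dataset(path, "csv")

    def test_csv_smiles_detection_case_insensitive(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("Smiles,act\nCCO,1\nbadsmiles(((,0\n")
        ds = read_dataset(path, "csv", label_column="act", label_kind="binary")
        assert [r.parse_ok for r in ds.records] == [True, False]

    def test_string_binary_labels_mapped_by_sorted_order(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("SMILES,act\nCCO,irritant\nCC,nonirritant\nCCC,irritant\n")
        ds = read_dataset(path, "csv", label_column="act", label_kind="binary")
        assert ds.label_map == {"irritant": 0, "nonirritant": 1}
        assert [r.label for r in ds.records] == [0, 1, 0]

    def test_three_string_values_rejected_for_binary(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("SMILES,act\nCCO,a\nCC,b\nCCC,c\n")
        with pytest.raises(ValueError, match="two distinct"):
            read_dataset(path, "csv", label_column="act", label_kind="binary")

    def test_missing_file_and_empty_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_dataset(tmp_path / "nope.csv", "csv")
        empty = tmp_path / "empty.smi"
        empty.write_text("")
        with pytest.raises(ValueError, match="empty file"):
            read_dataset(empty, "smiles")

    def test_reading_is_deterministic(self, tmp_path):
        path = tmp_path / "in.smi"
        path.write_text("CCO\tmol1\nc1ccccc1\tmol2\n")
        a = read_dataset(path, "smiles")
        b = read_dataset(path, "smiles")
        assert [(r.record_id, r.structure_text, r.parse_ok) for r in a.records] == [
            (r.record_id, r.structure_text, r.parse_ok) for r in b.records
        ]


class TestIntegrityCheck:
    def test_clean_dataset_is_identity(self):
        ds = Dataset(records=[MoleculeRecord("a", 0, "CCO")])
        clean, report = integrity_check(ds)
        assert clean.n == 1 and len(report) == 0

    def test_missing_label_removed_with_reason(self):
        ds = Dataset(
            records=[
                MoleculeRecord("a", 0, "CCO", label=1),
                MoleculeRecord("b", 1, "CC", label=None),
            ],
            label_kind="binary",
            label_column="y",
        )
        clean, report = integrity_check(ds)
        assert clean.n == 1
        assert report.rows == [(1, "missing_value")]

    def test_conservation_and_empty_error(self):
        records = [
            MoleculeRecord("a", 0, "CCO", parse_ok=True),
            MoleculeRecord("b", 1, "xxx", parse_ok=False),
            MoleculeRecord("c", 2, "CC", parse_ok=True),
        ]
        ds = Dataset(records=records)
        clean, report = integrity_check(ds)
        assert clean.n + len(report) == ds.n
        all_bad = Dataset(records=[MoleculeRecord("a", 0, "x", parse_ok=False)])
        with pytest.raises(ValueError, match="empty dataset"):
            integrity_check(all_bad)


class TestSummarize:
    def test_class_counts(self):
        recs = [MoleculeRecord(f"r{i}", i, "CCO", label=(0 if i < 6 else 1)) for i in range(10)]
        ds = Dataset(records=recs, label_kind="binary", label_column="y")
        s = summarize_dataset(ds)
        assert s.class_counts == {0: 6, 1: 4}
        assert sum(s.class_counts.values()) == s.n_retained

    def test_unlabeled_has_no_class_counts(self):
        ds = Dataset(records=[MoleculeRecord("a", 0, "CCO")])
        s = summarize_dataset(ds)
        assert s.class_counts is None and s.histogram is None
        assert s.n_retained == 1

    def test_continuous_histogram_deterministic(self):
        recs = [MoleculeRecord(f"r{i}", i, "CCO", label=float(i)) for i in range(20)]
        ds = Dataset(records=recs, label_kind="continuous", label_column="y")
        s1, s2 = summarize_dataset(ds), summarize_dataset(ds)
        assert s1.histogram == s2.histogram
        edges, counts = s1.histogram
        assert len(edges) == 11 and sum(counts) == 20


class TestManifest:
    def _populated(self):
        m = RunManifest()
        m.set_input(name="x.sdf", format="sdf")
        m.set_option("config", {"a": 1, "b": [1, 2]})
        m.set_seed("master", 42)
        m.set_stage("grouping", labels=np.array([0, 1, 1]), silhouette=np.float64(0.5))
        return m

    def test_round_trip_is_lossless(self, tmp_path):
        m = self._populated()
        save_manifest(m, tmp_path / "m.json")
        m2 = load_manifest(tmp_path / "m.json")
        assert m.to_dict() == m2.to_dict()

    def test_truncated_file_is_structured_error(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"schema_version": 1, "input"')
        with pytest.raises(ValueError, match="malformed manifest"):
            load_manifest(path)

    def test_incompatible_schema_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({"schema_version": 999}))
        with pytest.raises(ValueError, match="incompatible"):
            load_manifest(path)
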