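import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemgroup.dataio import Dataset, MoleculeRecord
from chemgroup.descriptors import (
    FeatureMatrix,
    FingerprintSpec,
    compute_descriptors,
    compute_fingerprints,
    scale_features,
)


def _ds(smiles):
    return Dataset(records=[MoleculeRecord(f"r{i}", i, s) for i, s in enumerate(smiles)])


class TestFingerprints:
    def test_morgan_shape_and_binary_values(self):
        fm = compute_fingerprints(_ds(["CCO", "c1ccccc1", "CC(=O)O"]),
                                  FingerprintSpec("morgan", 3, 2048))
        assert fm.values.shape == (3, 2048)
        assert set(np.unique(fm.values)) <= {0.0, 1.0}
        assert fm.column_kind == "binary"

    def test_identical_structures_identical_rows(self):
        fm = compute_fingerprints(_ds(["CCO", "CCO"]), FingerprintSpec("morgan", 2, 512))
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_methane_vs_ethanol_tanimoto_below_one(self):
        fm = compute_fingerprints(_ds(["C", "CCO"]), FingerprintSpec("morgan", 2, 512))
        a, b = fm.values[0].astype(bool), fm.values[1].astype(bool)
        tanimoto = (a & b).sum() / (a | b).sum()
        assert tanimoto < 1.0
        assert not np.array_equal(a, b)

    def test_maccs_has_166_keys(self):
        fm = compute_fingerprints(_ds(["CCO"]), FingerprintSpec("maccs"))
        assert fm.p == 166

    def test_feat_morgan_differs_from_morgan(self):
        ds = _ds(["CCOc1ccccc1N", "CC(N)c1ccncc1O"])
        m = compute_fingerprints(ds, FingerprintSpec("morgan", 2, 1024))
        f = compute_fingerprints(ds, FingerprintSpec("feat_morgan", 2, 1024))
        assert not np.array_equal(m.values, f.values)

    def test_row_order_invariance(self):
        smis = ["CCO", "c1ccccc1", "CC(=O)O", "CCN"]
        fm1 = compute_fingerprints(_ds(smis), FingerprintSpec("morgan", 2, 256))
        fm2 = compute_fingerprints(_ds(smis[::-1]), FingerprintSpec("morgan", 2, 256))
        by_id1 = dict(zip([s for s in smis], fm1.values))
        by_id2 = dict(zip([s for s in smis[::-1]], fm2.values))
        for s in smis:
            assert np.array_equal(by_id1[s], by_id2[s])


class TestDescriptors:
    def test_duplicate_structures_identical_rows(self):
        fm = compute_descriptors(_ds(["c1ccccc1O", "c1ccccc1O"]), "compact")
        assert np.allclose(fm.values[0], fm.values[1])
        assert fm.column_kind == "continuous"

    def test_extended_superset_of_compact(self):
        ds = _ds(["CCO"])
        compact = compute_descriptors(ds, "compact")
        extended = compute_descriptors(ds, "extended")
        assert set(compact.column_names) <= set(extended.column_names)
        assert extended.p > compact.p

    def test_nonfinite_column_dropped_entirely(self, monkeypatch):
        import chemgroup.descriptors as D

        real = D._descriptor_functions

        def patched(set_name):
            funcs = real(set_name)[:5]
            # descriptor that fails for benzene only → column must drop for all
            funcs.append(("always_nan_for_benzene",
                          lambda m: float("nan") if m.GetNumAtoms() == 6 else 1.0))
            return funcs

        monkeypatch.setattr(D, "_descriptor_functions", patched)
        fm = compute_descriptors(_ds(["CCO", "c1ccccc1"]), "compact")
        assert "always_nan_for_benzene" in fm.dropped_columns
        assert "always_nan_for_benzene" not in fm.column_names
        assert np.isfinite(fm.values).all()


class TestScaling:
    def test_minmax_example(self):
        fm = FeatureMatrix(["a", "b", "c"], ["x"], np.array([[0.0], [5.0], [10.0]]))
        out = scale_features(fm, "minmax")
        assert np.allclose(out.values[:, 0], [0.0, 0.5, 1.0])

    def test_decimal_examples(self):
        fm = FeatureMatrix(["a", "b"], ["x", "y"],
                           np.array([[345.0, 0.5], [-12.0, -0.25]]))
        out = scale_features(fm, "decimal")
        assert np.allclose(out.values[:, 0], [0.345, -0.012])
        assert out.scaling["params"][0]["j"] == 3
        # |max| already <= 1: j = 0, unchanged
        assert np.allclose(out.values[:, 1], [0.5, -0.25])
        assert out.scaling["params"][1]["j"] == 0

    def test_binary_passes_through_with_warning(self):
        fm = FeatureMatrix(["a", "b"], ["x"], np.array([[0.0], [1.0]]), column_kind="binary")
        with pytest.warns(UserWarning):
            out = scale_features(fm, "minmax")
        assert out is fm

    def test_constant_column_maps_to_zeros(self):
        fm = FeatureMatrix(["a", "b"], ["x"], np.array([[3.0], [3.0]]))
        for method in ("minmax", "zscore"):
            assert np.allclose(scale_features(fm, method).values, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=30,
        )
    )
    def test_scaling_contracts_hold_on_random_columns(self, col):
        values = np.array(col, dtype=float)[:, None]
        fm = FeatureMatrix([f"r{i}" for i in range(len(col))], ["x"], values)
        mm = scale_features(fm, "minmax").values
        assert mm.min() >= 0.0 and mm.max() <= 1.0
        zs = scale_features(fm, "zscore").values[:, 0]
        if values.std(ddof=0) > 0:
            assert abs(zs.mean()) < 1e-9
            assert abs(zs.std(ddof=0) - 1) < 1e-9
        dec = scale_features(fm, "decimal")
        assert np.abs(dec.values).max() <= 1.0
        j = dec.scaling["params"][0]["j"]
        if j > 0:  # smallest such j: one power of ten less must not suffice
            assert np.abs(values).max() / (10.0 ** (j - 1)) > 1.0

    def test_stored_parameters_replay_exactly(self):
        rng = np.random.default_rng(1)
        values = rng.normal(scale=30, size=(20, 4))
        fm = FeatureMatrix([f"r{i}" for i in range(20)],
                           [f"c{i}" for i in range(4)], values)
        for method in ("minmax", "zscore", "decimal"):
            scaled = scale_features(fm, method)
            assert np.array_equal(scaled.apply_scaling(values), scaled.values)
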