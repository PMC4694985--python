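"""Expression reading, probe collapsing and quantile normalization."""

import numpy as np
import pandas as pd
import pytest

from paslink.expression import (
    ControlSet,
    ExpressionMatrix,
    join_case_control,
    quantile_normalize,
    quantile_normalize_frame,
    read_expression,
)


def _write_tsv(path, df, index_label="id"):
    df.to_csv(path, sep="\t", index_label=index_label)


def _write_probe_map(path, mapping):
    path.write_text("".join(f"{p}\t{g}\n" for p, g in mapping.items()))


class TestReadExpression:
    def test_probe_collapse_by_mean(self, tmp_path):
        df = pd.DataFrame({"s1": [4.0, 6.0, 2.0]}, index=["p1", "p2", "p3"])
        _write_tsv(tmp_path / "m.tsv", df)
        _write_probe_map(tmp_path / "map.tsv", {"p1": "GENE_A", "p2": "GENE_A", "p3": "GENE_B"})
        m = read_expression(tmp_path / "m.tsv", probe_map=tmp_path / "map.tsv")
        assert m.data.loc["GENE_A", "s1"] == 5.0
        assert m.data.loc["GENE_B", "s1"] == 2.0

    def test_zero_intensity_clamped_to_floor(self, tmp_path):
        df = pd.DataFrame({"s1": [0.0, 3.0]}, index=["G1", "G2"])
        _write_tsv(tmp_path / "m.tsv", df)
        m = read_expression(tmp_path / "m.tsv", floor=1e-6)
        assert m.data.loc["G1", "s1"] == 1e-6

    def test_random_collapse_matches_groupby_oracle(self, tmp_path, rng):
        probes = [f"p{i}" for i in range(100)]
        genes = [f"G{i % 17}" for i in range(100)]
        values = rng.uniform(1, 100, size=(100, 4))
        df = pd.DataFrame(values, index=probes, columns=list("abcd"))
        _write_tsv(tmp_path / "m.tsv", df)
        _write_probe_map(tmp_path / "map.tsv", dict(zip(probes, genes)))
        m = read_expression(tmp_path / "m.tsv", probe_map=tmp_path / "map.tsv")
        # independent oracle: explicit loop over gene groups
        for gene in set(genes):
            rows = [i for i, g in enumerate(genes) if g == gene]
            expected = values[rows].mean(axis=0)
            np.testing.assert_allclose(m.data.loc[gene].to_numpy(), expected)

    def test_collapse_invariant_to_probe_order(self, tmp_path, rng):
        probes = [f"p{i}" for i in range(30)]
        genes = [f"G{i % 5}" for i in range(30)]
        values = rng.uniform(1, 10, size=(30, 3))
        df = pd.DataFrame(values, index=probes, columns=list("xyz"))
        perm = rng.permutation(30)
        _write_tsv(tmp_path / "a.tsv", df)
        _write_tsv(tmp_path / "b.tsv", df.iloc[perm])
        _write_probe_map(tmp_path / "map.tsv", dict(zip(probes, genes)))
        ma = read_expression(tmp_path / "a.tsv", probe_map=tmp_path / "map.tsv")
        mb = read_expression(tmp_path / "b.tsv", probe_map=tmp_path / "map.tsv")
        pd.testing.assert_frame_equal(ma.data, mb.data)

    def test_all_probes_unmapped_is_error(self, tmp_path):
        df = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        _write_tsv(tmp_path / "m.tsv", df)
        _write_probe_map(tmp_path / "map.tsv", {"other": "G1"})
        with pytest.raises(ValueError, match="no probe mapped"):
            read_expression(tmp_path / "m.tsv", probe_map=tmp_path / "map.tsv")

    def test_ragged_rows_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("id\ts1\ts2\nG1\t1.0\t2.0\nG2\t3.0\n")
        with pytest.raises(ValueError, match="ragged|missing"):
            read_expression(tmp_path / "m.tsv")


class TestQuantileNormalize:
    def test_two_columns_forced_values(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize_frame(df)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_multisets_are_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = quantile_normalize_frame(df)
        pd.testing.assert_frame_equal(out, df)

    def test_matches_sort_average_unsort_oracle(self, rng):
        X = rng.uniform(0, 100, size=(20, 5))
        df = pd.DataFrame(X)
        out = quantile_normalize_frame(df).to_numpy()
        # independent oracle: sort each column, average rows, place back
        ref = np.sort(X, axis=0).mean(axis=1)
        expected = np.empty_like(X)
        for j in range(X.shape[1]):
            expected[np.argsort(X[:, j]), j] = ref
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_sorted_columns_identical(self, rng):
        df = pd.DataFrame(rng.lognormal(3, 1, size=(200, 8)))
        out = quantile_normalize_frame(df).to_numpy()
        s = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(s[:, j], s[:, 0], rtol=1e-12)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.lognormal(2, 0.5, size=(100, 6)))
        once = quantile_normalize_frame(df)
        twice = quantile_normalize_frame(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_ties_get_mean_of_candidate_values(self):
        # column a has a three-way tie occupying ranks 1-3
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0, 9.0], "b": [1.0, 2.0, 3.0, 4.0]})
        out = quantile_normalize_frame(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert np.allclose(out["a"][:3], ref[:3].mean())
        assert np.isclose(out["a"][3], ref[3])

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            quantile_normalize_frame(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_matrix_wrapper_preserves_labels(self, rng):
        df = pd.DataFrame(rng.uniform(1, 9, (10, 3)), columns=list("abc"),
                          index=[f"G{i}" for i in range(10)])
        m = ExpressionMatrix(df, {"a": "case", "b": "control", "c": "control"})
        out = quantile_normalize(m)
        assert out.sample_labels == m.sample_labels


class TestJoin:
    def _control(self, genes, rng, n=3):
        df = pd.DataFrame(
            rng.uniform(1, 9, (len(genes), n)), index=genes,
            columns=[f"c{i}" for i in range(n)],
        )
        return ControlSet("ctrl", ExpressionMatrix(df))

    def test_inner_join_on_gene_symbol(self, rng):
        cases = ExpressionMatrix(
            pd.DataFrame(rng.uniform(1, 9, (3, 2)), index=["G1", "G2", "G3"],
                         columns=["s1", "s2"])
        )
        joint = join_case_control(cases, self._control(["G2", "G3", "G4"], rng))
        assert set(joint.data.index) == {"G2", "G3"}
        assert joint.sample_labels["s1"] == "case"
        assert joint.sample_labels["c0"] == "control"

    def test_empty_intersection_rejected(self, rng):
        cases = ExpressionMatrix(
            pd.DataFrame(rng.uniform(1, 9, (2, 2)), index=["G1", "G2"],
                         columns=["s1", "s2"])
        )
        with pytest.raises(ValueError, match="no shared genes"):
            join_case_control(cases, self._control(["X1", "X2"], rng))

    def test_control_set_needs_two_samples(self, rng):
        df = pd.DataFrame({"c0": [1.0, 2.0]}, index=["G1", "G2"])
        with pytest.raises(ValueError, match=">=2 samples"):
            ControlSet("ctrl", ExpressionMatrix(df))
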