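import numpy as np
import pandas as pd
import pytest

from reposcreen.errors import InvalidParameterError, ValidationError
from reposcreen.diffexp import (
    GroupDifferentialExpression,
    cluster_genes,
    differential_expression,
    group_expression_summary,
    intersect_deg_targets,
    preprocess,
    read_expression,
    read_labels,
)
from reposcreen.proximity import DrugTargetMap
from reposcreen.simulate import generate_expression, write_expression

from oracles import welch_t


def _labels(n_case, n_control):
    idx = [f"CASE{i}" for i in range(n_case)] + [
        f"CTRL{i}" for i in range(n_control)
    ]
    return pd.Series(["case"] * n_case + ["control"] * n_control, index=idx)


def _matrix(values, samples):
    return pd.DataFrame(
        values, index=[f"g{i}" for i in range(len(values))], columns=samples
    )


class TestPreprocess:
    def test_row_standardization_contract(self):
        m = _matrix([[2.0, 8.0]], ["s1", "s2"])
        out, flagged = preprocess(m)
        assert flagged == []
        # log2 -> (1, 3); centered/scaled with ddof=1 -> (-1/sqrt2, 1/sqrt2)
        np.testing.assert_allclose(
            out.iloc[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_constant_gene_flagged_and_zeroed(self):
        m = _matrix([[4.0, 4.0, 4.0]], ["s1", "s2", "s3"])
        out, flagged = preprocess(m)
        assert flagged == ["g0"]
        np.testing.assert_allclose(out.iloc[0], 0.0)

    def test_non_positive_without_pseudocount_is_error(self):
        m = _matrix([[0.0, 1.0]], ["s1", "s2"])
        with pytest.raises(ValidationError):
            preprocess(m)
        out, _ = preprocess(m, pseudo_count=1.0)
        assert np.isfinite(out.to_numpy()).all()

    def test_standardized_rows_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        m = _matrix(np.exp(rng.normal(size=(20, 15))), [f"s{i}" for i in range(15)])
        out, _ = preprocess(m)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestDifferentialExpression:
    def test_identical_groups_statistic_zero_p_one(self):
        m = _matrix([[1.0, 1.0, 1.0, 1.0]], ["CASE0", "CASE1", "CTRL0", "CTRL1"])
        out = differential_expression(m, _labels(2, 2))
        assert out["statistic"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0
        assert not out["is_deg"].iloc[0]

    def test_welch_matches_textbook_oracle(self):
        case = np.array([5.1, 5.0, 4.9])
        ctrl = np.array([3.1, 3.0, 2.9])
        m = _matrix([np.concatenate([case, ctrl])],
                    ["CASE0", "CASE1", "CASE2", "CTRL0", "CTRL1", "CTRL2"])
        out = differential_expression(m, _labels(3, 3))
        t_exp, p_exp = welch_t(case, ctrl)
        assert out["statistic"].iloc[0] == pytest.approx(t_exp, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p_exp, abs=1e-10)
        assert out["direction"].iloc[0] == "up"

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        samples = [f"CASE{i}" for i in range(5)] + [f"CTRL{i}" for i in range(5)]
        m = _matrix(rng.normal(size=(30, 10)), samples)
        labels = _labels(5, 5)
        shuffled = m[list(rng.permutation(samples))]
        a = differential_expression(m, labels)
        b = differential_expression(shuffled, labels)
        np.testing.assert_allclose(a["p"], b["p"])

    def test_group_below_two_samples_is_error(self):
        m = _matrix([[1.0, 2.0, 3.0]], ["CASE0", "CTRL0", "CTRL1"])
        with pytest.raises(ValidationError):
            differential_expression(m, _labels(1, 2))

    def test_pooled_option_runs(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(10, 8)),
                    [f"CASE{i}" for i in range(4)] + [f"CTRL{i}" for i in range(4)])
        out = differential_expression(m, _labels(4, 4), method="pooled")
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


class TestIntersectTargets:
    def _degs(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "statistic": [2.0, -2.5, 3.0, 0.1],
                "p": [0.01, 0.02, 0.03, 0.9],
                "direction": ["up", "down", "up", "up"],
            }
        )

    def test_no_overlap_empty(self):
        dtm = DrugTargetMap()
        dtm.add("D1", "one", ["x", "y"])
        assert len(intersect_deg_targets(self._degs(), dtm)) == 0

    def test_overlap_with_drug_annotation(self):
        dtm = DrugTargetMap()
        dtm.add("D1", "one", ["b", "c", "d"])
        dtm.add("D2", "two", ["c"])
        out = intersect_deg_targets(self._degs(), dtm)
        assert list(out["gene"]) == ["b", "c"]
        assert out.loc[out["gene"] == "c", "drugs"].iloc[0] == "D1,D2"

    def test_alpha_zero_is_empty_by_strict_inequality(self):
        dtm = DrugTargetMap()
        dtm.add("D1", "one", ["a", "b"])
        assert len(intersect_deg_targets(self._degs(), dtm, alpha=0.0)) == 0

    def test_candidate_subset_restricts_drugs(self):
        dtm = DrugTargetMap()
        dtm.add("D1", "one", ["b"])
        dtm.add("D2", "two", ["c"])
        out = intersect_deg_targets(self._degs(), dtm, drug_ids=["D2"])
        assert list(out["gene"]) == ["c"]


class TestGroupSummary:
    def test_textbook_quartiles(self):
        m = _matrix(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 9.0, 9.0, 9.0, 9.0, 9.0]],
            [f"CASE{i}" for i in range(5)] + [f"CTRL{i}" for i in range(5)],
        )
        out = group_expression_summary(m, _labels(5, 5), ["g0"])
        case_row = out[(out["group"] == "case")].iloc[0]
        assert case_row["median"] == 3.0
        assert case_row["q1"] == 2.0
        assert case_row["q3"] == 4.0

    def test_identical_groups_identical_summaries(self):
        m = _matrix([[1.0, 5.0, 2.0, 1.0, 5.0, 2.0]],
                    [f"CASE{i}" for i in range(3)] + [f"CTRL{i}" for i in range(3)])
        out = group_expression_summary(m, _labels(3, 3), ["g0"])
        a, b = out.iloc[0], out.iloc[1]
        for col in ("median", "q1", "q3", "whisker_low", "whisker_high"):
            assert a[col] == b[col]

    def test_matches_numpy_quantiles_on_random_data(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(3, 12))
        m = _matrix(vals, [f"CASE{i}" for i in range(6)] +
                    [f"CTRL{i}" for i in range(6)])
        out = group_expression_summary(m, _labels(6, 6), ["g1"])
        case = vals[1, :6]
        row = out[(out["gene"] == "g1") & (out["group"] == "case")].iloc[0]
        np.testing.assert_allclose(
            [row["q1"], row["median"], row["q3"]],
            np.percentile(case, [25, 50, 75]),
        )

    def test_unknown_gene_named_in_error(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]],
                    ["CASE0", "CASE1", "CTRL0", "CTRL1"])
        with pytest.raises(ValidationError, match="ghost"):
            group_expression_summary(m, _labels(2, 2), ["ghost"])


class TestClusterGenes:
    def _blocks(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=20)
        rows = [base + rng.normal(0, 0.1, 20) for _ in range(4)]
        rows += [-base + rng.normal(0, 0.1, 20) for _ in range(4)]
        return _matrix(rows, [f"s{i}" for i in range(20)])

    def test_recovers_anticorrelated_blocks(self):
        m = self._blocks()
        labels, order = cluster_genes(m, list(m.index), n_clusters=2)
        block_a = {labels[f"g{i}"] for i in range(4)}
        block_b = {labels[f"g{i}"] for i in range(4, 8)}
        assert len(block_a) == 1 and len(block_b) == 1
        assert block_a != block_b

    def test_n_clusters_equal_n_genes(self):
        m = self._blocks()
        labels, _ = cluster_genes(m, list(m.index), n_clusters=len(m))
        assert len(set(labels.values())) == len(m)

    def test_gene_order_invariance(self):
        m = self._blocks()
        genes = list(m.index)
        a, _ = cluster_genes(m, genes, 2)
        b, _ = cluster_genes(m, genes[::-1], 2)
        assert a == b

    def test_constant_gene_excluded(self):
        m = self._blocks()
        m.loc["flat"] = 1.0
        labels, _ = cluster_genes(m, list(m.index), 2)
        assert "flat" not in labels

    def test_fewer_than_two_genes_is_error(self):
        m = self._blocks()
        with pytest.raises(InvalidParameterError):
            cluster_genes(m, ["g0"], 2)


class TestModelAndIO:
    def test_model_end_to_end_on_synthetic_cohort(self, default_study):
        model = GroupDifferentialExpression(
            default_study.expression, default_study.labels
        )
        res = model.fit(alpha=0.05)
        planted = default_study.disease.genes
        recovered = set(res.degs) & planted
        assert len(recovered) / len(planted) > 0.9

    def test_unknown_label_rejected(self):
        m = _matrix([[1.0, 2.0]], ["s1", "s2"])
        labels = pd.Series(["case", "weird"], index=["s1", "s2"])
        with pytest.raises(ValidationError):
            GroupDifferentialExpression(m, labels)

    def test_expression_io_round_trip(self, tmp_path):
        expr, labels = generate_expression(
            [f"G{i:04d}" for i in range(20)], ["G0001"], 1.0, 3, 3, seed=0
        )
        write_expression(expr, labels, tmp_path / "e.tsv", tmp_path / "l.tsv")
        back = read_expression(tmp_path / "e.tsv")
        lab = read_labels(tmp_path / "l.tsv")
        assert back.shape == expr.shape
        assert (lab == labels).all()
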