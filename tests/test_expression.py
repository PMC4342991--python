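"""Tests for the expression pipeline: normalization, testing, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dsxscan import expression as ex

from oracles import pooled_t_oracle


def _samples(n_male=3, n_female=3):
    rows = [
        {"sample_id": f"male_{i + 1}", "sex": "male", "repeat_of": ""}
        for i in range(n_male)
    ] + [
        {"sample_id": f"female_{i + 1}", "sex": "female", "repeat_of": ""}
        for i in range(n_female)
    ]
    return pd.DataFrame(rows)


class TestLog2Transform:
    def test_values_and_flooring(self):
        m = pd.DataFrame({"a": [8.0, 0.5, 1024.0]})
        out = ex.log2_transform(m, floor=1.0)
        assert list(out["a"]) == [3.0, 0.0, 10.0]

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            ex.log2_transform(pd.DataFrame({"a": [1.0]}), floor=0.0)


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = pd.DataFrame({"c1": [5.0, 3.0, 1.0], "c2": [4.0, 2.0, 6.0]})
        out = ex.quantile_normalize(m)
        assert list(out["c1"]) == [5.5, 3.5, 1.5]
        assert list(out["c2"]) == [3.5, 1.5, 5.5]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(ex.quantile_normalize(m), m)

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [9.0, 4.0, 7.0]})
        pd.testing.assert_frame_equal(ex.quantile_normalize(m), m)

    def test_ties_get_mean_of_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = ex.quantile_normalize(m)
        # reference = mean of sorted cols = (1.5, 2.5, 5.5); the tied pair in
        # column a shares mean(1.5, 2.5) = 2.0
        assert list(out["a"]) == [2.0, 2.0, 5.5]
        assert list(out["b"]) == [1.5, 2.5, 5.5]

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            ex.quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))

    def test_column_multisets_identical_and_idempotent(self, rng):
        m = pd.DataFrame(rng.lognormal(2, 1, size=(200, 6)))
        out = ex.quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(out.shape[1]):
            np.testing.assert_allclose(
                np.sort(out.iloc[:, j].to_numpy()), ref, atol=1e-12
            )
        np.testing.assert_allclose(
            ex.quantile_normalize(out).to_numpy(), out.to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            out.mean(axis=0), out.mean(axis=0).iloc[0], atol=1e-12
        )


class TestSummarizeProbes:
    def test_single_probe_gene_passthrough(self):
        m = pd.DataFrame({"s1": [2.0]}, index=["p1"])
        out = ex.summarize_probes(m, pd.Series({"p1": "gA"}))
        assert out.loc["gA", "s1"] == 2.0

    @pytest.mark.parametrize("method,expected", [("median", 3.0), ("mean", 4.0)])
    def test_median_and_mean(self, method, expected):
        m = pd.DataFrame({"s1": [1.0, 3.0, 8.0]}, index=["p1", "p2", "p3"])
        pmap = pd.Series({"p1": "gA", "p2": "gA", "p3": "gA"})
        assert ex.summarize_probes(m, pmap, method).loc["gA", "s1"] == expected

    def test_unmapped_probe_rejected(self):
        m = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(ValueError):
            ex.summarize_probes(m, pd.Series({"pX": "gA"}))

    def test_gene_without_probes_warns_and_excluded(self, caplog):
        m = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        pmap = pd.Series({"p1": "gA", "p2": "gB"})
        with caplog.at_level("WARNING"):
            out = ex.summarize_probes(m, pmap)
        assert list(out.index) == ["gA"]
        assert "excluded" in caplog.text


class TestTTest:
    def test_identical_groups_give_p_one(self):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
            index=["gA"],
            columns=[f"male_{i}" for i in range(1, 4)]
            + [f"female_{i}" for i in range(1, 4)],
        )
        res = ex.t_test_per_gene(m, _samples())
        assert res.loc["gA", "p_raw"] == 1.0
        assert res.loc["gA", "log2_fc"] == 0.0

    def test_degenerate_variance_convention(self):
        m = pd.DataFrame(
            [[5.0, 5.0, 5.0, 1.0, 1.0, 1.0]],
            index=["gA"],
            columns=[f"male_{i}" for i in range(1, 4)]
            + [f"female_{i}" for i in range(1, 4)],
        )
        res = ex.t_test_per_gene(m, _samples())
        assert res.loc["gA", "p_raw"] == 0.0
        assert res.loc["gA", "log2_fc"] == 4.0

    def test_matches_textbook_formula(self):
        male = [2.1, 1.9, 2.0, 2.2]
        female = [1.0, 0.9, 1.1, 1.0]
        m = pd.DataFrame(
            [male + female],
            index=["gA"],
            columns=[f"male_{i}" for i in range(1, 5)]
            + [f"female_{i}" for i in range(1, 5)],
        )
        res = ex.t_test_per_gene(m, _samples(4, 4))
        _, p_expected = pooled_t_oracle(male, female)
        assert res.loc["gA", "p_raw"] == pytest.approx(p_expected, abs=1e-10)
        assert res.loc["gA", "log2_fc"] == pytest.approx(
            np.mean(male) - np.mean(female)
        )

    def test_label_negation_flips_sign_preserves_p(self, rng):
        values = rng.normal(size=(30, 8))
        cols = [f"male_{i}" for i in range(4)] + [f"female_{i}" for i in range(4)]
        m = pd.DataFrame(values, columns=cols)
        res = ex.t_test_per_gene(m, _samples(4, 4).assign(
            sample_id=cols))
        flipped_samples = _samples(4, 4).assign(
            sample_id=cols, sex=lambda d: d.sex.map({"male": "female", "female": "male"})
        )
        flipped = ex.t_test_per_gene(m, flipped_samples)
        np.testing.assert_allclose(res.log2_fc, -flipped.log2_fc)
        np.testing.assert_allclose(res.p_raw, flipped.p_raw, atol=1e-12)

    def test_single_sex_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=["male_1", "male_2"])
        samples = pd.DataFrame(
            {"sample_id": ["male_1", "male_2"], "sex": ["male", "male"],
             "repeat_of": ["", ""]}
        )
        with pytest.raises(ValueError, match="per sex"):
            ex.t_test_per_gene(m, samples)

    def test_repeat_averaging_reduces_columns(self):
        cols = ["male_1", "male_2", "male_3", "female_1", "female_2", "female_3"]
        samples = pd.DataFrame(
            {
                "sample_id": cols,
                "sex": ["male"] * 3 + ["female"] * 3,
                "repeat_of": ["", "", "male_1", "", "", "female_2"],
            }
        )
        m = pd.DataFrame([[4.0, 2.0, 0.0, 1.0, 3.0, 5.0]], index=["gA"], columns=cols)
        cfg = ex.DEConfig(include_repeats="average_into_parent")
        res = ex.t_test_per_gene(m, samples, cfg)
        # male_1 becomes (4+0)/2 = 2, female_2 becomes (3+5)/2 = 4
        assert res.loc["gA", "mean_male"] == pytest.approx(2.0)
        assert res.loc["gA", "mean_female"] == pytest.approx(2.5)


class TestAdjust:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 5, 0.05), (0.3, 5, 1.0), (0.2, 1, 0.2)],
    )
    def test_bonferroni(self, p, m, expected):
        arr = np.full(m, p)
        out = ex.adjust_pvalues(arr, "bonferroni")
        assert out[0] == pytest.approx(expected)

    def test_bh_order_preserving_and_bounded(self, rng):
        p = rng.uniform(size=50)
        out = ex.adjust_pvalues(p, "bh")
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(out[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ex.adjust_pvalues(np.array([0.5, 1.5]))


class TestClassify:
    @pytest.mark.parametrize(
        "p_adj,lfc,expected",
        [
            (0.01, 2.5, "male_strong"),
            (0.01, -2.5, "female_strong"),
            (0.01, 1.0, "not_strong"),
            (0.2, 5.0, "not_significant"),
            (0.01, 2.0, "not_strong"),  # strictly greater than threshold
        ],
    )
    def test_classes(self, p_adj, lfc, expected):
        df = pd.DataFrame({"log2_fc": [lfc], "p_adj": [p_adj]}, index=["g"])
        out, summary = ex.classify_bias(df)
        assert out.loc["g", "bias_class"] == expected
        assert summary["n_det"] == int(p_adj < 0.05)

    def test_summary_counts(self):
        df = pd.DataFrame(
            {"log2_fc": [3.0, -3.0, 0.5, 1.0], "p_adj": [0.01, 0.01, 0.01, 0.9]},
            index=list("abcd"),
        )
        _, summary = ex.classify_bias(df)
        assert summary == {
            "n_genes": 4, "n_det": 3, "n_male_strong": 1, "n_female_strong": 1,
        }


class TestVolcano:
    def test_values_and_cap(self, tmp_path):
        df = pd.DataFrame(
            {
                "log2_fc": [1.0, 2.0, 3.0],
                "p_adj": [0.05, 1.0, 0.0],
                "bias_class": ["not_strong"] * 3,
            },
            index=["a", "b", "c"],
        )
        out = ex.volcano_table(df, tmp_path / "v.tsv")
        assert out.neg_log10_p_adj[0] == pytest.approx(1.3010, abs=1e-4)
        assert out.neg_log10_p_adj[1] == 0.0
        assert out.neg_log10_p_adj[2] == ex.NEG_LOG10_CAP
        assert (tmp_path / "v.tsv").exists()

    def test_empty_results_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["log2_fc", "p_adj", "bias_class"])
        ex.volcano_table(df, tmp_path / "v.tsv")
        lines = (tmp_path / "v.tsv").read_text().splitlines()
        assert lines == ["gene_id\tlog2_fc\tneg_log10_p_adj\tbias_class"]


class TestStudyValidation:
    def test_probe_missing_from_map(self):
        study = ex.ExpressionStudy(
            intensities=pd.DataFrame(
                np.ones((2, 4)),
                index=["p1", "p2"],
                columns=["male_1", "male_2", "female_1", "female_2"],
            ),
            probe_to_gene=pd.Series({"p1": "g"}),
            samples=_samples(2, 2),
        )
        with pytest.raises(ValueError, match="probe"):
            study.validate()

    def test_too_few_per_sex(self):
        study = ex.ExpressionStudy(
            intensities=pd.DataFrame(
                np.ones((1, 3)),
                index=["p1"],
                columns=["male_1", "female_1", "female_2"],
            ),
            probe_to_gene=pd.Series({"p1": "g"}),
            samples=pd.DataFrame(
                {
                    "sample_id": ["male_1", "female_1", "female_2"],
                    "sex": ["male", "female", "female"],
                    "repeat_of": ["", "", ""],
                }
            ),
        )
        with pytest.raises(ValueError, match=">=2"):
            study.validate()


def test_run_de_is_deterministic_for_fixed_input():
    from dsxscan import simulate as sim

    study, _ = sim.simulate_expression(sim.ExprSimConfig(n_genes=30, seed=1234))
    r1, s1 = ex.run_de(study)
    r2, s2 = ex.run_de(study)
    pd.testing.assert_frame_equal(r1, r2)
    assert s1 == s2
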