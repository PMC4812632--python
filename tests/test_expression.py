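import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chromarch.expression import (
    ExpressionTable,
    condition_enrichment_table,
    group_mean_expression,
    induced_genes,
    induction_ratio,
    mark_counts_by_class,
    pairwise_welch,
    read_marks_tsv,
    welch_t_test,
)


def table(values, conditions, kind="rpkm", genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                      columns=conditions)
    return ExpressionTable(df, kind)


class TestInducedGenes:
    def test_fold_threshold_strict(self):
        t = table([[10, 25], [10, 20], [10, 10]], ["glucose", "cellulose"])
        ind = induced_genes(t, "cellulose", "glucose")
        assert ind == {"g0"}  # 2.5-fold in; exactly 2.0 and 1.0 out

    def test_zero_reference_pseudocount(self):
        t = table([[0.0, 1.0], [0.0, 0.1]], ["glucose", "cellulose"])
        fc = t.fold_change("cellulose", "glucose")
        assert fc["g0"] == pytest.approx(1.1 / 0.1)
        assert fc["g1"] == pytest.approx(0.2 / 0.1)

    def test_log_intensity_delogged_base2(self):
        t = table([[8.0, 10.0]], ["glucose", "cellulose"], kind="log_intensity")
        assert t.fold_change("cellulose", "glucose")["g0"] == pytest.approx(4.0)

    def test_unknown_condition_errors(self):
        t = table([[1, 2]], ["glucose", "cellulose"])
        with pytest.raises(KeyError):
            induced_genes(t, "xylose", "glucose")

    def test_planted_induced_set_recovered_exactly(self, dataset):
        for cond in ("cellulose", "lactose", "sophorose"):
            got = induced_genes(dataset.expression, cond, "glucose", fold=2.0)
            assert got == set(dataset.manifest["induced_genes"][cond])


class TestGroupMeans:
    def test_simple_mean_sd(self):
        t = table([[1.0], [2.0], [3.0]], ["glucose"])
        cls = {"g0": "A", "g1": "A", "g2": "A"}
        s = group_mean_expression(t, cls, "glucose")["A"]
        assert (s.n, s.mean, s.sd) == (3, 2.0, 1.0)

    def test_single_class_equals_global_mean(self, dataset):
        expr = dataset.expression
        cls = {g: "ALL" for g in expr.genes}
        s = group_mean_expression(expr, cls, "glucose")["ALL"]
        assert s.mean == pytest.approx(float(expr.values["glucose"].mean()))

    def test_outlier_exclusion_closed_form(self):
        vals = [1.0, 2.0, 3.0, 1000.0]
        t = table([[v] for v in vals], ["glucose"])
        cls = {f"g{i}": "A" for i in range(4)}
        with_out = group_mean_expression(t, cls, "glucose")["A"]
        without = group_mean_expression(t, cls, "glucose", exclusions=["g3"])["A"]
        # removing x from a mean of n values shifts it to (n*m - x)/(n-1)
        assert without.mean == pytest.approx((4 * with_out.mean - 1000.0) / 3)
        assert without.excluded_genes == ["g3"]
        assert without.n == 3

    def test_empty_class_flagged(self):
        t = table([[1.0]], ["glucose"])
        s = group_mean_expression(t, {"g0": "A"}, "glucose", exclusions=["g0"])["A"]
        assert s.n == 0 and np.isnan(s.mean)

    def test_cec_basal_deficit_recovered(self, dataset):
        cls = dataset.manifest["class_of_gene"]
        gm = group_mean_expression(dataset.expression, cls, "glucose")
        ratio = gm["MCC"].mean / gm["CEC"].mean
        assert 50 <= ratio <= 200


class TestInductionRatio:
    def test_doubled_values(self):
        t = table([[1.0, 2.0], [3.0, 6.0]], ["glucose", "cellulose"])
        cls = {"g0": "A", "g1": "A"}
        assert induction_ratio(t, cls, "cellulose", "glucose")["A"] == pytest.approx(2.0)

    def test_identity_condition_is_one(self):
        t = table([[5.0]], ["glucose"])
        assert induction_ratio(t, {"g0": "A"}, "glucose", "glucose")["A"] == 1.0

    def test_zero_reference_flagged_nan(self):
        t = table([[0.0, 2.0]], ["glucose", "cellulose"])
        assert np.isnan(induction_ratio(t, {"g0": "A"}, "cellulose", "glucose")["A"])

    def test_low_basal_class_has_highest_fold(self, dataset):
        cls = dataset.manifest["class_of_gene"]
        folds = induction_ratio(dataset.expression, cls, "cellulose", "glucose")
        assert folds["CEC"] > folds["NCEC"] > folds["MCC"]


class TestWelch:
    def test_identical_samples(self):
        r = welch_t_test([1, 2, 3], [1, 2, 3])
        assert (r.t, r.p_two_sided) == (0.0, 1.0)

    def test_symmetry(self):
        a, b = [1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0, 6.0]
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.t == -r2.t
        assert r1.p_two_sided == r2.p_two_sided
        assert r1.df == r2.df

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(2, 20)))
            b = rng.normal(0.5, 2, size=int(rng.integers(2, 20)))
            r = welch_t_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert r.t == pytest.approx(ref.statistic, rel=1e-12)
            assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_constant_unequal_samples(self):
        r = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert r.p_two_sided == 0.0 and np.isinf(r.t)

    def test_bh_applied_above_five_comparisons(self):
        rng = np.random.default_rng(1)
        groups = {f"G{i}": rng.normal(i * 0.1, 1, 10) for i in range(5)}  # 10 pairs
        df = pairwise_welch(groups)
        assert len(df) == 10
        assert (df["p_adj"] >= df["p"] - 1e-12).all()
        small = pairwise_welch({k: groups[k] for k in list(groups)[:3]})  # 3 pairs
        assert (small["p_adj"] == small["p"]).all()


class TestMarks:
    def test_counts_and_percentages(self):
        marks = {"g0": {"H3K9me3"}, "g1": {"H3K4me2", "H3K9me3"}}
        cls = {"g0": "CEC", "g1": "CEC", "g2": "MCC"}
        df = mark_counts_by_class(marks, cls)
        row = df[(df["class"] == "CEC") & (df["mark"] == "H3K9me3")].iloc[0]
        assert (row.n_marked, row.pct_marked) == (2, 100.0)
        row = df[(df["class"] == "MCC") & (df["mark"] == "H3K9me3")].iloc[0]
        assert (row.n_marked, row.pct_marked) == (0, 0.0)

    def test_no_marks_all_zero(self):
        df = mark_counts_by_class({}, {"g0": "CEC"})
        assert (df["n_marked"] == 0).all()

    def test_unsupported_mark_rejected(self, tmp_path):
        p = tmp_path / "marks.tsv"
        p.write_text("gene_id\tmark\ng0\tH4K16ac\n")
        with pytest.raises(ValueError, match="unsupported"):
            read_marks_tsv(str(p))

    def test_planted_h3k9_rates_recovered(self, dataset):
        cls = dataset.manifest["class_of_gene"]
        df = mark_counts_by_class(dataset.marks, cls)
        cec = df[(df["class"] == "CEC") & (df["mark"] == "H3K9me3")].iloc[0]
        mcc = df[(df["class"] == "MCC") & (df["mark"] == "H3K9me3")].iloc[0]
        assert cec.pct_marked == pytest.approx(8.0, abs=2.0)
        assert mcc.pct_marked == pytest.approx(1.0, abs=2.0)


class TestEnrichmentTable:
    def test_percentages_against_named_denominators(self):
        # 148-gene class: 120 induced -> 81.1 %, 64 induced -> 43.2 %
        n = 148
        genes = [f"g{i}" for i in range(n)]
        gl = np.ones(n)
        cond_a = np.where(np.arange(n) < 120, 3.0, 1.0)
        cond_b = np.where(np.arange(n) < 64, 3.0, 1.0)
        t = table(np.c_[gl, cond_a, cond_b],
                  ["glucose", "conidiation", "cellulose"], genes=genes)
        cls = {g: "SSCP" for g in genes}
        df = condition_enrichment_table(t, cls, ["conidiation", "cellulose"], "glucose")
        con = df[df["condition"] == "conidiation"].iloc[0]
        cel = df[df["condition"] == "cellulose"].iloc[0]
        assert (con.n_induced, con.pct_induced) == (120, 81.1)
        assert (cel.n_induced, cel.pct_induced) == (64, 43.2)

    def test_counts_partition_total_induced(self, dataset):
        cls = dataset.manifest["class_of_gene"]
        df = condition_enrichment_table(
            dataset.expression, cls, ["cellulose"], "glucose"
        )
        total = len(induced_genes(dataset.expression, "cellulose", "glucose"))
        assert int(df["n_induced"].sum()) == total

    def test_empty_class_row(self):
        t = table([[1.0, 3.0]], ["glucose", "cellulose"])
        df = condition_enrichment_table(t, {}, ["cellulose"], "glucose")
        assert df.empty
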