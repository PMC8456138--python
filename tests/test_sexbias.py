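from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from asexpress import sexbias
from asexpress.sexbias import ClassShiftResult, MalenessComparison


def make_de(padj, lfc, tested=True):
    idx = [f"g{i}" for i in range(len(padj))]
    return pd.DataFrame(
        {"padj": padj, "log2fc": lfc, "tested": [tested] * len(padj)}, index=idx
    )


class TestClassifySexBias:
    def test_basic_classes(self):
        de = make_de([0.01, 0.5, 0.01], [1.2, 0.3, -2.0])
        out = sexbias.classify_sex_bias(de)
        assert list(out) == ["FBG", "UBG", "MBG"]

    def test_untested_gene(self):
        de = make_de([np.nan], [np.nan])
        de["tested"] = [False]
        assert sexbias.classify_sex_bias(de).iloc[0] == "untested"

    def test_orientation_flag(self):
        de = make_de([0.01], [1.0])
        assert sexbias.classify_sex_bias(de, female_is_group_b=False).iloc[0] == "MBG"


class TestRelativeLogExpression:
    def test_simple_ratio(self):
        expr = pd.DataFrame({"t1": [8.0], "t2": [8.0], "r1": [2.0], "r2": [2.0]})
        out = sexbias.relative_log_expression(expr, ["t1", "t2"], ["r1", "r2"], pseudocount=0)
        assert out.iloc[0] == pytest.approx(2.0)

    def test_identity_is_zero(self):
        expr = pd.DataFrame({"a": [3.0, 9.0], "b": [5.0, 7.0]})
        out = sexbias.relative_log_expression(expr, ["a", "b"], ["a", "b"])
        assert np.allclose(out, 0.0)

    def test_zero_zero_with_pseudocount(self):
        expr = pd.DataFrame({"t": [0.0], "r": [0.0]})
        assert sexbias.relative_log_expression(expr, ["t"], ["r"], 1.0).iloc[0] == 0.0

    def test_zero_reference_without_pseudocount_errors(self):
        expr = pd.DataFrame({"t": [1.0], "r": [0.0]})
        with pytest.raises(ValueError, match="pseudocount"):
            sexbias.relative_log_expression(expr, ["t"], ["r"], 0.0)


def shifted_ratios(fbg, mbg, ubg, n=50, rng=None):
    rng = rng or np.random.default_rng(0)
    vals = np.concatenate([
        fbg + 0.01 * rng.normal(size=n),
        mbg + 0.01 * rng.normal(size=n),
        ubg + 0.01 * rng.normal(size=n),
    ])
    idx = [f"g{i}" for i in range(3 * n)]
    ratios = pd.Series(vals, index=idx)
    bias = pd.Series(["FBG"] * n + ["MBG"] * n + ["UBG"] * n, index=idx)
    return ratios, bias


class TestClassShiftTest:
    def test_complete_separation_masculinized(self):
        ratios, bias = shifted_ratios(-1.0, +1.0, 0.0)
        res = sexbias.class_shift_test(ratios, bias)
        assert res.pattern == "masculinized"
        assert res.pvalues["FBG"] < 1e-10 and res.pvalues["MBG"] < 1e-10

    def test_mirror_is_feminized(self):
        ratios, bias = shifted_ratios(+1.0, -1.0, 0.0)
        assert sexbias.class_shift_test(ratios, bias).pattern == "feminized"

    def test_same_distribution_is_none(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ratios, bias = shifted_ratios(0.0, 0.0, 0.0, rng=rng)
            hits += sexbias.class_shift_test(ratios, bias).pattern == "none"
        assert hits >= 9

    def test_shift_invariant_to_constant_offset(self):
        ratios, bias = shifted_ratios(-1.0, 1.0, 0.0)
        r1 = sexbias.class_shift_test(ratios, bias)
        r2 = sexbias.class_shift_test(ratios + 42.0, bias)
        assert r1.pattern == r2.pattern
        assert r1.pvalues == pytest.approx(r2.pvalues)

    def test_small_class_reported_na(self):
        ratios, bias = shifted_ratios(-1.0, 1.0, 0.0, n=50)
        bias[bias == "MBG"] = "UBG"
        bias.iloc[50:55] = "MBG"  # only 5 MBG genes
        res = sexbias.class_shift_test(ratios, bias)
        assert np.isnan(res.pvalues["MBG"])

    def test_empty_ubg_errors(self):
        ratios, bias = shifted_ratios(-1.0, 1.0, 0.0)
        bias[bias == "UBG"] = "untested"
        with pytest.raises(ValueError, match="UBG"):
            sexbias.class_shift_test(ratios, bias)


class TestConservedSexBias:
    def test_consensus_rules(self):
        idx = ["g1", "g2", "g3", "g4"]
        t1 = pd.Series(["FBG", "FBG", "FBG", "untested"], index=idx)
        t2 = pd.Series(["FBG", "UBG", "MBG", "FBG"], index=idx)
        t3 = pd.Series(["FBG", "FBG", "FBG", "FBG"], index=idx)
        out = sexbias.conserved_sex_bias([t1, t2, t3])
        assert out["g1"] == "FBG"       # 3/3
        assert out["g2"] == "UBG"       # 2/3
        assert out["g3"] == "UBG"       # conflicting classes
        assert out["g4"] == "untested"  # untested anywhere

    def test_output_subset_of_inputs(self):
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(300)]
        tables = [
            pd.Series(rng.choice(["FBG", "MBG", "UBG"], 300, p=[0.2, 0.2, 0.6]), index=idx)
            for _ in range(3)
        ]
        out = sexbias.conserved_sex_bias(tables)
        for cls in ("FBG", "MBG"):
            conserved = set(out.index[out == cls])
            for t in tables:
                assert conserved <= set(t.index[t == cls])

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            sexbias.conserved_sex_bias([pd.Series(["FBG"], index=["g"])])


class TestGeneSetFet:
    def test_hand_computed_odds_ratio(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        annotation = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 25)}
        odds, p = sexbias.gene_set_fet(query, annotation, universe)
        # table [[5,5],[15,75]] -> (5*75)/(5*15) = 5
        assert odds == pytest.approx(5.0)

    def test_independence_gives_unit_odds(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(20)}
        annotation = {f"g{i}" for i in range(10, 60)}  # overlap 10 = 20*50/100
        odds, _ = sexbias.gene_set_fet(query, annotation, universe)
        assert odds == pytest.approx(1.0)

    def test_nested_sets_match_hypergeometric_tail(self):
        # query contained in annotation: the observed overlap is maximal, so
        # the two-sided Fisher p equals the upper hypergeometric tail
        n, q, a = 20, 4, 9
        universe = {f"g{i}" for i in range(n)}
        query = {f"g{i}" for i in range(q)}
        annotation = {f"g{i}" for i in range(a)}
        _, p = sexbias.gene_set_fet(query, annotation, universe)
        tail = Fraction(0)
        for x in range(q, q + 1):  # P(X >= q) with X capped at q
            tail += Fraction(comb(a, x) * comb(n - a, q - x), comb(n, q))
        assert p == pytest.approx(float(tail))

    def test_zero_cell_haldane_flagged(self, caplog):
        universe = {f"g{i}" for i in range(10)}
        odds, _ = sexbias.gene_set_fet({"g0"}, {"g0"}, universe)
        assert np.isfinite(odds) and odds > 1

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            sexbias.gene_set_fet(set(), set(), set())


class TestExpressionDivergence:
    def make_means(self):
        cols = {
            ("ref", "F", "head"): [1.0],
            ("ref", "F", "gonad"): [3.0],
            ("tgt", "F", "head"): [2.0],
            ("tgt", "F", "gonad"): [5.0],
        }
        return pd.DataFrame(cols)

    def test_hand_computed_distance(self):
        d = sexbias.expression_divergence(
            self.make_means(), "ref", "tgt", [("head", "F"), ("gonad", "F")]
        )
        assert d.iloc[0] == pytest.approx(np.sqrt(5))

    def test_identity_zero(self):
        d = sexbias.expression_divergence(
            self.make_means(), "ref", "ref", [("head", "F"), ("gonad", "F")]
        )
        assert d.iloc[0] == 0.0

    def test_adding_slot_monotone(self):
        means = self.make_means()
        d1 = sexbias.expression_divergence(means, "ref", "tgt", [("head", "F")])
        d2 = sexbias.expression_divergence(means, "ref", "tgt", [("head", "F"), ("gonad", "F")])
        assert (d2 >= d1 - 1e-12).all()

    def test_missing_slot_errors(self):
        with pytest.raises(ValueError, match="missing"):
            sexbias.expression_divergence(self.make_means(), "ref", "tgt", [("head", "M")])

    def test_single_gene_class_reported_na(self):
        div = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        bias = pd.Series(["FBG", "UBG", "UBG"], index=["a", "b", "c"])
        res = sexbias.divergence_class_test(div, bias)
        assert np.isnan(res["pvalues"]["FBG_vs_UBG"]) or np.isfinite(res["pvalues"]["FBG_vs_UBG"])
        assert np.isnan(res["pvalues"]["FBG_vs_MBG"])


def shift_result(pattern, med_f, med_m, p=1e-6):
    sig = p < 0.05
    return ClassShiftResult(
        medians={"FBG": med_f, "MBG": med_m, "UBG": 0.0},
        pvalues={"FBG": p, "MBG": p},
        n_genes={"FBG": 100, "MBG": 100, "UBG": 500},
        pattern=pattern,
    )


def lda_cmp(male_like):
    scores = pd.Series(np.arange(6, dtype=float))
    groups = pd.Series(["train_F"] * 2 + ["train_M"] * 2 + ["asexual"] * 2)
    if male_like:
        return MalenessComparison(scores, groups, p_vs_female=0.001, p_vs_male=0.5,
                                  overlap_female_range=0.0,
                                  medians={"train_F": -1.0, "train_M": 1.0, "asexual": 0.5})
    return MalenessComparison(scores, groups, p_vs_female=0.5, p_vs_male=0.001,
                              overlap_female_range=1.0,
                              medians={"train_F": -1.0, "train_M": 1.0, "asexual": -1.0})


class TestDiagnoseMasculinization:
    def test_true_masculinization_pattern(self):
        fem = {l: shift_result("masculinized", -0.5, 0.5) for l in ("a1", "a2", "a3")}
        male = {l: shift_result("none", 0.0, 0.0, p=0.5) for l in ("kaz", "urm")}
        cons = {l: shift_result("masculinized", -0.5, 0.5) for l in ("a1", "a2", "a3")}
        out = sexbias.diagnose_masculinization(fem, male, cons, lda_cmp(True), fem)
        assert out["verdict"] == "true_masculinization"

    def test_turnover_mirror_pattern(self):
        fem = {l: shift_result("masculinized", -0.2, 0.15) for l in ("a1", "a2", "a3")}
        male = {l: shift_result("feminized", 0.2, -0.15) for l in ("kaz", "urm")}
        cons = {l: shift_result("none", -0.02, 0.01, p=0.5) for l in ("a1", "a2", "a3")}
        out = sexbias.diagnose_masculinization(fem, male, cons, lda_cmp(False), fem)
        assert out["verdict"] == "turnover_artifact"

    def test_null_pattern(self):
        fem = {l: shift_result("none", 0.0, 0.0, p=0.6) for l in ("a1", "a2", "a3")}
        male = {l: shift_result("none", 0.0, 0.0, p=0.6) for l in ("kaz", "urm")}
        cons = dict(fem)
        out = sexbias.diagnose_masculinization(fem, male, cons, lda_cmp(False), fem)
        assert out["verdict"] == "none"

    def test_small_artifact_shifts_do_not_count(self):
        # significant but tiny shifts (the winner's-curse signature) stay 'none'
        fem = {l: shift_result("masculinized", -0.05, 0.04) for l in ("a1", "a2", "a3")}
        male = {l: shift_result("feminized", 0.04, -0.05) for l in ("kaz", "urm")}
        cons = {l: shift_result("none", 0.0, 0.0, p=0.5) for l in ("a1", "a2", "a3")}
        out = sexbias.diagnose_masculinization(fem, male, cons, lda_cmp(False), fem)
        assert out["verdict"] == "none"

    def test_missing_male_control_undetermined(self):
        fem = {l: shift_result("masculinized", -0.5, 0.5) for l in ("a1", "a2", "a3")}
        out = sexbias.diagnose_masculinization(fem, {}, fem, lda_cmp(True), fem)
        assert out["verdict"] == "undetermined"

    def test_reversed_mirror_is_feminization(self):
        fem = {l: shift_result("feminized", 0.3, -0.3) for l in ("a1", "a2", "a3")}
        male = {l: shift_result("masculinized", -0.3, 0.3) for l in ("kaz", "urm")}
        cons = {l: shift_result("none", 0.0, 0.0, p=0.5) for l in ("a1", "a2", "a3")}
        out = sexbias.diagnose_masculinization(fem, male, cons, lda_cmp(False), fem)
        assert out["verdict"] == "feminization"
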