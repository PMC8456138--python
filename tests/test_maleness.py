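import numpy as np
import pandas as pd
import pytest

from asexpress import maleness


def synthetic_training(seed=0, n_genes=500, n_per_sex=6, shift=2.0, frac=0.1):
    """Quantile-normalized-like expression with a male shift on a gene subset."""
    rng = np.random.default_rng(seed)
    base = rng.gamma(2.0, 20.0, n_genes)
    biased = rng.choice(n_genes, int(frac * n_genes), replace=False)
    cols = {}
    labels = {}
    for i in range(n_per_sex):
        for sex in ("M", "F"):
            vals = base * np.exp2(0.2 * rng.normal(size=n_genes))
            if sex == "M":
                vals[biased] = vals[biased] * 2.0**shift
            sid = f"{sex.lower()}{i}"
            cols[sid] = vals
            labels[sid] = sex
    expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return expr, pd.Series(labels)


class TestFitMalenessModel:
    def test_separates_sexes_with_disjoint_ranges(self):
        hits = 0
        for seed in range(5):
            expr, labels = synthetic_training(seed)
            model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
            f = model.ld1_train[labels.index[labels == "F"]]
            m = model.ld1_train[labels.index[labels == "M"]]
            hits += f.max() < m.min()
        assert hits >= 4

    def test_orientation_male_higher(self):
        expr, labels = synthetic_training(1)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        assert model.class_means["M"] > model.class_means["F"]

    def test_permuted_labels_near_chance_loo_accuracy(self):
        expr, labels = synthetic_training(2, n_per_sex=6)
        rng = np.random.default_rng(2)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        acc = maleness.loo_accuracy(expr, permuted)
        assert acc <= 0.8  # far from the ~1.0 of true labels

    def test_true_labels_high_loo_accuracy(self):
        expr, labels = synthetic_training(3)
        assert maleness.loo_accuracy(expr, labels) >= 0.9

    def test_duplicating_samples_keeps_direction(self):
        expr, labels = synthetic_training(4)
        m1 = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        dup = pd.concat([expr, expr.add_suffix("_dup", axis=1)], axis=1)
        lab_dup = pd.concat([labels, labels.set_axis([f"{i}_dup" for i in labels.index])])
        m2 = maleness.fit_maleness_model(dup, lab_dup, loo_scores=False)
        d1 = m1.loadings @ m1.w
        d2 = m2.loadings @ m2.w
        cos = abs(d1 @ d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
        assert cos == pytest.approx(1.0, abs=0.05)

    def test_too_few_samples_rejected(self):
        expr, labels = synthetic_training(5, n_per_sex=1)
        with pytest.raises(ValueError, match=">= 2 training samples"):
            maleness.fit_maleness_model(expr, labels)

    def test_explicit_pc_count(self):
        expr, labels = synthetic_training(6)
        model = maleness.fit_maleness_model(expr, labels, pc_rule=3, loo_scores=False)
        assert model.loadings.shape[1] == 3


class TestMalenessScores:
    def test_scoring_training_reproduces_ld1(self):
        expr, labels = synthetic_training(7)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        rescored = maleness.maleness_scores(model, expr)
        assert np.allclose(rescored, model.ld1_train, atol=1e-9)

    def test_female_mean_sample_scores_at_female_centroid(self):
        expr, labels = synthetic_training(8)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        fmean_log = np.log2(expr[labels.index[labels == "F"]] + 1).mean(axis=1)
        probe = pd.DataFrame({"probe": np.exp2(fmean_log) - 1})
        score = maleness.maleness_scores(model, probe).iloc[0]
        assert score == pytest.approx(model.class_means["F"], abs=1e-6)

    def test_affine_in_log_space(self):
        expr, labels = synthetic_training(9)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        a = np.log2(expr.iloc[:, 0] + 1)
        b = np.log2(expr.iloc[:, 5] + 1)
        lam = 0.3
        mix = np.exp2(lam * a + (1 - lam) * b) - 1
        scores = maleness.maleness_scores(
            model, pd.DataFrame({"a": expr.iloc[:, 0], "b": expr.iloc[:, 5], "mix": mix})
        )
        assert scores["mix"] == pytest.approx(lam * scores["a"] + (1 - lam) * scores["b"], abs=1e-8)

    def test_missing_genes_rejected(self):
        expr, labels = synthetic_training(10)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        with pytest.raises(ValueError, match="missing model genes"):
            maleness.maleness_scores(model, expr.iloc[:-5])

    def test_negative_input_flagged(self):
        expr, labels = synthetic_training(11)
        model = maleness.fit_maleness_model(expr, labels, loo_scores=False)
        bad = expr.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            maleness.maleness_scores(model, bad)


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path):
        expr, labels = synthetic_training(12, n_per_sex=3)
        model = maleness.fit_maleness_model(expr, labels)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = maleness.MalenessModel.from_json(path)
        s1 = maleness.maleness_scores(model, expr)
        s2 = maleness.maleness_scores(back, expr)
        assert np.allclose(s1, s2)


class TestScoreComparison:
    def test_asexuals_identical_to_females(self):
        f = pd.Series([-1.0, -1.1, -0.9, -1.05], index=list("abcd"))
        m = pd.Series([1.0, 1.1, 0.9, 1.05], index=list("wxyz"))
        a = f.copy().set_axis(["p", "q", "r", "s"])
        cmp = maleness.score_comparison(a, f, m)
        assert cmp.overlap_female_range == 1.0
        assert cmp.p_vs_female > 0.05
        assert cmp.p_vs_male < 0.05

    def test_asexuals_above_males(self):
        f = pd.Series([-1.0, -1.1, -0.9, -1.2], index=list("abcd"))
        m = pd.Series([1.0, 1.1, 0.9, 1.2], index=list("wxyz"))
        a = pd.Series([2.0, 2.1, 2.2, 2.3], index=list("pqrs"))
        cmp = maleness.score_comparison(a, f, m)
        assert cmp.overlap_female_range == 0.0
        # complete separation at n=4 vs 4: exact two-sided p = 2/C(8,4)
        assert cmp.p_vs_male == pytest.approx(2 / 70, abs=1e-12)
        assert cmp.male_shifted()

    def test_single_asexual_na_tests(self):
        f = pd.Series([-1.0, -1.1], index=list("ab"))
        m = pd.Series([1.0, 1.1], index=list("xy"))
        a = pd.Series([-1.0], index=["p"])
        cmp = maleness.score_comparison(a, f, m)
        assert np.isnan(cmp.p_vs_female)
        assert cmp.overlap_female_range == 1.0

    def test_widened_female_range(self):
        f = pd.Series([-1.0, -0.9], index=list("ab"))
        m = pd.Series([1.0, 1.1], index=list("xy"))
        a = pd.Series([-1.3, -0.95], index=list("pq"))
        narrow = maleness.score_comparison(a, f, m)
        wide = maleness.score_comparison(a, f, m, female_range=(-1.5, -0.8))
        assert narrow.overlap_female_range == 0.5
        assert wide.overlap_female_range == 1.0
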