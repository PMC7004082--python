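import numpy as np
import pandas as pd
import pytest

from sitefidelity.personality import (BEHAVIOUR_COLS, adjusted_repeatability,
                                      classify_bold_shy, individual_boldness,
                                      pca_boldness)
from sitefidelity.synthetic import SimConfig, make_birds, simulate_personality


def dirichlet_tests(n, rng, alpha=(2.0, 1.0, 1.5, 0.8, 0.6)):
    X = rng.dirichlet(alpha, size=n)
    return pd.DataFrame(X, columns=BEHAVIOUR_COLS)


class TestPCA:
    def test_compositional_null_component(self, rng):
        """The sum-to-one constraint forces a zero fifth eigenvalue whose
        loadings are all 1/sqrt(5) in magnitude."""
        res = pca_boldness(dirichlet_tests(200, rng))
        assert res.eigenvalues[4] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.abs(res.loadings[:, 4]), 1 / np.sqrt(5), atol=1e-8)
        assert np.cumsum(res.variance_explained)[3] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal_and_variance_preserved(self, rng):
        tests = dirichlet_tests(120, rng)
        res = pca_boldness(tests)
        L = res.loadings
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        total_var = tests[BEHAVIOUR_COLS].var(ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, abs=1e-10)

    def test_pc1_oriented_by_sitting_loading(self, rng):
        res = pca_boldness(dirichlet_tests(80, rng))
        assert res.loadings[0, 0] > 0

    def test_too_few_tests_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_boldness(dirichlet_tests(5, rng))


def balanced_dataset(rng, n_birds=30, k=4, var_b=1.0, var_e=1.0):
    bird = np.repeat(np.arange(n_birds), k)
    y = rng.normal(0, np.sqrt(var_b), n_birds)[bird] + \
        rng.normal(0, np.sqrt(var_e), n_birds * k)
    return y, bird, k


class TestAdjustedRepeatability:
    def test_matches_anova_icc_on_balanced_design(self, rng):
        """On a balanced one-way design REML equals the classical
        (MSB - MSW) / (MSB + (k-1) MSW) intraclass correlation."""
        y, bird, k = balanced_dataset(rng)
        df = pd.DataFrame({"y": y, "bird": bird})
        msb = df.groupby("bird")["y"].mean().var(ddof=1) * k
        msw = df.groupby("bird")["y"].var(ddof=1).mean()
        icc = (msb - msw) / (msb + (k - 1) * msw)
        res = adjusted_repeatability(y, bird, n_boot=0)
        assert res.R == pytest.approx(icc, abs=1e-3)

    def test_no_between_variance_gives_near_zero(self, rng):
        y, bird, _ = balanced_dataset(rng, var_b=0.0)
        res = adjusted_repeatability(y, bird, n_boot=200, seed=0)
        assert res.R < 0.1
        assert res.ci95[0] == pytest.approx(0.0, abs=1e-6)
        assert res.p > 0.01

    def test_zero_within_variance_gives_one(self):
        bird = np.repeat(np.arange(10), 3)
        y = np.arange(10, dtype=float)[bird]
        res = adjusted_repeatability(y, bird, n_boot=50, seed=0)
        assert res.R == 1.0

    def test_invariant_to_affine_rescaling(self, rng):
        y, bird, _ = balanced_dataset(rng)
        r1 = adjusted_repeatability(y, bird, n_boot=0).R
        r2 = adjusted_repeatability(3.7 * y - 11.0, bird, n_boot=0).R
        assert r1 == pytest.approx(r2, abs=1e-8)

    def test_covariate_adjustment_removes_fixed_effect(self, rng):
        y, bird, _ = balanced_dataset(rng)
        x = rng.normal(0, 1, len(y))
        cov = pd.DataFrame({"x": x})
        r_clean = adjusted_repeatability(y, bird, n_boot=0).R
        r_adj = adjusted_repeatability(y + 5.0 * x, bird, covariates=cov,
                                       n_boot=0).R
        assert r_adj == pytest.approx(r_clean, abs=0.05)

    def test_requires_repeated_measures(self):
        with pytest.raises(ValueError):
            adjusted_repeatability([1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_recovers_planted_repeatability_across_seeds(self):
        """Estimated R sits inside its 95% bootstrap CI of the planted value
        in at least 90% of seeded replicate studies (100 birds x 3 tests)."""
        cover = 0
        for seed in range(20):
            cfg = SimConfig(n_birds_per_colony=25, boldness_repeatability=0.7,
                            rng_seed=seed)
            rng = np.random.default_rng(seed)
            birds = make_birds(cfg, rng)
            tests, _ = simulate_personality(cfg, rng, birds,
                                            n_tests_probs=(0.0, 0.0, 1.0, 0.0))
            pca = pca_boldness(tests)
            cov = pd.DataFrame({
                "date": (tests["date"] - tests["date"].min()) / pd.Timedelta(days=1),
                "test_number": tests["test_number"].astype(float)})
            res = adjusted_repeatability(pca.pc1_scores, tests["bird_id"], cov,
                                         n_boot=300, seed=seed)
            cover += res.ci95[0] <= 0.7 <= res.ci95[1]
        assert cover >= 18

    def test_zero_repeatability_ci_covers_zero(self):
        cfg = SimConfig(n_birds_per_colony=25, boldness_repeatability=0.0,
                        rng_seed=5)
        rng = np.random.default_rng(5)
        tests, _ = simulate_personality(cfg, rng,
                                        n_tests_probs=(0.0, 0.0, 1.0, 0.0))
        res = adjusted_repeatability(pca_boldness(tests).pc1_scores,
                                     tests["bird_id"], n_boot=300, seed=5)
        assert res.ci95[0] <= 0.05
        assert res.R < 0.2


class TestIndividualBoldness:
    def test_equals_per_bird_means_without_covariates(self):
        scores = np.array([1.0, 2.0, 4.0, 10.0, 0.0])
        birds = ["a", "a", "a", "b", "c"]
        out = individual_boldness(scores, birds).set_index("bird_id")
        assert out.loc["a", "boldness"] == pytest.approx(7 / 3)
        assert out.loc["b", "boldness"] == pytest.approx(10.0)
        assert out.loc["c", "boldness"] == pytest.approx(0.0)
        assert out["n_tests"].tolist() == [3, 1, 1]

    def test_shift_equivariance(self, rng):
        scores = rng.normal(0, 1, 40)
        birds = np.repeat([f"b{i}" for i in range(10)], 4)
        cov = pd.DataFrame({"x": rng.normal(0, 1, 40)})
        b0 = individual_boldness(scores, birds, cov)["boldness"]
        b1 = individual_boldness(scores + 2.5, birds, cov)["boldness"]
        assert np.allclose(b1 - b0, 2.5, atol=1e-10)

    def test_recovers_latent_ranking(self):
        cfg = SimConfig(n_birds_per_colony=25, boldness_repeatability=0.7,
                        rng_seed=3)
        rng = np.random.default_rng(3)
        birds = make_birds(cfg, rng)
        tests, _ = simulate_personality(cfg, rng, birds,
                                        n_tests_probs=(0.0, 0.0, 1.0, 0.0))
        pca = pca_boldness(tests)
        est = individual_boldness(pca.pc1_scores, tests["bird_id"])
        merged = est.merge(birds[["bird_id", "boldness_true"]], on="bird_id")
        rho = merged[["boldness", "boldness_true"]].corr(method="spearman").iloc[0, 1]
        assert rho > 0.8


class TestBoldShySplit:
    def test_even_split(self):
        df = pd.DataFrame({"bird_id": list("abcd"), "boldness": [1.0, 2, 3, 4]})
        out = classify_bold_shy(df)
        assert set(out.loc[out.group == "bold", "bird_id"]) == {"c", "d"}

    def test_median_bird_goes_to_shy(self):
        df = pd.DataFrame({"bird_id": list("abcde"), "boldness": [1.0, 2, 3, 4, 5]})
        out = classify_bold_shy(df)
        assert out.loc[out.bird_id == "c", "group"].item() == "shy"
        counts = out["group"].value_counts()
        assert counts["shy"] == 3 and counts["bold"] == 2

    def test_all_equal_scores_all_shy(self):
        df = pd.DataFrame({"bird_id": list("abcd"), "boldness": [1.0] * 4})
        out = classify_bold_shy(df)
        assert (out["group"] == "shy").all()

    def test_partition_is_complete_and_balanced(self, rng):
        df = pd.DataFrame({"bird_id": [f"b{i}" for i in range(133)],
                           "boldness": rng.normal(0, 1, 133)})
        out = classify_bold_shy(df)
        counts = out["group"].value_counts()
        assert counts.sum() == 133
        assert abs(counts["bold"] - counts["shy"]) <= 1
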