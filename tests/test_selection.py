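import numpy as np
import pandas as pd
import pytest

from magicgs.selection import (
    SmithHazelIndex,
    classify_lines,
    genetic_correlation_matrix,
    index_values,
    pca_of_genetic_values,
    smith_hazel_weights,
    trait_cov_matrices,
)


def _df(values, traits):
    return pd.DataFrame(values, columns=traits,
                        index=[f"L{i:02d}" for i in range(len(values))])


class TestTraitCovMatrices:
    def test_hand_table(self):
        pheno = _df([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]], ["a", "b"])
        gen = pheno * 0.5
        P, Gc = trait_cov_matrices(pheno, gen)
        # textbook sample covariance
        x = pheno["a"].to_numpy()
        y = pheno["b"].to_numpy()
        expected = np.sum((x - x.mean()) * (y - y.mean())) / 3
        assert P.loc["a", "b"] == pytest.approx(expected)
        assert Gc.loc["a", "b"] == pytest.approx(expected * 0.25)

    def test_rank_deficiency_detected(self):
        pheno = _df([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]], ["a", "b"])
        with pytest.warns(UserWarning, match="rank deficient"):
            trait_cov_matrices(pheno, pheno)

    def test_independent_traits_near_zero_offdiagonal(self):
        rng = np.random.default_rng(0)
        pheno = _df(rng.normal(size=(500, 2)), ["a", "b"])
        P, _ = trait_cov_matrices(pheno, pheno)
        assert abs(P.loc["a", "b"]) < 3 / np.sqrt(500)

    def test_mismatched_lines_rejected(self):
        pheno = _df(np.eye(4), list("abcd"))
        gen = pheno.copy()
        gen.index = [f"X{i}" for i in range(4)]
        with pytest.raises(ValueError, match="line sets"):
            trait_cov_matrices(pheno, gen)


class TestSmithHazelWeights:
    def test_two_trait_hand_solve(self):
        P = pd.DataFrame([[2.0, 0.0], [0.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        Gc = pd.DataFrame([[1.0, 0.0], [0.0, 0.5]], index=["a", "b"], columns=["a", "b"])
        b = smith_hazel_weights(P, Gc)
        np.testing.assert_allclose(b, [0.5, 0.5], atol=1e-12)

    def test_p_equal_g_gives_unit_weights(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 6))
        P = pd.DataFrame(A @ A.T, index=list("abc"), columns=list("abc"))
        b = smith_hazel_weights(P, P, a=[1, 1, 1])
        np.testing.assert_allclose(b, [1, 1, 1], atol=1e-8)

    def test_linearity_in_economic_weights(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 6))
        B = rng.normal(size=(3, 6))
        P = pd.DataFrame(A @ A.T + np.eye(3), index=list("abc"), columns=list("abc"))
        Gc = pd.DataFrame(B @ B.T, index=list("abc"), columns=list("abc"))
        b1 = smith_hazel_weights(P, Gc, a=[1, 2, 3])
        b3 = smith_hazel_weights(P, Gc, a=[3, 6, 9])
        np.testing.assert_allclose(3 * b1, b3, atol=1e-10)

    def test_singular_p_requires_ridge(self):
        P = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        Gc = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(np.linalg.LinAlgError):
            smith_hazel_weights(P, Gc)
        b = smith_hazel_weights(P, Gc, ridge=1e-6)
        assert b.attrs["ridge"] > 0

    def test_index_beats_random_weight_vectors(self):
        # the Smith-Hazel index maximises correlation with aggregate merit
        rng = np.random.default_rng(3)
        t, n = 4, 4000
        A = rng.normal(size=(t, t))
        Gm = A @ A.T + 0.5 * np.eye(t)
        E = rng.normal(size=(t, t)) * 0.6
        Pm = Gm + E @ E.T
        traits = [f"t{i}" for i in range(t)]
        g = rng.multivariate_normal(np.zeros(t), Gm, size=n)
        e = rng.multivariate_normal(np.zeros(t), Pm - Gm, size=n)
        x = g + e
        a = np.ones(t)
        merit = g @ a
        b = smith_hazel_weights(
            pd.DataFrame(Pm, index=traits, columns=traits),
            pd.DataFrame(Gm, index=traits, columns=traits),
            a,
        )
        r_sh = np.corrcoef(x @ b.to_numpy(), merit)[0, 1]
        rng2 = np.random.default_rng(4)
        best_random = max(
            np.corrcoef(x @ w, merit)[0, 1]
            for w in rng2.normal(size=(300, t))
        )
        assert r_sh >= best_random - 0.02


class TestIndexValues:
    def test_single_trait_reduces_to_gebv(self):
        x = _df([[1.0], [3.0], [2.0]], ["a"])
        b = pd.Series([1.0], index=["a"])
        out = index_values(b, x)
        np.testing.assert_allclose(out, x["a"])

    def test_zero_gebvs_give_zero_index(self):
        x = _df(np.zeros((4, 2)), ["a", "b"])
        out = index_values(pd.Series([1.0, 2.0], index=["a", "b"]), x)
        assert (out == 0).all()

    def test_matches_dot_product(self):
        rng = np.random.default_rng(5)
        x = _df(rng.normal(size=(7, 3)), ["a", "b", "c"])
        b = pd.Series(rng.normal(size=3), index=["a", "b", "c"])
        out = index_values(b, x)
        np.testing.assert_allclose(out, x.to_numpy() @ b.to_numpy())

    def test_missing_gebv_drops_line_with_warning(self):
        x = _df([[1.0, 2.0], [np.nan, 1.0], [0.5, 0.5]], ["a", "b"])
        with pytest.warns(UserWarning, match="dropped"):
            out = index_values(pd.Series([1.0, 1.0], index=["a", "b"]), x)
        assert len(out) == 2

    def test_constant_shift_preserves_ranking(self):
        rng = np.random.default_rng(6)
        x = _df(rng.normal(size=(10, 2)), ["a", "b"])
        b = pd.Series([0.7, -0.2], index=["a", "b"])
        r1 = index_values(b, x).rank()
        r2 = index_values(b, x + 5.0).rank()
        pd.testing.assert_series_equal(r1, r2)


class TestClassifyLines:
    def test_strict_ordering(self):
        idx = pd.Series([5.0, 1.0, 3.0, 4.0, 2.0, 0.0],
                        index=list("ABCDEF"))
        tol, sus = classify_lines(idx, k=2)
        assert tol == ["A", "D"]
        assert sus == ["F", "B"]

    def test_half_split_partitions(self):
        idx = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))
        tol, sus = classify_lines(idx, k=2)
        assert sorted(tol + sus) == list("ABCD")

    def test_tie_broken_lexicographically(self):
        idx = pd.Series([3.0, 2.0, 2.0, 1.0], index=["D", "B", "A", "C"])
        tol, _ = classify_lines(idx, k=2)
        assert tol == ["D", "A"]

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            classify_lines(pd.Series([1.0, 2.0], index=list("AB")), k=2)


class TestGeneticCorrelationMatrix:
    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(7)
        gv = _df(rng.normal(size=(30, 3)), ["a", "b", "c"])
        corr, pvals, masked = genetic_correlation_matrix(gv)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        pd.testing.assert_frame_equal(corr, corr.T)

    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(8)
        n = 184
        z = rng.normal(size=n)
        a = z + rng.normal(size=n) * 0.5
        b = z + rng.normal(size=n) * 0.5
        gv = pd.DataFrame({"a": a, "b": b})
        corr, _, _ = genetic_correlation_matrix(gv)
        assert corr.loc["a", "b"] == pytest.approx(0.8, abs=0.1)

    def test_mask_hides_insignificant(self):
        rng = np.random.default_rng(9)
        gv = _df(rng.normal(size=(5, 2)), ["a", "b"])
        corr, pvals, masked = genetic_correlation_matrix(gv)
        if pvals.loc["a", "b"] >= 0.05:
            assert np.isnan(masked.loc["a", "b"])

    def test_constant_trait_gives_nan(self):
        gv = _df(np.column_stack([np.ones(6), np.arange(6.0)]), ["a", "b"])
        corr, _, _ = genetic_correlation_matrix(gv)
        assert np.isnan(corr.loc["a", "b"])


class TestPcaOfGeneticValues:
    def test_perfectly_correlated_traits(self):
        x = np.arange(10.0)
        gv = pd.DataFrame({"a": x, "b": 2 * x + 1})
        scores, loadings, varexp = pca_of_genetic_values(gv)
        assert varexp[0] == pytest.approx(1.0)

    def test_variance_fractions_from_construction(self):
        rng = np.random.default_rng(10)
        n = 4000
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        gv = pd.DataFrame({
            "a": z1, "b": z1 + 0.1 * rng.normal(size=n), "c": z2,
        })
        _, _, varexp = pca_of_genetic_values(gv)
        # two strongly correlated traits + one independent: PC1 ~ 2/3, PC2 ~ 1/3
        assert varexp[0] == pytest.approx(2 / 3, abs=0.03)
        assert varexp[1] == pytest.approx(1 / 3, abs=0.03)

    def test_sign_convention(self):
        rng = np.random.default_rng(11)
        gv = _df(rng.normal(size=(20, 3)), ["a", "b", "c"])
        _, loadings, _ = pca_of_genetic_values(gv)
        for col in loadings.columns:
            j = loadings[col].abs().idxmax()
            assert loadings.loc[j, col] > 0

    def test_zero_variance_trait_dropped(self):
        gv = pd.DataFrame({"a": np.ones(6), "b": np.arange(6.0),
                           "c": np.arange(6.0) ** 2})
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, loadings, _ = pca_of_genetic_values(gv)
        assert "a" not in loadings.index


class TestSmithHazelIndexModel:
    def test_end_to_end_on_simulated_values(self):
        rng = np.random.default_rng(12)
        traits = ["t1", "t2", "t3"]
        n = 60
        g = rng.normal(size=(n, 3))
        x = g + rng.normal(size=(n, 3)) * 0.7
        pheno = _df(x, traits)
        gen = _df(g, traits)
        res = SmithHazelIndex(pheno, gen).fit()
        assert len(res.index) == n
        tol, sus = res.classify(k=3)
        assert len(tol) == 3 and len(sus) == 3
        assert set(tol).isdisjoint(sus)
        # applying the fitted weights to new lines never refits b
        new = _df(rng.normal(size=(10, 3)), traits)
        new.index = [f"N{i}" for i in range(10)]
        applied = res.apply(new)
        np.testing.assert_allclose(applied, new.to_numpy() @ res.b.to_numpy())
        assert "weights b" in res.summary()


def test_plot_helpers_return_axes():
    import matplotlib
    matplotlib.use("Agg")
    rng = np.random.default_rng(13)
    traits = ["t1", "t2"]
    g = _df(rng.normal(size=(20, 2)), traits)
    x = g + rng.normal(size=(20, 2))
    res = SmithHazelIndex(x, g).fit()
    ax = res.plot_index(k=2)
    assert ax is not None
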