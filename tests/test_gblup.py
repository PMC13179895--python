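import numpy as np
import pandas as pd
import pytest

from magicgs.gblup import (
    GBLUP,
    adjusted_means,
    genetic_cv,
    predict_unphenotyped,
    _REMLCore,
)
from magicgs.genotypes import GRM, filter_maf, vanraden_grm
from magicgs.phenotypes import derive_traits
from magicgs.simulate import SimConfig, TraitSpec, simulate_dataset


def brute_restricted_ll(y, X, Z, G, theta):
    """Independent dense-V restricted log-likelihood (no constants)."""
    sa2, sn2, se2 = theta
    V = sa2 * Z @ G @ Z.T + sn2 * Z @ Z.T + se2 * np.eye(len(y))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * (ldV + ldX + y @ P @ y)


class TestAdjustedMeans:
    def _pheno(self, values):
        rows = []
        for (line, exp), v in values.items():
            rows.append({"line": line, "experiment": exp, "stage": "final", "y": v})
        return pd.DataFrame(rows)

    def test_balanced_no_experiment_effect_equals_raw_means(self):
        vals = {("A", 1): 1.0, ("A", 2): 3.0, ("B", 1): 2.0, ("B", 2): 4.0}
        am = adjusted_means(self._pheno(vals), "y")
        assert am.means["A"] == pytest.approx(2.0)
        assert am.means["B"] == pytest.approx(3.0)

    def test_additive_shift_design(self):
        # 3 lines x 2 experiments, experiment 2 shifted by +1
        mu = {"A": 1.0, "B": 2.0, "C": 4.0}
        vals = {(l, 1): m for l, m in mu.items()}
        vals.update({(l, 2): m + 1.0 for l, m in mu.items()})
        am = adjusted_means(self._pheno(vals), "y")
        # hand OLS oracle: marginal mean = de-shifted line mean + mean shift
        for l, m in mu.items():
            assert am.means[l] == pytest.approx(m + 0.5, abs=1e-10)

    def test_unbalanced_design_recovers_line_effects(self):
        # line C unobserved in experiment 2; oracle via explicit lstsq
        vals = {("A", 1): 1.0, ("A", 2): 2.0, ("B", 1): 2.0, ("B", 2): 3.0,
                ("C", 1): 5.0}
        am = adjusted_means(self._pheno(vals), "y")
        X = np.array([
            # intercept, lineB, lineC, exp2
            [1, 0, 0, 0], [1, 0, 0, 1], [1, 1, 0, 0], [1, 1, 0, 1], [1, 0, 1, 0],
        ], dtype=float)
        yv = np.array([1, 2, 2, 3, 5.0])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        expected_c = beta[0] + beta[2] + 0.5 * beta[3]
        assert am.means["C"] == pytest.approx(expected_c, abs=1e-8)

    def test_single_experiment_equals_raw_means(self):
        vals = {("A", 1): 1.0, ("B", 1): 5.0}
        am = adjusted_means(self._pheno(vals), "y")
        assert am.means["A"] == 1.0 and am.means["B"] == 5.0


@pytest.fixture(scope="module")
def small_model():
    cfg = SimConfig(
        seed=29, n_magic_lines=8, n_phenotyped=8, n_snps=50,
        traits=[TraitSpec("Total DW", h2=0.5, sn2_share=0.2, mean=4.75, sd=0.9)],
        genetic_corr=None,
    )
    sd = simulate_dataset(cfg)
    dt = derive_traits(sd.pheno)
    grm = vanraden_grm(sd.gm)
    model = GBLUP.from_phenotypes(dt, grm, "Total DW")
    core = _REMLCore(model.y, model.X, model.Z, model._components(True))
    return model, core


class TestRemlCore:
    def test_likelihood_identity_matches_dense_formula(self, small_model):
        model, core = small_model
        G = core.A[0]  # effective (regularised) covariance
        for theta in [(1.0, 0.3, 0.5), (0.2, 0.8, 1.5), (2.0, 0.05, 0.4)]:
            dense = brute_restricted_ll(model.y, model.X, model.Z, G, theta)
            assert core.loglik(np.array(theta)) == pytest.approx(dense, abs=1e-8)

    def test_reml_beats_dense_grid(self, small_model):
        model, core = small_model
        theta, ll, converged, _, _ = core.fit()
        assert converged
        G = core.A[0]
        vary = np.var(model.y)
        grid = np.linspace(0.05, 2.0, 12) * vary
        best = -np.inf
        for a in grid:
            for b in grid:
                for c in grid:
                    best = max(
                        best,
                        brute_restricted_ll(model.y, model.X, model.Z, G, (a, b, c)),
                    )
        assert ll >= best - 1e-4

    def test_score_matches_numeric_gradient(self, small_model):
        _, core = small_model
        theta = np.array([0.5, 0.3, 0.8])
        score, _, _, _ = core._iteration_quantities(theta)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            num = (core.loglik(theta + e) - core.loglik(theta - e)) / (2 * eps)
            assert score[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def fitted(sim_module):
    sd, dt, grm = sim_module
    return GBLUP.from_phenotypes(dt, grm, "Total DW").fit()


@pytest.fixture(scope="module")
def sim_module():
    cfg = SimConfig(seed=17, n_magic_lines=70, n_phenotyped=70, n_snps=400)
    sd = simulate_dataset(cfg)
    dt = derive_traits(sd.pheno)
    grm = vanraden_grm(filter_maf(sd.gm, 0.04))
    return sd, dt, grm


class TestGblupFit:
    def test_components_nonnegative_and_converged(self, fitted):
        assert fitted.converged
        assert fitted.sigma_a2 >= 0
        assert fitted.sigma_n2 >= 0
        assert fitted.sigma_e2 > 0

    def test_h2_equals_H2_without_residual_genetic(self, fitted):
        if fitted.sigma_n2 == 0:
            assert fitted.h2 == fitted.H2
        else:  # pragma: no cover - depends on draw
            assert fitted.h2 <= fitted.H2 + 1e-12

    def test_gebv_sum_near_zero(self, fitted):
        scale = np.abs(fitted.gebv).max() or 1.0
        assert abs(fitted.gebv.sum()) / (len(fitted.gebv) * scale) < 0.05

    def test_gebv_tracks_truth(self, sim_module, fitted):
        sd, _, _ = sim_module
        tbv = sd.truth.tbv.loc[fitted.gebv.index, "Total DW"]
        assert np.corrcoef(tbv, fitted.gebv)[0, 1] > 0.4

    def test_heritability_scale_invariance(self, sim_module):
        sd, dt, grm = sim_module
        fit1 = GBLUP.from_phenotypes(dt, grm, "Total DW").fit()
        dt5 = dt.copy()
        dt5["Total DW"] = dt5["Total DW"] * 5.0
        fit5 = GBLUP.from_phenotypes(dt5, grm, "Total DW").fit()
        assert fit5.h2 == pytest.approx(fit1.h2, abs=1e-4)
        assert fit5.H2 == pytest.approx(fit1.H2, abs=1e-4)
        assert fit5.sigma_a2 == pytest.approx(25 * fit1.sigma_a2, rel=1e-3)

    def test_identity_grm_reduces_to_repeatability_model(self, sim_module):
        sd, dt, _ = sim_module
        lines = sorted(dt.loc[dt.role == "magic", "line"].unique())
        ident = GRM(lines, np.eye(len(lines)))
        both = GBLUP.from_phenotypes(dt, ident, "Total DW").fit()
        single = GBLUP.from_phenotypes(
            dt, ident, "Total DW", residual_genetic=False
        ).fit()
        assert both.sigma_g2 == pytest.approx(single.sigma_a2, rel=0.02)
        assert both.sigma_e2 == pytest.approx(single.sigma_e2, rel=0.02)

    def test_null_trait_hits_zero_boundary(self, sim_module):
        sd, dt, grm = sim_module
        rng = np.random.default_rng(0)
        null = dt.copy()
        null["Total DW"] = rng.normal(size=len(null))
        fit = GBLUP.from_phenotypes(null, grm, "Total DW").fit()
        # without genetic signal the additive component stays a small
        # fraction of the residual and GEBVs shrink well below the
        # phenotypic standard deviation
        sdy = null.loc[null.stage == "final", "Total DW"].std()
        assert fit.sigma_a2 < 0.15 * fit.sigma_e2
        assert np.abs(fit.gebv).max() < 0.5 * sdy

    def test_variance_components_sum_to_phenotypic_structure(self, fitted, sim_module):
        # the fitted phenotypic variance sa2*mean(diag G) + sn2 + se2 should be
        # close to the raw plant-level variance of the trait
        sd, dt, grm = sim_module
        y = dt.loc[(dt.stage == "final") & (dt.role == "magic"), "Total DW"]
        total = fitted.sigma_a2 * np.diag(
            grm.subset(list(fitted.gebv.index)).values
        ).mean() + fitted.sigma_n2 + fitted.sigma_e2
        assert total == pytest.approx(np.var(y), rel=0.35)

    def test_summary_mentions_components(self, fitted):
        text = fitted.summary()
        assert "sigma_a2" in text and "H2" in text


class TestHeritabilityEdgeCases:
    def _mk(self, pev_a, pev_g, sa2, sn2):
        from magicgs.gblup import GBLUPResults

        idx = ["A", "B"]
        return GBLUPResults(
            model=None, trait="t", sigma_a2=sa2, sigma_n2=sn2, sigma_e2=1.0,
            gebv=pd.Series(0.0, index=idx),
            residual_genetic_blup=pd.Series(0.0, index=idx),
            pev_additive=pd.Series(pev_a, index=idx),
            pev_total=pd.Series(pev_g, index=idx),
            beta=pd.Series([0.0], index=["intercept"]),
            loglik=0.0, converged=True, n_iter=1,
        )

    def test_zero_pev_gives_unit_heritability(self):
        assert self._mk(0.0, 0.0, 1.0, 0.0).H2 == 1.0

    def test_pev_equal_to_variance_gives_zero(self):
        fit = self._mk(1.0, 1.5, 1.0, 0.5)
        assert fit.H2 == 0.0
        assert fit.h2 == 0.0

    def test_zero_denominator_is_nan(self):
        assert np.isnan(self._mk(0.5, 0.5, 0.0, 0.0).h2)


class TestGeneticCv:
    def test_sd_mode(self, fitted):
        g = genetic_cv(fitted, 10.0)
        assert g == pytest.approx(100 * np.sqrt(fitted.sigma_g2) / 10.0)

    def test_literal_mode(self, fitted):
        assert genetic_cv(fitted, 10.0, mode="literal") == pytest.approx(
            fitted.sigma_g2 / 10.0
        )

    def test_invalid_mean(self, fitted):
        with pytest.raises(ValueError):
            genetic_cv(fitted, 0.0)


@pytest.fixture(scope="module")
def pd_setup():
    # well-conditioned PD relationship matrix so the conditional and
    # joint routes are algebraically identical
    rng = np.random.default_rng(3)
    q = 30
    B = rng.normal(size=(q, 2 * q))
    G = B @ B.T / (2 * q) + 0.3 * np.eye(q)
    ids = [f"L{i:02d}" for i in range(q)]
    grm = GRM(ids, G)
    train = ids[:24]
    L = np.linalg.cholesky(G)
    u = L @ rng.normal(size=q)
    y = pd.Series(u[:24] + rng.normal(size=24) * 0.5, index=train)
    fit = GBLUP.from_means(y, grm).fit()
    return grm, fit, ids


class TestPredictUnphenotyped:
    def test_routes_agree(self, pd_setup):
        grm, fit, ids = pd_setup
        new = ids[24:]
        cond = fit.predict(new, grm, method="conditional")
        joint = fit.predict(new, grm, method="joint")
        np.testing.assert_allclose(cond, joint, atol=1e-8)

    def test_duplicate_line_gets_identical_gebv(self, pd_setup):
        grm, fit, ids = pd_setup
        twin_of = ids[0]
        G2 = np.zeros((len(ids) + 1, len(ids) + 1))
        G2[: len(ids), : len(ids)] = grm.values
        pos = 0
        G2[-1, :-1] = grm.values[pos]
        G2[:-1, -1] = grm.values[:, pos]
        G2[-1, -1] = grm.values[pos, pos]
        grm2 = GRM(ids + ["twin"], G2)
        pred = fit.predict(["twin"], grm2)
        assert pred["twin"] == pytest.approx(fit.gebv[twin_of], abs=1e-8)

    def test_orthogonal_line_predicts_zero(self, pd_setup):
        grm, fit, ids = pd_setup
        G2 = np.zeros((len(ids) + 1, len(ids) + 1))
        G2[: len(ids), : len(ids)] = grm.values
        G2[-1, -1] = 1.0
        grm2 = GRM(ids + ["stranger"], G2)
        assert fit.predict(["stranger"], grm2)["stranger"] == pytest.approx(0.0, abs=1e-10)

    def test_holdout_correlates_with_truth(self, sim_module):
        sd, dt, grm = sim_module
        means = adjusted_means(dt[dt.role == "magic"], "Total DW")
        train = means.means.index[:50]
        hold = means.means.index[50:]
        fit = GBLUP.from_means(means.means[train], grm).fit()
        pred = fit.predict(list(hold), grm)
        tbv = sd.truth.tbv.loc[hold, "Total DW"]
        assert np.corrcoef(tbv, pred)[0, 1] > 0.2
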