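"""GBLUP: genomic prediction by REML-fitted mixed models.

The model for a single trait is

    y = X b + Z u_a + Z u_n + e,
    u_a ~ N(0, sigma_a^2 G),  u_n ~ N(0, sigma_n^2 I),  e ~ N(0, sigma_e^2 I)

where ``y`` holds plant-level observations, ``X`` carries fixed experiment
effects, ``Z`` maps plants to lines, and ``G`` is the VanRaden genomic
relationship matrix. ``u_a`` are the genomic estimated breeding values
(GEBVs); ``u_n`` absorbs line-level genetic variation not captured by the
markers, so the total genetic effect of a line is ``u_a + u_n``.

Variance components are estimated by average-information (AI) REML with
EM-flavoured fallback steps, computed through Henderson's mixed-model
equations so the per-iteration cost scales with the number of lines rather
than the number of plants. Components that converge onto the zero boundary
are dropped from the active set and the remaining components refitted,
which reproduces the common outcome sigma_n^2 = 0.

Heritabilities follow the Cullis prediction-error-variance form:

    H^2 = 1 - PEV_g / sigma_g^2      (total genetic, sigma_g^2 = sigma_a^2 + sigma_n^2)
    h^2 = 1 - PEV_a / sigma_a^2      (additive)

with PEV the mean diagonal of the BLUP prediction-error-variance matrix of
the corresponding genetic estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM

__all__ = [
    "AdjustedMeans",
    "adjusted_means",
    "GBLUP",
    "GBLUPResults",
    "genetic_cv",
    "predict_unphenotyped",
]


# ----------------------------------------------------------------------
# adjusted means (fixed-effects linear model)
# ----------------------------------------------------------------------

@dataclass
class AdjustedMeans:
    """Per-line adjusted means for one trait from a line+experiment OLS fit."""

    trait: str
    means: pd.Series  # indexed by line
    n_experiments: int
    n_plants: int

    @property
    def line_ids(self) -> list[str]:
        return list(self.means.index)


def adjusted_means(pheno: pd.DataFrame, trait: str, stage: str = "final") -> AdjustedMeans:
    """Adjusted line means: OLS on fixed line and experiment effects.

    Fits ``trait ~ line + experiment`` on the given stage's records and
    returns, for each line, the estimable marginal mean: the line's fitted
    value averaged over all experiments (unweighted). With a balanced
    design or a single experiment this equals the raw line mean.
    """
    import statsmodels.formula.api as smf

    df = pheno[pheno["stage"] == stage] if "stage" in pheno.columns else pheno
    df = df[["line", "experiment", trait]].dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    df["line"] = df["line"].astype(str)
    df = df.rename(columns={trait: "_y"})
    experiments = sorted(df["experiment"].unique())
    lines = sorted(df["line"].unique())
    if len(experiments) == 1 or len(lines) == 1:
        means = df.groupby("line")["_y"].mean().reindex(lines)
        return AdjustedMeans(trait, means.rename(trait), len(experiments), len(df))
    fit = smf.ols("_y ~ C(line) + C(experiment)", data=df).fit()
    grid = pd.DataFrame(
        [(l, e) for l in lines for e in experiments], columns=["line", "experiment"]
    )
    pred = fit.predict(grid)
    means = (
        pd.Series(np.asarray(pred), index=pd.MultiIndex.from_frame(grid))
        .groupby(level=0)
        .mean()
        .reindex(lines)
    )
    return AdjustedMeans(trait, means.rename(trait), len(experiments), len(df))


# ----------------------------------------------------------------------
# REML core over Henderson's mixed-model equations
# ----------------------------------------------------------------------

class _REMLCore:
    """REML for y = Xb + sum_i Z u_i + e with u_i ~ N(0, s_i^2 A_i).

    All random components share the incidence matrix Z (plants -> lines).
    ``components`` maps names to q x q covariance matrices (None = identity).
    """

    def __init__(self, y, X, Z, components: dict):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.Z = np.asarray(Z, float)
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.q = self.Z.shape[1]
        self.names = list(components)
        self.k = len(self.names)
        self.A = []
        self.Ainv = []
        self.logdetA = []
        self.cov_jitter = {}
        for name in self.names:
            A = components[name]
            if A is None:
                self.A.append(None)
                self.Ainv.append(np.eye(self.q))
                self.logdetA.append(0.0)
            else:
                # a genomic relationship matrix is singular by construction
                # (column centering); lift its spectrum so the MME stay
                # well conditioned, and record the applied jitter
                A = np.asarray(A, float)
                w, U = np.linalg.eigh(A)
                target = 1e-6 * max(w.max(), 1.0)
                jitter = max(0.0, target - w.min())
                w = w + jitter
                self.cov_jitter[name] = jitter
                self.A.append(A + jitter * np.eye(self.q))
                self.Ainv.append((U / w) @ U.T)
                self.logdetA.append(float(np.log(w).sum()))
        # design cross-products
        W = np.hstack([self.X] + [self.Z] * self.k)
        self.W = W
        self.WtW = W.T @ W
        self.Wty = W.T @ self.y
        self.yty = float(self.y @ self.y)
        self.ZtZ = self.Z.T @ self.Z
        self.WtZ = W.T @ self.Z
        self.m = self.p + self.k * self.q

    # -- likelihood ----------------------------------------------------
    def _M(self, theta):
        """MME coefficient matrix scaled by sigma_e^2: W'W + blockdiag(0, se2/si2 * Ainv_i)."""
        se2 = theta[-1]
        M = self.WtW.copy()
        for i in range(self.k):
            sl = slice(self.p + i * self.q, self.p + (i + 1) * self.q)
            M[sl, sl] += (se2 / theta[i]) * self.Ainv[i]
        return M

    def loglik(self, theta) -> float:
        """Restricted log-likelihood (no additive constant)."""
        theta = np.asarray(theta, float)
        if np.any(theta <= 0):
            return -np.inf
        se2 = theta[-1]
        M = self._M(theta)
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetM = 2.0 * np.log(np.diag(L)).sum()
        bhat = self._chol_solve(L, self.Wty)
        yPy = (self.yty - bhat @ self.Wty) / se2
        neg2 = (
            self.n * np.log(se2)
            + sum(self.q * np.log(theta[i]) + self.logdetA[i] for i in range(self.k))
            + logdetM
            - self.m * np.log(se2)
            + yPy
        )
        return -0.5 * neg2

    @staticmethod
    def _chol_solve(L, b):
        from scipy.linalg import solve_triangular

        z = solve_triangular(L, b, lower=True)
        return solve_triangular(L.T, z, lower=False)

    # -- score / AI pieces ---------------------------------------------
    def _P_apply(self, Minv, v):
        """Apply the REML projection matrix P to vector(s) v via the MME."""
        se2 = self._se2
        return (v - self.W @ (Minv @ (self.W.T @ v))) / se2

    def _iteration_quantities(self, theta):
        se2 = theta[-1]
        self._se2 = se2
        M = self._M(theta)
        L = np.linalg.cholesky(M)
        Minv = self._chol_solve(L, np.eye(self.m))
        bhat = Minv @ self.Wty
        e = self.y - self.W @ bhat
        Py = e / se2
        # Z'PZ common to all genetic components
        T = Minv @ self.WtZ
        ZtPZ = (self.ZtZ - self.WtZ.T @ T) / se2
        traces = []
        quads = []
        fvecs = []
        for i in range(self.k):
            Ai = self.A[i]
            if Ai is None:
                traces.append(np.trace(ZtPZ))
                ZPy = self.Z.T @ Py
                fvecs.append(self.Z @ ZPy)
            else:
                traces.append(float(np.sum(Ai * ZtPZ)))
                ZPy = self.Z.T @ Py
                fvecs.append(self.Z @ (Ai @ ZPy))
            quads.append(float(Py @ fvecs[-1]))
        # residual component V_e = I
        trP = (self.n - float(np.sum(Minv * self.WtW))) / se2
        traces.append(trP)
        fvecs.append(Py.copy())
        quads.append(float(Py @ Py))
        score = np.array([-0.5 * (traces[i] - quads[i]) for i in range(self.k + 1)])
        # average information matrix
        Pf = [self._P_apply(Minv, f) for f in fvecs]
        kk = self.k + 1
        AI = np.empty((kk, kk))
        for i in range(kk):
            for j in range(i, kk):
                AI[i, j] = AI[j, i] = 0.5 * float(fvecs[i] @ Pf[j])
        return score, AI, Minv, bhat

    # -- driver ---------------------------------------------------------
    def fit(self, maxiter: int = 200, tol_theta: float = 1e-8, tol_ll: float = 1e-9):
        vary = float(np.var(self.y)) or 1.0
        kk = self.k + 1
        theta = np.full(kk, vary / kk)
        ll = self.loglik(theta)
        # the residual floor is larger: a vanishing sigma_e^2 makes the MME
        # numerically singular, so it is bounded away from zero
        floor = np.full(kk, 1e-10 * vary)
        floor[-1] = 1e-6 * vary
        history = [(theta.copy(), ll)]
        converged = False
        for it in range(maxiter):
            score, AI, _, _ = self._iteration_quantities(theta)
            step = None
            try:
                # minimum-norm solve handles a singular AI matrix (exactly
                # collinear components, e.g. an identity relationship matrix)
                step, *_ = np.linalg.lstsq(AI, score, rcond=1e-8)
                if not np.all(np.isfinite(step)):
                    step = None
            except np.linalg.LinAlgError:
                pass
            accepted = False
            accept_tol = 1e-10 * (1.0 + abs(ll))
            if step is not None:
                frac = 1.0
                for _ in range(30):
                    # clip componentwise so one bounded component does not
                    # stall progress of the others
                    cand = np.maximum(theta + frac * step, floor)
                    cand_ll = self.loglik(cand)
                    if cand_ll >= ll - accept_tol and np.any(cand != theta):
                        theta_new, ll_new = cand, cand_ll
                        accepted = True
                        break
                    frac *= 0.5
            if not accepted:
                # EM-flavoured scaled-gradient step (always ascent direction)
                qs = np.array([self.q] * self.k + [self.n], float)
                em = theta + (2.0 * theta**2 / qs) * score
                em = np.maximum(em, floor)
                frac = 1.0
                for _ in range(30):
                    cand = theta + frac * (em - theta)
                    cand_ll = self.loglik(cand)
                    if cand_ll >= ll - accept_tol:
                        theta_new, ll_new = cand, cand_ll
                        accepted = True
                        break
                    frac *= 0.5
            if not accepted:
                # neither the AI nor the EM direction improves the
                # likelihood beyond numerical noise: boundary optimum
                converged = True
                break
            dtheta = np.max(np.abs(theta_new - theta) / (theta + 1.0))
            dll = abs(ll_new - ll)
            theta, ll = theta_new, ll_new
            history.append((theta.copy(), ll))
            if dtheta < tol_theta or dll < max(tol_ll, 2.0 * accept_tol):
                # a noise-tiny AI step can mimic convergence while the
                # gradient is still large: probe an EM step before stopping
                probe_score, _, _, _ = self._iteration_quantities(theta)
                qs = np.array([self.q] * self.k + [self.n], float)
                probe = np.maximum(theta + (2.0 * theta**2 / qs) * probe_score, floor)
                probe_ll = self.loglik(probe)
                if probe_ll > ll + 10.0 * accept_tol:
                    theta, ll = probe, probe_ll
                    history.append((theta.copy(), ll))
                    continue
                converged = True
                break
        return theta, ll, converged, len(history) - 1, history

    def solve_blup(self, theta):
        """BLUE/BLUP solutions and prediction-error variances at ``theta``."""
        se2 = theta[-1]
        M = self._M(theta)
        L = np.linalg.cholesky(M)
        Minv = self._chol_solve(L, np.eye(self.m))
        sol = Minv @ self.Wty
        beta = sol[: self.p]
        us = [
            sol[self.p + i * self.q : self.p + (i + 1) * self.q] for i in range(self.k)
        ]
        Cinv = se2 * Minv  # inverse MME coefficient matrix
        blocks = {}
        for i in range(self.k):
            for j in range(self.k):
                sli = slice(self.p + i * self.q, self.p + (i + 1) * self.q)
                slj = slice(self.p + j * self.q, self.p + (j + 1) * self.q)
                blocks[(i, j)] = Cinv[sli, slj]
        return beta, us, blocks


# ----------------------------------------------------------------------
# public model / results objects
# ----------------------------------------------------------------------

class GBLUP:
    """Single-trait GBLUP model (statsmodels-style: construct, then fit).

    Parameters
    ----------
    y : array-like
        Phenotypic observations (plants, or line means in means mode).
    lines : sequence of str
        Line label per observation; must be covered by ``grm``.
    grm : GRM
        Genomic relationship matrix (may cover extra, unphenotyped lines).
    experiment : sequence, optional
        Experiment label per observation; fitted as fixed effects
        (reference coding, first experiment as reference). Omitted in
        means mode.
    residual_genetic : bool
        Include the iid residual genetic component ``u_n``. Forced off in
        means mode, where it is confounded with the residual.
    """

    def __init__(self, y, lines, grm: GRM, experiment=None, residual_genetic: bool = True,
                 trait: str = "trait"):
        y = np.asarray(y, float)
        lines = [str(l) for l in lines]
        ok = ~np.isnan(y)
        y, lines = y[ok], [l for l, o in zip(lines, ok) if o]
        if experiment is not None:
            experiment = [e for e, o in zip(experiment, ok) if o]
        self.trait = trait
        self.line_levels = sorted(set(lines))
        if len(self.line_levels) < 2:
            raise ValueError("need at least two phenotyped lines")
        missing = set(self.line_levels) - set(grm.line_ids)
        if missing:
            raise KeyError(f"lines missing from GRM: {sorted(missing)[:5]}")
        self.grm_train = grm.subset(self.line_levels)
        self.grm_full = grm
        q = len(self.line_levels)
        idx = {l: i for i, l in enumerate(self.line_levels)}
        Z = np.zeros((len(y), q))
        Z[np.arange(len(y)), [idx[l] for l in lines]] = 1.0
        self.means_mode = experiment is None and np.allclose(Z.sum(axis=0), 1.0)
        if experiment is not None:
            levels = sorted(set(experiment))
            X = np.ones((len(y), len(levels)))
            for j, lev in enumerate(levels[1:], start=1):
                X[:, j] = np.array([1.0 if e == lev else 0.0 for e in experiment])
            self.experiment_levels = levels
        else:
            X = np.ones((len(y), 1))
            self.experiment_levels = []
        self.residual_genetic = residual_genetic and not self.means_mode
        self.y, self.X, self.Z = y, X, Z

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_phenotypes(cls, pheno: pd.DataFrame, grm: GRM, trait: str,
                        stage: str = "final", role: str | None = "magic",
                        residual_genetic: bool = True) -> "GBLUP":
        """Plant-level model with fixed experiment effects from a long table."""
        df = pheno
        if "stage" in df.columns:
            df = df[df["stage"] == stage]
        if role is not None and "role" in df.columns:
            df = df[df["role"] == role]
        df = df[["line", "experiment", trait]].dropna(subset=[trait])
        df = df[df["line"].astype(str).isin(set(grm.line_ids))]
        return cls(df[trait], df["line"], grm, experiment=list(df["experiment"]),
                   residual_genetic=residual_genetic, trait=trait)

    @classmethod
    def from_means(cls, means: AdjustedMeans | pd.Series, grm: GRM,
                   trait: str | None = None) -> "GBLUP":
        """Means-mode model: one record per line, intercept only, no u_n."""
        if isinstance(means, AdjustedMeans):
            ser = means.means
            trait = trait or means.trait
        else:
            ser = means
            trait = trait or str(ser.name or "trait")
        ser = ser.dropna()
        ser = ser[ser.index.astype(str).isin(set(grm.line_ids))]
        return cls(ser.to_numpy(), list(ser.index.astype(str)), grm,
                   residual_genetic=False, trait=trait)

    # -- fitting ----------------------------------------------------------
    def _components(self, include_rg: bool) -> dict:
        comps: dict = {"additive": self.grm_train.values}
        if include_rg:
            comps["residual_genetic"] = None
        return comps

    def fit(self, maxiter: int = 200, tol_theta: float = 1e-8,
            tol_ll: float = 1e-9) -> "GBLUPResults":
        """Estimate variance components by AI-REML and return results.

        Components converging onto the zero boundary (below 1e-6 of the
        phenotypic variance, with no likelihood gain from re-entering) are
        fixed at exactly zero by dropping them and refitting the rest.
        """
        include_rg = self.residual_genetic
        vary = float(np.var(self.y)) or 1.0
        boundary_tol = 1e-6 * vary
        dropped: list[str] = []
        while True:
            names = ["additive"] + (["residual_genetic"] if include_rg else [])
            core = _REMLCore(self.y, self.X, self.Z, self._components(include_rg))
            theta, ll, converged, n_iter, history = core.fit(
                maxiter=maxiter, tol_theta=tol_theta, tol_ll=tol_ll
            )
            at_boundary = [
                names[i] for i in range(len(names)) if theta[i] < boundary_tol
            ]
            if "residual_genetic" in at_boundary and include_rg:
                include_rg = False
                dropped.append("residual_genetic")
                continue
            break
        if not converged:
            raise RuntimeError(
                f"REML did not converge in {maxiter} iterations for trait "
                f"{self.trait!r}; trace: {[(t.round(6).tolist(), l) for t, l in history[-3:]]}"
            )
        beta, us, blocks = core.solve_blup(theta)
        sa2 = float(theta[0])
        sn2 = float(theta[1]) if include_rg else 0.0
        se2 = float(theta[-1])
        if sa2 < boundary_tol:
            sa2 = float(theta[0])  # kept as estimated; may be ~0 under a null trait
        gebv = pd.Series(us[0], index=self.line_levels, name="gebv")
        if include_rg:
            un = pd.Series(us[1], index=self.line_levels, name="residual_genetic")
        else:
            un = pd.Series(0.0, index=self.line_levels, name="residual_genetic")
        pev_a = np.diag(blocks[(0, 0)]).copy()
        if include_rg:
            pev_g = np.diag(
                blocks[(0, 0)] + blocks[(1, 1)] + blocks[(0, 1)] + blocks[(1, 0)]
            ).copy()
        else:
            pev_g = pev_a
        return GBLUPResults(
            model=self,
            trait=self.trait,
            sigma_a2=sa2,
            sigma_n2=sn2,
            sigma_e2=se2,
            gebv=gebv,
            residual_genetic_blup=un,
            pev_additive=pd.Series(pev_a, index=self.line_levels),
            pev_total=pd.Series(pev_g, index=self.line_levels),
            beta=pd.Series(
                beta,
                index=(["intercept"] + [f"experiment[{e}]" for e in self.experiment_levels[1:]])
                if self.experiment_levels else ["intercept"],
            ),
            loglik=float(ll),
            converged=converged,
            n_iter=n_iter,
            dropped_components=dropped,
        )


@dataclass
class GBLUPResults:
    """Fitted GBLUP: variance components, BLUPs, PEV, heritabilities."""

    model: GBLUP = field(repr=False)
    trait: str
    sigma_a2: float
    sigma_n2: float
    sigma_e2: float
    gebv: pd.Series = field(repr=False)
    residual_genetic_blup: pd.Series = field(repr=False)
    pev_additive: pd.Series = field(repr=False)
    pev_total: pd.Series = field(repr=False)
    beta: pd.Series = field(repr=False)
    loglik: float
    converged: bool
    n_iter: int
    dropped_components: list = field(default_factory=list)
    clamped: dict = field(default_factory=dict)

    # -- heritabilities --------------------------------------------------
    @property
    def sigma_g2(self) -> float:
        """Total genetic variance sigma_a^2 + sigma_n^2."""
        return self.sigma_a2 + self.sigma_n2

    @property
    def total_genetic(self) -> pd.Series:
        """Total genetic value per line: u_a + u_n."""
        return (self.gebv + self.residual_genetic_blup).rename("total_genetic")

    def _cullis(self, pev_mean: float, denom: float, label: str) -> float:
        if denom <= 0:
            return float("nan")
        val = 1.0 - pev_mean / denom
        if not 0.0 <= val <= 1.0:
            self.clamped[label] = val
            val = min(max(val, 0.0), 1.0)
        return val

    @property
    def H2(self) -> float:
        """Broad-sense heritability 1 - mean(PEV_g) / sigma_g^2 (Cullis form)."""
        return self._cullis(float(self.pev_total.mean()), self.sigma_g2, "H2")

    @property
    def h2(self) -> float:
        """Narrow-sense heritability 1 - mean(PEV_a) / sigma_a^2 (Cullis form)."""
        return self._cullis(float(self.pev_additive.mean()), self.sigma_a2, "h2")

    def genetic_cv(self, trait_mean: float, mode: str = "sd") -> float:
        return genetic_cv(self, trait_mean, mode=mode)

    # -- prediction -------------------------------------------------------
    def predict(self, new_line_ids, grm_all: GRM | None = None,
                method: str = "conditional") -> pd.Series:
        return predict_unphenotyped(self, grm_all or self.model.grm_full,
                                    new_line_ids, method=method)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"GBLUP results: {self.trait}",
            "=" * 40,
            f"observations: {len(self.model.y)}   lines: {len(self.gebv)}",
            f"REML log-likelihood: {self.loglik:.4f}  ({self.n_iter} iterations)",
            "",
            f"{'component':<22}{'estimate':>12}",
            f"{'sigma_a2 (additive)':<22}{self.sigma_a2:>12.6g}",
            f"{'sigma_n2 (resid gen.)':<22}{self.sigma_n2:>12.6g}",
            f"{'sigma_e2 (residual)':<22}{self.sigma_e2:>12.6g}",
            "",
            f"H2 (Cullis, total genetic): {self.H2:.3f}",
            f"h2 (Cullis, additive):      {self.h2:.3f}",
            f"mean PEV (additive):        {float(self.pev_additive.mean()):.6g}",
        ]
        if self.dropped_components:
            lines.append(f"components at zero boundary: {', '.join(self.dropped_components)}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-line table of GEBV, residual genetic BLUP and total value."""
        return pd.DataFrame(
            {
                "gebv": self.gebv,
                "residual_genetic": self.residual_genetic_blup,
                "total_genetic": self.total_genetic,
                "pev_additive": self.pev_additive,
            }
        )

    def plot_variance_components(self, ax=None):
        """Stacked bar of the additive, residual genetic and residual
        variance components."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(3, 4))
        bottom = 0.0
        for label, val, color in [
            ("sigma_a2", self.sigma_a2, "forestgreen"),
            ("sigma_n2", self.sigma_n2, "goldenrod"),
            ("sigma_e2", self.sigma_e2, "lightgray"),
        ]:
            ax.bar([self.trait], [val], bottom=[bottom], label=label, color=color)
            bottom += val
        ax.set_ylabel("variance")
        ax.legend()
        return ax


def genetic_cv(fit: GBLUPResults, trait_mean: float, mode: str = "sd") -> float:
    """Genetic coefficient of variation for a trait.

    Default ``mode='sd'`` returns the percentage 100*sqrt(sigma_g^2)/mean,
    the dimensionless dispersion measure comparable across traits. The
    ``'literal'`` mode returns sigma_g^2/mean (a variance-over-mean ratio).
    """
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive for gCV")
    sg2 = fit.sigma_g2
    if mode == "sd":
        return 100.0 * float(np.sqrt(sg2)) / trait_mean
    if mode == "literal":
        return float(sg2) / trait_mean
    raise ValueError("mode must be 'sd' or 'literal'")


def predict_unphenotyped(fit: GBLUPResults, grm_all: GRM, new_line_ids,
                         method: str = "conditional") -> pd.Series:
    """Additive genetic values for lines without phenotypes.

    ``conditional`` uses u_new = G_{new,train} G_{train,train}^{-1} u_train;
    ``joint`` re-solves the mixed-model equations over training plus new
    lines at the fitted variance components. The two agree to numerical
    precision.
    """
    new_line_ids = [str(l) for l in new_line_ids]
    train = list(fit.gebv.index)
    missing = set(new_line_ids) | set(train)
    missing -= set(grm_all.line_ids)
    if missing:
        raise KeyError(f"lines missing from GRM: {sorted(missing)[:5]}")
    if method == "conditional":
        Gtt = grm_all.block(train, train)
        Gnt = grm_all.block(new_line_ids, train)
        # minimum-norm solve: exact for BLUPs, which lie in range(G_tt)
        # even when the training block is singular (centered GRM)
        sol, *_ = np.linalg.lstsq(Gtt, fit.gebv.to_numpy(), rcond=None)
        return pd.Series(Gnt @ sol, index=new_line_ids, name="gebv")
    if method == "joint":
        model = fit.model
        all_ids = train + [l for l in new_line_ids if l not in set(train)]
        G = grm_all.block(all_ids, all_ids)
        qa = len(all_ids)
        idx = {l: i for i, l in enumerate(all_ids)}
        Zfull = np.zeros((model.Z.shape[0], qa))
        for i, l in enumerate(model.line_levels):
            Zfull[:, idx[l]] = model.Z[:, i]
        comps: dict = {"additive": G}
        theta = [fit.sigma_a2]
        if fit.sigma_n2 > 0:
            comps["residual_genetic"] = None
            theta.append(fit.sigma_n2)
        theta.append(fit.sigma_e2)
        core = _REMLCore(model.y, model.X, Zfull, comps)
        _, us, _ = core.solve_blup(np.asarray(theta))
        ua = pd.Series(us[0], index=all_ids)
        return ua.reindex(new_line_ids).rename("gebv")
    raise ValueError("method must be 'conditional' or 'joint'")
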