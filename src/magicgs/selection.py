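"""Smith-Hazel linear selection index and multivariate genetic summaries.

The index over t traits is I = b'x with weights b = P^{-1} G a, where P is
the phenotypic covariance matrix between traits (here computed from
adjusted line means), G the genetic covariance matrix (from additive
genetic values), and a the economic weights (all ones by default). Lines
with the highest index values are classified drought tolerant and the
lowest susceptible.

Also provided: the genetic correlation matrix between traits with
significance masking, and a PCA of standardised genetic values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "trait_cov_matrices",
    "smith_hazel_weights",
    "index_values",
    "classify_lines",
    "genetic_correlation_matrix",
    "pca_of_genetic_values",
    "SmithHazelIndex",
    "SmithHazelResults",
]


def trait_cov_matrices(pheno_values: pd.DataFrame,
                       genetic_values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample covariance matrices over lines: P (phenotypic), Gc (genetic).

    Both inputs are lines x traits with identical indices and columns.
    Rank deficiency of P is detected and reported as a warning; the solve
    in :func:`smith_hazel_weights` will then need a ridge.
    """
    if list(pheno_values.columns) != list(genetic_values.columns):
        raise ValueError("trait columns of the two tables must match")
    if not pheno_values.index.equals(genetic_values.index):
        raise ValueError("line sets of phenotypic and genetic tables must match")
    t = pheno_values.shape[1]
    if len(pheno_values) < t + 1:
        raise ValueError("need at least t+1 lines for a t-trait covariance matrix")
    P = pheno_values.cov()
    Gc = genetic_values.cov()
    if np.linalg.matrix_rank(P.to_numpy(), tol=1e-10 * np.trace(P)) < t:
        warnings.warn("phenotypic covariance matrix P is rank deficient", stacklevel=2)
    return P, Gc


def smith_hazel_weights(P: pd.DataFrame, Gc: pd.DataFrame, a=None,
                        ridge: float | None = None) -> pd.Series:
    """Index weights b = P^{-1} G a.

    ``a`` defaults to ones. For near-singular P pass ``ridge`` (or use the
    conventional 1e-6 * mean diagonal); the applied ridge is attached to
    the returned Series attrs together with P's condition number.
    """
    traits = list(P.columns)
    Pm = np.asarray(P, float)
    Gm = np.asarray(Gc, float)
    if a is None:
        a = np.ones(len(traits))
    a = np.asarray(a, float)
    cond = float(np.linalg.cond(Pm))
    applied = 0.0
    if ridge is not None:
        applied = ridge * float(np.mean(np.diag(Pm)))
        Pm = Pm + applied * np.eye(len(traits))
    elif cond > 1e12:
        raise np.linalg.LinAlgError(
            f"P is singular (condition number {cond:.3g}); pass a ridge"
        )
    b = np.linalg.solve(Pm, Gm @ a)
    resid = float(np.linalg.norm(Pm @ b - Gm @ a))
    if resid > 1e-10 * (1.0 + float(np.linalg.norm(Gm @ a))):
        raise np.linalg.LinAlgError("P b = G a solve residual too large")
    out = pd.Series(b, index=traits, name="b")
    out.attrs["condition_number"] = cond
    out.attrs["ridge"] = applied
    return out


def index_values(b: pd.Series, x: pd.DataFrame) -> pd.Series:
    """Per-line index I = sum_t b_t x_t; lines with missing GEBVs are dropped."""
    x = x[list(b.index)]
    complete = x.dropna()
    if len(complete) < len(x):
        warnings.warn(
            f"{len(x) - len(complete)} lines dropped from index (missing GEBVs)",
            stacklevel=2,
        )
    return (complete @ b.to_numpy()).rename("index")


def classify_lines(index: pd.Series, k: int = 3) -> tuple[list[str], list[str]]:
    """Top-k (tolerant) and bottom-k (susceptible) lines by index value.

    Ties are broken by lexicographic line identifier, so the classification
    is deterministic.
    """
    if len(index) < 2 * k:
        raise ValueError("need at least 2k lines to classify")
    df = index.rename("index").rename_axis("line").reset_index()
    df["line"] = df["line"].astype(str)
    tol = df.sort_values(["index", "line"], ascending=[False, True])["line"].head(k)
    sus = df.sort_values(["index", "line"], ascending=[True, True])["line"].head(k)
    return list(tol), list(sus)


def genetic_correlation_matrix(genetic_values: pd.DataFrame, p_mask: float = 0.05):
    """Pearson correlations between traits' genetic values with p-values.

    Returns ``(corr, pvals, masked)``; ``masked`` has correlations with
    p >= ``p_mask`` set to NaN (display rule). Constant traits give NaN.
    """
    if len(genetic_values) < 4:
        raise ValueError("need at least 4 lines for genetic correlations")
    traits = list(genetic_values.columns)
    t = len(traits)
    corr = pd.DataFrame(np.eye(t), index=traits, columns=traits)
    pvals = pd.DataFrame(np.zeros((t, t)), index=traits, columns=traits)
    for i in range(t):
        for j in range(i + 1, t):
            a = genetic_values.iloc[:, i]
            bcol = genetic_values.iloc[:, j]
            if a.std() == 0 or bcol.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(a, bcol)
            corr.iloc[i, j] = corr.iloc[j, i] = r
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    masked = corr.where((pvals < p_mask) | np.eye(t, dtype=bool))
    return corr, pvals, masked


def pca_of_genetic_values(genetic_values: pd.DataFrame):
    """PCA of standardised genetic values (eigen-decomposition of the
    trait correlation matrix).

    Zero-variance traits are dropped with a warning. Sign convention: each
    component's largest-magnitude loading is positive. Returns
    ``(scores, loadings, varexp)``.
    """
    gv = genetic_values.copy()
    sd = gv.std(ddof=1)
    drop = sd[sd == 0].index
    if len(drop):
        warnings.warn(f"dropping zero-variance traits from PCA: {list(drop)}",
                      stacklevel=2)
        gv = gv.drop(columns=drop)
    if gv.shape[1] < 2 or len(gv) < 3:
        raise ValueError("PCA needs at least 2 non-constant traits and 3 lines")
    Zs = (gv - gv.mean()) / gv.std(ddof=1)
    R = np.corrcoef(Zs.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    comp_names = [f"PC{i+1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=gv.columns, columns=comp_names)
    scores = pd.DataFrame(Zs.to_numpy() @ evecs, index=gv.index, columns=comp_names)
    varexp = evals / evals.sum()
    return scores, loadings, varexp


# ----------------------------------------------------------------------
# model-style wrapper
# ----------------------------------------------------------------------

class SmithHazelIndex:
    """Smith-Hazel index model over a set of traits.

    Built from per-line phenotypic values (adjusted means) and additive
    genetic values (GEBVs) for the same lines; ``fit`` solves for the
    weights and evaluates the index.
    """

    def __init__(self, pheno_values: pd.DataFrame, genetic_values: pd.DataFrame,
                 economic_weights=None, ridge: float | None = None):
        self.pheno_values = pheno_values
        self.genetic_values = genetic_values
        self.traits = list(pheno_values.columns)
        self.a = (np.ones(len(self.traits)) if economic_weights is None
                  else np.asarray(economic_weights, float))
        self.ridge = ridge

    def fit(self) -> "SmithHazelResults":
        P, Gc = trait_cov_matrices(self.pheno_values, self.genetic_values)
        b = smith_hazel_weights(P, Gc, self.a, ridge=self.ridge)
        idx = index_values(b, self.genetic_values)
        return SmithHazelResults(model=self, P=P, Gc=Gc, b=b, index=idx)


@dataclass
class SmithHazelResults:
    """Fitted index: covariance matrices, weights, and per-line values."""

    model: SmithHazelIndex = field(repr=False)
    P: pd.DataFrame = field(repr=False)
    Gc: pd.DataFrame = field(repr=False)
    b: pd.Series
    index: pd.Series = field(repr=False)

    def classify(self, k: int = 3) -> tuple[list[str], list[str]]:
        return classify_lines(self.index, k=k)

    def apply(self, genetic_values: pd.DataFrame) -> pd.Series:
        """Evaluate the fitted weights on new lines' genetic values.

        Used for index-based ranking of unphenotyped lines; the weights are
        never re-estimated from predictions.
        """
        return index_values(self.b, genetic_values)

    def plot_index(self, k: int = 3, ax=None):
        """Sorted per-line index values with tolerant/susceptible ends marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        srt = self.index.sort_values(ascending=False)
        tol, sus = self.classify(k=k)
        colors = ["forestgreen" if l in tol else "firebrick" if l in sus
                  else "lightgray" for l in srt.index]
        ax.bar(range(len(srt)), srt.to_numpy(), color=colors, width=1.0)
        ax.set_ylabel("index value")
        ax.set_xlabel("lines (sorted)")
        return ax

    def summary(self) -> str:
        lines = [
            "Smith-Hazel selection index",
            "=" * 40,
            f"traits: {', '.join(self.b.index)}",
            f"economic weights a: {np.asarray(self.model.a).tolist()}",
            f"P condition number: {self.b.attrs.get('condition_number', float('nan')):.3g}",
            "",
            "weights b:",
        ]
        lines += [f"  {t:<20}{w:>10.4f}" for t, w in self.b.items()]
        tol, sus = self.classify()
        lines += ["", f"most tolerant: {', '.join(tol)}",
                  f"most susceptible: {', '.join(sus)}"]
        return "\n".join(lines)
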