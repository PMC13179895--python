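"""Genome-wide association scan with population-structure covariates.

Per-SNP general linear model on adjusted line means: the trait is regressed
on an intercept, the leading principal components of the dosage matrix
(population structure), and the SNP dosage; a two-sided t-test on the
dosage coefficient gives the p-value. Significance uses the Bonferroni
threshold -log10(alpha / n_snps). Associated regions around a significant
peak are delimited by linkage disequilibrium (squared dosage correlation
with the peak) plus a -log10(p) support rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, genotype_pca
from .gblup import AdjustedMeans

__all__ = [
    "GwasScan",
    "GenomicRegion",
    "run_gwas",
    "bonferroni_threshold",
    "ld_r2",
    "define_region",
]


@dataclass
class GwasScan:
    """Per-SNP association results plus scan metadata.

    ``table`` columns: marker, chrom, pos, maf, beta, se, t, p, neglog10p,
    r2_snp (partial R^2 of the SNP given covariates).
    """

    table: pd.DataFrame
    trait: str
    n_pcs: int
    n_snps: int
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        """Bonferroni -log10(p) significance threshold for this scan."""
        return bonferroni_threshold(self.n_snps, self.alpha)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["neglog10p"] >= self.threshold]

    def peak(self) -> pd.Series:
        """Row of the most significant SNP."""
        return self.table.loc[self.table["neglog10p"].idxmax()]

    def manhattan_data(self) -> pd.DataFrame:
        """Tidy table (chrom, pos, neglog10p) for Manhattan plotting."""
        return self.table[["marker", "chrom", "pos", "neglog10p"]].copy()

    def qq_data(self) -> pd.DataFrame:
        """Observed vs expected -log10(p) quantiles for a QQ plot."""
        p = np.sort(self.table["p"].dropna().to_numpy())
        exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
        return pd.DataFrame({"expected": exp, "observed": -np.log10(p)})

    def plot_manhattan(self, ax=None):
        """Manhattan plot with the Bonferroni threshold line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(self.table.groupby("chrom", sort=False)):
            x = grp["pos"] + offset
            ax.scatter(x, grp["neglog10p"], s=6,
                       color="steelblue" if i % 2 == 0 else "darkorange")
            ticks.append(x.mean())
            labels.append(str(chrom))
            offset += grp["pos"].max()
        ax.axhline(self.threshold, color="red", linestyle="--", linewidth=1)
        ax.set_xticks(ticks, labels)
        ax.set_ylabel(r"$-\log_{10}(p)$")
        ax.set_title(f"GWAS: {self.trait}")
        return ax


@dataclass
class GenomicRegion:
    """LD-delimited associated region around a significant peak SNP."""

    chrom: str
    start: int
    end: int
    peak_marker: str
    peak_pos: int
    peak_neglog10p: float
    peak_r2: float
    peak_maf: float
    window_bp: int
    r2_min: float
    support_logp: float
    n_support: int

    @property
    def length(self) -> int:
        return self.end - self.start


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_snps), the genome-wide significance line."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_snps))


def run_gwas(gm: GenotypeMatrix, means: AdjustedMeans | pd.Series,
             n_pcs: int = 3, alpha: float = 0.05, trait: str | None = None) -> GwasScan:
    """Single-trait GLM scan: mean ~ intercept + PCs + SNP dosage.

    Lines are intersected between the genotype matrix and the means. SNPs
    collinear with the covariates (zero residual dosage variance) get
    missing p-values. Partial R^2 of the SNP term is t^2/(t^2 + df).
    """
    if isinstance(means, AdjustedMeans):
        ser = means.means
        trait = trait or means.trait
    else:
        ser = means
        trait = trait or str(ser.name or "trait")
    ser = ser.dropna()
    common = [l for l in gm.line_ids if l in set(ser.index.astype(str))]
    if len(common) < 3:
        raise ValueError("need at least 3 lines shared between genotypes and means")
    sub = gm.take_lines(common)
    y = ser.reindex(common).to_numpy(float)
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    if n_pcs > 0:
        pcs, _ = genotype_pca(sub, n_pcs)
        Q = np.column_stack([np.ones(len(common)), pcs])
    else:
        Q = np.ones((len(common), 1))
    # residualize phenotype and dosages against the covariates
    Qp, _ = np.linalg.qr(Q)
    ry = y - Qp @ (Qp.T @ y)
    D = sub.dosages
    rD = D - Qp @ (Qp.T @ D)
    dd = np.einsum("ij,ij->j", rD, rD)
    df = len(common) - Q.shape[1] - 1
    if df < 1:
        raise ValueError("not enough lines for the requested number of covariates")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (rD.T @ ry) / dd
        rss = ry @ ry - beta**2 * dd
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / dd)
        t = beta / se
    ok = dd > 1e-12 * len(common)
    beta[~ok] = np.nan
    se[~ok] = np.nan
    t[~ok] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[~ok] = np.nan
    with np.errstate(invalid="ignore"):
        r2_snp = t**2 / (t**2 + df)
    table = pd.DataFrame(
        {
            "marker": sub.marker_map["marker"].to_numpy(),
            "chrom": sub.marker_map["chrom"].to_numpy(),
            "pos": sub.marker_map["pos"].to_numpy(),
            "maf": sub.maf,
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "neglog10p": -np.log10(p),
            "r2_snp": r2_snp,
        }
    )
    return GwasScan(table=table, trait=trait, n_pcs=n_pcs, n_snps=int(ok.sum()),
                    alpha=alpha)


def ld_r2(gm: GenotypeMatrix, snp_i, snp_j) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    idx = {m: k for k, m in enumerate(gm.marker_map["marker"])}
    i = idx[snp_i] if not isinstance(snp_i, (int, np.integer)) else int(snp_i)
    j = idx[snp_j] if not isinstance(snp_j, (int, np.integer)) else int(snp_j)
    a = gm.dosages[:, i]
    b = gm.dosages[:, j]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD r^2 undefined for monomorphic SNPs")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def define_region(scan: GwasScan, gm: GenotypeMatrix, peak_marker: str,
                  window_bp: int = 4_000_000, r2_min: float = 0.4,
                  support_logp: float = 5.0,
                  full_window_each_side: bool = False) -> GenomicRegion:
    """Delimit the associated region around a significant peak SNP.

    Candidate SNPs lie on the peak's chromosome within the physical window
    (by default +/- ``window_bp``/2, i.e. a total window of ``window_bp``;
    with ``full_window_each_side`` the window extends ``window_bp`` each
    side). A SNP supports the region if its dosage r^2 with the peak is at
    least ``r2_min`` and it is either significant at the scan threshold or
    has -log10(p) above ``support_logp``. The region spans the outermost
    supporting SNPs; with no support it collapses to the peak position.
    """
    tab = scan.table.set_index("marker")
    if peak_marker not in tab.index:
        raise KeyError(f"unknown marker {peak_marker!r}")
    peak = tab.loc[peak_marker]
    if peak["neglog10p"] < scan.threshold:
        raise ValueError(
            f"peak {peak_marker!r} is not significant at the Bonferroni threshold"
        )
    half = window_bp if full_window_each_side else window_bp // 2
    cand = tab[(tab["chrom"] == peak["chrom"])
               & (np.abs(tab["pos"] - peak["pos"]) <= half)
               & (tab.index != peak_marker)]
    support = []
    for marker, row in cand.iterrows():
        if np.isnan(row["neglog10p"]):
            continue
        strong = row["neglog10p"] >= scan.threshold or row["neglog10p"] > support_logp
        if not strong:
            continue
        try:
            r2 = ld_r2(gm, marker, peak_marker)
        except ValueError:
            continue
        if r2 >= r2_min:
            support.append(int(row["pos"]))
    if support:
        start = min(min(support), int(peak["pos"]))
        end = max(max(support), int(peak["pos"]))
    else:
        start = end = int(peak["pos"])
    return GenomicRegion(
        chrom=str(peak["chrom"]), start=start, end=end,
        peak_marker=peak_marker, peak_pos=int(peak["pos"]),
        peak_neglog10p=float(peak["neglog10p"]), peak_r2=float(peak["r2_snp"]),
        peak_maf=float(peak["maf"]), window_bp=window_bp, r2_min=r2_min,
        support_logp=support_logp, n_support=len(support),
    )
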