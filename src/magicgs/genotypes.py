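"""SNP genotype handling and the genomic relationship matrix.

The central container is :class:`GenotypeMatrix`, a lines x markers matrix of
alternate-allele dosages (0/1/2) with a physical marker map. From it the
module derives marker filters (minor-allele frequency, physical-distance
thinning), the VanRaden genomic relationship matrix used by GBLUP, and
principal components of the dosage matrix used as population-structure
covariates in association scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "read_vcf",
    "read_dosage_csv",
    "write_dosage_csv",
    "filter_maf",
    "thin_by_distance",
    "vanraden_grm",
    "genotype_pca",
]

#: ascending ladder of diagonal-bending constants tried when the GRM is not PSD
BEND_LADDER = (1e-8, 1e-6, 1e-4)


@dataclass
class GenotypeMatrix:
    """Lines x markers alternate-allele dosage matrix with a marker map.

    Parameters
    ----------
    line_ids : sequence of str
        Unique line identifiers, one per row of ``dosages``.
    dosages : ndarray of shape (n_lines, n_markers)
        Alternate-allele counts in {0, 1, 2}; no missing values.
    marker_map : DataFrame with columns ``marker``, ``chrom``, ``pos``
        1-based physical positions, strictly increasing within chromosome.
    """

    line_ids: list[str]
    dosages: np.ndarray
    marker_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (lines x markers) array")
        if len(self.line_ids) != self.dosages.shape[0]:
            raise ValueError("line_ids length does not match dosage rows")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        self.marker_map = self.marker_map.reset_index(drop=True)
        required = {"marker", "chrom", "pos"}
        if not required.issubset(self.marker_map.columns):
            raise ValueError(f"marker_map must have columns {sorted(required)}")
        if len(self.marker_map) != self.dosages.shape[1]:
            raise ValueError("marker_map length does not match dosage columns")
        if np.isnan(self.dosages).any():
            raise ValueError("dosages contain missing values; impute or drop first")
        bad = ~np.isin(self.dosages, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosages must be integers in {0, 1, 2}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate allele frequency p = column mean / 2."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency min(p, 1 - p)."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New GenotypeMatrix keeping markers at positional indices ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            line_ids=self.line_ids,
            dosages=self.dosages[:, idx],
            marker_map=self.marker_map.iloc[idx],
        )

    def take_lines(self, line_ids: list[str]) -> "GenotypeMatrix":
        """New GenotypeMatrix restricted to ``line_ids`` in the given order."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise KeyError(f"lines not in genotype matrix: {missing[:5]}")
        rows = [pos[l] for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.dosages[rows], self.marker_map)

    def assert_sorted_map(self) -> None:
        """Raise if positions are not strictly increasing within chromosome."""
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker map not strictly increasing on chromosome {chrom}"
                )


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with bending record.

    ``values`` is symmetric n x n; ``bend_epsilon`` is the constant added to
    the diagonal (0.0 when the raw matrix was already positive
    semi-definite).
    """

    line_ids: list[str]
    values: np.ndarray
    bend_epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    def subset(self, line_ids: list[str]) -> "GRM":
        """GRM restricted to ``line_ids`` in the given order."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        rows = np.array([pos[l] for l in line_ids])
        return GRM(list(line_ids), self.values[np.ix_(rows, rows)], self.bend_epsilon)

    def block(self, rows: list[str], cols: list[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        r = np.array([pos[l] for l in rows])
        c = np.array([pos[l] for l in cols])
        return self.values[np.ix_(r, c)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


# -- input / output ------------------------------------------------------

def read_vcf(path, skip_multiallelic: bool = True, impute_mean: bool = False) -> GenotypeMatrix:
    """Load biallelic SNP dosages from a VCF file.

    GT fields are converted to alternate-allele counts. Multi-allelic
    records are skipped when ``skip_multiallelic`` is set, otherwise they
    raise. Missing genotypes raise unless ``impute_mean`` is set, in which
    case they are replaced by the rounded per-marker mean dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    markers: list[tuple[str, str, int]] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "pass skip_multiallelic=True to drop such sites"
            )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        miss = gt == 2
        if miss.any():
            if not impute_mean:
                raise ValueError(
                    f"missing genotype at {var.CHROM}:{var.POS}; "
                    "pass impute_mean=True to mean-impute"
                )
            dos[miss] = np.nan
            dos[miss] = np.round(np.nanmean(dos))
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append((name, var.CHROM, var.POS))
        cols.append(dos)
    if not cols:
        raise ValueError(f"no biallelic SNP records found in {path}")
    marker_map = pd.DataFrame(markers, columns=["marker", "chrom", "pos"])
    return GenotypeMatrix(samples, np.column_stack(cols), marker_map)


def write_dosage_csv(gm: GenotypeMatrix, path, map_path=None) -> None:
    """Write dosages as CSV (rows = lines, header = marker ids) plus a map sidecar."""
    df = pd.DataFrame(
        gm.dosages.astype(int), index=gm.line_ids, columns=gm.marker_map["marker"]
    )
    df.index.name = "line"
    df.to_csv(path)
    if map_path is not None:
        gm.marker_map.to_csv(map_path, index=False)


def read_dosage_csv(path, map_path) -> GenotypeMatrix:
    """Inverse of :func:`write_dosage_csv`."""
    df = pd.read_csv(path, index_col=0)
    marker_map = pd.read_csv(map_path)
    if list(df.columns) != list(marker_map["marker"].astype(str)):
        raise ValueError("dosage CSV marker order does not match map CSV")
    return GenotypeMatrix(list(df.index.astype(str)), df.to_numpy(float), marker_map)


# -- marker filters ------------------------------------------------------

def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep markers whose minor allele frequency strictly exceeds ``min_maf``.

    The inequality is strict, so a marker with MAF exactly at the cutoff is
    removed, and monomorphic markers are always removed for any
    ``min_maf >= 0``.
    """
    if not 0.0 <= min_maf < 0.5:
        raise ValueError("min_maf must satisfy 0 <= min_maf < 0.5")
    keep = np.flatnonzero(gm.maf > min_maf)
    return gm.take_markers(keep)


def thin_by_distance(gm: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right physical thinning within each chromosome.

    Walks each chromosome in map order keeping the first marker and then
    every marker at least ``min_bp`` from the last kept one, so retained
    markers are pairwise >= ``min_bp`` apart.
    """
    if min_bp < 0:
        raise ValueError("min_bp must be non-negative")
    gm.assert_sorted_map()
    if min_bp == 0:
        return gm
    keep: list[int] = []
    for _, grp in gm.marker_map.groupby("chrom", sort=False):
        last = None
        for idx, pos in zip(grp.index, grp["pos"]):
            if last is None or pos - last >= min_bp:
                keep.append(idx)
                last = pos
    return gm.take_markers(np.sort(keep))


# -- genomic relationship matrix -----------------------------------------

def vanraden_grm(gm: GenotypeMatrix) -> GRM:
    """VanRaden genomic relationship matrix G = W W' / (2 sum p(1-p)).

    W is the dosage matrix with twice the allele frequency subtracted from
    each column. Monomorphic markers contribute nothing to either numerator
    or denominator. If the resulting matrix is not positive semi-definite
    (numerically), the smallest constant from ``BEND_LADDER`` restoring a
    minimum eigenvalue >= -1e-8 is added to the diagonal and recorded.
    """
    if gm.n_lines < 2:
        raise ValueError("GRM needs at least two lines")
    p = gm.allele_freq
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0.0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    W = gm.dosages - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    eps = 0.0
    if np.linalg.eigvalsh(G).min() < -1e-8:
        for cand in BEND_LADDER:
            if np.linalg.eigvalsh(G + cand * np.eye(gm.n_lines)).min() >= -1e-8:
                eps = cand
                break
        else:  # pragma: no cover - centered cross-products cannot get here
            raise ValueError("GRM could not be bent to positive semi-definite")
        G = G + eps * np.eye(gm.n_lines)
    return GRM(gm.line_ids, G, bend_epsilon=eps)


# -- principal components ------------------------------------------------

def genotype_pca(gm: GenotypeMatrix, n_components: int, scale: bool = False):
    """Principal components of the centered dosage matrix.

    Returns ``(scores, varexp)``: per-line scores of shape
    (n_lines, n_components) and the fraction of total dosage variance each
    component explains (non-increasing, summing to <= 1). Columns are
    centered; with ``scale`` they are additionally divided by their standard
    deviation (monomorphic columns are left unscaled).
    """
    max_rank = min(gm.n_lines, gm.n_markers)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    X = gm.dosages - gm.dosages.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        raise ValueError("dosage matrix has zero variance; PCA undefined")
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    scores = u[:, :n_components] * s[:n_components]
    varexp = (s[:n_components] ** 2) / total
    return scores, varexp
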