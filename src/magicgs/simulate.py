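"""Synthetic MAGIC population generator with a known truth set.

Emulates an 8-founder multi-parent advanced generation inter-cross
(MAGIC) population of inbred lines evaluated under water stress: seven
"cultivated" founders drawn from a common allele-frequency spectrum plus
one divergent "wild" founder; a balanced funnel (pairs -> 4-ways ->
8-ways) with recombination by the Haldane map function (crossovers as a
Poisson process on the cM map, no interference); then selfing by
single-seed descent. Trait phenotypes follow the GBLUP generative model -
additive values from planted QTL, an iid residual genetic effect, fixed
experiment shifts and plant-level residual noise - and are emitted as raw
organ weights and measurements so the phenotype-derivation pipeline can be
exercised end to end.

Heritability convention: a trait's ``h2`` is defined on the line-mean
(adjusted-means) scale, h2 = sa2 / (sa2 + sn2 + se2_plant / n_experiments)
with the line-mean phenotypic variance normalised to ``sd**2``; additive
and residual-genetic draws are rescaled to their target sample variances
so the realised components match the configuration.

The trial design mirrors a three-experiment completely randomised layout:
per experiment each MAGIC line contributes one stressed (final) plant and
one destructive baseline plant, each parent three of each; 6 plants per
MAGIC line and 18 per parent in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "TraitSpec",
    "SimConfig",
    "SimTruth",
    "SimData",
    "default_traits",
    "default_genetic_corr",
    "simulate_founders",
    "simulate_magic",
    "simulate_traits",
    "simulate_trial_design",
    "simulate_dataset",
]


@dataclass
class TraitSpec:
    """One simulated trait: heritability structure and raw-scale placement.

    ``h2`` is the line-mean narrow-sense heritability, ``sn2_share`` the
    residual-genetic fraction of line-mean phenotypic variance, ``sd`` the
    line-mean phenotypic standard deviation on the trait's raw scale and
    ``experiment_sd`` the standard deviation of fixed experiment shifts.
    """

    name: str
    h2: float = 0.4
    sn2_share: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    n_qtl: int = 100
    experiment_sd: float | None = None  # default 0.3 * sd

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 for {self.name!r} must be in [0, 1]")
        if self.h2 + self.sn2_share > 1.0 + 1e-12:
            raise ValueError(f"h2 + sn2_share for {self.name!r} exceeds 1")
        if self.experiment_sd is None:
            self.experiment_sd = 0.3 * self.sd

    def variance_components(self, n_experiments: int) -> dict:
        """Plant-level (sa2, sn2, se2) implied by the line-mean h2."""
        total = self.sd**2
        sa2 = self.h2 * total
        sn2 = self.sn2_share * total
        se2 = (total - sa2 - sn2) * n_experiments
        return {"sa2": sa2, "sn2": sn2, "se2": se2}


def default_traits() -> list[TraitSpec]:
    """The six drought-index traits with moderate, realistic settings.

    Means/SDs sit on realistic raw scales for water-stressed eggplant
    (grams of dry weight, percent water content, flavonol index units,
    umol/g proline); heritabilities are moderate with residual genetic
    variance present for the flavonol and water-content traits.
    """
    return [
        TraitSpec("Total DW", h2=0.44, sn2_share=0.0, mean=4.75, sd=0.85),
        TraitSpec("Total DW growth", h2=0.21, sn2_share=0.0, mean=2.91, sd=0.55),
        TraitSpec("Root DW", h2=0.42, sn2_share=0.0, mean=1.08, sd=0.20),
        TraitSpec("Flav", h2=0.46, sn2_share=0.23, mean=1.37, sd=0.10),
        TraitSpec("Total WC", h2=0.43, sn2_share=0.25, mean=83.74, sd=1.30),
        TraitSpec("Pro", h2=0.31, sn2_share=0.0, mean=108.0, sd=20.0),
    ]


def default_genetic_corr() -> pd.DataFrame:
    """Genetic correlations among the six default traits.

    Biomass traits correlate positively with each other and with proline;
    water content correlates negatively with biomass; flavonols correlate
    with root biomass. The matrix is symmetric positive definite.
    """
    traits = [t.name for t in default_traits()]
    R = np.array([
        # TotDW  TotDWg RootDW  Flav   TotWC   Pro
        [1.00,  0.70,  0.50,  0.30, -0.45,  0.40],   # Total DW
        [0.70,  1.00,  0.35,  0.10, -0.30,  0.30],   # Total DW growth
        [0.50,  0.35,  1.00,  0.40, -0.20,  0.10],   # Root DW
        [0.30,  0.10,  0.40,  1.00, -0.35,  0.10],   # Flav
        [-0.45, -0.30, -0.20, -0.35,  1.00, -0.10],  # Total WC
        [0.40,  0.30,  0.10,  0.10, -0.10,  1.00],   # Pro
    ])
    if np.linalg.eigvalsh(R).min() <= 0:  # pragma: no cover - fixed matrix
        raise ValueError("default genetic correlation matrix not positive definite")
    return pd.DataFrame(R, index=traits, columns=traits)


@dataclass
class SimConfig:
    """Configuration for one synthetic MAGIC study."""

    seed: int
    n_founders: int = 8
    n_chromosomes: int = 4
    chrom_length_bp: int = 60_000_000
    cm_per_mb: float = 1.0
    n_snps: int = 2000
    n_magic_lines: int = 325
    n_phenotyped: int = 184
    selfing_generations: int = 5
    n_experiments: int = 3
    traits: list = field(default_factory=default_traits)
    genetic_corr: pd.DataFrame | None = field(default_factory=default_genetic_corr)
    shared_qtl: int = 100  # size of the shared QTL set when traits are correlated

    def __post_init__(self):
        if self.n_founders & (self.n_founders - 1):
            raise ValueError("n_founders must be a power of two (balanced funnel)")
        if self.genetic_corr is not None:
            R = np.asarray(self.genetic_corr, float)
            names = [t.name for t in self.traits]
            if list(self.genetic_corr.columns) != names:
                raise ValueError("genetic_corr columns must match trait names")
            if not np.allclose(R, R.T) or np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValueError("genetic_corr must be symmetric positive semi-definite")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def parent_ids(self) -> list[str]:
        return [f"P{i+1}" for i in range(self.n_founders)]

    @property
    def magic_ids(self) -> list[str]:
        width = len(str(self.n_magic_lines))
        return [f"L{i+1:0{width}d}" for i in range(self.n_magic_lines)]


@dataclass
class SimTruth:
    """Truth ledger serialised alongside simulated data."""

    qtl_effects: pd.DataFrame = field(repr=False)  # markers x traits
    tbv: pd.DataFrame = field(repr=False)          # lines (+parents) x traits
    residual_genetic: pd.DataFrame = field(repr=False)
    varcomps: pd.DataFrame = field(repr=False)     # traits x (sa2, sn2, se2)
    experiment_effects: pd.DataFrame = field(repr=False)
    phenotyped_lines: list = field(default_factory=list)
    f1_heterozygosity: float = float("nan")
    founder_origins: np.ndarray | None = field(default=None, repr=False)

    def founder_shares(self, n_founders: int) -> pd.DataFrame:
        """Per-line genome fraction inherited from each founder."""
        if self.founder_origins is None:
            raise ValueError("founder origins were not recorded")
        n_lines = self.founder_origins.shape[0]
        counts = np.zeros((n_lines, n_founders))
        flat = self.founder_origins.reshape(n_lines, -1)
        for f in range(n_founders):
            counts[:, f] = (flat == f).mean(axis=1)
        return pd.DataFrame(counts, columns=[f"P{f+1}" for f in range(n_founders)])


@dataclass
class SimData:
    """Bundle of one simulated study."""

    config: SimConfig
    gm: GenotypeMatrix                 # MAGIC lines
    founder_gm: GenotypeMatrix         # parents P1..P8
    pheno: pd.DataFrame                # raw long-format plant records
    truth: SimTruth


# ----------------------------------------------------------------------
# genomes
# ----------------------------------------------------------------------

def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=per[c], replace=False)) + 1
        chrom = f"chr{c+1:02d}"
        rows += [(f"{chrom}_{p}", chrom, int(p)) for p in pos]
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos"])


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Fully homozygous founder haplotypes; the last founder is divergent.

    Cultivated founders draw alleles from a shared per-marker frequency
    spectrum; the wild founder draws from an independent spectrum, giving
    it an elevated allele-frequency distance from the rest. Markers
    monomorphic across the panel are redrawn so every site segregates.
    Returns ``(haplotypes, marker_map)`` with haplotypes of shape
    (n_founders, n_snps) in {0, 1}.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    marker_map = _marker_map(cfg, rng)
    m = len(marker_map)
    p = rng.uniform(0.1, 0.9, size=m)
    hap = (rng.random((cfg.n_founders - 1, m)) < p).astype(np.int8)
    p_wild = rng.beta(0.4, 0.4, size=m)
    wild = (rng.random(m) < p_wild).astype(np.int8)
    hap = np.vstack([hap, wild])
    # redraw monomorphic sites until all segregate
    for _ in range(100):
        mono = hap.min(axis=0) == hap.max(axis=0)
        if not mono.any():
            break
        k = int(mono.sum())
        hap[:-1, mono] = (rng.random((cfg.n_founders - 1, k)) < p[mono]).astype(np.int8)
        hap[-1, mono] = (rng.random(k) < p_wild[mono]).astype(np.int8)
    return hap, marker_map


class _Genome:
    """Per-chromosome marker cM coordinates for meiosis."""

    def __init__(self, marker_map: pd.DataFrame, cm_per_mb: float):
        self.slices = []
        self.cm = []
        start = 0
        for _, grp in marker_map.groupby("chrom", sort=False):
            n = len(grp)
            self.slices.append(slice(start, start + n))
            self.cm.append(grp["pos"].to_numpy(float) * cm_per_mb / 1e6)
            start += n
        self.n_markers = start


def _gamete(hap_pair: np.ndarray, ori_pair: np.ndarray, genome: _Genome,
            rng: np.random.Generator):
    """One meiosis: recombine a haplotype pair under the Haldane model."""
    g_hap = np.empty(genome.n_markers, dtype=np.int8)
    g_ori = np.empty(genome.n_markers, dtype=np.int8)
    for sl, cm in zip(genome.slices, genome.cm):
        length = cm[-1] - cm[0] if len(cm) > 1 else 0.0
        n_xo = rng.poisson(length / 100.0)
        breaks = np.sort(rng.uniform(cm[0], cm[0] + length, size=n_xo)) if n_xo else np.empty(0)
        phase = (rng.integers(2) + np.searchsorted(breaks, cm, side="right")) % 2
        g_hap[sl] = np.where(phase == 0, hap_pair[0, sl], hap_pair[1, sl])
        g_ori[sl] = np.where(phase == 0, ori_pair[0, sl], ori_pair[1, sl])
    return g_hap, g_ori


def simulate_magic(founders: np.ndarray, marker_map: pd.DataFrame, cfg: SimConfig,
                   rng: np.random.Generator | None = None):
    """Funnel-cross and self the founders into near-homozygous MAGIC lines.

    Per line a random founder permutation feeds a balanced funnel (pairs,
    4-way, 8-way crosses) followed by ``cfg.selfing_generations`` of
    single-seed-descent selfing. Returns ``(gm, origins, f1_het)``:
    dosages of the final lines, the founder-of-origin array of shape
    (n_lines, 2, n_markers), and the mean per-line heterozygosity of the
    8-way F1 before selfing (the baseline that selfing halves each
    generation).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    genome = _Genome(marker_map, cfg.cm_per_mb)
    nf, m = founders.shape
    dosages = np.empty((cfg.n_magic_lines, m), dtype=np.int8)
    origins = np.empty((cfg.n_magic_lines, 2, m), dtype=np.int8)
    f1_het = np.empty(cfg.n_magic_lines)
    base_ori = np.arange(nf, dtype=np.int8)[:, None] * np.ones(m, dtype=np.int8)
    for i in range(cfg.n_magic_lines):
        perm = rng.permutation(nf)
        # individuals are (haplotype pair, origin pair) tuples
        level = [
            (founders[[a, b]], base_ori[[a, b]])
            for a, b in zip(perm[0::2], perm[1::2])
        ]
        while len(level) > 1:
            nxt = []
            for j in range(0, len(level), 2):
                h1, o1 = _gamete(*level[j], genome, rng)
                h2, o2 = _gamete(*level[j + 1], genome, rng)
                nxt.append((np.vstack([h1, h2]), np.vstack([o1, o2])))
            level = nxt
        ind_hap, ind_ori = level[0]
        f1_het[i] = float(np.mean(ind_hap[0] != ind_hap[1]))
        for _ in range(cfg.selfing_generations):
            h1, o1 = _gamete(ind_hap, ind_ori, genome, rng)
            h2, o2 = _gamete(ind_hap, ind_ori, genome, rng)
            ind_hap, ind_ori = np.vstack([h1, h2]), np.vstack([o1, o2])
        dosages[i] = ind_hap.sum(axis=0)
        origins[i] = ind_ori
    gm = GenotypeMatrix(cfg.magic_ids, dosages, marker_map)
    return gm, origins, float(f1_het.mean())


# ----------------------------------------------------------------------
# trial design and traits
# ----------------------------------------------------------------------

def simulate_trial_design(cfg: SimConfig, phenotyped_lines: list[str] | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plant-level layout: per experiment, 1 stress + 1 baseline plant per
    MAGIC line and 3 + 3 per parent, in completely randomised order."""
    rng = rng or np.random.default_rng(cfg.seed)
    lines = phenotyped_lines if phenotyped_lines is not None else cfg.magic_ids[: cfg.n_phenotyped]
    rows = []
    for exp in range(1, cfg.n_experiments + 1):
        for line in lines:
            rows.append((line, "magic", exp, "final"))
            rows.append((line, "magic", exp, "baseline"))
        for par in cfg.parent_ids:
            for _ in range(3):
                rows.append((par, "parent", exp, "final"))
                rows.append((par, "parent", exp, "baseline"))
    df = pd.DataFrame(rows, columns=["line", "role", "experiment", "stage"])
    df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    df.insert(0, "plant_id", [f"plant{i+1:05d}" for i in range(len(df))])
    return df


def _line_effects(dosages_all: np.ndarray, cfg: SimConfig, rng: np.random.Generator):
    """True breeding values and residual genetic effects for all individuals.

    ``dosages_all`` stacks MAGIC lines then parents. Additive values come
    from QTL effects (a shared QTL set with correlated per-trait effects
    when ``cfg.genetic_corr`` is set, otherwise independent per-trait QTL
    sets); each trait's TBV and residual genetic draws are rescaled to hit
    the target sample variances exactly.
    """
    n_ind, m = dosages_all.shape
    names = cfg.trait_names
    t = len(names)
    poly = np.flatnonzero(dosages_all.std(axis=0) > 0)
    comps = {
        spec.name: spec.variance_components(cfg.n_experiments) for spec in cfg.traits
    }
    tbv = np.zeros((n_ind, t))
    effects = pd.DataFrame(0.0, index=range(m), columns=names)
    sa2 = np.array([comps[name]["sa2"] for name in names])
    if cfg.genetic_corr is not None:
        # shared QTL set; LD among QTL distorts naive correlated effects,
        # so whiten the realised scores and re-mix to the target
        # correlation -- the result is still a linear model in the QTL
        # dosages with well-defined effects
        n_qtl = min(cfg.shared_qtl, len(poly))
        qtl = np.sort(rng.choice(poly, size=n_qtl, replace=False))
        S = dosages_all[:, qtl] - dosages_all[:, qtl].mean(axis=0)
        E = rng.standard_normal((n_qtl, t))
        tbv0 = S @ E
        C0 = np.cov(tbv0, rowvar=False, ddof=1)
        L0 = np.linalg.cholesky(C0 + 1e-12 * np.trace(C0) * np.eye(t))
        LR = np.linalg.cholesky(
            np.asarray(cfg.genetic_corr, float) + 1e-10 * np.eye(t)
        )
        B = np.linalg.solve(L0.T, LR.T) * np.sqrt(sa2)
        tbv = tbv0 @ B
        effects.loc[qtl, :] = E @ B
    else:
        for j, spec in enumerate(cfg.traits):
            n_qtl = min(spec.n_qtl, len(poly))
            qtl = np.sort(rng.choice(poly, size=n_qtl, replace=False))
            eff = rng.standard_normal(n_qtl)
            raw = dosages_all[:, qtl] @ eff
            raw = raw - raw.mean()
            sd = raw.std(ddof=1)
            scale = np.sqrt(sa2[j]) / sd if sd > 0 else 0.0
            tbv[:, j] = raw * scale
            effects.loc[qtl, spec.name] = eff * scale
    un = np.zeros((n_ind, t))
    for j, spec in enumerate(cfg.traits):
        c = comps[spec.name]
        if c["sn2"] > 0:
            draw = rng.standard_normal(n_ind)
            draw = (draw - draw.mean()) / draw.std(ddof=1)
            un[:, j] = draw * np.sqrt(c["sn2"])
    return tbv, un, effects, comps


def simulate_traits(gm: GenotypeMatrix, founder_gm: GenotypeMatrix, cfg: SimConfig,
                    rng: np.random.Generator | None = None):
    """Phenotype records for the trial design plus the truth ledger.

    Each plant's value for a simulated trait is mean + TBV + residual
    genetic + experiment shift + plant noise. Biomass/water traits are
    re-expressed as raw organ fresh/dry weights (leaf/stem split around a
    realistic aerial partition, fresh weights back-computed from the water
    content), with destructive baseline plants carrying the final weights
    minus the growth-trait value, so the derivation pipeline reproduces
    the planted trait values.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    names = cfg.trait_names
    phenotyped = sorted(rng.choice(cfg.magic_ids, size=cfg.n_phenotyped, replace=False))
    design = simulate_trial_design(cfg, phenotyped, rng)
    all_ids = list(gm.line_ids) + list(founder_gm.line_ids)
    dos_all = np.vstack([gm.dosages, founder_gm.dosages])
    tbv, un, effects, comps = _line_effects(dos_all, cfg, rng)
    tbv = pd.DataFrame(tbv, index=all_ids, columns=names)
    un = pd.DataFrame(un, index=all_ids, columns=names)
    exp_eff = pd.DataFrame(
        {s.name: rng.normal(0.0, s.experiment_sd, size=cfg.n_experiments)
         for s in cfg.traits},
        index=range(1, cfg.n_experiments + 1),
    )
    spec_by = {s.name: s for s in cfg.traits}

    def plant_value(trait, line, exp):
        s = spec_by[trait]
        c = comps[trait]
        return (s.mean + tbv.at[line, trait] + un.at[line, trait]
                + exp_eff.at[exp, trait] + rng.normal(0.0, np.sqrt(c["se2"])))

    def value_or(trait, line, exp, fallback_mean, fallback_sd):
        if trait in spec_by:
            return plant_value(trait, line, exp)
        return fallback_mean + rng.normal(0.0, fallback_sd)

    records = []
    # pair finals with baselines per (line, experiment, replicate slot)
    design = design.sort_values(["line", "experiment", "stage"], kind="stable")
    grouped = design.groupby(["line", "experiment"], sort=False)
    for (line, exp), grp in grouped:
        finals = grp[grp["stage"] == "final"]
        bases = grp[grp["stage"] == "baseline"]
        for (_, frow), (_, brow) in zip(finals.iterrows(), bases.iterrows()):
            total = max(value_or("Total DW", line, exp, 4.75, 0.9), 0.5)
            root = value_or("Root DW", line, exp, 1.08, 0.25)
            root = float(np.clip(root, 0.05 * total, 0.8 * total))
            aerial = total - root
            leaf_share = rng.beta(152.0, 48.0)  # mean 0.76, sd ~0.03
            wc = float(np.clip(value_or("Total WC", line, exp, 83.7, 1.5), 55.0, 96.0))
            growth = value_or("Total DW growth", line, exp, 2.9, 0.6)
            growth = float(np.clip(growth, 0.1 * total, 0.85 * total))
            base_total = total - growth
            base_root = float(np.clip(root * base_total / total, 0.05 * base_total,
                                      0.8 * base_total))
            leafn_f = max(rng.normal(5.2, 1.0), 1.0)
            stem_f = max(rng.normal(13.8, 2.5), 2.0)
            for row, tot, rt, stage in ((frow, total, root, "final"),
                                        (brow, base_total, base_root, "baseline")):
                aer = tot - rt
                dw_leaf = leaf_share * aer
                dw_stem = aer - dw_leaf
                wcs = np.clip(wc + rng.normal(0.0, 0.3, size=3), 50.0, 97.0)
                rec = {
                    "plant_id": row["plant_id"], "line": line, "role": row["role"],
                    "experiment": exp, "stage": stage,
                    "dw_leaf": dw_leaf, "dw_stem": dw_stem, "dw_root": rt,
                    "fw_leaf": dw_leaf / (1 - wcs[0] / 100),
                    "fw_stem": dw_stem / (1 - wcs[1] / 100),
                    "fw_root": rt / (1 - wcs[2] / 100),
                    "leaf_number": leafn_f if stage == "final" else max(leafn_f - rng.normal(1.0, 0.3), 1.0),
                    "stem_length": stem_f if stage == "final" else max(stem_f - rng.normal(3.5, 0.8), 1.0),
                }
                if stage == "final":
                    rec.update({
                        "chl": value_or("Chl", line, exp, 42.9, 4.0),
                        "flav": value_or("Flav", line, exp, 1.37, 0.12),
                        "anth": value_or("Anth", line, exp, 0.34, 0.03),
                        "nbi": value_or("NBI", line, exp, 31.6, 3.0),
                        "pro": max(value_or("Pro", line, exp, 108.0, 25.0), 1.0),
                    })
                else:
                    rec.update({"chl": np.nan, "flav": np.nan, "anth": np.nan,
                                "nbi": np.nan, "pro": np.nan})
                records.append(rec)
    pheno = pd.DataFrame(records)
    truth = SimTruth(
        qtl_effects=effects.loc[(effects != 0).any(axis=1)],
        tbv=tbv, residual_genetic=un,
        varcomps=pd.DataFrame(comps).T[["sa2", "sn2", "se2"]],
        experiment_effects=exp_eff,
        phenotyped_lines=list(phenotyped),
    )
    return pheno, truth


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Full synthetic study: genomes, trial phenotypes, and truth."""
    rng = np.random.default_rng(cfg.seed)
    founders, marker_map = simulate_founders(cfg, rng)
    gm, origins, f1_het = simulate_magic(founders, marker_map, cfg, rng)
    founder_gm = GenotypeMatrix(cfg.parent_ids, founders * 2, marker_map)
    pheno, truth = simulate_traits(gm, founder_gm, cfg, rng)
    truth.f1_heterozygosity = f1_het
    truth.founder_origins = origins
    return SimData(config=cfg, gm=gm, founder_gm=founder_gm, pheno=pheno, truth=truth)
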