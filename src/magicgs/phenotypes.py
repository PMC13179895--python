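"""Derived drought-stress traits from raw plant-level measurements.

Raw records are long-format rows, one per plant: identifiers (``line``,
``experiment``, ``role`` in {magic, parent}, ``stage`` in {baseline,
final}), organ fresh/dry weights in grams (``fw_leaf``/``dw_leaf``,
``fw_stem``/``dw_stem``, ``fw_root``/``dw_root``), ``leaf_number``,
``stem_length`` (cm), the optical indices ``chl``, ``flav``, ``anth``,
``nbi`` and proline ``pro`` (umol / g DW).

:func:`derive_traits` computes the 25 analysis traits: organ, aerial and
total dry weights; water contents on a fresh-weight basis; the aerial/root
ratio; growth during the stress period via destructive-baseline
subtraction; and the pass-through optical/biochemical traits.

Water content uses the fresh-weight basis 100*(FW-DW)/FW, the only basis
bounded by 100% and consistent with observed leaf tissue values of ~70-88%.
Aggregate water contents (aerial, total) are computed from summed fresh and
dry weights rather than averaged percentages, so that mass is conserved.

Growth rules: every final-stage MAGIC plant is paired with the single
destructive baseline plant of the same line in the same experiment; parent
plants are corrected by the mean of that parent's baseline replicates
within the experiment. Plants without a usable baseline get missing growth
values and are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RAW_COLUMNS",
    "TRAIT_NAMES",
    "GROWTH_SOURCE",
    "water_content",
    "watering_target",
    "aggregate_organs",
    "growth_traits",
    "derive_traits",
]

RAW_COLUMNS = [
    "line", "experiment", "role", "stage",
    "fw_leaf", "fw_stem", "fw_root",
    "dw_leaf", "dw_stem", "dw_root",
    "leaf_number", "stem_length",
    "chl", "flav", "anth", "nbi", "pro",
]

#: raw/base trait feeding each growth trait
GROWTH_SOURCE = {
    "Leaf DW growth": "Leaf DW",
    "Stem DW growth": "Stem DW",
    "Root DW growth": "Root DW",
    "Aerial DW growth": "Aerial DW",
    "Total DW growth": "Total DW",
    "Leaf number growth": "Leaf Number",
    "Stem length growth": "Stem Length",
}

#: the 25 derived analysis traits
TRAIT_NAMES = [
    "Stem Length", "Stem DW", "Anth", "Flav", "Total WC", "Leaf WC",
    "Stem WC", "Leaf Number", "Aerial WC", "Aerial/Root ratio", "Chl",
    "Leaf number growth", "Stem length growth", "NBI", "Stem DW growth",
    "Root WC", "Aerial DW", "Leaf DW", "Total DW", "Root DW",
    "Root DW growth", "Pro", "Aerial DW growth", "Total DW growth",
    "Leaf DW growth",
]


def water_content(fw, dw):
    """Water content in percent on a fresh-weight basis: 100*(FW-DW)/FW.

    Accepts scalars or arrays; raises on non-positive FW or DW > FW.
    """
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(fw[~np.isnan(fw)] <= 0):
            raise ValueError("fresh weight must be positive")
        bad = (dw > fw) | (dw < 0)
        if np.any(bad[~np.isnan(bad.astype(float))].astype(bool) & ~np.isnan(dw)):
            raise ValueError("dry weight must satisfy 0 <= DW <= FW")
    out = np.clip(100.0 * (fw - dw) / fw, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def watering_target(mass_at_100fc: float, fc_fraction: float) -> float:
    """Gravimetric watering target: water mass at a given field-capacity fraction.

    E.g. a pot holding 780 g of water at 100% FC is watered to
    ``watering_target(780, 0.30) == 234`` g under 30% FC stress.
    """
    if mass_at_100fc <= 0:
        raise ValueError("mass at 100% field capacity must be positive")
    if not 0 < fc_fraction <= 1:
        raise ValueError("fc_fraction must be in (0, 1]")
    return fc_fraction * mass_at_100fc


def aggregate_organs(df: pd.DataFrame) -> pd.DataFrame:
    """Per-plant organ aggregates: dry weights, ratio, and water contents.

    Adds Leaf/Stem/Root/Aerial/Total DW, Aerial/Root ratio and the five
    water-content columns. Rows with zero root DW get a missing ratio.
    """
    out = df.copy()
    out["Leaf DW"] = out["dw_leaf"]
    out["Stem DW"] = out["dw_stem"]
    out["Root DW"] = out["dw_root"]
    out["Aerial DW"] = out["dw_leaf"] + out["dw_stem"]
    out["Total DW"] = out["Aerial DW"] + out["dw_root"]
    ratio = out["Aerial DW"] / out["dw_root"].where(out["dw_root"] > 0)
    out["Aerial/Root ratio"] = ratio

    def wc(fw, dw):
        fw = fw.where(fw > 0)
        return 100.0 * (fw - dw) / fw

    out["Leaf WC"] = wc(out["fw_leaf"], out["dw_leaf"])
    out["Stem WC"] = wc(out["fw_stem"], out["dw_stem"])
    out["Root WC"] = wc(out["fw_root"], out["dw_root"])
    fw_aerial = out["fw_leaf"] + out["fw_stem"]
    out["Aerial WC"] = wc(fw_aerial, out["Aerial DW"])
    out["Total WC"] = wc(fw_aerial + out["fw_root"], out["Total DW"])
    return out


def growth_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Growth during the stress period via destructive-baseline subtraction.

    ``df`` must already carry the base trait columns (see
    :func:`aggregate_organs`); baseline rows supply the reference values.
    MAGIC lines: final minus the single same-line, same-experiment baseline
    plant. Parents: final minus the experiment-specific mean of that
    parent's baselines. Finals without a baseline are flagged in
    ``missing_baseline`` and get NaN growth.
    """
    out = df.copy()
    base_traits = sorted(set(GROWTH_SOURCE.values()))
    for col in base_traits:
        if col not in out.columns:
            raise KeyError(f"growth_traits needs base column {col!r}; derive it first")
    is_base = out["stage"] == "baseline"
    base = out[is_base]
    # per (line, experiment): MAGIC expects exactly one baseline plant
    counts = base.groupby(["line", "experiment"]).size()
    magic_multi = counts[
        counts.index.get_level_values("line").isin(out.loc[out["role"] == "magic", "line"])
        & (counts > 1)
    ]
    if len(magic_multi):
        raise ValueError(
            f"MAGIC lines with more than one baseline plant per experiment: "
            f"{list(magic_multi.index[:3])}"
        )
    ref = base.groupby(["line", "experiment"])[base_traits].mean()
    out["missing_baseline"] = False
    for growth_name, src in GROWTH_SOURCE.items():
        out[growth_name] = np.nan
    final_mask = out["stage"] == "final"
    keys = pd.MultiIndex.from_frame(out.loc[final_mask, ["line", "experiment"]])
    have = keys.isin(ref.index)
    idx_final = out.index[final_mask]
    out.loc[idx_final[~have], "missing_baseline"] = True
    matched = ref.reindex(keys)
    for growth_name, src in GROWTH_SOURCE.items():
        out.loc[idx_final, growth_name] = (
            out.loc[idx_final, src].to_numpy() - matched[src].to_numpy()
        )
    return out


def derive_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Full derived-trait table: aggregates, growth, and pass-through traits.

    Idempotent: re-deriving on an already-derived table recomputes the same
    columns from the raw ones.
    """
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"raw phenotype table missing columns: {missing}")
    fw = df[["fw_leaf", "fw_stem", "fw_root"]].to_numpy(float)
    dw = df[["dw_leaf", "dw_stem", "dw_root"]].to_numpy(float)
    both = ~(np.isnan(fw) | np.isnan(dw))
    if np.any((dw > fw)[both]) or np.any((dw < 0)[both]):
        raise ValueError("organ weights must satisfy 0 <= DW <= FW")
    keep = [c for c in ("plant_id",) if c in df.columns]
    out = aggregate_organs(df[keep + RAW_COLUMNS].copy())
    out["Leaf Number"] = out["leaf_number"]
    out["Stem Length"] = out["stem_length"]
    out = growth_traits(out)
    out["Chl"] = out["chl"]
    out["Flav"] = out["flav"]
    out["Anth"] = out["anth"]
    out["NBI"] = out["nbi"]
    out["Pro"] = out["pro"]
    return out
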