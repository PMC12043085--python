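"""Somatic T cell driver landscape and gene-level copy-number aggregation.

Somatic single-nucleotide/indel calls are kept when they hit a driver-gene
panel with pathogenic/likely pathogenic annotation and a protein-altering
consequence. Each patient is assigned a mutational configuration (STAT3 only,
other drivers only, coexistence, or none) and a driver mutational burden.

Copy-number calls are lifted from segment level to gene level by a
length-weighted mean of segment log2 depth over the gene interval; genes
substantially covered by blacklist intervals (hypervariable regions, common
population CNVs) are excluded from calling.
"""

from __future__ import annotations

import pandas as pd

from ieilgl.config import RunConfig
from ieilgl.clinical import round_half_up_percent

ALLOWED_CONSEQUENCES = {"missense", "nonsense", "frameshift", "indel"}

#: Default driver panel: genes recurrently mutated in T cell neoplasms and
#: lymphoid clonal hematopoiesis. A stub — real runs supply the full panel
#: as an input table.
DEFAULT_DRIVER_PANEL: list[str] = [
    "STAT3", "STAT5B", "STAT5A", "STAT6", "TNFAIP3", "KMT2C", "KMT2D",
    "KDM6A", "KMT5C", "TET2", "DNMT3A", "CREBBP", "DDX3X", "TP53", "CSMD3",
    "POT1", "NOTCH1", "NRAS", "STAG2", "CACNA1E", "SEPTIN4", "CHD2", "LRP1B",
    "TTN", "PCLO", "VCAN", "XIRP2", "UBA1", "KRAS", "KDR",
]


class SomaticError(ValueError):
    pass


def filter_driver_mutations(variants: pd.DataFrame, panel: list[str]) -> pd.DataFrame:
    """Keep panel-gene variants with P/LP pathogenicity and allowed consequence."""
    if not panel:
        raise SomaticError("driver panel must be non-empty")
    panel_set = set(panel)
    kept = variants[
        variants["gene"].isin(panel_set)
        & variants["pathogenicity"].isin(["P", "LP"])
        & variants["consequence"].isin(ALLOWED_CONSEQUENCES)
    ]
    return kept.reset_index(drop=True)


def mutational_configuration(
    kept: pd.DataFrame, patient_ids: list[str]
) -> pd.DataFrame:
    """Per-patient mutational configuration and driver burden.

    Configuration: ``stat3_only`` (STAT3 mutated, no other driver),
    ``other_only``, ``coexistence`` (both), or ``none``. Burden is the count
    of kept variants.
    """
    rows = []
    for pid in patient_ids:
        mine = kept[kept["patient_id"] == pid]
        has_stat3 = (mine["gene"] == "STAT3").any()
        has_other = (mine["gene"] != "STAT3").any()
        if has_stat3 and has_other:
            config = "coexistence"
        elif has_stat3:
            config = "stat3_only"
        elif has_other:
            config = "other_only"
        else:
            config = "none"
        rows.append({
            "patient_id": pid,
            "configuration": config,
            "stat3_mutated": bool(has_stat3),
            "other_mutated": bool(has_other),
            "driver_burden": len(mine),
        })
    return pd.DataFrame(rows)


def summarize_landscape(config_table: pd.DataFrame, kept: pd.DataFrame) -> dict:
    """Cohort-level driver tallies with stored numerators/denominators."""
    n = len(config_table)
    if n == 0:
        raise SomaticError("empty cohort")
    mutated = int((config_table["configuration"] != "none").sum())
    stat3 = int(config_table["stat3_mutated"].sum())
    other = int(config_table["other_mutated"].sum())
    return {
        "cohort_n": n,
        "kept_variants": len(kept),
        "mutated_genes": int(kept["gene"].nunique()),
        "driver_mutated": mutated,
        "driver_mutated_pct": round_half_up_percent(mutated, n),
        "stat3_mutated": stat3,
        "stat3_mutated_pct": round_half_up_percent(stat3, n),
        "other_mutated": other,
        "other_mutated_pct": round_half_up_percent(other, n),
        "coexistence": int((config_table["configuration"] == "coexistence").sum()),
        "mean_burden": float(config_table["driver_burden"].mean()),
        "max_burden": int(config_table["driver_burden"].max()),
    }


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def gene_level_cn(
    segments: pd.DataFrame,
    gene_coords: pd.DataFrame,
    blacklists: pd.DataFrame | None = None,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Gene-level copy-number calls from per-patient segments.

    For each (patient, gene): ``weighted_log2`` is the overlap-length-weighted
    mean of segment log2 over the gene interval (0-based half-open). Calls:
    ``gain`` iff weighted_log2 >= cfg.cn_gain_log2, ``loss`` iff
    <= cfg.cn_loss_log2, else ``neutral``. A gene whose interval overlaps
    blacklist intervals by >= cfg.blacklist_overlap_fraction of its length is
    ``excluded`` regardless of signal. A gene with no segment overlap is
    ``neutral`` with missing log2 and ``no_coverage`` flag set.
    """
    cfg = cfg or RunConfig()
    for _, g in gene_coords.iterrows():
        if not g["start"] < g["end"]:
            raise SomaticError(f"gene {g['gene']}: start must be < end")
    excluded_genes = set()
    if blacklists is not None and len(blacklists):
        for _, g in gene_coords.iterrows():
            glen = g["end"] - g["start"]
            bl = blacklists[blacklists["chrom"] == g["chrom"]]
            covered = sum(
                _overlap(g["start"], g["end"], b["start"], b["end"])
                for _, b in bl.iterrows()
            )
            # ignores blacklist self-overlap; inputs are expected merged
            if covered >= cfg.blacklist_overlap_fraction * glen:
                excluded_genes.add(g["gene"])

    rows = []
    for pid, segs in segments.groupby("patient_id", sort=True):
        for _, g in gene_coords.iterrows():
            if g["gene"] in excluded_genes:
                rows.append({"patient_id": pid, "gene": g["gene"],
                             "weighted_log2": float("nan"), "call": "excluded",
                             "no_coverage": False})
                continue
            here = segs[segs["chrom"] == g["chrom"]]
            w_total = 0.0
            acc = 0.0
            for _, s in here.iterrows():
                w = _overlap(g["start"], g["end"], s["start"], s["end"])
                if w > 0:
                    w_total += w
                    acc += w * float(s["log2"])
            if w_total == 0:
                rows.append({"patient_id": pid, "gene": g["gene"],
                             "weighted_log2": float("nan"), "call": "neutral",
                             "no_coverage": True})
                continue
            wl = acc / w_total
            if wl >= cfg.cn_gain_log2:
                call = "gain"
            elif wl <= cfg.cn_loss_log2:
                call = "loss"
            else:
                call = "neutral"
            rows.append({"patient_id": pid, "gene": g["gene"],
                         "weighted_log2": wl, "call": call, "no_coverage": False})
    return pd.DataFrame(rows, columns=["patient_id", "gene", "weighted_log2",
                                       "call", "no_coverage"])
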