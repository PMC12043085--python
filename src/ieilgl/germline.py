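"""Germline IEI variant triage, hcD carrier classification and burden testing.

The triage proceeds in three steps:

1. **Hard filtering** — a candidate variant survives iff it is rare in the
   population (gnomAD MAF below the configured ceiling), well supported by
   reads (depth, alternate reads, VAF at germline levels), of a protein-
   altering consequence class, outside repetitive regions, not a duplicate of
   a somatic call in the same patient, and not annotated benign/likely benign.
2. **Selection** — pathogenic/likely pathogenic (P/LP) variants are selected
   unconditionally; variants of uncertain significance (VUS) are selected only
   when overrepresented in the cohort, i.e. the one-sided binomial upper-tail
   p-value for the observed allele count versus its population expectation
   survives Benjamini-Hochberg correction at the configured FDR.
3. **hcD classification** — a carrier is high-confidence deleterious (hcD)
   when a rule fires: (a) any P/LP variant; (b) a heterozygous VUS in a
   dominant-trait gene; (c) biallelic P/LP/VUS in a recessive-trait gene
   (homozygous, or >= 2 distinct heterozygous variants presumed in trans).

Burden statistics report the per-patient variant count distribution, the
combined cohort burden, and a chi-square comparison against an external
control cohort's carrier count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ieilgl.config import RunConfig
from ieilgl.clinical import round_half_up_percent
from ieilgl import stats

ALLOWED_CONSEQUENCES = {"missense", "nonsense", "frameshift", "indel", "splice_site"}


class TriageError(ValueError):
    pass


@dataclass
class TriageResult:
    """Everything the triage computed, at variant, patient and cohort level."""

    variants: pd.DataFrame          # per-row flags: passed_filters, overrep_p/q, selected
    per_patient: pd.DataFrame       # selected_variant_count, is_carrier, is_hcd_carrier, hcd_rules
    cohort_n: int
    combined_burden: float = 0.0    # carriers / cohort_n
    expected_probability: float = 0.0
    summary: dict = field(default_factory=dict)


def filter_candidates(variants: pd.DataFrame, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Flag each candidate with ``passed_filters`` (pure flagging, no drops)."""
    cfg = cfg or RunConfig()
    df = variants.copy()
    df["passed_filters"] = (
        (df["population_af"] < cfg.rarity_max_af)
        & (df["depth"] >= cfg.min_depth)
        & (df["alt_reads"] >= cfg.min_alt_reads)
        & (df["vaf"] >= cfg.min_germline_vaf)
        & df["consequence"].isin(ALLOWED_CONSEQUENCES)
        & ~df["in_repetitive_region"].astype(bool)
        & ~df["matches_somatic_call"].astype(bool)
        & ~df["acmg"].isin(["B", "LB"])
    )
    return df


def overrepresentation_screen(
    flagged: pd.DataFrame, cohort_n: int, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Per-variant overrepresentation p/q and the final ``selected`` flag.

    Variants are grouped by (gene, hgvs); the observed allele count across
    the cohort (het = 1 allele, hom = 2) is tested against
    Binomial(2 * cohort_n, population AF) one-sided. BH correction runs over
    the filtered VUS only — P/LP are selected unconditionally and do not
    enter the family. A population AF of exactly 0 is floored at
    1/(2 * reference cohort size) so the tail test stays defined.
    """
    if cohort_n <= 0:
        raise TriageError("cohort_n must be positive")
    cfg = cfg or RunConfig()
    df = flagged.copy()
    dup = df.duplicated(subset=["patient_id", "gene", "hgvs"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TriageError(
            f"duplicate (patient, variant) row: {row['patient_id']} {row['gene']} {row['hgvs']}"
        )
    df["overrep_p"] = np.nan
    df["overrep_q"] = np.nan
    df["selected"] = False

    passed = df[df["passed_filters"]]
    af_floor = 1.0 / (2.0 * cfg.reference_cohort_size)
    tail = stats.binomial_upper_tail if cfg.overrep_test == "binomial" else stats.poisson_upper_tail

    pvals: dict[tuple[str, str], float] = {}
    for (gene, hgvs), grp in passed.groupby(["gene", "hgvs"], sort=True):
        alleles = int((grp["zygosity"] == "hom").sum() * 2 + (grp["zygosity"] == "het").sum())
        af = max(float(grp["population_af"].iloc[0]), af_floor)
        pvals[(gene, hgvs)] = tail(alleles, 2 * cohort_n, min(af, 1.0))

    keys = list(pvals)
    idx = pd.MultiIndex.from_arrays([df["gene"], df["hgvs"]])
    if keys:
        pmap = pd.Series(pvals, dtype=float)
        df.loc[df["passed_filters"], "overrep_p"] = pmap.reindex(
            idx[df["passed_filters"].to_numpy()]
        ).to_numpy()

    # BH family: the filtered VUS only (P/LP selected unconditionally)
    acmg_by_key = passed.groupby(["gene", "hgvs"])["acmg"].first()
    vus_keys = [k for k in keys if acmg_by_key[k] == "VUS"]
    if vus_keys:
        q, _ = stats.bh_adjust([pvals[k] for k in vus_keys], cfg.fdr_alpha)
        qmap = pd.Series(dict(zip(vus_keys, q)))
        df.loc[df["passed_filters"], "overrep_q"] = qmap.reindex(
            idx[df["passed_filters"].to_numpy()]
        ).to_numpy()

    is_plp = df["acmg"].isin(["P", "LP"])
    df["selected"] = df["passed_filters"] & (
        is_plp | ((df["acmg"] == "VUS") & (df["overrep_q"] <= cfg.fdr_alpha))
    )
    return df


def classify_hcd(
    patient_variants: pd.DataFrame, panel: pd.DataFrame
) -> tuple[bool, list[str]]:
    """hcD call for one patient from their *selected* variants.

    Rules (any fires -> hcD):
      a. any P/LP variant;
      b. any heterozygous VUS in a dominant-trait (AD or AD_AR) gene;
      c. any homozygous selected variant in a recessive-capable (AR/AD_AR/XL)
         gene, or >= 2 distinct heterozygous selected variants in one such
         gene (presumed compound heterozygote; unphased calls).

    X-linked hemizygous calls are encoded as ``hom`` upstream, so XL genes
    flow through rule (c). Returns ``(is_hcd, fired_rule_tags)``.
    """
    panel_map = panel.set_index("gene")["inheritance"]
    missing = set(patient_variants["gene"]) - set(panel_map.index)
    if missing:
        raise TriageError(f"genes absent from panel: {sorted(missing)}")
    tags: list[str] = []
    if patient_variants["acmg"].isin(["P", "LP"]).any():
        tags.append("a")
    for _, v in patient_variants.iterrows():
        inh = panel_map[v["gene"]]
        if v["acmg"] == "VUS" and v["zygosity"] == "het" and inh in ("AD", "AD_AR"):
            if "b" not in tags:
                tags.append("b")
    recessive = {"AR", "AD_AR", "XL"}
    for gene, grp in patient_variants.groupby("gene"):
        if panel_map[gene] not in recessive:
            continue
        hom = (grp["zygosity"] == "hom").any()
        n_het = grp.loc[grp["zygosity"] == "het", "hgvs"].nunique()
        if hom or n_het >= 2:
            if "c" not in tags:
                tags.append("c")
            break
    return bool(tags), tags


def run_triage(
    variants: pd.DataFrame,
    panel: pd.DataFrame,
    cohort_n: int,
    cohort_patient_ids: list[str] | None = None,
    cfg: RunConfig | None = None,
) -> TriageResult:
    """Filter, screen and classify; assemble per-patient and cohort results."""
    cfg = cfg or RunConfig()
    screened = overrepresentation_screen(filter_candidates(variants, cfg), cohort_n, cfg)
    selected = screened[screened["selected"]]

    if cohort_patient_ids is None:
        cohort_patient_ids = sorted(variants["patient_id"].unique())
    rows = []
    for pid in cohort_patient_ids:
        mine = selected[selected["patient_id"] == pid]
        if len(mine):
            is_hcd, tags = classify_hcd(mine, panel)
        else:
            is_hcd, tags = False, []
        rows.append({
            "patient_id": pid,
            "selected_variant_count": len(mine),
            "is_carrier": len(mine) > 0,
            "is_hcd_carrier": is_hcd,
            "hcd_rules": ",".join(tags),
        })
    per_patient = pd.DataFrame(rows)

    carriers = int(per_patient["is_carrier"].sum())
    uniq = selected.drop_duplicates(subset=["gene", "hgvs"])
    expected_probability = float(uniq["population_af"].sum())
    return TriageResult(
        variants=screened,
        per_patient=per_patient,
        cohort_n=cohort_n,
        combined_burden=carriers / cohort_n,
        expected_probability=expected_probability,
    )


def burden_statistics(
    triage: TriageResult, control_carriers: int, control_n: int
) -> dict:
    """Cohort burden summary plus the chi-square carrier comparison.

    Reports the individual burden distribution among carriers (median and
    range of selected variants per carrier), the combined burden, hcD
    frequency, the simplified expected probability (sum of selected variants'
    population AFs), and Pearson's chi-square on
    ``[[carriers, n - carriers], [control_carriers, control_n - control_carriers]]``.
    """
    if control_n <= 0:
        raise TriageError("control_n must be positive")
    pp = triage.per_patient
    carriers = int(pp["is_carrier"].sum())
    if carriers > triage.cohort_n:
        raise TriageError("carriers exceed cohort size")
    if control_carriers > control_n:
        raise TriageError("control carriers exceed control size")
    carrier_counts = pp.loc[pp["is_carrier"], "selected_variant_count"]
    hcd = int(pp["is_hcd_carrier"].sum())

    if carriers == 0 and control_carriers == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chi_square_test(stats.ContingencyTable((
            (carriers, triage.cohort_n - carriers),
            (control_carriers, control_n - control_carriers),
        )))
    summary = {
        "cohort_n": triage.cohort_n,
        "carriers": carriers,
        "combined_burden": carriers / triage.cohort_n,
        "combined_burden_pct": round_half_up_percent(carriers, triage.cohort_n),
        "hcd_carriers": hcd,
        "hcd_rate": hcd / triage.cohort_n,
        "hcd_rate_pct": round_half_up_percent(hcd, triage.cohort_n),
        "median_variants_in_carriers": float(carrier_counts.median()) if carriers else 0.0,
        "min_variants_in_carriers": int(carrier_counts.min()) if carriers else 0,
        "max_variants_in_carriers": int(carrier_counts.max()) if carriers else 0,
        "expected_probability": triage.expected_probability,
        "control_carriers": control_carriers,
        "control_n": control_n,
        "control_burden": control_carriers / control_n,
        "chi2_statistic": chi2,
        "chi2_p": p,
    }
    triage.summary = summary
    return summary
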