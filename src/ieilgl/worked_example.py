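"""A compact reference cohort encoding the headline tallies of a 92-patient
T-LGLL immunogenomic study, for demonstration and verification.

The builders construct input tables whose counts match the published cohort
summary — 43 selected germline IEI variants (40 VUS, 3 P/LP) in 38 genes
carried by 34 of 92 patients (median 1 per carrier, range 1-3), 15 hcD
carriers, 167 of 63,026 control carriers, 64 of 201 hypogammaglobulinemic
patients (39 with a plausible acquired cause), 186 of 241 with an immune
defect, 91 somatic driver variants in 30 genes across 62 of 92 patients (42
STAT3-mutated), and 227 reference-matched expanded clonotypes of which 185
are pathogen-directed. Running the pipeline's summary operations over these
tables reproduces the headline percentages, so the tables double as an
end-to-end worked example.
"""

from __future__ import annotations

import pandas as pd

from ieilgl.repertoire import Clonotype, Repertoire

CONTROL_CARRIERS = 167
CONTROL_N = 63026


def germline_example() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Germline variant table + IEI panel: 43 variants in 34 of 92 carriers.

    Carrier multiplicity is 27 x 1, 5 x 2, 2 x 3 (median 1, range 1-3,
    total 43). Three variants are P/LP; the remaining 40 are VUS with very
    low population frequency so a single cohort observation is already
    overrepresented. Genes are arranged so exactly 15 carriers satisfy an
    hcD rule: 3 via P/LP (rule a) and 12 via a heterozygous VUS in a
    dominant-trait gene (rule b); every other VUS sits in a recessive gene.
    """
    multiplicity = [1] * 27 + [2] * 5 + [3] * 2  # 34 carriers, 43 variants
    rows = []
    n_genes = 38
    gene_of = [f"IEI{i:03d}" for i in range(n_genes)]
    # variants 0..2 are P/LP (their carriers are hcD via rule a);
    # variants 3..14 are VUS in AD genes (rule b); the rest are VUS in AR genes
    variant_idx = 0
    for c, mult in enumerate(multiplicity):
        pid = f"P{c:03d}"
        for _ in range(mult):
            # beyond the 38 distinct genes, reuse recessive genes so no
            # additional carrier picks up a dominant-trait (rule b) variant
            gi = variant_idx if variant_idx < n_genes else 15 + (variant_idx - n_genes) % 23
            gene = gene_of[gi]
            acmg = "P" if variant_idx < 3 else "VUS"
            rows.append({
                "patient_id": pid, "gene": gene, "hgvs": f"c.{variant_idx + 1}A>G",
                "consequence": "missense", "population_af": 1e-6, "acmg": acmg,
                "zygosity": "het", "vaf": 0.48, "depth": 80, "alt_reads": 38,
                "in_repetitive_region": False, "matches_somatic_call": False,
            })
            variant_idx += 1
    variants = pd.DataFrame(rows)
    inheritance = ["AD" if i < 15 else "AR" for i in range(n_genes)]
    panel = pd.DataFrame({
        "gene": gene_of,
        "iuis_category": ["immune_dysregulation" if i < 15 else "combined_TB"
                          for i in range(n_genes)],
        "inheritance": inheritance,
        "onset": ["adult"] * n_genes,
    })
    return variants, panel


def cohort_patient_ids() -> list[str]:
    return [f"P{i:03d}" for i in range(92)]


def clinical_example() -> pd.DataFrame:
    """Clinical table with the published phenotype tallies.

    241 patients with blood counts; immunoglobulins measured in the first
    201, of whom 64 are hypogammaglobulinemic (IgA low in 32, i.e. 16%, IgG
    low in the other 32) and 39 of the 64 carry an acquired-cause history
    flag. 122 further patients are lymphocytopenic, so 186 of 241 (77%) have
    an immune defect.
    """
    rows = []
    for i in range(241):
        row: dict = {"patient_id": f"C{i:03d}"}
        hypo = i < 64
        row["alc"] = 0.5 if 64 <= i < 186 else 2.0
        if i < 201:
            row["IgA"] = 40.0 if i < 32 else 200.0
            row["IgG"] = 500.0 if 32 <= i < 64 else 1000.0
            row["IgM"] = 150.0
        row["anti_b_cell_therapy"] = bool(hypo and i < 39)
        rows.append(row)
    return pd.DataFrame(rows)


def somatic_example() -> tuple[pd.DataFrame, list[str], list[str]]:
    """Somatic driver table: 91 P/LP variants, 30 genes, 62 of 92 carriers.

    42 patients are STAT3-mutated (25 of them also carry another driver);
    20 further patients carry non-STAT3 drivers only. Returns the variant
    table, the driver panel and the cohort patient ids.
    """
    other_genes = [f"DRV{i:02d}" for i in range(29)]
    rows = []
    other_count = 0
    for i in range(92):
        pid = f"P{i:03d}"
        if i < 42:  # STAT3-mutated
            rows.append({"patient_id": pid, "gene": "STAT3",
                         "consequence": "missense", "pathogenicity": "P", "vaf": 0.2})
            if i < 25:  # coexistence with another driver
                rows.append({"patient_id": pid, "gene": other_genes[other_count % 29],
                             "consequence": "missense", "pathogenicity": "LP", "vaf": 0.1})
                other_count += 1
        elif i < 62:  # non-STAT3 drivers only
            rows.append({"patient_id": pid, "gene": other_genes[other_count % 29],
                         "consequence": "nonsense", "pathogenicity": "P", "vaf": 0.15})
            other_count += 1
            if i < 46:  # four two-hit patients bring the total to 91 variants
                rows.append({"patient_id": pid, "gene": other_genes[(other_count + 7) % 29],
                             "consequence": "frameshift", "pathogenicity": "LP", "vaf": 0.1})
    variants = pd.DataFrame(rows)
    panel = ["STAT3"] + other_genes
    return variants, panel, cohort_patient_ids()


def hcd_somatic_example() -> tuple[pd.DataFrame, list[str], list[str]]:
    """Driver table for the 15 hcD carriers: 4 STAT3-mutated (1 with a
    second driver), 9 with non-STAT3 drivers in total."""
    rows = []
    for i in range(15):
        pid = f"H{i:02d}"
        if i < 4:
            rows.append({"patient_id": pid, "gene": "STAT3",
                         "consequence": "missense", "pathogenicity": "P", "vaf": 0.2})
        if i in (3, 4, 5, 6, 7, 8, 9, 10, 11):  # 9 with other drivers (1 overlap)
            rows.append({"patient_id": pid, "gene": "TNFAIP3",
                         "consequence": "missense", "pathogenicity": "LP", "vaf": 0.1})
    panel = ["STAT3", "TNFAIP3"]
    return pd.DataFrame(rows), panel, [f"H{i:02d}" for i in range(15)]


def specificity_example() -> tuple[Repertoire, pd.DataFrame]:
    """Expanded clonotypes with 227 reference matches, 185 pathogen-directed."""
    clones = [Clonotype(f"CASSEX{i}F", templates=20) for i in range(250)]
    rows = []
    for i in range(227):
        category = ("infection" if i < 185
                    else "autoimmunity" if i < 206 else "tumor_surveillance")
        rows.append({"cdr3_aa": clones[i].cdr3_aa,
                     "condition_category": category,
                     "condition_label": f"{category}_{i}"})
    reference = pd.DataFrame(rows)
    return Repertoire("EXPANDED", clones), reference
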