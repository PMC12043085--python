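"""Synthetic cohort generator: every pipeline input with planted, labelled
statistical structure.

The generator emulates the study's inputs at their analysis scale — 92
whole-exome patients, 201-241 clinically phenotyped patients, ImmunoSEQ-style
clonotype tables rarefied to thousands of templates — with controllable
effect sizes: germline variants planted at an enrichment factor over their
population frequency, hyperexpanded clones planted above the 10-template
bound, expression shifts planted on score genes in designated cell groups,
and clinical analytes drawn so a target fraction falls below the lower normal
bound. Truth labels are always emitted alongside the data; downstream
recovery tests consume them.

All draws flow from ``numpy.random.default_rng`` (PCG64) seeded from the
spec, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ieilgl.repertoire import Repertoire, Clonotype

AA = "ACDEFGHIKLMNPQRSTVWY"


class SimulationError(ValueError):
    pass


@dataclass
class PlantedVariant:
    gene: str
    population_af: float
    cohort_enrichment_factor: float
    acmg: str = "VUS"
    inheritance: str = "AD"

    def __post_init__(self) -> None:
        if self.cohort_enrichment_factor < 1:
            raise SimulationError("enrichment must be >= 1")
        if not 0 <= self.population_af <= 1:
            raise SimulationError("population_af must lie in [0, 1]")


def default_planted_variants() -> list[PlantedVariant]:
    """Eight rare VUS planted at 50x their population frequency in AD genes."""
    return [
        PlantedVariant(gene=f"IEIG{i:03d}", population_af=1e-4,
                       cohort_enrichment_factor=50.0, acmg="VUS", inheritance="AD")
        for i in range(8)
    ]


@dataclass
class SimulationSpec:
    """Knobs of the synthetic cohort; defaults encode the study conditions."""

    n_patients: int = 92
    n_clinical_patients: int = 201
    n_panel_genes: int = 60
    planted_variants: list[PlantedVariant] = field(default_factory=default_planted_variants)
    n_null_variants: int = 40
    null_af: float = 5e-4
    # somatic: driver rates from the cohort tallies (STAT3 46%, other drivers 49%)
    stat3_rate: float = 0.46
    other_rate: float = 0.49
    burden_max: int = 4
    # repertoire: heavy-tailed clone sizes, planted hyperexpansions
    n_clonotypes: int = 10_000
    powerlaw_exponent: float = 2.5
    planted_hyperexpanded: int = 5
    planted_hyperexpanded_sizes: tuple[int, int] = (50, 2000)
    n_reference_clonotypes: int = 2000
    reference_match_fraction: dict[str, float] = field(default_factory=lambda: {
        "infection": 0.02, "autoimmunity": 0.01, "tumor_surveillance": 0.01,
    })
    # expression: three cell groups, shift on score genes in the designated group
    n_cells_per_group: int = 300
    n_genes: int = 500
    expression_shift: float = 1.0
    shifted_group: str = "STAT3mt"
    noise_sd: float = 1.0
    # clinical: target fractions below the lower normal bound
    hypogamma_fraction: float = 0.32
    acquired_cause_fraction: float = 0.61
    lymphopenia_fraction: float = 0.10
    subset_low_fractions: dict[str, float] = field(default_factory=lambda: {
        "CD3": 0.20, "CD4": 0.35, "CD8": 0.15, "NK": 0.58, "B": 0.44,
    })
    analyte_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stat3_rate", "other_rate", "hypogamma_fraction",
                     "acquired_cause_fraction", "lymphopenia_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if sum(self.reference_match_fraction.values()) > 1:
            raise SimulationError("reference match fractions must sum to <= 1")


def _rng(spec: SimulationSpec, stage: str) -> np.random.Generator:
    # stable stage hash: process-salted builtin hash() would break determinism
    stage_key = zlib.crc32(stage.encode())
    return np.random.default_rng([spec.seed % (2**31), stage_key % (2**31)])


# ---------------------------------------------------------------- germline

def simulate_germline(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Germline variant table + IEI panel + per-variant truth labels.

    Each planted variant appears heterozygous in each patient independently
    with probability ``min(2 * af * enrichment, 0.5)``; null variants with
    probability ``2 * af``. Read depth ~ NegBin(mean 80, dispersion 0.2);
    het VAF ~ Beta(20, 20). Variants observed in no patient are absent from
    the table (as in real calling).
    """
    rng = _rng(spec, "germline")
    patients = [f"P{i:03d}" for i in range(1, spec.n_patients + 1)]

    genes = [f"IEIG{i:03d}" for i in range(spec.n_panel_genes)]
    inh = rng.choice(["AD", "AR", "XL", "AD_AR"], size=spec.n_panel_genes,
                     p=[0.35, 0.45, 0.08, 0.12])
    # planted variants dictate their gene's inheritance
    planted_genes = {pv.gene: pv.inheritance for pv in spec.planted_variants}
    panel = pd.DataFrame({
        "gene": genes,
        "iuis_category": rng.choice(
            ["combined_TB", "immune_dysregulation", "BMF", "phagocyte",
             "B_cell", "innate", "other"], size=spec.n_panel_genes),
        "inheritance": [planted_genes.get(g, i) for g, i in zip(genes, inh)],
        "onset": rng.choice(["early", "adult"], size=spec.n_panel_genes, p=[0.4, 0.6]),
    })

    specs = []
    for i, pv in enumerate(spec.planted_variants):
        if pv.gene not in set(genes):
            raise SimulationError(f"planted gene {pv.gene} outside panel")
        prob = 2.0 * pv.population_af * pv.cohort_enrichment_factor
        if prob > 0.5:
            raise SimulationError(f"planted carrier probability {prob:.3f} exceeds cap 0.5")
        specs.append((pv.gene, f"c.{100+i}A>G", pv.population_af, pv.acmg, prob, True))
    null_gene_pool = [g for g in genes if g not in planted_genes]
    for i in range(spec.n_null_variants):
        gene = null_gene_pool[i % len(null_gene_pool)]
        specs.append((gene, f"c.{1000+i}C>T", spec.null_af, "VUS",
                      2.0 * spec.null_af, False))

    rows, truth_rows = [], []
    for gene, hgvs, af, acmg, prob, planted in specs:
        carriers = [p for p in patients if rng.random() < prob]
        truth_rows.append({"gene": gene, "hgvs": hgvs, "population_af": af,
                           "planted": planted, "n_carriers": len(carriers)})
        for pid in carriers:
            depth = max(int(rng.negative_binomial(5, 5 / 85.0)), 1)
            vaf = float(rng.beta(20, 20))
            alt = min(depth, max(0, round(vaf * depth)))
            rows.append({
                "patient_id": pid, "gene": gene, "hgvs": hgvs,
                "consequence": "missense", "population_af": af, "acmg": acmg,
                "zygosity": "het", "vaf": vaf, "depth": depth, "alt_reads": alt,
                "in_repetitive_region": False, "matches_somatic_call": False,
            })
    variants = pd.DataFrame(rows, columns=[
        "patient_id", "gene", "hgvs", "consequence", "population_af", "acmg",
        "zygosity", "vaf", "depth", "alt_reads", "in_repetitive_region",
        "matches_somatic_call"])
    return variants, panel, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------- somatic

def simulate_somatic(spec: SimulationSpec, driver_panel: list[str] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic driver variant table + per-patient truth configuration."""
    from ieilgl.somatic import DEFAULT_DRIVER_PANEL

    rng = _rng(spec, "somatic")
    panel = driver_panel or DEFAULT_DRIVER_PANEL
    others = [g for g in panel if g != "STAT3"]
    patients = [f"P{i:03d}" for i in range(1, spec.n_patients + 1)]
    rows, truth = [], []
    for pid in patients:
        has_stat3 = rng.random() < spec.stat3_rate
        n_other = 0
        if rng.random() < spec.other_rate:
            n_other = int(rng.integers(1, spec.burden_max - int(has_stat3) + 1))
        if has_stat3:
            rows.append({"patient_id": pid, "gene": "STAT3",
                         "consequence": "missense", "pathogenicity": "P",
                         "vaf": float(rng.beta(2, 6))})
        for g in rng.choice(others, size=n_other, replace=False):
            rows.append({"patient_id": pid, "gene": str(g),
                         "consequence": str(rng.choice(["missense", "nonsense", "frameshift"])),
                         "pathogenicity": str(rng.choice(["P", "LP"])),
                         "vaf": float(rng.beta(2, 6))})
        truth.append({"patient_id": pid, "stat3_mutated": has_stat3,
                      "n_other_drivers": n_other})
    cols = ["patient_id", "gene", "consequence", "pathogenicity", "vaf"]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(truth)


# -------------------------------------------------------------- repertoire

def _random_cdr3(rng: np.random.Generator) -> str:
    middle = "".join(rng.choice(list(AA), size=int(rng.integers(6, 13))))
    return f"CASS{middle}F"


def simulate_repertoire(spec: SimulationSpec) -> tuple[Repertoire, pd.DataFrame, pd.DataFrame]:
    """One repertoire + specificity reference + per-clone truth labels.

    Background clone sizes follow a discrete power law (Zipf, configurable
    exponent) truncated at 10 templates so the planted hyperexpanded clones
    (sizes drawn log-uniformly from the configured range, all > 10) are the
    exact hyperexpansion truth. A configured fraction of clones copies its
    CDR3 from the generated reference, per condition category.
    """
    rng = _rng(spec, "repertoire")
    n = spec.n_clonotypes
    sizes = rng.zipf(spec.powerlaw_exponent, size=2 * n)
    sizes = sizes[sizes <= 10][:n]
    while len(sizes) < n:
        extra = rng.zipf(spec.powerlaw_exponent, size=n)
        sizes = np.concatenate([sizes, extra[extra <= 10]])[:n]

    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < n + spec.n_reference_clonotypes:
        c = _random_cdr3(rng)
        if c not in seen:
            seen.add(c)
            cdr3s.append(c)
    sample_cdr3s = cdr3s[:n]
    ref_cdr3s = cdr3s[n:]

    categories = list(spec.reference_match_fraction)
    ref_rows = []
    for i, c in enumerate(ref_cdr3s):
        cat = categories[i % len(categories)] if categories else "other"
        ref_rows.append({"cdr3_aa": c, "condition_category": cat,
                         "condition_label": f"{cat}_{i}"})
    reference = pd.DataFrame(ref_rows, columns=["cdr3_aa", "condition_category",
                                                "condition_label"])

    # overwrite a planted fraction of sample CDR3s with reference sequences
    matched_category = np.array([""] * n, dtype=object)
    cursor = 0
    for cat, frac in spec.reference_match_fraction.items():
        k = int(round(frac * n))
        pool = reference[reference["condition_category"] == cat]["cdr3_aa"].tolist()
        for j in range(k):
            idx = cursor + j
            sample_cdr3s[idx] = pool[j % len(pool)]
            matched_category[idx] = cat
        cursor += k

    hyper_flags = np.zeros(n, dtype=bool)
    lo, hi = spec.planted_hyperexpanded_sizes
    if lo <= 10:
        raise SimulationError("planted hyperexpanded sizes must exceed 10 templates")
    hyper_idx = rng.choice(n, size=spec.planted_hyperexpanded, replace=False)
    for idx in hyper_idx:
        sizes[idx] = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        hyper_flags[idx] = True

    clones = [
        Clonotype(cdr3_aa=c, templates=int(s), in_frame=True, has_stop=False)
        for c, s in zip(sample_cdr3s, sizes)
    ]
    truth = pd.DataFrame({
        "cdr3_aa": sample_cdr3s,
        "templates": sizes.astype(int),
        "planted_hyperexpanded": hyper_flags,
        "matched_category": matched_category,
    })
    return Repertoire("SIM", clones), reference, truth


# -------------------------------------------------------------- expression

def simulate_expression(spec: SimulationSpec, score_genes: list[str] | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells x genes matrix + cell annotation.

    Per-gene baselines are spread uniformly over [0, 4] (log-normalized
    scale) so expression-bin matching has structure; cell values are
    Normal(baseline, noise_sd); cells of the designated group get +shift on
    the score genes.
    """
    rng = _rng(spec, "expression")
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    if score_genes is None:
        score_genes = genes[: 15]
    missing = set(score_genes) - set(genes)
    if missing:
        raise SimulationError(f"score genes outside simulated gene space: {sorted(missing)}")
    groups = ["STAT3mt", "STAT3wt", "healthy_control"]
    baselines = rng.uniform(0.0, 4.0, size=spec.n_genes)
    cell_ids, cell_groups = [], []
    for g in groups:
        for i in range(spec.n_cells_per_group):
            cell_ids.append(f"{g}_{i:04d}")
            cell_groups.append(g)
    values = rng.normal(baselines, spec.noise_sd,
                        size=(len(cell_ids), spec.n_genes))
    shift_cols = [genes.index(g) for g in score_genes]
    shift_rows = [i for i, g in enumerate(cell_groups) if g == spec.shifted_group]
    values[np.ix_(shift_rows, shift_cols)] += spec.expression_shift
    matrix = pd.DataFrame(values, index=cell_ids, columns=genes)
    annotation = pd.DataFrame({
        "cell_id": cell_ids,
        "clone_id": [f"clone_{g}" for g in cell_groups],
        "clone_templates": 50,
        "group": cell_groups,
    })
    return matrix, annotation


# ---------------------------------------------------------------- clinical

def _lognormal_with_low_fraction(rng, low: float, frac_low: float,
                                 sigma: float, size: int) -> np.ndarray:
    """Lognormal draws with P(X < low) = frac_low exactly (by construction)."""
    mu = np.log(low) - sigma * sps.norm.ppf(frac_low)
    return rng.lognormal(mu, sigma, size=size)


def simulate_clinical(spec: SimulationSpec, ranges: dict[str, tuple[float, float]] | None = None
                      ) -> pd.DataFrame:
    """Clinical table (labs + history flags) hitting the target low fractions.

    Hypogammaglobulinemia is drawn at the patient level with probability
    ``hypogamma_fraction``; affected patients get at least one Ig isotype
    below its bound, others have all isotypes within/above range. Among
    hypogammaglobulinemic patients, acquired-cause history flags are set with
    probability ``acquired_cause_fraction``.
    """
    from ieilgl.config import DEFAULT_NORMAL_RANGES

    rng = _rng(spec, "clinical")
    ranges = ranges or DEFAULT_NORMAL_RANGES
    n = spec.n_clinical_patients
    rows = []
    sigma = spec.analyte_sigma
    for i in range(n):
        row: dict = {"patient_id": f"C{i:03d}"}
        lymphopenic = rng.random() < spec.lymphopenia_fraction
        if lymphopenic:
            row["alc"] = float(rng.uniform(0.2, 0.99))
        else:
            row["alc"] = float(_lognormal_with_low_fraction(rng, 1.0, 1e-6, 0.5, 1)[0])
        row["lgl_count"] = float(rng.lognormal(np.log(1.0), 0.6))
        for analyte, frac in spec.subset_low_fractions.items():
            low = ranges[analyte][0]
            row[analyte] = float(_lognormal_with_low_fraction(rng, low, frac, sigma, 1)[0])
        hypo = rng.random() < spec.hypogamma_fraction
        ig_lows = {"IgG": 0.45, "IgA": 0.50, "IgM": 0.56}  # conditional isotype mix
        any_low = False
        for ig, p_low in ig_lows.items():
            low, high = ranges[ig]
            if hypo and rng.random() < p_low:
                row[ig] = float(rng.uniform(0.3 * low, 0.95 * low))
                any_low = True
            else:
                row[ig] = float(rng.uniform(low * 1.02, high))
        if hypo and not any_low:
            row["IgG"] = float(rng.uniform(0.3 * ranges["IgG"][0], 0.95 * ranges["IgG"][0]))
        acquired = hypo and rng.random() < spec.acquired_cause_fraction
        flags = ["prior_hematolymphoid_neoplasm", "anti_b_cell_therapy",
                 "other_immunosuppression", "chemo", "good_syndrome_or_cvid_like",
                 "transplant"]
        for f in flags:
            row[f] = False
        if acquired:
            row[str(rng.choice(flags))] = True
        row["family_history_immune_or_hematolymphoid"] = bool(rng.random() < 0.10)
        rows.append(row)
    return pd.DataFrame(rows)
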