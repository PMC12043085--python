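"""Clinical immune-defect phenotyping against laboratory normal ranges.

A patient's labs (absolute lymphocyte count, lymphocyte subsets by flow
cytometry, immunoglobulin levels) are compared with configured normal ranges
to flag deficits; hypogammaglobulinemia (any Ig isotype below its lower
bound) is screened for plausible acquired causes from the clinical history;
and cohort-level tallies report each deficit over the patients in whom the
analyte was actually measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ieilgl.config import RunConfig

SUBSET_ANALYTES = ("CD3", "CD4", "CD8", "NK", "B")
IG_ANALYTES = ("IgG", "IgA", "IgM")

#: History flags that make hypogammaglobulinemia a plausible acquired finding.
ACQUIRED_CAUSE_FLAGS = (
    "prior_hematolymphoid_neoplasm",
    "anti_b_cell_therapy",
    "other_immunosuppression",
    "chemo",
    "good_syndrome_or_cvid_like",
    "transplant",
)


class LabsError(ValueError):
    pass


@dataclass
class PatientLabs:
    """One patient's laboratory values. Counts in 1e9 cells/L, Ig in mg/dL.

    Analytes not measured are simply absent from the mappings (``None`` for
    the scalar counts) and never contribute to flags or denominators.
    """

    patient_id: str
    alc: float | None = None
    lgl_count: float | None = None
    subsets: dict[str, float] = field(default_factory=dict)
    ig: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in [("alc", self.alc), ("lgl_count", self.lgl_count),
                            *self.subsets.items(), *self.ig.items()]:
            if value is not None and (value < 0 or math.isnan(value)):
                raise LabsError(f"{name} must be >= 0, got {value!r}")


@dataclass
class HistoryFlags:
    """Clinical-history booleans screened as acquired causes of hypogamma."""

    prior_hematolymphoid_neoplasm: bool = False
    anti_b_cell_therapy: bool = False
    other_immunosuppression: bool = False
    chemo: bool = False
    good_syndrome_or_cvid_like: bool = False
    transplant: bool = False
    family_history_immune_or_hematolymphoid: bool = False

    def any_acquired_cause(self) -> bool:
        return any(getattr(self, f) for f in ACQUIRED_CAUSE_FLAGS)


@dataclass
class ImmunePhenotype:
    """Derived immune-defect phenotype for one patient.

    ``low_flags`` holds a boolean per analyte that was measured; analytes
    never measured are absent (not False). ``hypogamma_cause`` is
    ``not_applicable`` exactly when there is no hypogammaglobulinemia.
    """

    patient_id: str
    low_flags: dict[str, bool] = field(default_factory=dict)
    hypogamma_any: bool | None = None
    hypogamma_cause: str = "not_applicable"
    lymphocytopenia: bool | None = None
    low_or_normal_alc: bool | None = None
    immune_defect: bool | None = None

    def __post_init__(self) -> None:
        if self.hypogamma_any:
            if self.hypogamma_cause == "not_applicable":
                raise LabsError("hypogamma without a cause classification")
        elif self.hypogamma_cause != "not_applicable":
            raise LabsError("cause classification without hypogamma")


def classify_labs(labs: PatientLabs, cfg: RunConfig | None = None) -> ImmunePhenotype:
    """Flag each measured analyte as low against its configured normal range.

    An analyte is low iff its value is strictly below the range's lower
    bound. ``low_or_normal_alc`` is true iff ALC <= the configured threshold
    (default 4.0 x 1e9/L); ``lymphocytopenia`` iff ALC < the lymphopenia
    bound (default 1.0). Missing analytes yield absent flags, never False.
    """
    cfg = cfg or RunConfig()
    ranges = cfg.normal_ranges
    low_flags: dict[str, bool] = {}
    for analyte in (*SUBSET_ANALYTES, *IG_ANALYTES):
        value = labs.subsets.get(analyte) if analyte in SUBSET_ANALYTES else labs.ig.get(analyte)
        if value is None or analyte not in ranges:
            continue
        low_flags[analyte] = value < ranges[analyte][0]
    measured_any = bool(low_flags) or labs.alc is not None
    if not measured_any:
        raise LabsError(f"patient {labs.patient_id}: no analyte present")

    hypogamma: bool | None
    measured_igs = [a for a in IG_ANALYTES if a in low_flags]
    hypogamma = any(low_flags[a] for a in measured_igs) if measured_igs else None

    lymphocytopenia = low_or_normal = None
    if labs.alc is not None:
        lymphocytopenia = labs.alc < cfg.lymphopenia_threshold
        low_or_normal = labs.alc <= cfg.low_normal_alc_threshold

    immune_defect: bool | None = None
    if lymphocytopenia is not None or hypogamma is not None:
        immune_defect = bool(lymphocytopenia) or bool(hypogamma)

    return ImmunePhenotype(
        patient_id=labs.patient_id,
        low_flags=low_flags,
        hypogamma_any=hypogamma,
        hypogamma_cause="unexplained" if hypogamma else "not_applicable",
        lymphocytopenia=lymphocytopenia,
        low_or_normal_alc=low_or_normal,
        immune_defect=immune_defect,
    )


def screen_hypogamma_cause(pheno: ImmunePhenotype, history: HistoryFlags) -> str:
    """Classify hypogammaglobulinemia as acquired-candidate or unexplained.

    ``acquired_candidate`` iff the patient is hypogammaglobulinemic and any
    acquired-cause history flag (prior hemato-lymphoid neoplasm, anti-B-cell
    or other immunosuppressive therapy, chemotherapy, Good syndrome or
    CVID-like condition, transplant) is set; ``unexplained`` iff
    hypogammaglobulinemic with no flag; ``not_applicable`` otherwise.
    """
    if not pheno.hypogamma_any:
        cause = "not_applicable"
    elif history.any_acquired_cause():
        cause = "acquired_candidate"
    else:
        cause = "unexplained"
    pheno.hypogamma_cause = cause
    return cause


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer percent with ties rounded away from zero (reporting style)."""
    if denominator == 0:
        raise LabsError("zero denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def summarize_cohort_phenotypes(phenotypes: list[ImmunePhenotype]) -> pd.DataFrame:
    """Per-flag counts and proportions over the patients assessed for it.

    Returns one row per statistic with columns ``statistic``, ``numerator``,
    ``denominator``, ``fraction``, ``percent`` (half-up integer percent).
    Denominators count only patients in whom the analyte/composite was
    evaluable, so no denominator can exceed the cohort size.
    """
    if not phenotypes:
        raise LabsError("empty cohort")
    rows = []

    def tally(name: str, values: list[bool | None]) -> None:
        present = [v for v in values if v is not None]
        if not present:
            return
        num, den = sum(present), len(present)
        rows.append({
            "statistic": name, "numerator": num, "denominator": den,
            "fraction": num / den, "percent": round_half_up_percent(num, den),
        })

    analytes = sorted({a for p in phenotypes for a in p.low_flags})
    for analyte in analytes:
        tally(f"low_{analyte}", [p.low_flags.get(analyte) for p in phenotypes])
    tally("lymphocytopenia", [p.lymphocytopenia for p in phenotypes])
    tally("low_or_normal_alc", [p.low_or_normal_alc for p in phenotypes])
    tally("hypogamma_any", [p.hypogamma_any for p in phenotypes])
    tally("immune_defect", [p.immune_defect for p in phenotypes])

    hypo = [p for p in phenotypes if p.hypogamma_any]
    if hypo:
        for cause in ("acquired_candidate", "unexplained"):
            num = sum(p.hypogamma_cause == cause for p in hypo)
            rows.append({
                "statistic": f"hypogamma_{cause}", "numerator": num,
                "denominator": len(hypo), "fraction": num / len(hypo),
                "percent": round_half_up_percent(num, len(hypo)),
            })
    return pd.DataFrame(rows, columns=["statistic", "numerator", "denominator",
                                       "fraction", "percent"])


def phenotype_cohort(clinical: pd.DataFrame, cfg: RunConfig | None = None) -> list[ImmunePhenotype]:
    """Run classification + cause screening over a validated clinical table."""
    cfg = cfg or RunConfig()

    def present(row, name):  # missing cells arrive as None or NaN
        return name in row.index and row[name] is not None and pd.notna(row[name])

    phenotypes = []
    for _, row in clinical.iterrows():
        labs = PatientLabs(
            patient_id=row["patient_id"],
            alc=float(row["alc"]) if present(row, "alc") else None,
            lgl_count=float(row["lgl_count"]) if present(row, "lgl_count") else None,
            subsets={a: float(row[a]) for a in SUBSET_ANALYTES if present(row, a)},
            ig={a: float(row[a]) for a in IG_ANALYTES if present(row, a)},
        )
        pheno = classify_labs(labs, cfg)
        history = HistoryFlags(**{
            f: bool(row[f]) for f in (*ACQUIRED_CAUSE_FLAGS,
                                      "family_history_immune_or_hematolymphoid")
            if present(row, f)
        })
        screen_hypogamma_cause(pheno, history)
        phenotypes.append(pheno)
    return phenotypes
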