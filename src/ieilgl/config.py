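"""Run configuration: the thresholds and reference ranges every stage shares.

Defaults encode the analysis constants of the study design: rare variants are
gnomAD MAF < 1%; germline calls need depth >= 10, >= 4 alternate reads and
VAF >= 40%; the VUS overrepresentation screen is controlled at FDR 0.05;
TCR repertoires are rarefied to 5,420 templates; expression-score high/low
calls use the 90th percentile. Clinical normal ranges are the flow-cytometry
and immunoglobulin reference intervals used for phenotyping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Laboratory normal ranges. Cell subsets in 1e9 cells/L; immunoglobulins in mg/dL.
DEFAULT_NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "CD3": (0.96, 2.39),
    "CD4": (0.53, 1.67),
    "CD8": (0.28, 0.96),
    "NK": (0.10, 0.57),
    "B": (0.08, 0.66),
    "IgG": (717.0, 1411.0),
    "IgA": (78.0, 391.0),
    "IgM": (53.0, 334.0),
}

#: TCR signaling gene set: TCR complex constant elements plus signalosome
#: components. Reconstruction from the genes named in the source analyses,
#: not a printed list — editable via config.
DEFAULT_TCR_GENE_SET: list[str] = [
    "TRAC", "TRDC", "CD247", "CD2", "CD3D", "CD3E", "CD3G", "CD5",
    "CD8A", "LAT", "LCK", "ZAP70", "SYK", "FYN", "PLCG1",
]

#: STAT3 activation signature. Reconstruction (9 canonical STAT3 targets),
#: not a printed list — editable via config.
DEFAULT_STAT3_GENE_SET: list[str] = [
    "SOCS3", "BCL3", "JUNB", "PIM1", "MYC", "OSM", "IL2RA", "CISH", "STAT3",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    Attributes
    ----------
    rarity_max_af:
        Maximum population (gnomAD) allele frequency for a variant to count
        as rare. Default 0.01.
    min_depth, min_alt_reads:
        Read-support filters on germline calls. Defaults 10 and 4.
    min_germline_vaf:
        Minimum variant allele fraction for a germline call; lower VAFs are
        treated as probable somatic/artifactual. Default 0.40.
    fdr_alpha:
        Benjamini-Hochberg FDR level for the VUS overrepresentation screen.
    downsample_templates:
        Rarefaction depth for TCR repertoires (templates). Default 5420.
    score_percentile:
        Quantile for expression-score high/low calls. Default 0.90.
    lymphopenia_threshold:
        ALC below this (1e9/L) is lymphocytopenia. Default 1.0.
    low_normal_alc_threshold:
        ALC at or below this (1e9/L) counts as "low/normal". Default 4.0.
    cn_gain_log2, cn_loss_log2:
        Gene-level weighted-log2 cutoffs for copy-number gain/loss calls.
    blacklist_overlap_fraction:
        Minimum fraction of a gene covered by a blacklist interval for the
        gene's CN call to be excluded. Default 0.5.
    reference_cohort_size:
        Pseudo-count denominator for variants reported with population AF 0:
        the AF is floored at 1/(2 * reference_cohort_size).
    overrep_test:
        "binomial" (exact upper tail, default) or "poisson" approximation.
    seeds:
        Stage-name -> integer seed mapping for every stochastic step.
    """

    rarity_max_af: float = 0.01
    min_depth: int = 10
    min_alt_reads: int = 4
    min_germline_vaf: float = 0.40
    fdr_alpha: float = 0.05
    downsample_templates: int = 5420
    score_percentile: float = 0.90
    lymphopenia_threshold: float = 1.0
    low_normal_alc_threshold: float = 4.0
    cn_gain_log2: float = 0.3
    cn_loss_log2: float = -0.3
    blacklist_overlap_fraction: float = 0.5
    reference_cohort_size: int = 63026
    overrep_test: str = "binomial"
    seeds: dict[str, int] = field(default_factory=dict)
    normal_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMAL_RANGES)
    )
    gene_sets: dict[str, list[str]] = field(
        default_factory=lambda: {
            "TCR": list(DEFAULT_TCR_GENE_SET),
            "STAT3": list(DEFAULT_STAT3_GENE_SET),
        }
    )

    def __post_init__(self) -> None:
        for name in ("rarity_max_af", "min_germline_vaf", "fdr_alpha", "score_percentile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.downsample_templates <= 0:
            raise ConfigError("downsample_templates must be positive")
        if self.reference_cohort_size <= 0:
            raise ConfigError("reference_cohort_size must be positive")
        if self.overrep_test not in ("binomial", "poisson"):
            raise ConfigError("overrep_test must be 'binomial' or 'poisson'")
        for analyte, bounds in self.normal_ranges.items():
            low, high = bounds
            if not low < high:
                raise ConfigError(
                    f"normal range for {analyte} must satisfy low < high, got {bounds!r}"
                )
            self.normal_ranges[analyte] = (float(low), float(high))

    def seed_for(self, stage: str, default: int = 0) -> int:
        """Seed for a named stage, falling back to ``default``."""
        return int(self.seeds.get(stage, default))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "normal_ranges" in raw:
            raw = dict(raw)
            raw["normal_ranges"] = {
                k: tuple(v) for k, v in raw["normal_ranges"].items()
            }
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        payload["normal_ranges"] = {k: list(v) for k, v in payload["normal_ranges"].items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
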