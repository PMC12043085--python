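"""End-to-end orchestration: run every stage whose inputs are present and
assemble a cohort summary mirroring the headline tallies.

Inputs live in one directory as dialect-named TSV files
(``germline_variants.tsv``, ``iei_panel.tsv``, ``somatic_variants.tsv``,
``cn_segments.tsv``, ``gene_coords.tsv``, ``repertoire.tsv``,
``specificity_reference.tsv``, ``expression.tsv``/``.mtx``,
``cell_annotation.tsv``, ``clinical.tsv``). Stages with missing inputs are
skipped; the summary records which ran. Every percentage in the summary is
stored with its numerator and denominator so it recomputes exactly, and the
run manifest carries the config hash and seeds for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from ieilgl import __version__, clinical, germline, io, repertoire as rep, scoring, somatic
from ieilgl.config import RunConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _config_hash(cfg: RunConfig) -> str:
    import dataclasses

    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _path(input_dir: Path, name: str) -> Path | None:
    p = input_dir / name
    return p if p.exists() else None


def run_phenotype_stage(input_dir: Path, cfg: RunConfig) -> dict:
    table = io.read_table(input_dir / "clinical.tsv", "clinical")
    phenos = clinical.phenotype_cohort(table, cfg)
    summary = clinical.summarize_cohort_phenotypes(phenos)
    return {"table": summary, "phenotypes": phenos,
            "stats": {r["statistic"]: {"numerator": int(r["numerator"]),
                                       "denominator": int(r["denominator"]),
                                       "percent": int(r["percent"])}
                      for _, r in summary.iterrows()}}


def run_triage_stage(input_dir: Path, cfg: RunConfig,
                     control_carriers: int | None = None,
                     control_n: int | None = None) -> dict:
    variants = io.read_table(input_dir / "germline_variants.tsv", "germline_variants")
    panel = io.read_table(input_dir / "iei_panel.tsv", "iei_panel")
    cohort_file = input_dir / "cohort_patients.txt"
    if cohort_file.exists():
        patients = cohort_file.read_text().split()
    else:
        patients = sorted(variants["patient_id"].unique())
    result = germline.run_triage(variants, panel, cohort_n=len(patients),
                                 cohort_patient_ids=patients, cfg=cfg)
    out = {"triage": result}
    if control_carriers is not None and control_n is not None:
        out["summary"] = germline.burden_statistics(result, control_carriers, control_n)
    return out


def run_somatic_stage(input_dir: Path, cfg: RunConfig,
                      driver_panel: list[str] | None = None) -> dict:
    variants = io.read_table(input_dir / "somatic_variants.tsv", "somatic_variants")
    panel = driver_panel
    panel_file = input_dir / "driver_panel.txt"
    if panel is None:
        panel = (panel_file.read_text().split() if panel_file.exists()
                 else somatic.DEFAULT_DRIVER_PANEL)
    kept = somatic.filter_driver_mutations(variants, panel)
    cohort_file = input_dir / "cohort_patients.txt"
    patients = (cohort_file.read_text().split() if cohort_file.exists()
                else sorted(variants["patient_id"].unique()))
    config_table = somatic.mutational_configuration(kept, patients)
    out = {"kept": kept, "configurations": config_table,
           "summary": somatic.summarize_landscape(config_table, kept)}
    seg_path = _path(input_dir, "cn_segments.tsv")
    coord_path = _path(input_dir, "gene_coords.tsv")
    if seg_path and coord_path:
        segments = io.read_table(seg_path, "cn_segments")
        coords = io.read_table(coord_path, "gene_coords")
        bl_path = _path(input_dir, "blacklist.bed")
        blacklists = io.read_bed(bl_path) if bl_path else None
        out["cn_calls"] = somatic.gene_level_cn(segments, coords, blacklists, cfg)
    return out


def run_repertoire_stage(input_dir: Path, cfg: RunConfig) -> dict:
    table = io.read_table(input_dir / "repertoire.tsv", "repertoire")
    out: dict = {"samples": {}}
    sample_col = table["sample_id"] if "sample_id" in table.columns else pd.Series(
        ["sample"] * len(table))
    excluded = []
    for sid, grp in table.groupby(sample_col):
        r = rep.filter_productive(rep.Repertoire.from_table(grp, str(sid)))
        try:
            down = rep.downsample(r, cfg.downsample_templates,
                                  seed=cfg.seed_for("repertoire"))
        except rep.InsufficientDepth:
            excluded.append(str(sid))
            continue
        entry: dict = {"diversity": rep.diversity_metrics(down)}
        classes = [rep.classify_expansion(c.templates)["class"] for c in down.clonotypes]
        entry["expansion_counts"] = pd.Series(classes).value_counts().to_dict()
        ref_path = _path(input_dir, "specificity_reference.tsv")
        if ref_path:
            reference = io.read_table(ref_path, "specificity_reference")
            for scope in ("whole", "pathological_only"):
                _, s = rep.annotate_specificities(down, reference, scope)
                entry[f"specificity_{scope}"] = s
        out["samples"][str(sid)] = entry
    out["excluded_insufficient_depth"] = excluded
    return out


def run_scores_stage(input_dir: Path, cfg: RunConfig) -> dict:
    expr_path = _path(input_dir, "expression.tsv") or _path(input_dir, "expression.mtx")
    matrix, _ = io.read_expression(expr_path)
    annotation = io.read_table(input_dir / "cell_annotation.tsv", "cell_annotation")
    groups = annotation.set_index("cell_id")["group"].reindex(matrix.index)
    seed = cfg.seed_for("scores")
    out: dict = {"scores": {}}
    flags = {}
    for name in ("TCR", "STAT3"):
        gene_set = cfg.gene_sets.get(name, [])
        present = [g for g in gene_set if g in matrix.columns]
        if not present:
            continue
        scores = scoring.module_score(matrix, present, seed=seed)
        flags[name] = scoring.percentile_threshold(scores, cfg.score_percentile)
        out["scores"][name] = scores
    if {"TCR", "STAT3"} <= set(flags):
        out["coexpression"] = scoring.coexpression_contingency(
            flags["STAT3"], flags["TCR"], groups, name_a="STAT3", name_b="TCR")
    out["high_flags"] = flags
    return out


STAGES = {
    "phenotype": ("clinical.tsv", run_phenotype_stage),
    "triage": ("germline_variants.tsv", run_triage_stage),
    "somatic": ("somatic_variants.tsv", run_somatic_stage),
    "repertoire": ("repertoire.tsv", run_repertoire_stage),
    "scores": ("cell_annotation.tsv", run_scores_stage),
}


def run_pipeline(cfg: RunConfig, input_dir: str | Path) -> dict:
    """Run every stage whose inputs exist; return the cohort summary.

    The summary dict has one section per executed stage plus a ``manifest``
    with config hash, seeds and package version. Deterministic given
    identical config and inputs.
    """
    input_dir = Path(input_dir)
    summary: dict = {"manifest": {
        "config_hash": _config_hash(cfg),
        "seeds": dict(cfg.seeds),
        "version": __version__,
        "stages_run": [],
    }}
    for stage, (sentinel, runner) in STAGES.items():
        if not (input_dir / sentinel).exists():
            continue
        try:
            summary[stage] = runner(input_dir, cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(stage, str(exc)) from exc
        summary["manifest"]["stages_run"].append(stage)
    return summary


def summary_to_json(summary: dict) -> str:
    """Serialize the numeric portion of a pipeline summary deterministically."""

    def default(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, pd.Series):
            return o.to_dict()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()
                    if isinstance(v, (int, float, str, bool, dict, list))}
        return str(o)

    return json.dumps(summary, default=default, sort_keys=True, indent=2)
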