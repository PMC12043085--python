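"""TCR-beta repertoire analysis: productive filtering, fixed-depth
downsampling, diversity metrics, expansion classes and CDR3 specificity
matching.

A repertoire is a bag of clonotypes (CDR3 amino-acid sequence, optional V/J
genes) each supported by a template count. Repertoires are normalized for
sequencing depth by rarefaction: exactly ``n`` templates are drawn uniformly
without replacement from the template multiset (multivariate hypergeometric),
so per-clone sampled counts never exceed the originals and totals are exact.
Samples below the rarefaction depth are excluded with an explicit signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ieilgl.clinical import round_half_up_percent


class RepertoireError(ValueError):
    pass


class InsufficientDepth(RepertoireError):
    """Sample has fewer templates than the rarefaction depth; excluded."""


@dataclass(frozen=True)
class Clonotype:
    cdr3_aa: str
    templates: int
    v_gene: str | None = None
    j_gene: str | None = None
    in_frame: bool = True
    has_stop: bool = False

    def __post_init__(self) -> None:
        if self.templates < 1:
            raise RepertoireError(f"templates must be >= 1, got {self.templates}")

    @property
    def productive(self) -> bool:
        return self.in_frame and not self.has_stop

    @property
    def key(self) -> tuple:
        """Clonotype identity: (cdr3, V, J) when V/J known, else CDR3 alone."""
        if self.v_gene or self.j_gene:
            return (self.cdr3_aa, self.v_gene, self.j_gene)
        return (self.cdr3_aa,)


@dataclass
class Repertoire:
    sample_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    @property
    def total_templates(self) -> int:
        return sum(c.templates for c in self.clonotypes)

    @property
    def unique_clonotypes(self) -> int:
        return len(self.clonotypes)

    @classmethod
    def from_table(cls, df: pd.DataFrame, sample_id: str = "sample") -> "Repertoire":
        """Build from a validated clonotype table (ImmunoSEQ-style dialect)."""
        clones = []
        for _, r in df.iterrows():
            clones.append(Clonotype(
                cdr3_aa=r["cdr3_aa"],
                templates=int(r["templates"]),
                v_gene=r.get("v_gene"),
                j_gene=r.get("j_gene"),
                in_frame=bool(r["in_frame"]) if r.get("in_frame") is not None else True,
                has_stop=bool(r["has_stop"]) if r.get("has_stop") is not None else False,
            ))
        sid = df["sample_id"].iloc[0] if "sample_id" in df.columns and len(df) else sample_id
        return cls(sample_id=sid, clonotypes=clones)


def filter_productive(rep: Repertoire) -> Repertoire:
    """Retain only productive rearrangements (in frame, no stop codon)."""
    return Repertoire(rep.sample_id, [c for c in rep.clonotypes if c.productive])


def downsample(rep: Repertoire, n: int = 5420, seed: int = 0) -> Repertoire:
    """Rarefy to exactly ``n`` templates, uniformly without replacement.

    Raises :class:`InsufficientDepth` when the repertoire holds fewer than
    ``n`` templates (the sample is excluded from normalized comparisons).
    Bit-reproducible for a fixed seed. Clonotypes drawn zero times are
    dropped.
    """
    if n <= 0:
        raise RepertoireError("rarefaction depth must be positive")
    total = rep.total_templates
    if total < n:
        raise InsufficientDepth(
            f"sample {rep.sample_id}: {total} templates < rarefaction depth {n}"
        )
    if total == n:
        return Repertoire(rep.sample_id, list(rep.clonotypes))
    rng = np.random.default_rng(seed)
    counts = np.array([c.templates for c in rep.clonotypes], dtype=np.int64)
    sampled = rng.multivariate_hypergeometric(counts, n)
    kept = [replace(c, templates=int(k))
            for c, k in zip(rep.clonotypes, sampled) if k > 0]
    return Repertoire(rep.sample_id, kept)


def downsample_unique(rep: Repertoire, n: int, seed: int = 0) -> Repertoire:
    """Alternative rarefaction unit: draw ``n`` unique clonotypes uniformly."""
    if n <= 0:
        raise RepertoireError("rarefaction depth must be positive")
    if rep.unique_clonotypes < n:
        raise InsufficientDepth(
            f"sample {rep.sample_id}: {rep.unique_clonotypes} clonotypes < {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(rep.unique_clonotypes, size=n, replace=False)
    return Repertoire(rep.sample_id, [rep.clonotypes[i] for i in sorted(idx)])


def diversity_metrics(rep: Repertoire) -> dict:
    """Unique clonotypes, inverse Simpson index, and mean clone size.

    Inverse Simpson = 1 / sum(p_i^2) with p_i the template share of clone i;
    it ranges from 1 (monoclonal) to the number of clonotypes (even spread).
    """
    if not rep.clonotypes:
        raise RepertoireError("empty repertoire")
    counts = np.array([c.templates for c in rep.clonotypes], dtype=float)
    p = counts / counts.sum()
    return {
        "unique_clonotypes": len(counts),
        "inverse_simpson": float(1.0 / np.sum(p ** 2)),
        "mean_clone_size": float(counts.sum() / len(counts)),
    }


def classify_expansion(templates: int) -> dict:
    """Expansion class from template count.

    Classes: nonexpanded (1), normal (2-5), pathological (>5), hyperexpanded
    (>10). Hyperexpanded clones are a nested subset of pathological ones, so
    both flags are reported alongside the finest class label.
    """
    if templates < 1:
        raise RepertoireError(f"templates must be >= 1, got {templates}")
    if templates == 1:
        label = "nonexpanded"
    elif templates <= 5:
        label = "normal"
    elif templates <= 10:
        label = "pathological"
    else:
        label = "hyperexpanded"
    return {
        "class": label,
        "pathological": templates > 5,
        "hyperexpanded": templates > 10,
    }


def annotate_specificities(
    rep: Repertoire, reference: pd.DataFrame, scope: str = "whole"
) -> tuple[pd.DataFrame, dict]:
    """Exact-CDR3 matches against a clonotype-specificity reference.

    ``scope`` is ``whole`` or ``pathological_only`` (>5 templates). A
    clonotype matching reference entries in several condition categories
    counts once per category and is flagged ambiguous. Returns the per-match
    table and a summary with matched fraction and per-category proportions of
    matched clonotypes.
    """
    if reference.empty:
        raise RepertoireError("specificity reference must be non-empty")
    if scope not in ("whole", "pathological_only"):
        raise RepertoireError(f"unknown scope {scope!r}")
    clones = [c for c in rep.clonotypes
              if scope == "whole" or c.templates > 5]
    ref_by_cdr3: dict[str, list[tuple[str, str]]] = {}
    for _, r in reference.iterrows():
        ref_by_cdr3.setdefault(r["cdr3_aa"], []).append(
            (r["condition_category"], r["condition_label"])
        )
    rows = []
    matched = 0
    cat_counts: dict[str, int] = {}
    for c in clones:
        hits = ref_by_cdr3.get(c.cdr3_aa)
        if not hits:
            continue
        matched += 1
        cats = sorted({cat for cat, _ in hits})
        for cat, label in hits:
            rows.append({
                "cdr3_aa": c.cdr3_aa, "templates": c.templates,
                "condition_category": cat, "condition_label": label,
                "ambiguous": len(cats) > 1,
            })
        for cat in cats:
            cat_counts[cat] = cat_counts.get(cat, 0) + 1
    n_scope = len(clones)
    summary = {
        "scope": scope,
        "clonotypes_in_scope": n_scope,
        "matched_clonotypes": matched,
        "matched_fraction": matched / n_scope if n_scope else 0.0,
        "matched_pct": round_half_up_percent(matched, n_scope) if n_scope else 0,
        "category_counts": cat_counts,
        "category_fractions": {k: v / matched for k, v in cat_counts.items()} if matched else {},
    }
    return pd.DataFrame(rows, columns=["cdr3_aa", "templates", "condition_category",
                                       "condition_label", "ambiguous"]), summary
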