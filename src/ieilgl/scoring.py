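"""Gene-set expression scoring and percentile-threshold coexpression calls.

``module_score`` implements the binned-control gene-set score used for
single-cell data: for each set gene, control genes are drawn (seeded,
uniformly) from the gene's dataset-wide average-expression bin, and the score
is the per-cell mean of set-gene expression minus the mean over the pooled
control genes. This matches the widely used single-cell scoring convention
(Seurat ``AddModuleScore`` / scanpy ``score_genes``) while keeping the draw
fully deterministic given a seed.

Bulk samples are scored with a geometric mean over the set genes. Signature
construction intersects an internally derived up-regulated list with external
up-regulated lists. High/low calls cut at an empirical percentile over all
cells pooled, and coexpression proportions are compared across groups with an
r x 2 chi-square.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ieilgl import stats
from ieilgl.stats import ContingencyTable


class ScoringError(ValueError):
    pass


def _mean_expression_bins(matrix: pd.DataFrame, n_bins: int) -> pd.Series:
    """Bin genes by dataset-wide mean expression into equal-size rank bins."""
    means = matrix.mean(axis=0)
    ranks = means.rank(method="first") - 1  # 0-based, deterministic tie-break
    return (ranks * n_bins / len(means)).astype(int).clip(upper=n_bins - 1)


def module_score(
    matrix: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell binned-control gene-set score.

    Parameters
    ----------
    matrix:
        cells x genes normalized expression (log-normalized by convention).
    gene_set:
        Gene symbols to score; genes absent from the matrix are dropped with
        a warning, but at least one must be present.
    n_bins, n_ctrl:
        Number of average-expression bins, and control genes drawn per set
        gene (without replacement within a bin, capped at bin size).
    seed:
        Makes the control draw deterministic.

    Returns a float Series indexed by cell id: mean expression over the set
    genes minus mean expression over the pooled control genes.
    """
    present = [g for g in gene_set if g in matrix.columns]
    missing = [g for g in gene_set if g not in matrix.columns]
    if not present:
        raise ScoringError(f"no gene of the set is in the matrix; missing: {missing}")
    if missing:
        warnings.warn(f"genes absent from matrix, skipped: {missing}", stacklevel=2)

    bins = _mean_expression_bins(matrix, n_bins)
    rng = np.random.default_rng(seed)
    control: set[str] = set()
    by_bin: dict[int, list[str]] = {}
    for b in range(n_bins):
        by_bin[b] = sorted(bins.index[bins == b])
    for g in present:  # deterministic order: the set's own order
        pool = by_bin[int(bins[g])]
        k = min(n_ctrl, len(pool))
        control.update(rng.choice(pool, size=k, replace=False))
    ctrl_genes = sorted(control)
    set_mean = matrix[present].mean(axis=1)
    ctrl_mean = matrix[ctrl_genes].mean(axis=1)
    return (set_mean - ctrl_mean).rename("module_score")


def geometric_mean_score(
    bulk: pd.DataFrame, gene_set: list[str], pseudocount: float = 0.0
) -> pd.Series:
    """Per-sample geometric mean of the set genes (samples x genes input)."""
    present = [g for g in gene_set if g in bulk.columns]
    if not present:
        raise ScoringError("no gene of the set is in the matrix")
    values = bulk[present].to_numpy(dtype=float)
    if (values < 0).any():
        raise ScoringError("expression values must be non-negative")
    with np.errstate(divide="ignore"):
        logs = np.log(values + pseudocount)
    return pd.Series(np.exp(logs.mean(axis=1)), index=bulk.index, name="gm_score")


def build_stat3_signature(
    up_in_mt: list[str], external_up_lists: list[list[str]]
) -> list[str]:
    """Signature = internally up-regulated genes that any external up-list
    corroborates: ``up_in_mt`` intersected with the union of the external
    lists. Deduplicated, order of ``up_in_mt`` preserved. An empty
    intersection warns but is not an error.
    """
    if not up_in_mt or not external_up_lists or not any(external_up_lists):
        raise ScoringError("gene lists must be non-empty")
    external = set().union(*map(set, external_up_lists))
    seen = set()
    out = []
    for g in up_in_mt:
        if g in external and g not in seen:
            seen.add(g)
            out.append(g)
    if not out:
        warnings.warn("signature intersection is empty", stacklevel=2)
    return out


def percentile_threshold(scores: pd.Series, pct: float = 0.90) -> pd.Series:
    """High/low call per cell: high iff score strictly above the empirical
    ``pct`` quantile computed over all cells pooled. Ties at the threshold
    are low. Constant scores yield all-low with a warning.
    """
    if len(scores) < 10:
        raise ScoringError("need at least 10 cells for a percentile call")
    threshold = float(np.quantile(scores.to_numpy(dtype=float), pct))
    if scores.nunique() == 1:
        warnings.warn("constant scores: no cell called high", stacklevel=2)
    return (scores > threshold).rename("high")


def coexpression_contingency(
    high_a: pd.Series, high_b: pd.Series, groups: pd.Series,
    name_a: str = "A", name_b: str = "B",
) -> dict:
    """Per-group high-call proportions and cross-group chi-square tests.

    ``high_a``/``high_b`` are boolean per-cell flags aligned on the same cell
    index as ``groups``. Reports, for each group, the proportion of cells
    high on A, high on B, and double-high (with stored counts), plus an
    r x 2 chi-square per flag across groups with >= 1 cell. Groups with zero
    cells are excluded with a warning.
    """
    if not (high_a.index.equals(groups.index) and high_b.index.equals(groups.index)):
        raise ScoringError("flags and group labels must be aligned on cells")
    group_names = [g for g in pd.unique(groups)]
    per_group = {}
    for g in group_names:
        mask = groups == g
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"group {g!r} has no cells; excluded", stacklevel=2)
            continue
        a = int(high_a[mask].sum())
        b = int(high_b[mask].sum())
        ab = int((high_a[mask] & high_b[mask]).sum())
        per_group[g] = {
            "n": n,
            f"{name_a}_high": a, f"{name_a}_high_frac": a / n,
            f"{name_b}_high": b, f"{name_b}_high_frac": b / n,
            "double_high": ab, "double_high_frac": ab / n,
        }
    out: dict = {"per_group": per_group}
    total = sum(v["n"] for v in per_group.values())
    dbl = sum(v["double_high"] for v in per_group.values())
    out["double_high_overall_frac"] = dbl / total if total else 0.0
    if len(per_group) >= 2:
        for label, key in ((name_a, f"{name_a}_high"), (name_b, f"{name_b}_high")):
            table = ContingencyTable(tuple(
                (v[key], v["n"] - v[key]) for v in per_group.values()
            ))
            try:
                chi2, p = stats.chi_square_test(table)
            except stats.StatsError:  # degenerate flag (all high or all low)
                chi2, p = float("nan"), float("nan")
            out[f"{label}_chi2"] = chi2
            out[f"{label}_chi2_p"] = p
    return out
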