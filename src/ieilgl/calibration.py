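"""Seeded recovery experiments on synthetic cohorts.

These are the package's self-checks of statistical behaviour: the
overrepresentation screen's false-discovery proportion and planted-variant
recall over replicate cohorts, the rarefaction sampler against its
hypergeometric expectation, and module-score recovery of a planted
expression shift. Each function is deterministic given its seed and returns
the raw counts alongside the summary rates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ieilgl import germline, repertoire as rep, scoring
from ieilgl.config import RunConfig
from ieilgl.simulate import SimulationSpec, simulate_expression, simulate_germline


def overrepresentation_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    spec: SimulationSpec | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """FDP and recall of the VUS overrepresentation screen over replicates.

    Each replicate simulates a cohort with the spec's planted (enriched) and
    null variants, runs the full filter + screen, and tallies selections
    against the truth labels. Returns the pooled false-discovery proportion
    among selected VUS and the recall of planted variants, counted over the
    planted variants actually present in the cohort (a variant observed in
    no patient cannot be recovered).
    """
    spec = spec or SimulationSpec()
    cfg = cfg or RunConfig()
    true_sel = false_sel = planted_present = planted_recovered = 0
    for r in range(n_replicates):
        rspec = dataclasses.replace(spec, seed=seed + 10_000 + r)
        variants, _, truth = simulate_germline(rspec)
        if variants.empty:
            continue
        screened = germline.overrepresentation_screen(
            germline.filter_candidates(variants, cfg), rspec.n_patients, cfg)
        sel_keys = set(map(tuple, screened.loc[screened["selected"],
                                               ["gene", "hgvs"]].values))
        planted_keys = set(map(tuple, truth.loc[truth["planted"],
                                                ["gene", "hgvs"]].values))
        present_keys = set(map(tuple, truth.loc[truth["n_carriers"] > 0,
                                                ["gene", "hgvs"]].values))
        true_sel += len(sel_keys & planted_keys)
        false_sel += len(sel_keys - planted_keys)
        planted_present += len(planted_keys & present_keys)
        planted_recovered += len(sel_keys & planted_keys & present_keys)
    selected = true_sel + false_sel
    return {
        "n_replicates": n_replicates,
        "selected": selected,
        "false_selected": false_sel,
        "fdp": false_sel / selected if selected else 0.0,
        "planted_present": planted_present,
        "planted_recovered": planted_recovered,
        "recall": planted_recovered / planted_present if planted_present else 0.0,
    }


def downsampling_calibration(
    counts: tuple[int, ...] = (8000, 2000),
    n: int = 5420,
    n_seeds: int = 500,
    seed: int = 0,
) -> dict:
    """Mean sampled clone shares vs the hypergeometric expectation.

    Rarefaction without replacement makes each clone's sampled count
    Hypergeometric(total, clone, n), so its expected share equals its
    original share. Returns the observed mean share of the first clone, the
    expectation, and the z-distance in units of the Monte-Carlo SE.
    """
    clones = [rep.Clonotype(cdr3_aa=f"CASSDS{i}F", templates=c)
              for i, c in enumerate(counts)]
    r = rep.Repertoire("CAL", clones)
    total = sum(counts)
    shares = np.empty(n_seeds)
    for s in range(n_seeds):
        down = rep.downsample(r, n, seed=seed + s)
        by_key = {c.cdr3_aa: c.templates for c in down.clonotypes}
        shares[s] = by_key.get(clones[0].cdr3_aa, 0) / n
    expected_share = counts[0] / total
    # per-draw variance of the hypergeometric count, scaled to a share
    var_count = n * (counts[0] / total) * (1 - counts[0] / total) * (total - n) / (total - 1)
    se_mean = np.sqrt(var_count / n**2 / n_seeds)
    observed = float(shares.mean())
    return {
        "observed_mean_share": observed,
        "expected_share": expected_share,
        "se": float(se_mean),
        "z": float((observed - expected_share) / se_mean),
    }


def expression_shift_recovery(
    n_replicates: int = 20,
    seed: int = 0,
    spec: SimulationSpec | None = None,
    cfg: RunConfig | None = None,
) -> dict:
    """How often the shifted cell group has the highest high-score fraction.

    Each replicate simulates three cell groups with the configured shift on
    the score genes in the designated group, computes the binned-control
    module score, thresholds at the configured percentile over pooled cells,
    and checks whether the shifted group's high-score fraction strictly
    exceeds both other groups'.
    """
    spec = spec or SimulationSpec()
    cfg = cfg or RunConfig()
    wins = 0
    for r in range(n_replicates):
        rspec = dataclasses.replace(spec, seed=seed + 20_000 + r)
        matrix, annotation = simulate_expression(rspec)
        score_genes = list(matrix.columns[:15])
        scores = scoring.module_score(matrix, score_genes, seed=rspec.seed)
        high = scoring.percentile_threshold(scores, cfg.score_percentile)
        groups = annotation.set_index("cell_id")["group"].reindex(matrix.index)
        fracs = high.groupby(groups).mean()
        shifted = fracs[rspec.shifted_group]
        if all(shifted > v for g, v in fracs.items() if g != rspec.shifted_group):
            wins += 1
    return {"n_replicates": n_replicates, "wins": wins,
            "win_fraction": wins / n_replicates}
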