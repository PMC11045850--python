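"""Population statistics across LED conditions.

Paired two-sided Wilcoxon signed-rank tests against a reference condition
with Bonferroni correction over the non-reference conditions, plus a
Spearman rank-correlation trend test of the per-unit effect against the
condition ordering (LED intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import wilcoxon_paired

__all__ = ["ConditionComparison", "compare_conditions"]


@dataclass
class ConditionComparison:
    reference: float
    conditions: list            # non-reference condition values, ordered
    n_units: int
    mean: dict                  # condition -> population mean delta
    sem: dict
    p_raw: dict                 # condition -> raw Wilcoxon p vs reference
    p_adjusted: dict            # Bonferroni: min(1, p * n_comparisons)
    spearman_rho: float         # pooled (intensity, per-unit delta) trend
    spearman_p: float
    per_condition_means_rho: float  # trend on condition means (n = #conditions)


def compare_conditions(per_unit_deltas: dict, reference_condition):
    """Compare per-unit effects across conditions against a reference.

    Parameters
    ----------
    per_unit_deltas : mapping ``condition -> {unit_id -> delta}``.
        Conditions are numeric (LED intensity, mW/mm^2).  Units missing from
        any condition are dropped with a warning (tests are paired).
    reference_condition : key of the reference (no-LED, or e.g. 8 mW/mm^2).

    Returns a :class:`ConditionComparison`.  The Bonferroni family is the
    number of non-reference conditions.  The Spearman trend is computed on
    pooled (condition value, per-unit delta) pairs; a rank trend across the
    per-condition means is reported alongside.
    """
    if reference_condition not in per_unit_deltas:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    conds = sorted(c for c in per_unit_deltas if c != reference_condition)
    if not conds:
        raise ValueError("need at least 2 conditions")

    common = set(per_unit_deltas[reference_condition])
    for c in conds:
        common &= set(per_unit_deltas[c])
    dropped = set().union(*(set(per_unit_deltas[c]) for c in per_unit_deltas)) - common
    if dropped:
        warnings.warn(f"{len(dropped)} unit(s) not present in every condition "
                      f"were dropped from paired tests")
    units = sorted(common)
    if not units:
        raise ValueError("no units present in every condition")

    ref = np.array([per_unit_deltas[reference_condition][u] for u in units])
    n_comp = len(conds)
    mean, sem, p_raw, p_adj = {}, {}, {}, {}
    for c in conds + [reference_condition]:
        vals = np.array([per_unit_deltas[c][u] for u in units])
        mean[c] = float(vals.mean())
        sem[c] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.inf
    for c in conds:
        vals = np.array([per_unit_deltas[c][u] for u in units])
        p = wilcoxon_paired(vals, ref)
        p_raw[c] = p
        p_adj[c] = min(1.0, p * n_comp)

    xs, ys = [], []
    for c in conds + [reference_condition]:
        for u in units:
            xs.append(float(c))
            ys.append(per_unit_deltas[c][u])
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.all(ys == ys[0]):
        rho, p_rho = 0.0, 1.0  # degenerate: identical deltas everywhere
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = stats.spearmanr(xs, ys)
        rho, p_rho = float(r.statistic), float(r.pvalue)
        if np.isnan(rho):
            rho, p_rho = 0.0, 1.0

    order = sorted(conds + [reference_condition])
    means_seq = [mean[c] for c in order]
    if len(set(means_seq)) < 2:
        rho_means = 0.0
    else:
        rho_means = float(stats.spearmanr(order, means_seq).statistic)

    return ConditionComparison(
        reference=reference_condition, conditions=conds, n_units=len(units),
        mean=mean, sem=sem, p_raw=p_raw, p_adjusted=p_adj,
        spearman_rho=rho, spearman_p=p_rho,
        per_condition_means_rho=rho_means,
    )
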