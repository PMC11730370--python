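"""Indicator value analysis and combinatorial predictive modeling.

Works on presence/absence data. The group-size-corrected indicator value
uses per-group occurrence frequencies f_k: specificity
A = f_target / sum_k f_k, sensitivity B = f_target, and the indicator
statistic is sqrt(A * B). Significance comes from whole-sample group
label permutations. Combinations of up to ``max_order`` taxa are present
in a sample only if all members are (AND rule); perfect-specificity
(A = 1) combinations form cross-cohort exposure predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class IndicatorResult:
    unit: tuple[str, ...]
    target_group: str
    A: float
    B: float
    stat: float
    p: float | None = None


@dataclass
class PredictorSet:
    entries: list[IndicatorResult]
    selection_rule: str = ""
    max_order: int = 3
    n_evaluated: int = 0


def _group_frequencies(pa: np.ndarray, codes: np.ndarray, n_groups: int
                       ) -> np.ndarray:
    """(n_groups x n_units) occurrence frequency matrix."""
    freqs = np.empty((n_groups, pa.shape[1]))
    for g in range(n_groups):
        freqs[g] = pa[codes == g].mean(axis=0)
    return freqs


def indval_g(pa: np.ndarray, groups, unit_index: int,
             target_group=None) -> IndicatorResult:
    """Group-size-corrected indicator value of one unit (no p-value).

    If ``target_group`` is None the group maximizing the statistic is
    chosen.
    """
    pa = np.asarray(pa)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    col = pa[:, unit_index]
    if not np.isin(col, (0, 1)).all():
        raise ValueError("unit column must be binary")
    freqs = _group_frequencies(pa[:, [unit_index]], codes, len(labels))[:, 0]
    total = freqs.sum()
    if total == 0:
        raise ValueError("unit absent from all samples: A undefined")
    A_all = freqs / total
    stat_all = np.sqrt(A_all * freqs)
    if target_group is None:
        g = int(np.argmax(stat_all))
    else:
        g = int(np.flatnonzero(labels == target_group)[0])
    return IndicatorResult(unit=(str(unit_index),),
                           target_group=str(labels[g]),
                           A=float(A_all[g]), B=float(freqs[g]),
                           stat=float(stat_all[g]))


def indval_stat(A: float, B: float) -> float:
    """sqrt(A * B): the indicator value index from printed A and B."""
    return float(np.sqrt(A * B))


def multipatt(pa: np.ndarray, groups, unit_names=None,
              n_perm: int = 999, seed: int = 0) -> list[IndicatorResult]:
    """Best-group indicator value per unit with permutation p-values.

    Permutations shuffle whole samples' group labels, preserving
    co-occurrence structure. p = (1 + hits) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pa = np.asarray(pa)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if unit_names is None:
        unit_names = [str(j) for j in range(pa.shape[1])]

    def best_stats(cds):
        freqs = _group_frequencies(pa, cds, len(labels))
        totals = freqs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(totals > 0, freqs / totals, 0.0)
        return np.sqrt(A * freqs)  # n_groups x n_units

    stats_obs = best_stats(codes)
    best_group = stats_obs.argmax(axis=0)
    obs = stats_obs.max(axis=0)
    rng = np.random.default_rng(seed)
    hits = np.zeros(pa.shape[1], dtype=int)
    for _ in range(n_perm):
        perm_stats = best_stats(rng.permutation(codes)).max(axis=0)
        hits += perm_stats >= obs
    pvals = (1 + hits) / (1 + n_perm)

    results = []
    for j, name in enumerate(unit_names):
        totals = pa[:, j].sum()
        if totals == 0:
            continue  # A undefined; unit skipped (flagged by absence)
        g = best_group[j]
        freqs = _group_frequencies(pa[:, [j]], codes, len(labels))[:, 0]
        A = freqs[g] / freqs.sum()
        results.append(IndicatorResult(
            unit=(name,), target_group=str(labels[g]),
            A=float(A), B=float(freqs[g]), stat=float(obs[j]),
            p=float(pvals[j])))
    return results


def combine_units(pa: np.ndarray, members, name_index: dict | None = None
                  ) -> np.ndarray:
    """AND-combination column: present iff every member is present."""
    pa = np.asarray(pa)
    cols = []
    for m in members:
        if isinstance(m, str):
            if name_index is None or m not in name_index:
                raise KeyError(f"unknown member {m!r}")
            cols.append(name_index[m])
        else:
            if not 0 <= int(m) < pa.shape[1]:
                raise KeyError(f"unknown member index {m}")
            cols.append(int(m))
    return np.logical_and.reduce(pa[:, cols] > 0, axis=1).astype(np.int8)


def search_combinations(pa: np.ndarray, groups, target_group,
                        unit_names=None, max_order: int = 3,
                        min_B: float = 0.2, candidate_cap: int = 60
                        ) -> PredictorSet:
    """Evaluate A, B, stat for all combinations (order <= max_order) of a
    candidate list: units with individual sensitivity >= ``min_B`` in the
    target group, capped at ``candidate_cap`` (highest-B first)."""
    pa = np.asarray(pa)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if target_group not in labels:
        raise ValueError(f"target group {target_group!r} has no samples")
    if unit_names is None:
        unit_names = [str(j) for j in range(pa.shape[1])]
    t = int(np.flatnonzero(labels == target_group)[0])
    target_mask = codes == t

    freqs_all = _group_frequencies(pa, codes, len(labels))
    B_single = freqs_all[t]
    with np.errstate(invalid="ignore", divide="ignore"):
        totals = freqs_all.sum(axis=0)
        A_single = np.where(totals > 0, B_single / totals, 0.0)
    stat_single = np.sqrt(A_single * B_single)
    candidates = np.flatnonzero(B_single >= min_B)
    if len(candidates) > candidate_cap:
        # cap by target-group indicator value so group-associated taxa
        # survive ahead of ubiquitous ones
        order = np.argsort(-stat_single[candidates], kind="stable")
        candidates = candidates[order[:candidate_cap]]
        candidates.sort()

    group_sizes = np.bincount(codes, minlength=len(labels))
    entries = []
    n_eval = 0
    bool_pa = pa[:, candidates] > 0
    for order_k in range(1, max_order + 1):
        for combo in combinations(range(len(candidates)), order_k):
            col = np.logical_and.reduce(bool_pa[:, combo], axis=1)
            n_eval += 1
            freqs = np.bincount(codes[col], minlength=len(labels)) \
                / group_sizes
            total = freqs.sum()
            if total == 0:
                continue
            A = freqs[t] / total
            B = freqs[t]
            entries.append(IndicatorResult(
                unit=tuple(unit_names[candidates[i]] for i in combo),
                target_group=str(target_group),
                A=float(A), B=float(B), stat=indval_stat(A, B)))
    return PredictorSet(entries=entries,
                        selection_rule=f"B>={min_B}, cap={candidate_cap}",
                        max_order=max_order, n_evaluated=n_eval)


def _rank_key(e: IndicatorResult):
    # descending stat, ties by descending B, then lexicographic unit
    return (-e.stat, -e.B, e.unit)


def prune_predictors(candidates: PredictorSet, pa: np.ndarray, groups,
                     name_index: dict, top_n: int | None = None
                     ) -> PredictorSet:
    """Greedy coverage selection.

    Iteratively adds the highest-stat combination covering at least one
    not-yet-covered target-group sample, stopping when coverage stops
    growing or ``top_n`` entries are selected. Ties break by descending
    B then lexicographic unit name.
    """
    if not candidates.entries:
        raise ValueError("no candidate combinations to prune")
    pa = np.asarray(pa)
    groups = np.asarray(groups)
    target = candidates.entries[0].target_group
    target_mask = groups == target
    ranked = sorted(candidates.entries, key=_rank_key)
    covered = np.zeros(pa.shape[0], dtype=bool)
    selected = []
    for entry in ranked:
        if top_n is not None and len(selected) >= top_n:
            break
        col = combine_units(pa, entry.unit, name_index).astype(bool)
        gain = col & target_mask & ~covered
        if gain.any():
            selected.append(entry)
            covered |= col & target_mask
    return PredictorSet(entries=selected,
                        selection_rule="greedy coverage by stat",
                        max_order=candidates.max_order,
                        n_evaluated=candidates.n_evaluated)


def predict_exposure(test_pa: np.ndarray, test_taxa: list[str],
                     predictors: PredictorSet, truth=None,
                     top_n: int = 8) -> dict:
    """Call samples exposed iff any perfect-specificity predictor
    combination is fully present.

    Only A = 1 predictors are used, ranked (stat desc, B desc,
    lexicographic) and truncated to ``top_n``. Members absent from the
    test taxon universe make their combination absent. Returns calls and,
    when true labels are given, per-class accuracy fractions.
    """
    perfect = [e for e in predictors.entries if e.A >= 1.0 - 1e-12]
    if not perfect:
        raise ValueError("no perfect-specificity (A=1) predictors")
    perfect = sorted(perfect, key=_rank_key)[:top_n]
    test_pa = np.asarray(test_pa)
    name_index = {t: j for j, t in enumerate(test_taxa)}
    calls = np.zeros(test_pa.shape[0], dtype=bool)
    for entry in perfect:
        if not all(m in name_index for m in entry.unit):
            continue
        calls |= combine_units(test_pa, entry.unit, name_index).astype(bool)
    out = {
        "calls": np.where(calls, "exposed", "not_exposed"),
        "n_predictors_used": len(perfect),
        "predictors": [e.unit for e in perfect],
    }
    if truth is not None:
        truth = np.asarray(truth)
        for cls in ("exposed", "not_exposed"):
            mask = truth == cls
            if mask.any():
                out[f"accuracy_{cls}"] = float(
                    (out["calls"][mask] == cls).mean())
    return out


def results_to_frame(results: list[IndicatorResult]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(unit="+".join(r.unit), target_group=r.target_group,
             A=r.A, B=r.B, stat=r.stat, p=r.p)
        for r in results])
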