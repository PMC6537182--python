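"""Repeated stratified cross-validation and method comparison.

Reliability of a predictor is the Pearson correlation between predicted
and observed phenotypes in held-out folds.  Folds are stratified by
population: each population's members are dealt round-robin so every
fold's per-population counts are proportional within one sample.
Methods are compared with a Kruskal-Wallis rank test and Holm-adjusted
pairwise Mann-Whitney tests rendered as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FoldPlan", "CvReliability", "stratified_folds", "repeated_cv", "compare_methods"]


@dataclass
class FoldPlan:
    """Test-set ids per (round, fold), stratified by population."""

    rounds: int
    k: int
    folds: list[tuple[int, int, list[str]]]   # (round, fold, test sample ids)
    seed: int

    def iter_folds(self):
        yield from self.folds


@dataclass
class CvReliability:
    method: str
    trait: str
    correlations: np.ndarray
    skipped: list[tuple[int, int, str]] = field(default_factory=list)


def stratified_folds(
    populations: pd.Series, k: int = 5, rounds: int = 50, seed: int = 0
) -> FoldPlan:
    """Population-proportional fold assignment.

    Per round, each population's members are shuffled and dealt
    round-robin (with a seeded starting offset) into the k folds, so the
    per-population counts across folds differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    populations = populations.dropna()
    n = len(populations)
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    folds: list[tuple[int, int, list[str]]] = []
    pops = sorted(populations.astype(str).unique())
    for r in range(1, rounds + 1):
        buckets: list[list[str]] = [[] for _ in range(k)]
        for pop in pops:
            members = list(populations.index[populations.astype(str) == pop])
            rng.shuffle(members)
            offset = int(rng.integers(k))
            for i, s in enumerate(members):
                buckets[(offset + i) % k].append(s)
        for f, ids in enumerate(buckets, start=1):
            folds.append((r, f, ids))
    return FoldPlan(rounds, k, folds, seed)


def repeated_cv(
    predictor,
    y: pd.Series,
    plan: FoldPlan,
    method: str = "model",
    trait: str = "trait",
) -> CvReliability:
    """Run a fit/predict pair over every fold of the plan.

    ``predictor(train_ids, test_ids) -> array of predictions for
    test_ids``.  Folds with zero variance in either the observed or the
    predicted values are skipped and logged, as are predictor failures.
    """
    cors: list[float] = []
    skipped: list[tuple[int, int, str]] = []
    for r, f, test_ids in plan.iter_folds():
        train_ids = [s for s in y.index if s not in set(test_ids)]
        if not test_ids:
            continue
        try:
            yhat = np.asarray(predictor(train_ids, test_ids), dtype=float)
        except Exception as exc:  # noqa: BLE001 - the run must continue
            skipped.append((r, f, f"predictor failure: {exc}"))
            continue
        obs = y.loc[test_ids].to_numpy(float)
        if obs.std() == 0 or yhat.std() == 0:
            skipped.append((r, f, "zero variance"))
            continue
        cors.append(float(np.corrcoef(obs, yhat)[0, 1]))
    return CvReliability(method, trait, np.array(cors), skipped)


def compare_methods(
    results: list[CvReliability], alpha: float = 0.01
) -> tuple[float, int, float, dict[str, str]]:
    """Kruskal-Wallis omnibus test plus a compact letter display.

    Pairwise two-sided Mann-Whitney tests with Holm adjustment decide
    which methods differ; the insert-and-absorb algorithm assembles
    letters so that two methods share a letter iff their adjusted p
    exceeds alpha.
    """
    if len(results) < 2:
        raise ValueError("need at least two methods")
    groups = {r.method: np.asarray(r.correlations, float) for r in results}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every method needs at least two values")
    names = list(groups)
    values = [groups[m] for m in names]
    if all((v == values[0][0]).all() for v in values):
        return 0.0, len(names) - 1, 1.0, {m: "a" for m in names}
    H, p = stats.kruskal(*values)

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = []
    for i, j in pairs:
        if (values[i] == values[j][0]).all() and (values[j] == values[j][0]).all():
            raw.append(1.0)
        else:
            raw.append(stats.mannwhitneyu(values[i], values[j],
                                          alternative="two-sided").pvalue)
    adj = _holm(np.array(raw))
    significant = {pairs[t] for t in range(len(pairs)) if adj[t] <= alpha}
    letters = _compact_letters(len(names), significant)
    # order letters by mean rank so 'a' marks the best-performing group
    order = np.argsort([-np.median(v) for v in values], kind="stable")
    rank_of = {int(idx): pos for pos, idx in enumerate(order)}
    group_sets = letters
    display = _assign_letters(len(names), group_sets, rank_of)
    return float(H), len(names) - 1, float(p), {names[i]: display[i] for i in range(len(names))}


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _compact_letters(n: int, significant: set[tuple[int, int]]) -> list[set[int]]:
    """Insert-and-absorb: letter groups such that a significant pair never
    shares a group and a non-significant pair shares at least one."""
    groups: list[set[int]] = [set(range(n))]
    for i, j in sorted(significant):
        new_groups: list[set[int]] = []
        for g in groups:
            if i in g and j in g:
                new_groups.append(g - {i})
                new_groups.append(g - {j})
            else:
                new_groups.append(g)
        # absorb groups contained in another
        groups = []
        for g in new_groups:
            if any(g < h for h in new_groups if g is not h) or g in groups:
                continue
            groups.append(g)
    return groups


def _assign_letters(n: int, groups: list[set[int]], rank_of: dict[int, int]) -> list[str]:
    # order groups by the best (lowest) member rank so 'a' is the top group
    ordered = sorted(groups, key=lambda g: min(rank_of[m] for m in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(n)]
    for li, g in enumerate(ordered):
        for m in sorted(g):
            out[m] += alphabet[li % len(alphabet)]
    return ["".join(sorted(s)) for s in out]
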