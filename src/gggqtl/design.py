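"""Balanced allocation of RILs to conditions (the GGG design step).

In a generalized genetical genomics design each line is measured in exactly
one condition, so genotype and condition must be decoupled by construction:
the allele distribution within every subpopulation should match the other
subpopulations and the full population. The objective here scores exactly
that, summed over markers, and a restart + pairwise-swap hill-climb
minimizes it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import DRY, IMBIBED, DesignAllocation, GenotypeMatrix

log = logging.getLogger(__name__)


def _freq_components(calls: np.ndarray):
    """Per-line contributions: allele sum (NaN as 0) and non-missing count."""
    obs = ~np.isnan(calls)
    s = np.where(obs, calls, 0.0)
    return s, obs.astype(float)


def _score_from_sums(s_by, n_by, s_pop, n_pop) -> float:
    """Balance objective given per-condition allele sums/counts per marker.

    f = MM-allele frequency = (mean call + 1)/2; markers where any
    subpopulation has no observed call are skipped.
    """
    k = len(s_by)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = [(s / n + 1.0) / 2.0 for s, n in zip(s_by, n_by)]
        f_pop = (s_pop / n_pop + 1.0) / 2.0
    valid = n_pop > 0
    for n in n_by:
        valid &= n > 0
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.warning("design_score: skipping %d markers with an all-missing subpopulation", n_skipped)
    total = np.zeros(len(f_pop))
    for i in range(k):
        for j in range(i + 1, k):
            total += np.where(valid, (freqs[i] - freqs[j]) ** 2, 0.0)
        total += np.where(valid, (freqs[i] - f_pop) ** 2, 0.0)
    return float(total.sum())


def design_score(geno: GenotypeMatrix, assignment: pd.Series) -> float:
    """Sum over markers of squared allele-frequency discrepancies.

    For two conditions A, B this is
    ``sum_m (f_A - f_B)^2 + (f_A - f_pop)^2 + (f_B - f_pop)^2``
    where f is the 'MM' frequency among non-missing calls; 0 iff every marker
    has identical frequencies in both subpopulations and the population.
    """
    missing = set(geno.lines) - set(assignment.index)
    if missing:
        raise ValueError(f"assignment does not cover lines {sorted(missing)[:5]}")
    calls = geno.calls.to_numpy(dtype=float)
    s, n = _freq_components(calls)
    labels = assignment.loc[geno.lines]
    conds = list(pd.unique(labels))
    s_by, n_by = [], []
    for c in conds:
        rows = (labels == c).to_numpy()
        s_by.append(s[rows].sum(axis=0))
        n_by.append(n[rows].sum(axis=0))
    return _score_from_sums(s_by, n_by, s.sum(axis=0), n.sum(axis=0))


def allocate(
    geno: GenotypeMatrix,
    n_conditions: int = 2,
    n_restarts: int = 10,
    max_iters: int = 10_000,
    seed: int | None = None,
    conditions: tuple[str, ...] | None = None,
) -> DesignAllocation:
    """Optimize the balance objective by restarted pairwise-swap hill-climbing.

    Each restart draws a random balanced split (sizes differing by at most 1),
    then repeatedly sweeps candidate cross-condition line swaps in seeded
    random order, accepting any strictly score-reducing swap, until a full
    sweep yields no improvement or ``max_iters`` swaps were accepted. The best
    allocation over restarts is returned; deterministic for a seed.
    """
    n_lines = geno.n_lines
    if n_conditions < 1 or n_conditions > n_lines:
        raise ValueError(f"n_conditions must be in [1, {n_lines}]")
    if conditions is None:
        conditions = (DRY, IMBIBED) if n_conditions == 2 else tuple(
            f"cond{i + 1}" for i in range(n_conditions)
        )
    if len(conditions) != n_conditions:
        raise ValueError("len(conditions) must equal n_conditions")

    calls = geno.calls.to_numpy(dtype=float)
    s_line, n_line = _freq_components(calls)  # per-line marker contributions
    s_pop, n_pop = s_line.sum(axis=0), n_line.sum(axis=0)
    rng = np.random.default_rng(seed)
    sizes = [n_lines // n_conditions + (1 if i < n_lines % n_conditions else 0)
             for i in range(n_conditions)]

    def score_of(groups: list[np.ndarray]) -> float:
        s_by = [s_line[g].sum(axis=0) for g in groups]
        n_by = [n_line[g].sum(axis=0) for g in groups]
        return _score_from_sums(s_by, n_by, s_pop, n_pop)

    best_groups, best_score = None, np.inf
    for _ in range(max(1, n_restarts)):
        perm = rng.permutation(n_lines)
        groups = []
        start = 0
        for sz in sizes:
            groups.append(perm[start : start + sz].copy())
            start += sz
        current = score_of(groups)
        accepted = 0
        improved = True
        while improved and accepted < max_iters:
            improved = False
            pairs = [
                (a, b, ia, ib)
                for a in range(n_conditions)
                for b in range(a + 1, n_conditions)
                for ia in range(len(groups[a]))
                for ib in range(len(groups[b]))
            ]
            rng.shuffle(pairs)
            for a, b, ia, ib in pairs:
                groups[a][ia], groups[b][ib] = groups[b][ib], groups[a][ia]
                trial = score_of(groups)
                if trial < current - 1e-15:
                    current = trial
                    improved = True
                    accepted += 1
                    if accepted >= max_iters:
                        break
                else:
                    groups[a][ia], groups[b][ib] = groups[b][ib], groups[a][ia]
        if current < best_score:
            best_score, best_groups = current, [g.copy() for g in groups]

    assignment = pd.Series(index=pd.Index(geno.lines, name="line"), dtype=object)
    for c, g in zip(conditions, best_groups):
        assignment.iloc[g] = c
    return DesignAllocation(assignment, conditions, balance_score=best_score)


def exhaustive_best_score(geno: GenotypeMatrix, conditions=(DRY, IMBIBED)) -> float:
    """Minimum balance score over all balanced two-way splits (oracle; tiny n only)."""
    from itertools import combinations

    n = geno.n_lines
    if n > 16:
        raise ValueError("exhaustive search is for small populations only")
    idx = np.arange(n)
    best = np.inf
    calls = geno.calls.to_numpy(dtype=float)
    s_line, n_line = _freq_components(calls)
    s_pop, n_pop = s_line.sum(axis=0), n_line.sum(axis=0)
    for grp in combinations(idx, n // 2):
        a = np.array(grp)
        b = np.setdiff1d(idx, a)
        sc = _score_from_sums(
            [s_line[a].sum(axis=0), s_line[b].sum(axis=0)],
            [n_line[a].sum(axis=0), n_line[b].sum(axis=0)],
            s_pop, n_pop,
        )
        best = min(best, sc)
    return best
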