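"""Metabolite-matrix preprocessing and differential abundance.

The canonical order for GC-TOF/MS abundance tables here is: log2 transform,
per-metabolite median centering (the log-scale equivalent of dividing each
metabolite by its median over the whole sample set), Z-score outlier removal
per trait, then sequential-KNN imputation of remaining holes. Differential
abundance between the two conditions is tested nonparametrically by the rank
product with a label-permutation false-positive-proportion estimate, and
parametrically by per-metabolite one-way ANOVA with BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MetaboliteMatrix

log = logging.getLogger(__name__)


def _as_frame(matrix) -> tuple[pd.DataFrame, bool]:
    if isinstance(matrix, MetaboliteMatrix):
        return matrix.values, True
    return matrix, False


def _wrap(values: pd.DataFrame, matrix):
    if isinstance(matrix, MetaboliteMatrix):
        return matrix.with_values(values)
    return values


def log2_transform(matrix):
    """Elementwise log2; missing entries preserved; non-positive cells are an error."""
    df, _ = _as_frame(matrix)
    bad = (df <= 0).any()
    if bad.any():
        col = bad.index[bad.to_numpy().argmax()]
        row = df.index[(df[col] <= 0).to_numpy().argmax()]
        raise ValueError(f"non-positive abundance at sample {row!r}, metabolite {col!r}")
    return _wrap(np.log2(df), matrix)


def median_normalize(matrix):
    """Center each metabolite at its across-sample median (log-scale data).

    Columns with no observed value cannot be centered and are dropped with a
    warning.
    """
    df, _ = _as_frame(matrix)
    empty = df.isna().all()
    if empty.any():
        log.warning("median_normalize: dropping all-missing metabolites %s",
                    list(df.columns[empty]))
        df = df.loc[:, ~empty]
    return _wrap(df - df.median(axis=0, skipna=True), matrix)


def remove_outliers(vector, z_cutoff: float = 3.0):
    """Set entries with |Z| > cutoff to missing (single pass).

    Mean and sd are computed once from all non-missing values; a zero-variance
    vector is returned unchanged. Note the single-pass |Z| of one extreme value
    among n is bounded by (n-1)/sqrt(n), so small vectors cannot lose points.
    """
    x = pd.Series(vector, dtype=float) if not isinstance(vector, pd.Series) else vector.astype(float)
    obs = x.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return x.copy()
    z = (x - obs.mean()) / sd
    out = x.copy()
    out[z.abs() > z_cutoff] = np.nan
    return out


def remove_outliers_matrix(matrix, z_cutoff: float = 3.0):
    """Column-wise Z-score outlier removal (columns with < 3 values pass through)."""
    df, _ = _as_frame(matrix)
    out = df.copy()
    for c in df.columns:
        if df[c].notna().sum() >= 3:
            out[c] = remove_outliers(df[c], z_cutoff)
    return _wrap(out, matrix)


def impute_missing(matrix, k: int = 10):
    """Sequential K-nearest-neighbour imputation of missing entries.

    Variables are processed from least to most missing; each is imputed from
    the k nearest complete-or-already-imputed variables (Euclidean distance on
    the target's observed samples), neighbour values averaged with 1/distance
    weights. Observed entries are never altered. A matrix with no complete
    column is bootstrapped by mean-filling the least-missing column first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df, _ = _as_frame(matrix)
    if not df.isna().any().any():
        return _wrap(df.copy(), matrix)
    if df.notna().sum(axis=1).min() < 1:
        raise ValueError("a sample has no observed values at all")

    out = df.copy()
    n_miss = df.isna().sum()
    done = list(df.columns[n_miss == 0])
    todo = sorted(df.columns[n_miss > 0], key=lambda c: (n_miss[c], list(df.columns).index(c)))
    if not done:
        first = todo.pop(0)
        out[first] = out[first].fillna(out[first].mean())
        done.append(first)

    for col in todo:
        target = out[col]
        obs = target.notna().to_numpy()
        pool = out[done].to_numpy()
        t = target.to_numpy()
        diffs = pool[obs] - t[obs, None]
        dist = np.sqrt((diffs**2).sum(axis=0))
        order = np.argsort(dist, kind="stable")[: min(k, len(done))]
        d = dist[order]
        if d[0] == 0:
            sel = order[d == 0]
            fill = pool[:, sel].mean(axis=1)
        else:
            w = 1.0 / d
            fill = (pool[:, order] * w[None, :]).sum(axis=1) / w.sum()
        filled = t.copy()
        filled[~obs] = fill[~obs]
        out[col] = filled
        done.append(col)
    return _wrap(out, matrix)


def preprocess(matrix, log2: bool = True, z_cutoff: float = 3.0, impute_k: int = 10,
               impute: bool = True):
    """The standard chain: (log2) -> median-center -> outlier removal -> imputation."""
    m = log2_transform(matrix) if log2 else matrix
    m = median_normalize(m)
    m = remove_outliers_matrix(m, z_cutoff)
    if impute:
        m = impute_missing(m, impute_k)
    return m


@dataclass
class RankProductResult:
    """Per-metabolite rank-product statistics.

    ``table`` columns: rp_up, rp_down, rp (smaller of the two), direction
    ('up'/'down' in the second condition), p_perm (pooled permutation
    p-value) and pfp (estimated false-positive proportion).
    """

    table: pd.DataFrame
    n_perm: int
    conditions: tuple[str, str]


def _rank_products(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean ranks for up- and down-regulation from an M x K diff matrix."""
    r_up = stats.rankdata(-diffs, axis=0, method="average")
    r_down = stats.rankdata(diffs, axis=0, method="average")
    rp_up = np.exp(np.log(r_up).mean(axis=1))
    rp_down = np.exp(np.log(r_down).mean(axis=1))
    return rp_up, rp_down


def rank_product_test(
    matrix,
    conditions=None,
    n_perm: int = 1000,
    max_pairings: int = 100,
    seed: int | None = None,
) -> RankProductResult:
    """Two-group unpaired rank product with label-permutation pfp.

    Fold changes (log-scale differences) are computed for between-group sample
    pairings (all of them, subsampled to ``max_pairings`` for large groups),
    metabolites ranked within each pairing, and the rank product taken as the
    geometric mean of ranks. The null distribution is built by shuffling the
    condition labels ``n_perm`` times and recomputing; pfp for a metabolite is
    the expected count of null metabolites at or beyond its RP divided by its
    rank among observed RPs.
    """
    df, is_mm = _as_frame(matrix)
    if conditions is None:
        if not is_mm:
            raise ValueError("pass condition labels when giving a bare DataFrame")
        conditions = matrix.conditions
    labels = pd.Series(conditions, index=df.index) if not isinstance(conditions, pd.Series) else conditions
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"rank product needs exactly 2 conditions, got {groups}")
    if df.isna().any().any():
        raise ValueError("rank product requires a complete matrix; impute first")
    ia = np.flatnonzero((labels == groups[0]).to_numpy())
    ib = np.flatnonzero((labels == groups[1]).to_numpy())
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need at least 2 samples per condition")

    rng = np.random.default_rng(seed)
    x = df.to_numpy(dtype=float)
    m = x.shape[1]

    def pair_diffs(a_idx, b_idx):
        pairs = [(i, j) for i in a_idx for j in b_idx]
        if len(pairs) > max_pairings:
            sel = rng.choice(len(pairs), size=max_pairings, replace=False)
            pairs = [pairs[s] for s in sel]
        # columns are pairings; rows metabolites
        return np.stack([x[j] - x[i] for i, j in pairs], axis=1)

    rp_up, rp_down = _rank_products(pair_diffs(ia, ib))

    null_up = np.empty((n_perm, m))
    null_down = np.empty((n_perm, m))
    all_idx = np.concatenate([ia, ib])
    for p in range(n_perm):
        perm = rng.permutation(all_idx)
        nu, nd = _rank_products(pair_diffs(perm[: len(ia)], perm[len(ia):]))
        null_up[p] = nu
        null_down[p] = nd

    def stats_for(rp, null):
        pool = np.sort(null.ravel())
        n_pool = pool.size
        count = np.searchsorted(pool, rp, side="right")
        p_perm = (count + 1) / (n_pool + 1)
        expected = count / n_perm  # expected null metabolites at or beyond RP
        rank_obs = stats.rankdata(rp, method="max")
        pfp = expected / rank_obs
        return p_perm, pfp

    p_up, pfp_up = stats_for(rp_up, null_up)
    p_down, pfp_down = stats_for(rp_down, null_down)
    use_up = rp_up <= rp_down
    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "rp": np.where(use_up, rp_up, rp_down),
            "direction": np.where(use_up, "up", "down"),
            "p_perm": np.where(use_up, p_up, p_down),
            "pfp": np.where(use_up, pfp_up, pfp_down),
        },
        index=pd.Index(df.columns, name="metabolite"),
    )
    return RankProductResult(table, n_perm, (groups[0], groups[1]))


def anova_per_metabolite(matrix, conditions=None) -> pd.DataFrame:
    """One-way ANOVA per metabolite across condition groups, BH over metabolites.

    Returns a DataFrame (metabolite x [F, p, q, ok]); metabolites with a
    degenerate group (fewer than 2 observed values) are flagged ok=False and
    excluded from the BH family.
    """
    df, is_mm = _as_frame(matrix)
    if conditions is None:
        if not is_mm:
            raise ValueError("pass condition labels when giving a bare DataFrame")
        conditions = matrix.conditions
    labels = pd.Series(conditions, index=df.index) if not isinstance(conditions, pd.Series) else conditions
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")

    rows = []
    for col in df.columns:
        samples = [df[col][labels == g].dropna().to_numpy() for g in groups]
        if any(len(s) < 2 for s in samples):
            rows.append((col, np.nan, np.nan, False))
            continue
        grand = np.concatenate(samples)
        ssb = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df_b = len(groups) - 1
        df_w = len(grand) - len(groups)
        if ssb == 0:
            f_stat, p = 0.0, 1.0
        elif ssw == 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (ssb / df_b) / (ssw / df_w)
            p = float(stats.f.sf(f_stat, df_b, df_w))
        rows.append((col, f_stat, p, True))
    out = pd.DataFrame(rows, columns=["metabolite", "F", "p", "ok"]).set_index("metabolite")
    out["q"] = np.nan
    ok = out["ok"] & out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    return out
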