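"""Linking the metabolome to germination phenotypes.

Three complementary views: (1) a ranked table of single metabolite <->
trait Spearman correlations with BH correction, each reported with the
percent of trait variance it explains (100*Rs^2); (2) canonical correlation
analysis (CCA) for the best correlation attainable by a *combination* of
metabolites — the contrast the pairwise table understates (a best single
|Rs| of 0.406 explains 16.48% of variance, while a canonical correlation of
0.60 explains 36%); and (3) PLS regression with K-fold cross-validation as
the honesty check on that combination (CCA correlations are in-sample and
optimistic when variables rival samples).

When metabolites outnumber samples the CCA block is reduced to its leading
principal components first (configured variance fraction, default 0.9) and
the canonical weights are mapped back to metabolite space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .network import MIN_SHARED_SAMPLES
from .types import MetaboliteMatrix, PhenotypeMatrix

log = logging.getLogger(__name__)


def _frame(x):
    if isinstance(x, (MetaboliteMatrix, PhenotypeMatrix)):
        return x.values
    return pd.DataFrame(x)


def pairwise_trait_correlation(metab, pheno) -> pd.DataFrame:
    """Spearman correlation of every metabolite with every phenotype trait.

    Pairs are computed on shared non-missing samples (>= 4), BH-adjusted
    across all metabolite x trait pairs, and sorted by |Rs| (descending)
    within trait. ``pct_variance`` is 100 * Rs^2 — the share of trait
    variance a single metabolite explains.
    """
    mv, pv = _frame(metab), _frame(pheno)
    shared = mv.index.intersection(pv.index)
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError("need at least 4 shared samples")
    mv, pv = mv.loc[shared], pv.loc[shared]
    rows = []
    for trait in pv.columns:
        y = pv[trait].to_numpy(dtype=float)
        for met in mv.columns:
            x = mv[met].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < MIN_SHARED_SAMPLES or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((met, trait, np.nan, np.nan, n))
                continue
            rs, p = stats.spearmanr(x[ok], y[ok])
            rows.append((met, trait, float(rs), float(p), n))
    out = pd.DataFrame(rows, columns=["metabolite", "trait", "rs", "p", "n"])
    out["p_bh"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    out["pct_variance"] = 100.0 * out["rs"] ** 2
    out["abs_rs"] = out["rs"].abs()
    out = (out.sort_values(["trait", "abs_rs"], ascending=[True, False])
              .drop(columns="abs_rs").reset_index(drop=True))
    return out


@dataclass
class CcaResult:
    """Canonical correlations with weights mapped back to original variables."""

    correlations: np.ndarray            # rho_1 >= rho_2 >= ... in [0, 1]
    x_weights: pd.DataFrame             # original X variables x canonical pairs
    y_weights: pd.DataFrame
    reduction: str                      # "none" or e.g. "pca:12"

    @property
    def variance_explained_pct(self) -> np.ndarray:
        return 100.0 * self.correlations**2


def _orthobasis(x: np.ndarray, tol: float = 1e-10):
    """SVD-based orthonormal column basis of a centered matrix plus the map
    from basis coefficients back to variable-space weights."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > tol * (s[0] if len(s) else 1.0)).sum())
    q = u[:, :rank]
    back = vt[:rank].T / s[:rank]  # variables x rank: w = back @ (basis coefs)
    return q, back, rank


def canonical_correlation(x, y, reduction: float | int | None = 0.9) -> CcaResult:
    """Canonical correlation analysis of two centered blocks via QR/SVD.

    ``reduction`` controls the PCA pre-step on X: a float in (0, 1] keeps the
    leading components capturing that variance fraction, an int keeps that
    many components, ``None`` disables it. The pre-step is forced whenever X
    has >= n-1 columns (the ill-posed regime where raw CCA is vacuous).
    Canonical weights are returned in the original metabolite space.
    """
    xf, yf = _frame(x), _frame(y)
    if not xf.index.equals(yf.index):
        shared = xf.index.intersection(yf.index)
        xf, yf = xf.loc[shared], yf.loc[shared]
    if xf.isna().any().any() or yf.isna().any().any():
        raise ValueError("CCA requires complete matrices; impute first")
    n = len(xf)
    xc = xf.to_numpy(dtype=float) - xf.to_numpy(dtype=float).mean(axis=0)
    yc = yf.to_numpy(dtype=float) - yf.to_numpy(dtype=float).mean(axis=0)

    reduce_map = None
    reduction_desc = "none"
    need = xc.shape[1] >= n - 1
    if reduction is not None or need:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        frac = np.cumsum(s**2) / (s**2).sum()
        if isinstance(reduction, int) and reduction is not None and not isinstance(reduction, bool):
            k = min(reduction, len(s))
        elif reduction is None:
            k = len(s)
        else:
            k = int(np.searchsorted(frac, float(reduction)) + 1)
        k = max(1, min(k, n - 2 if n > 2 else 1, int((s > 1e-10).sum())))
        if need or (reduction is not None and k < xc.shape[1]):
            reduce_map = vt[:k].T            # variables x components
            xc = xc @ reduce_map
            reduction_desc = f"pca:{k}"

    qx, back_x, rx = _orthobasis(xc)
    qy, back_y, ry = _orthobasis(yc)
    if min(rx, ry) == 0:
        raise ValueError("a block is rank-deficient after centering")
    u, s, vt = np.linalg.svd(qx.T @ qy, full_matrices=False)
    rho = np.clip(s, 0.0, 1.0)
    a = back_x @ u          # reduced-X weights
    b = back_y @ vt.T
    if reduce_map is not None:
        a = reduce_map @ a  # back to metabolite space
    pairs = [f"CC{i + 1}" for i in range(len(rho))]
    return CcaResult(
        correlations=rho,
        x_weights=pd.DataFrame(a, index=xf.columns, columns=pairs),
        y_weights=pd.DataFrame(b, index=yf.columns, columns=pairs),
        reduction=reduction_desc,
    )


def pls_weights(x, y, n_components: int = 1) -> np.ndarray:
    """X-weight vectors of a fitted PLS regression (first weight ~ cov(X, y))."""
    xf = _frame(x).to_numpy(dtype=float)
    yv = np.asarray(_frame(y)).reshape(len(xf), -1)
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(xf, yv)
    return model.x_weights_


def pls_cross_validate(x, y, max_components: int = 10, folds: int = 10,
                       seed: int | None = None) -> pd.DataFrame:
    """K-fold cross-validated PLS regression of one response on X.

    Returns one row per component count with PRESS, RMSEP and
    Q2 = 1 - PRESS/TSS (TSS about the grand mean). Component counts beyond
    what the folds can support are truncated with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    xf = _frame(x)
    yv = np.asarray(_frame(y)).reshape(-1)
    n = len(xf)
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    xa = xf.to_numpy(dtype=float)
    cap = min(max_components, xa.shape[1], n - n // folds - 1)
    if cap < max_components:
        log.warning("pls_cross_validate: truncating to %d components", cap)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xa))
    tss = float(((yv - yv.mean()) ** 2).sum())
    rows = []
    for ncomp in range(1, cap + 1):
        press = 0.0
        for train, test in splits:
            model = PLSRegression(n_components=ncomp, scale=False)
            model.fit(xa[train], yv[train])
            pred = model.predict(xa[test]).reshape(-1)
            press += float(((yv[test] - pred) ** 2).sum())
        rows.append((ncomp, press, np.sqrt(press / n),
                     1.0 - press / tss if tss > 0 else np.nan))
    return pd.DataFrame(rows, columns=["n_components", "PRESS", "RMSEP", "Q2"])
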