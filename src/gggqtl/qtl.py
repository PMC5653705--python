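"""Per-marker linear-model QTL mapping with condition and interaction terms.

Every trait is regressed marker-by-marker on the model

    y = b0 + b1*e + b2*g + b3*(e:g) + eps

with the condition e coded 0/1 (first declared condition = 0) and the
genotype g coded +1 ('MM') / -1 ('Pimp'). Term significance is the partial F
test of dropping that single 1-df term from the full model, which equals the
squared t of its coefficient; LOD = -log10(p), with p floored at 1e-15 so
LOD caps at 15. Genome-wide significance comes from permutations that
shuffle genotype line labels *within* condition, preserving the E structure
under the no-G/no-GxE null.

The scan is vectorized across markers and traits through batched normal
equations but is numerically identical to the per-pair loop (tested).

Allele-substitution effects per condition follow from the coding:
effect in the baseline condition = b2, in the second condition = b2 + b3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import DesignAllocation, GeneticMap, GenotypeMatrix

log = logging.getLogger(__name__)

P_FLOOR = 1e-15
LOD_CEILING = -np.log10(P_FLOOR)

TERMS = ("E", "G", "GxE")
_TERM_COL = {"E": 1, "G": 2, "GxE": 3}  # design-matrix column of each term


def _lod_from_p(p):
    return -np.log10(np.clip(p, P_FLOOR, None))


# ---------------------------------------------------------------------------
# single fits


def fit_single_env(y, g) -> tuple[float, float]:
    """OLS of a trait on a single +/-1 genotype column in one condition.

    Returns (LOD, effect): LOD = -log10 of the two-sided p for the slope
    (1-df F test), effect = the slope. A monomorphic marker yields
    (nan, nan) with a warning.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    if len(np.unique(g)) < 2:
        log.warning("fit_single_env: monomorphic marker, LOD undefined")
        return np.nan, np.nan
    n = len(y)
    x = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    dof = n - 2
    if dof <= 0:
        return np.nan, float(beta[1])
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    if sigma2 == 0:
        return LOD_CEILING, float(beta[1])
    t2 = beta[1] ** 2 / (sigma2 * xtx_inv[1, 1])
    p = stats.f.sf(t2, 1, dof)
    return float(_lod_from_p(p)), float(beta[1])


def fit_combined(y, g, e) -> dict:
    """Full-model fit for one trait at one marker.

    Returns a dict with lod_e, lod_g, lod_gxe, the coefficient vector, and
    the per-condition allele effects (effect_cond0 = b2, effect_cond1 =
    b2 + b3). Terms that cannot be estimated (empty genotype-by-condition
    cell making the design rank-deficient) come back NaN.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g) | np.isnan(e))
    y, g, e = y[keep], g[keep], e[keep]
    n = len(y)
    x = np.column_stack([np.ones(n), e, g, e * g])
    out = {k: np.nan for k in ("lod_e", "lod_g", "lod_gxe",
                               "effect_cond0", "effect_cond1")}
    out["beta"] = np.full(4, np.nan)
    if n < 5 or np.linalg.matrix_rank(x) < 4:
        return out
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    dof = n - 4
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    for term, col in _TERM_COL.items():
        if sigma2 == 0:
            lod = LOD_CEILING
        else:
            t2 = beta[col] ** 2 / (sigma2 * xtx_inv[col, col])
            lod = float(_lod_from_p(stats.f.sf(t2, 1, dof)))
        out["lod_" + term.lower()] = lod
    out["beta"] = beta
    out["effect_cond0"] = float(beta[2])
    out["effect_cond1"] = float(beta[2] + beta[3])
    return out


# ---------------------------------------------------------------------------
# batched scan


def _batch_stats(y_mat: np.ndarray, g_mat: np.ndarray, e: np.ndarray):
    """Batched full-model statistics for complete data.

    y_mat: (n, T) traits; g_mat: (n, M) +/-1 genotypes; e: (n,) 0/1.
    Returns dict of (M, T) arrays f_e, f_g, f_gxe (squared-t statistics),
    (M, T) effect arrays, (M, 4, T) coefficients, the residual dof, and a
    boolean (M,) mask of estimable markers.
    """
    n, t_count = y_mat.shape
    m = g_mat.shape[1]
    h = g_mat * e[:, None]
    ones = np.ones(n)

    se = float(e.sum())
    sg = g_mat.sum(axis=0)
    sh = h.sum(axis=0)
    sgg = (g_mat * g_mat).sum(axis=0)
    shh = (h * h).sum(axis=0)
    sgh = (g_mat * h).sum(axis=0)
    seg = e @ g_mat
    seh = e @ h

    xtx = np.empty((m, 4, 4))
    xtx[:, 0, 0] = n
    xtx[:, 0, 1] = xtx[:, 1, 0] = se
    xtx[:, 0, 2] = xtx[:, 2, 0] = sg
    xtx[:, 0, 3] = xtx[:, 3, 0] = sh
    xtx[:, 1, 1] = se
    xtx[:, 1, 2] = xtx[:, 2, 1] = seg
    xtx[:, 1, 3] = xtx[:, 3, 1] = seh
    xtx[:, 2, 2] = sgg
    xtx[:, 2, 3] = xtx[:, 3, 2] = sgh
    xtx[:, 3, 3] = shh

    # estimable iff the genotype varies within each condition
    ok = np.ones(m, dtype=bool)
    for cond in (0.0, 1.0):
        sub = g_mat[e == cond]
        if len(sub):
            ok &= sub.min(axis=0) < sub.max(axis=0)
    if not ok.any():
        raise ValueError("no estimable markers (all monomorphic within a condition)")

    xty = np.empty((m, 4, t_count))
    xty[:, 0, :] = ones @ y_mat
    xty[:, 1, :] = e @ y_mat
    xty[:, 2, :] = g_mat.T @ y_mat
    xty[:, 3, :] = h.T @ y_mat

    beta = np.full((m, 4, t_count), np.nan)
    inv = np.full((m, 4, 4), np.nan)
    beta[ok] = np.linalg.solve(xtx[ok], xty[ok])
    inv[ok] = np.linalg.inv(xtx[ok])

    yy = (y_mat * y_mat).sum(axis=0)
    rss = np.clip(yy[None, :] - np.einsum("mkt,mkt->mt", beta, xty), 0.0, None)
    dof = n - 4
    sigma2 = rss / dof

    out = {"beta": beta, "dof": dof, "ok": ok}
    with np.errstate(invalid="ignore", divide="ignore"):
        for term, col in _TERM_COL.items():
            var = sigma2 * inv[:, col, col][:, None]
            f = np.where(var > 0, beta[:, col, :] ** 2 / var, np.inf)
            f[~ok] = np.nan
            out["f_" + term.lower()] = f
    out["effect_cond0"] = beta[:, 2, :]
    out["effect_cond1"] = beta[:, 2, :] + beta[:, 3, :]
    return out


@dataclass
class ScanResult:
    """LOD profiles and effects for every trait x marker pair.

    Each LOD/effect attribute is a DataFrame (traits as rows, markers as
    columns); ``effect_norm_*`` expresses the allele effect as a fraction of
    the trait's observed range.
    """

    map: GeneticMap
    lod_e: pd.DataFrame
    lod_g: pd.DataFrame
    lod_gxe: pd.DataFrame
    effect_cond0: pd.DataFrame
    effect_cond1: pd.DataFrame
    effect_norm_cond0: pd.DataFrame
    effect_norm_cond1: pd.DataFrame
    conditions: tuple[str, str]

    def lod(self, term: str) -> pd.DataFrame:
        return {"E": self.lod_e, "G": self.lod_g, "GxE": self.lod_gxe}[term]

    @property
    def traits(self) -> list[str]:
        return list(self.lod_g.index)

    def allele_sign(self) -> pd.DataFrame:
        """Which parental allele elevates the trait (mean effect over conditions)."""
        mean_eff = (self.effect_cond0 + self.effect_cond1) / 2.0
        return mean_eff.apply(lambda c: np.where(c > 0, "MM", "Pimp"))

    def to_long(self) -> pd.DataFrame:
        rows = []
        mk = self.map.markers
        for trait in self.traits:
            frame = pd.DataFrame({
                "trait": trait,
                "marker": self.lod_g.columns,
                "chrom": mk["chrom"].to_numpy(),
                "cm": mk["cm"].to_numpy(),
                "lod_e": self.lod_e.loc[trait].to_numpy(),
                "lod_g": self.lod_g.loc[trait].to_numpy(),
                "lod_gxe": self.lod_gxe.loc[trait].to_numpy(),
                f"effect_{self.conditions[0]}": self.effect_cond0.loc[trait].to_numpy(),
                f"effect_{self.conditions[1]}": self.effect_cond1.loc[trait].to_numpy(),
                f"effect_norm_{self.conditions[0]}": self.effect_norm_cond0.loc[trait].to_numpy(),
                f"effect_norm_{self.conditions[1]}": self.effect_norm_cond1.loc[trait].to_numpy(),
            })
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)


def _design_vectors(traits, geno: GenotypeMatrix, design: DesignAllocation):
    """Align trait samples to genotype rows; return (Y, G, e, trait names)."""
    samples = traits.samples
    unknown = set(samples["line"]) - set(geno.lines)
    if unknown:
        raise ValueError(f"samples reference ungenotyped lines {sorted(unknown)[:5]}")
    y = traits.values.to_numpy(dtype=float)
    g = geno.calls.loc[samples["line"]].to_numpy(dtype=float)
    e = (samples["condition"] == design.conditions[1]).to_numpy(dtype=float)
    if not ((samples["condition"] == design.conditions[0]) | (e == 1)).all():
        raise ValueError("sample conditions outside the design's condition set")
    return y, g, e, list(traits.values.columns)


def normalized_effect(trait_values, effect):
    """Allele effect as a fraction of the trait's observed range (NaN if flat)."""
    v = np.asarray(trait_values, dtype=float)
    rng_ = np.nanmax(v) - np.nanmin(v)
    if not np.isfinite(rng_) or rng_ == 0:
        return np.nan if np.isscalar(effect) else np.full_like(np.asarray(effect, float), np.nan)
    return np.asarray(effect, dtype=float) / rng_


def scan(traits, geno: GenotypeMatrix, design: DesignAllocation) -> ScanResult:
    """Fit the combined model at every trait x marker pair.

    Complete traits go through the batched path; traits with missing values
    are re-fit on their observed rows (still batched across markers). Markers
    that are monomorphic within a condition yield NaN rather than aborting
    the scan.
    """
    y, g, e, trait_names = _design_vectors(traits, geno, design)
    if np.isnan(g).any():
        raise ValueError("scan requires complete genotype calls")
    m = g.shape[1]
    t_count = len(trait_names)
    shape = (m, t_count)
    lod = {k: np.full(shape, np.nan) for k in ("e", "g", "gxe")}
    eff0 = np.full(shape, np.nan)
    eff1 = np.full(shape, np.nan)

    complete = ~np.isnan(y).any(axis=0)

    def fill(cols, res, dof):
        for key in ("e", "g", "gxe"):
            f = res["f_" + key]
            with np.errstate(invalid="ignore"):
                p = stats.f.sf(f, 1, dof)
            lod[key][:, cols] = _lod_from_p(p)
            lod[key][:, cols][np.isnan(f)] = np.nan
        eff0[:, cols] = res["effect_cond0"]
        eff1[:, cols] = res["effect_cond1"]

    if complete.any():
        res = _batch_stats(y[:, complete], g, e)
        fill(np.flatnonzero(complete), res, res["dof"])
    for j in np.flatnonzero(~complete):
        rows = ~np.isnan(y[:, j])
        res = _batch_stats(y[rows][:, [j]], g[rows], e[rows])
        fill(np.array([j]), res, res["dof"])

    ranges = np.nanmax(y, axis=0) - np.nanmin(y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm0 = np.where(ranges > 0, eff0 / ranges[None, :], np.nan)
        norm1 = np.where(ranges > 0, eff1 / ranges[None, :], np.nan)

    markers = geno.map.marker_names()

    def frame(arr):
        return pd.DataFrame(arr.T, index=trait_names, columns=markers)

    return ScanResult(
        map=geno.map,
        lod_e=frame(lod["e"]),
        lod_g=frame(lod["g"]),
        lod_gxe=frame(lod["gxe"]),
        effect_cond0=frame(eff0),
        effect_cond1=frame(eff1),
        effect_norm_cond0=frame(norm0),
        effect_norm_cond1=frame(norm1),
        conditions=(design.conditions[0], design.conditions[1]),
    )


# ---------------------------------------------------------------------------
# permutation threshold


@dataclass
class ThresholdResult:
    alpha: float
    n_perm: int
    null_max_lod: np.ndarray  # pooled per-trait genome-wide maxima
    threshold: float
    terms: tuple[str, ...] = ("G", "GxE")


def permutation_threshold(
    traits,
    geno: GenotypeMatrix,
    design: DesignAllocation,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | None = None,
    terms: tuple[str, ...] = ("G", "GxE"),
) -> ThresholdResult:
    """Genome-wide LOD threshold by within-condition genotype permutation.

    Each permutation shuffles which genotyped line is paired with which
    sample, separately within each condition (so the trait-condition
    association survives while any genotype linkage is destroyed), rescans,
    and records the genome-wide max LOD over the requested terms for every
    trait. The threshold is the empirical (1 - alpha) quantile of the pooled
    per-trait maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    y, g, e, _ = _design_vectors(traits, geno, design)
    if np.isnan(y).any():
        y = pd.DataFrame(y).fillna(pd.DataFrame(y).mean()).to_numpy()
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(e == 0)
    idx1 = np.flatnonzero(e == 1)
    f_keys = ["f_" + t.lower() for t in terms]

    maxima = np.empty((n_perm, y.shape[1]))
    dof = None
    for p_i in range(n_perm):
        perm = np.arange(len(e))
        perm[idx0] = rng.permutation(idx0)
        perm[idx1] = rng.permutation(idx1)
        res = _batch_stats(y, g[perm], e)
        dof = res["dof"]
        f_max = np.nanmax(
            np.stack([np.nanmax(res[k], axis=0) for k in f_keys]), axis=0
        )
        maxima[p_i] = f_max
    lod_max = _lod_from_p(stats.f.sf(maxima, 1, dof))
    pooled = lod_max.ravel()
    threshold = float(np.quantile(pooled, 1.0 - alpha))
    return ThresholdResult(alpha, n_perm, pooled, threshold, tuple(terms))


# ---------------------------------------------------------------------------
# QTL calls, hotspots, overlap

CALL_COLUMNS = [
    "trait", "term", "chrom", "peak_marker", "peak_cm", "peak_lod",
    "ci_lo_cm", "ci_hi_cm", "effect", "allele_sign",
]


def call_qtl(scan_result: ScanResult, thr: ThresholdResult | float,
             terms: tuple[str, ...] = ("G", "GxE"), lod_drop: float = 1.5) -> pd.DataFrame:
    """Call QTL peaks from supra-threshold LOD runs.

    Per trait and term, every chromosome carrying markers with LOD >=
    threshold yields one QTL: peak at the chromosome's max-LOD
    marker, support interval the contiguous stretch around the peak with
    LOD >= peak - ``lod_drop``, signed effect the mean per-condition allele
    effect at the peak, and allele_sign 'MM' if the MM allele elevates the
    trait.
    """
    threshold = thr.threshold if isinstance(thr, ThresholdResult) else float(thr)
    mk = scan_result.map.markers
    chroms = mk["chrom"].to_numpy()
    cms = mk["cm"].to_numpy()
    rows = []
    for term in terms:
        lod_df = scan_result.lod(term)
        for trait in scan_result.traits:
            lod_vec = lod_df.loc[trait].to_numpy()
            sig = np.flatnonzero(np.nan_to_num(lod_vec, nan=-1.0) >= threshold)
            if sig.size == 0:
                continue
            # supra-threshold runs merged per chromosome: one call per
            # chromosome carrying any significant marker
            breaks = np.flatnonzero(chroms[sig[1:]] != chroms[sig[:-1]])
            for run in np.split(sig, breaks + 1):
                peak = run[np.argmax(lod_vec[run])]
                chrom = chroms[peak]
                # 1.5-LOD support interval: walk outwards on the chromosome
                lo = hi = peak
                floor = lod_vec[peak] - lod_drop
                while lo - 1 >= 0 and chroms[lo - 1] == chrom and \
                        np.nan_to_num(lod_vec[lo - 1], nan=-np.inf) >= floor:
                    lo -= 1
                while hi + 1 < len(lod_vec) and chroms[hi + 1] == chrom and \
                        np.nan_to_num(lod_vec[hi + 1], nan=-np.inf) >= floor:
                    hi += 1
                eff = (scan_result.effect_cond0.loc[trait].iloc[peak]
                       + scan_result.effect_cond1.loc[trait].iloc[peak]) / 2.0
                rows.append((
                    trait, term, int(chrom), mk.index[peak], float(cms[peak]),
                    float(lod_vec[peak]), float(cms[lo]), float(cms[hi]),
                    float(eff), "MM" if eff > 0 else "Pimp",
                ))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def hotspot_table(calls: pd.DataFrame, gmap: GeneticMap, window_cm: float = 10.0) -> pd.DataFrame:
    """Bin the genome and count distinct traits with a QTL peak per bin.

    Bins above the 95th percentile of per-bin trait counts are flagged as
    hotspots.
    """
    rows = []
    for chrom, sub in gmap.markers.groupby("chrom", sort=False):
        top = sub["cm"].max()
        n_bins = int(np.floor(top / window_cm)) + 1
        for b in range(n_bins):
            lo, hi = b * window_cm, (b + 1) * window_cm
            if len(calls):
                in_bin = calls[(calls["chrom"] == chrom)
                               & (calls["peak_cm"] >= lo) & (calls["peak_cm"] < hi)]
                count = in_bin["trait"].nunique()
            else:
                count = 0
            rows.append((int(chrom), lo, hi, count))
    out = pd.DataFrame(rows, columns=["chrom", "bin_lo_cm", "bin_hi_cm", "n_traits"])
    if len(out) == 0 or len(calls) == 0:
        out["hotspot"] = False
        return out
    cutoff = np.percentile(out["n_traits"], 95)
    out["hotspot"] = (out["n_traits"] > cutoff) & (out["n_traits"] > 0)
    return out


def qtl_overlap(mqtl_calls: pd.DataFrame, phqtl_calls: pd.DataFrame,
                window_cm: float = 10.0) -> pd.DataFrame:
    """Count metabolite QTLs within ``window_cm`` of each phenotype QTL peak."""
    rows = []
    for _, ph in phqtl_calls.iterrows():
        if len(mqtl_calls):
            near = mqtl_calls[
                (mqtl_calls["chrom"] == ph["chrom"])
                & ((mqtl_calls["peak_cm"] - ph["peak_cm"]).abs() <= window_cm)
            ]
            count = len(near)
            traits = sorted(near["trait"].unique())
        else:
            count, traits = 0, []
        rows.append((ph["trait"], ph["term"], ph["chrom"], ph["peak_cm"],
                     count, ";".join(map(str, traits))))
    return pd.DataFrame(rows, columns=[
        "ph_trait", "ph_term", "chrom", "peak_cm", "n_mqtl", "mqtl_traits"])
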