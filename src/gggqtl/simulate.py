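"""Synthetic study generator: RIL genotypes, metabolomes and phenotypes.

Emulates the statistical skeleton of a two-condition generalized genetical
genomics (GGG) germination experiment: ~100 F8 recombinant inbred lines
genotyped at 865 markers on 12 chromosomes, each line assayed in exactly one
of two developmental conditions (dry seed / 6 h imbibed), with metabolite
abundances generated from an additive G + E + GxE linear model plus
correlated pathway-block factors and log-normal (i.e. Gaussian on the log2
scale) noise, and germination phenotypes built as sparse linear combinations
of metabolites.

Every generator is deterministic for a seed and returns the planted truth so
downstream recovery tests can score themselves.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .types import (
    DRY,
    GERMINATION_TRAITS,
    IMBIBED,
    DesignAllocation,
    GeneticMap,
    GenotypeMatrix,
    MetaboliteMatrix,
    PhenotypeMatrix,
    QtlTruthTable,
)

# study-scale defaults: 12 tomato chromosomes, 865 mapped markers, ~167
# measured metabolites of which 66 are structurally identified
DEFAULT_N_CHROM = 12
DEFAULT_N_MARKERS = 865
DEFAULT_CHROM_LENGTH_CM = 120.0
DEFAULT_N_LINES = 100
DEFAULT_N_METABOLITES = 167
DEFAULT_N_KNOWN = 66
#: pathway-module structure: six correlated blocks, mirroring the handful of
#: tight metabolic modules a seed metabolome decomposes into
DEFAULT_BLOCK_SPEC: tuple[tuple[int, float], ...] = ((10, 0.7),) * 6


def haldane_recombination(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, no interference."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination(r: np.ndarray | float) -> np.ndarray | float:
    """Expected recombination between homozygous RILs derived by selfing: 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_map(
    n_chrom: int = DEFAULT_N_CHROM,
    n_markers: int = DEFAULT_N_MARKERS,
    chrom_length: float = DEFAULT_CHROM_LENGTH_CM,
    seed: int | None = None,
) -> GeneticMap:
    """Uniform-random marker map with near-equal marker counts per chromosome."""
    if n_chrom < 1 or n_markers < n_chrom or chrom_length <= 0:
        raise ValueError(
            "need n_chrom >= 1, n_markers >= n_chrom and chrom_length > 0; "
            f"got ({n_chrom}, {n_markers}, {chrom_length})"
        )
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_markers, n_chrom)
    rows = []
    idx = 0
    for c in range(1, n_chrom + 1):
        k = base + (1 if c <= extra else 0)
        pos = np.sort(rng.uniform(0.0, chrom_length, size=k))
        # enforce strict ordering against (measure-zero) ties
        for j in range(1, k):
            if pos[j] <= pos[j - 1]:
                pos[j] = np.nextafter(pos[j - 1], np.inf)
        for p in pos:
            rows.append((f"m{idx + 1:04d}", c, float(p)))
            idx += 1
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "cm"]).set_index("marker")
    return GeneticMap(markers)


def simulate_ril_genotypes(
    gmap: GeneticMap, n_lines: int = DEFAULT_N_LINES, seed: int | None = None
) -> GenotypeMatrix:
    """Homozygous RIL mosaics by a Markov walk along each chromosome.

    The first marker of each chromosome is +1/-1 with probability 1/2; between
    adjacent markers the allele switches with the RIL-by-selfing recombination
    fraction 2r/(1+2r), r from the Haldane map function, so each marker's
    expected 'MM' frequency is 0.5 and linkage decays with map distance.
    """
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    for _, sub in gmap.markers.groupby("chrom", sort=False):
        k = len(sub)
        first = rng.choice([-1.0, 1.0], size=n_lines)
        if k == 1:
            cols.append(first[:, None])
            continue
        gaps = np.diff(sub["cm"].to_numpy())
        r_eff = ril_recombination(haldane_recombination(gaps))
        switches = rng.random((n_lines, k - 1)) < r_eff[None, :]
        steps = np.concatenate([first[:, None], np.where(switches, -1.0, 1.0)], axis=1)
        cols.append(np.cumprod(steps, axis=1))
    calls = pd.DataFrame(
        np.concatenate(cols, axis=1),
        index=pd.Index([f"RIL{i + 1:03d}" for i in range(n_lines)], name="line"),
        columns=gmap.marker_names(),
    )
    return GenotypeMatrix(calls, gmap)


def default_truth_table(
    gmap: GeneticMap,
    n_metabolites: int = DEFAULT_N_METABOLITES,
    n_qtl: int = 25,
    beta_g: float = 1.0,
    beta_gxe: float = 0.5,
    beta_e: float = 1.0,
    sigma: float = 1.0,
    seed: int | None = None,
) -> QtlTruthTable:
    """A plausible planted architecture: ``n_qtl`` metabolites each with one
    causal marker and G, E and GxE effects; the remainder pure noise with an
    E shift (imbibition moves much of the metabolome)."""
    rng = np.random.default_rng(seed)
    names = metabolite_names(n_metabolites)
    markers = rng.choice(gmap.marker_names(), size=min(n_qtl, n_metabolites), replace=False)
    rows = []
    for i, name in enumerate(names):
        if i < len(markers):
            sign = rng.choice([-1.0, 1.0])
            rows.append((name, markers[i], 0.0, beta_e, sign * beta_g, sign * beta_gxe, sigma))
        else:
            rows.append((name, None, 0.0, beta_e if i % 2 == 0 else 0.0, 0.0, 0.0, sigma))
    return QtlTruthTable(pd.DataFrame(rows, columns=list(QtlTruthTable.COLUMNS)))


def metabolite_names(n: int, n_known: int = DEFAULT_N_KNOWN) -> list[str]:
    """Names distinguishing 'known' (identified) from 'unknown' centrotypes."""
    known = min(n_known, n)
    return [f"met_{i + 1:03d}" for i in range(known)] + [
        f"unk_{i + 1:03d}" for i in range(n - known)
    ]


def plant_metabolome(
    geno: GenotypeMatrix,
    design: DesignAllocation,
    truth: QtlTruthTable,
    block_spec: Sequence[tuple[int, float]] = DEFAULT_BLOCK_SPEC,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> MetaboliteMatrix:
    """Generate log2-scale metabolite abundances with planted QTL effects.

    value(sample s, metabolite m) =
        beta0 + beta_e*e_s + beta_g*g_s + beta_gxe*e_s*g_s
        + lambda_b * u_{b(m), s} + Normal(0, sigma_m)

    with e coded 0/1 (first declared condition = 0), g coded +/-1 at the
    metabolite's causal marker, and u a per-block standard-normal sample
    factor with loading lambda = sigma*sqrt(rho/(1-rho)) so the within-block
    correlation of otherwise-null metabolites is ~rho. Missing entries are
    knocked out completely at random at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    truth.validate_against(geno.map)
    unassigned = set(geno.lines) - set(design.assignment.index)
    if unassigned:
        raise ValueError(f"lines without condition assignment: {sorted(unassigned)[:5]}")

    rng = np.random.default_rng(seed)
    lines = geno.lines
    cond = design.assignment.loc[lines]
    e = (cond == design.conditions[1]).to_numpy(dtype=float)
    n = len(lines)
    tbl = truth.table
    mets = list(tbl["trait"])
    m = len(mets)

    # block membership: consecutive blocks over the metabolite list
    block_of = np.full(m, -1)
    pos = 0
    for b, (size, _rho) in enumerate(block_spec):
        block_of[pos : pos + size] = b
        pos += size
        if pos >= m:
            break
    u = rng.standard_normal((n, len(block_spec)))

    values = np.empty((n, m))
    sigma = tbl["sigma"].to_numpy(dtype=float)
    noise = rng.standard_normal((n, m)) * sigma[None, :]
    for j in range(m):
        row = tbl.iloc[j]
        y = row["beta0"] + row["beta_e"] * e
        if row["marker"] is not None and not pd.isna(row["marker"]):
            g = geno.calls[row["marker"]].to_numpy(dtype=float)
            y = y + row["beta_g"] * g + row["beta_gxe"] * e * g
        b = block_of[j]
        if b >= 0:
            rho = block_spec[b][1]
            lam = sigma[j] * np.sqrt(rho / (1.0 - rho))
            y = y + lam * u[:, b]
        values[:, j] = y + noise[:, j]

    if missing_rate > 0:
        holes = rng.random((n, m)) < missing_rate
        values = np.where(holes, np.nan, values)

    samples = pd.DataFrame({"line": lines, "condition": cond.to_numpy()}, index=pd.Index(lines, name="sample"))
    vdf = pd.DataFrame(values, index=samples.index, columns=mets)
    ann = pd.DataFrame(
        {
            "known": [not str(x).startswith("unk_") for x in mets],
            "pathway": [f"PW{block_of[j] + 1}" if block_of[j] >= 0 else "" for j in range(m)],
        },
        index=pd.Index(mets, name="metabolite"),
    )
    return MetaboliteMatrix(vdf, samples, ann)


def plant_phenotypes(
    metab: MetaboliteMatrix,
    n_traits: int = 5,
    sparsity: float = 0.1,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> PhenotypeMatrix:
    """Germination traits as sparse weighted sums of metabolite columns.

    Each trait picks ``round(sparsity * n_metabolites)`` (>= 1, <= 20%)
    metabolites with standard-normal weights; Gmax is affinely squashed and
    clipped into [0, 1] to look like a germination fraction. The generating
    weights are recorded on the returned object for recovery tests.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if not 0.0 <= sparsity <= 0.2:
        raise ValueError("sparsity must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    vals = metab.values
    filled = vals.fillna(vals.mean())  # generation only; holes stay in the metabolome
    mcols = list(vals.columns)
    n_active = max(1, round(sparsity * len(mcols))) if sparsity > 0 else 0

    names = [
        GERMINATION_TRAITS[i] if i < len(GERMINATION_TRAITS) else f"trait_{i + 1}"
        for i in range(n_traits)
    ]
    weights = pd.DataFrame(0.0, index=pd.Index(mcols, name="metabolite"), columns=names)
    out = {}
    for t in names:
        active = rng.choice(mcols, size=n_active, replace=False)
        w = rng.standard_normal(n_active)
        weights.loc[active, t] = w
        y = filled[active].to_numpy() @ w + noise_sd * rng.standard_normal(len(filled))
        if t == "Gmax":
            sd = y.std(ddof=0)
            z = (y - y.mean()) / sd if sd > 0 else y * 0.0
            y = np.clip(0.5 + 0.2 * z, 0.0, 1.0)
        out[t] = y
    values = pd.DataFrame(out, index=vals.index)
    return PhenotypeMatrix(values, metab.samples.copy(), weights)
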