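"""Core data containers shared across the pipeline.

All tabular payloads are pandas objects so they slice, join and export
naturally; the dataclasses here only add the invariants that tie them
together (map consistency, sample bookkeeping, allele coding).

Conventions
-----------
* Genotype calls are coded ``+1`` for the *S. lycopersicum* ('MM') allele and
  ``-1`` for the *S. pimpinellifolium* ('Pimp') allele; missing calls are NaN.
  RILs at F8 are treated as fully homozygous (two allele classes only).
* Condition labels are arbitrary strings; in the two-condition germination
  design they default to ``"dry"`` and ``"imbibed6h"``, with dry coded 0 and
  imbibed 1 in the scan model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MM = 1
PIMP = -1

#: default condition labels of the dry / 6 h imbibed germination design
DRY = "dry"
IMBIBED = "imbibed6h"


@dataclass
class GeneticMap:
    """Ordered marker map: one row per marker with chromosome and cM position.

    ``markers`` is a DataFrame indexed by marker name with columns
    ``chrom`` (int) and ``cm`` (float), ordered by (chrom, cm).
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "cm"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"map needs columns {sorted(required)}")
        if self.markers.index.has_duplicates:
            dupes = self.markers.index[self.markers.index.duplicated()].unique()
            raise ValueError(f"duplicate marker names: {list(dupes[:5])}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["cm"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.markers["chrom"]))

    def marker_names(self) -> list[str]:
        return list(self.markers.index)


@dataclass
class GenotypeMatrix:
    """RIL x marker allele calls (+1/-1/NaN) tied to a :class:`GeneticMap`."""

    calls: pd.DataFrame
    map: GeneticMap

    def __post_init__(self) -> None:
        if list(self.calls.columns) != self.map.marker_names():
            raise ValueError("genotype columns must match map markers, in map order")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == MM) | (vals == PIMP)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"unknown allele code {vals[tuple(bad)]!r} at line "
                f"{self.calls.index[bad[0]]!r}, marker {self.calls.columns[bad[1]]!r}"
            )
        all_missing = np.isnan(vals).all(axis=0)
        if all_missing.any():
            name = self.calls.columns[int(np.argmax(all_missing))]
            raise ValueError(f"marker {name!r} has no observed calls")

    @property
    def lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_lines(self) -> int:
        return len(self.calls)


@dataclass
class DesignAllocation:
    """Assignment of each RIL to exactly one condition (the e term).

    ``assignment`` maps RIL id -> condition label; ``balance_score`` is the
    allele-frequency balance objective of the assignment (0 = perfect).
    """

    assignment: pd.Series
    conditions: tuple[str, ...]
    balance_score: float = np.nan

    def __post_init__(self) -> None:
        extra = set(self.assignment.unique()) - set(self.conditions)
        if extra:
            raise ValueError(f"assignment uses undeclared conditions {sorted(extra)}")
        sizes = self.assignment.value_counts()
        if len(sizes) == len(self.conditions) and sizes.max() - sizes.min() > 1:
            raise ValueError("subpopulation sizes differ by more than 1")

    def lines_in(self, condition: str) -> list[str]:
        return list(self.assignment.index[self.assignment == condition])

    def sizes(self) -> dict[str, int]:
        return {c: int((self.assignment == c).sum()) for c in self.conditions}


@dataclass
class QtlTruthTable:
    """Planted generative parameters for synthetic traits.

    One row per trait: the causal marker and the intercept, condition,
    additive and interaction coefficients of the generating linear model,
    plus the residual sd.
    """

    table: pd.DataFrame  # columns: trait, marker, beta0, beta_e, beta_g, beta_gxe, sigma

    COLUMNS = ("trait", "marker", "beta0", "beta_e", "beta_g", "beta_gxe", "sigma")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        if (self.table["sigma"] <= 0).any():
            raise ValueError("sigma must be > 0")

    def validate_against(self, gmap: GeneticMap) -> None:
        known = set(gmap.marker_names())
        bad = set(self.table["marker"].dropna()) - known
        if bad:
            raise ValueError(f"truth table references unknown markers {sorted(bad)[:5]}")


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite abundance table (log2 scale downstream).

    ``samples`` carries one row per sample with columns ``line`` and
    ``condition``; ``values`` is indexed identically by sample id. Optional
    ``annotations`` (indexed by metabolite) may carry ``known`` (bool) and
    ``pathway`` (semicolon-joined pathway ids).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not {"line", "condition"}.issubset(self.samples.columns):
            raise ValueError("samples needs columns 'line' and 'condition'")
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same sample index")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> pd.Series:
        return self.samples["condition"]

    def with_values(self, values: pd.DataFrame) -> "MetaboliteMatrix":
        return MetaboliteMatrix(values, self.samples, self.annotations)


@dataclass
class PhenotypeMatrix:
    """Sample x germination-trait table (Gmax, t10inv, t50inv, MGR, AUC).

    When generated synthetically, ``weights`` records the sparse
    metabolite-combination weights of each trait for recovery tests.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same sample index")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


GERMINATION_TRAITS = ("Gmax", "t10inv", "t50inv", "MGR", "AUC")


@dataclass
class CorrelationMatrix:
    """All-pairs Spearman correlations with raw and BH-adjusted p-values."""

    rs: pd.DataFrame
    p_raw: pd.DataFrame
    p_bh: pd.DataFrame
    n_obs: pd.DataFrame = field(default=None)  # pairwise-complete sample counts

    @property
    def variables(self) -> list[str]:
        return list(self.rs.columns)
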