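"""Readers and writers for every table the pipeline touches, plus the
structured run configuration.

All tabular formats are plain delimited text with header rows: genotypes as
CSV (lines x markers) with a marker-map side table, abundance/phenotype
matrices as TSV with leading ``sample``/``line``/``condition`` columns,
pathway annotation as GMT, graphs as edge-list TSV or GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .types import DesignAllocation, GeneticMap, GenotypeMatrix, MetaboliteMatrix, PhenotypeMatrix, QtlTruthTable

log = logging.getLogger(__name__)

DEFAULT_ALLELE_CODES = {
    "MM": 1.0, "Pimp": -1.0, "A": 1.0, "B": -1.0,
    "1": 1.0, "+1": 1.0, "-1": -1.0, "1.0": 1.0, "-1.0": -1.0,
}
MISSING_TOKENS = {"", "NA", "NaN", "nan", "-", "U"}


# ---------------------------------------------------------------------------
# genetic map + genotypes

def write_map(gmap: GeneticMap, path) -> None:
    gmap.markers.to_csv(path, sep="\t", index_label="marker")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", index_col="marker")
    return GeneticMap(df[["chrom", "cm"]].astype({"chrom": int, "cm": float}))


def write_genotypes(geno: GenotypeMatrix, geno_path, map_path=None) -> None:
    out = geno.calls.replace({1.0: "MM", -1.0: "Pimp"})
    out.to_csv(geno_path, index_label="line")
    if map_path is not None:
        write_map(geno.map, map_path)


def read_genotypes(geno_path, map_path, allele_codes: dict | None = None) -> GenotypeMatrix:
    codes = dict(DEFAULT_ALLELE_CODES if allele_codes is None else allele_codes)
    gmap = read_map(map_path)
    raw = pd.read_csv(geno_path, index_col="line", dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate line id {dup!r} in {geno_path}")

    def decode(cell, line, marker):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() in MISSING_TOKENS:
            return np.nan
        token = str(cell).strip()
        if token not in codes:
            raise ValueError(f"unknown allele code {token!r} at line {line!r}, marker {marker!r}")
        return codes[token]

    decoded = pd.DataFrame(
        [[decode(raw.at[li, mk], li, mk) for mk in raw.columns] for li in raw.index],
        index=raw.index, columns=raw.columns, dtype=float,
    )
    log.info("read_genotypes: %d lines x %d markers", *decoded.shape)
    return GenotypeMatrix(decoded, gmap)


# ---------------------------------------------------------------------------
# sample x variable matrices

def write_matrix(matrix, path) -> None:
    """Metabolite/phenotype TSV: sample id, line, condition, then variables."""
    df = matrix.values.copy()
    meta = matrix.samples[["line", "condition"]]
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index_label="sample")


def read_matrix(path, kind: str = "metabolite"):
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if not {"line", "condition"}.issubset(df.columns):
        raise ValueError(f"{path}: expected 'line' and 'condition' columns")
    samples = df[["line", "condition"]]
    values = df.drop(columns=["line", "condition"]).astype(float)
    log.info("read_matrix(%s): %d samples x %d variables", kind, *values.shape)
    if kind == "phenotype":
        return PhenotypeMatrix(values, samples)
    return MetaboliteMatrix(values, samples)


# ---------------------------------------------------------------------------
# allocation, truth table, annotation

def write_allocation(design: DesignAllocation, path) -> None:
    design.assignment.rename("condition").to_csv(path, sep="\t", index_label="line")


def read_allocation(path, conditions: tuple[str, ...] | None = None) -> DesignAllocation:
    s = pd.read_csv(path, sep="\t", index_col="line")["condition"]
    conds = conditions if conditions is not None else tuple(pd.unique(s))
    return DesignAllocation(s, conds)


def write_truth(truth: QtlTruthTable, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path) -> QtlTruthTable:
    df = pd.read_csv(path, sep="\t")
    df["marker"] = df["marker"].where(df["marker"].notna(), None)
    return QtlTruthTable(df)


def write_gmt(pathways: dict, path) -> None:
    with open(path, "w") as fh:
        for pw, members in pathways.items():
            fh.write("\t".join([pw, pw] + sorted(map(str, members))) + "\n")


def read_gmt(path) -> dict:
    """GMT: pathway, description, members... — empty sets skipped with warning."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT row")
            members = [m for m in parts[2:] if m]
            if not members:
                log.warning("%s:%d: pathway %r has no members, skipped", path, lineno, parts[0])
                continue
            out[parts[0]] = set(members)
    return out


def annotation_to_pathways(ann: pd.DataFrame) -> dict:
    """Metabolite-annotation frame (with 'pathway' column) -> pathway->members."""
    out: dict[str, set] = {}
    for met, row in ann.iterrows():
        for pw in str(row.get("pathway", "")).split(";"):
            if pw:
                out.setdefault(pw, set()).add(met)
    return out


# ---------------------------------------------------------------------------
# network exports

def write_edge_list(network, path) -> None:
    rows = [(u, v, d.get("rs", d.get("weight", np.nan)), d.get("weight", np.nan))
            for u, v, d in network.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "rs", "abs_rs"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(network, path) -> None:
    nx.write_graphml(network.graph, path)


def write_correlation_long(corr, path) -> None:
    cols = corr.rs.columns
    rows = []
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            rows.append((a, b, corr.rs.iloc[i, j], corr.p_raw.iloc[i, j],
                         corr.p_bh.iloc[i, j]))
    pd.DataFrame(rows, columns=["var1", "var2", "rs", "p", "p_bh"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


def _range(name, value, lo, hi, lo_open=False):
    ok = (value > lo if lo_open else value >= lo) and value <= hi
    if not ok:
        raise ValueError(f"config: {name}={value} outside [{lo}, {hi}]")


@dataclass
class PipelineConfig:
    """Structured configuration of a full run; unknown keys are rejected."""

    # paths (None -> synthetic generation for inputs, required for outputs)
    genotypes: str | None = None
    map: str | None = None
    metabolites: str | None = None
    phenotypes: str | None = None
    annotations: str | None = None
    output_dir: str = "gggqtl_out"
    # synthetic dimensions (used when no input paths given)
    n_lines: int = 100
    n_chrom: int = 12
    n_markers: int = 865
    chrom_length_cm: float = 120.0
    n_metabolites: int = 167
    missing_rate: float = 0.05
    # seeds
    seed: int = 1
    # design
    n_restarts: int = 10
    # preprocessing
    log2: bool = True
    z_cutoff: float = 3.0
    impute_k: int = 10
    rp_n_perm: int = 200
    # scan
    n_perm: int = 1000
    alpha: float = 0.01
    hotspot_window_cm: float = 10.0
    overlap_window_cm: float = 10.0
    # network
    corr_threshold: float = 0.5
    corr_fdr: float = 0.05
    d_in: float = 0.5
    cp_in: float = 0.5
    overlapping: bool = True
    sweep: bool = False
    sweep_n_random: int = 100
    # integration
    reduction: float = 0.9
    pls_folds: int = 10
    pls_max_components: int = 10

    def __post_init__(self) -> None:
        _range("missing_rate", self.missing_rate, 0.0, 0.499)
        _range("alpha", self.alpha, 0.0, 1.0, lo_open=True)
        _range("corr_threshold", self.corr_threshold, 0.0, 1.0)
        _range("corr_fdr", self.corr_fdr, 0.0, 1.0, lo_open=True)
        _range("d_in", self.d_in, 0.0, 1.0, lo_open=True)
        _range("cp_in", self.cp_in, 0.0, 1.0, lo_open=True)
        _range("reduction", self.reduction, 0.0, 1.0, lo_open=True)
        _range("z_cutoff", self.z_cutoff, 0.0, np.inf, lo_open=True)
        for name in ("n_lines", "n_chrom", "n_markers", "n_metabolites",
                     "impute_k", "n_perm", "rp_n_perm", "pls_folds",
                     "pls_max_components", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"config: {name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
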