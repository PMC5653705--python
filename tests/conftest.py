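import numpy as np
import pandas as pd
import pytest

from gggqtl import design, simulate
from gggqtl.types import DRY, IMBIBED, DesignAllocation, GeneticMap, GenotypeMatrix


@pytest.fixture(scope="session")
def small_map():
    return simulate.simulate_map(n_chrom=3, n_markers=30, chrom_length=100.0, seed=11)


@pytest.fixture(scope="session")
def small_geno(small_map):
    return simulate.simulate_ril_genotypes(small_map, n_lines=60, seed=12)


@pytest.fixture(scope="session")
def small_design(small_geno):
    return design.allocate(small_geno, 2, n_restarts=3, seed=13)


@pytest.fixture(scope="session")
def study_map():
    """Map at the study's dimensions: 12 chromosomes, 865 markers."""
    return simulate.simulate_map(seed=1)


def make_geno(calls: np.ndarray, positions=None, chrom=None, lines=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw call array (lines x markers)."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if positions is None:
        positions = np.arange(m, dtype=float) * 10.0
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    markers = pd.DataFrame(
        {"chrom": chrom, "cm": positions},
        index=pd.Index([f"m{i + 1}" for i in range(m)], name="marker"),
    )
    idx = lines if lines is not None else [f"L{i + 1}" for i in range(n)]
    return GenotypeMatrix(pd.DataFrame(calls, index=idx, columns=markers.index),
                          GeneticMap(markers))


def even_split(lines) -> DesignAllocation:
    """Deterministic alternating allocation used where balance is irrelevant."""
    labels = [DRY if i % 2 == 0 else IMBIBED for i in range(len(lines))]
    return DesignAllocation(pd.Series(labels, index=pd.Index(lines, name="line")),
                            (DRY, IMBIBED))
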