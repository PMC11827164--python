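import numpy as np
import pandas as pd
import pytest

from coexnet.containers import CountMatrix, SampleSheet
from coexnet.normalize import normalize_and_average
from coexnet.simulate import PlantedStructure, SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_raw_matrix() -> CountMatrix:
    frame = pd.DataFrame(
        {"s1": [2, 10, 100], "s2": [4, 20, 200]},
        index=["g1", "g2", "g3"],
    )
    return CountMatrix(frame, stage="raw")


@pytest.fixture
def duplicate_sheet() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "condition": ["c1", "c1"],
        "replicate": [1, 2],
    }))


@pytest.fixture(scope="session")
def planted_module_dataset():
    """120 genes, module of 11 (focal + 10 partners) at loading 0.95."""
    config = SimulationConfig(n_genes=120, seed=7)
    structure = PlantedStructure("module", tuple(range(10, 21)), 0.95)
    matrix, sheet, annotation, truth = simulate_dataset(config, [structure])
    averaged = normalize_and_average(matrix, sheet)
    return averaged, annotation, truth


@pytest.fixture(scope="session")
def planted_cluster_dataset():
    """54 genes on one contig with a 4-gene contiguous block at indices 20-23."""
    config = SimulationConfig(n_genes=54, genes_per_contig=54, seed=11)
    structure = PlantedStructure("contiguous_cluster", (20, 21, 22, 23), 0.9)
    matrix, sheet, annotation, truth = simulate_dataset(config, [structure])
    averaged = normalize_and_average(matrix, sheet)
    return averaged, annotation, truth


def rank_average(values) -> np.ndarray:
    """Independent average-rank oracle: midrank of tied groups, 1-based."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average of 1-based positions
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    """Textbook Pearson formula, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    mx, my = x.sum() / n, y.sum() / n
    num = float(((x - mx) * (y - my)).sum())
    den = float(np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum()))
    return num / den


def spearman_oracle(x, y) -> float:
    """Brute-force rank-then-Pearson Spearman."""
    return pearson_oracle(rank_average(x), rank_average(y))
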