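"""Core in-memory containers for the co-expression pipeline.

Everything downstream operates on a genes x samples count matrix, a sample
sheet mapping samples to (condition, replicate) slots, per-gene genomic
coordinates, and named gene cohorts. The containers are thin, validated
wrappers around pandas objects; coordinates are stored 0-based half-open
internally and converted only at the file-format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "GeneCohort",
    "Strand",
]

#: Valid values for the matrix ``stage`` flag.
STAGES = ("raw", "normalized", "averaged")

Strand = str  # one of "+", "-", "unknown"


@dataclass
class CountMatrix:
    """Genes x samples expression matrix with a processing-stage flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample (or condition) columns.
        Entries must be finite and non-negative; at ``stage="raw"`` they must
        additionally be whole numbers.
    stage
        One of ``"raw"`` (integer counts straight from read quantification),
        ``"normalized"`` (divided by size factors) or ``"averaged"``
        (normalized, replicate-averaged and rounded; columns are conditions).
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if self.values.empty:
            raise ValueError("count matrix is empty")
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene ID(s): {', '.join(map(str, dup_genes))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValueError(
                f"duplicate sample ID(s): {', '.join(map(str, dup_samples))}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count matrix contains non-numeric entries")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if self.stage == "raw" and not np.allclose(arr, np.round(arr)):
            raise ValueError("stage='raw' requires integer counts")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Row-subset preserving the requested order; missing IDs are an error."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"gene ID(s) not in matrix: {', '.join(missing)}")
        return CountMatrix(self.values.loc[list(gene_ids)].copy(), stage=self.stage)


@dataclass
class SampleSheet:
    """Maps each sample to one (condition, replicate) slot."""

    frame: pd.DataFrame  # columns: sample_id, condition, replicate

    REQUIRED = ("sample_id", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s): {', '.join(missing)}")
        f = self.frame
        dup = f["sample_id"][f["sample_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"sample(s) listed more than once: {', '.join(map(str, dup))}")
        if (f["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive integers")
        slot = f[["condition", "replicate"]].astype(str).agg("/".join, axis=1)
        if slot.duplicated().any():
            raise ValueError("two samples occupy the same (condition, replicate) slot")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["condition"].astype(str)))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.frame[self.frame["condition"].astype(str) == condition]
        return [str(s) for s in sel.sort_values("replicate")["sample_id"]]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]


@dataclass
class GeneAnnotation:
    """Per-gene genomic coordinates, 0-based half-open.

    ``frame`` is indexed by gene_id with columns chrom, start, end, strand.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end", "strand"):
            if col not in self.frame.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()].unique()
            raise ValueError(f"duplicate annotation record(s): {', '.join(map(str, dup))}")
        bad = self.frame[self.frame["start"] >= self.frame["end"]]
        if len(bad):
            raise ValueError(
                f"non-positive span for gene(s): {', '.join(map(str, bad.index))}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index


@dataclass
class GeneCohort:
    """A named list of gene IDs (e.g. the 13-gene cell-wall set)."""

    name: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.members)
        if len(set(members)) != len(members):
            seen: set[str] = set()
            dups = sorted({m for m in members if m in seen or seen.add(m)})
            raise ValueError(f"cohort {self.name!r} has duplicate member(s): {dups}")
        self.members = members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def missing_from(self, matrix: CountMatrix) -> list[str]:
        """Members absent from the matrix (callers decide whether to error)."""
        index = set(matrix.values.index.astype(str))
        return [m for m in self.members if m not in index]


def cohort_from_ids(name: str, ids: Iterable[str | int]) -> GeneCohort:
    return GeneCohort(name=name, members=tuple(str(i) for i in ids))
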