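"""Normalization, replicate averaging and housekeeping-relative expression
tiers.

The size-factor estimator is the median-of-ratios used by DESeq2: each gene's
reference is its geometric mean across samples (genes with any zero count are
ignored), and each sample's factor is the median over those genes of
count/reference. Only the size factors are re-implemented here — dispersion
estimation and differential testing are deliberately out of scope, because
nothing downstream consumes them.

Replicate averaging follows the study design the defaults mirror: normalized
counts are averaged within each condition and rounded half-away-from-zero to
whole numbers; conditions with a single sample pass through unaveraged.

Expression tiers are assigned relative to a housekeeping reference (actin,
beta-tubulin, GAPDH by default): per condition the reference is the arithmetic
mean of the housekeeping genes, a gene's peak ratio is its maximum
value/reference over conditions, and the tier is the highest threshold the
peak ratio strictly exceeds (high > 50%, moderate > 5%, detectable > 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "SizeFactors",
    "HousekeepingSet",
    "ClassificationThresholds",
    "ExpressionClassification",
    "HeatmapTable",
    "DEFAULT_HOUSEKEEPING",
    "median_of_ratios_size_factors",
    "apply_size_factors",
    "normalize_and_average",
    "classify_expression",
    "log10_heatmap",
    "proportion_percent",
    "category_sum",
    "round_half_away",
]

#: Actin, beta-tubulin and GAPDH protein IDs used as the default reference.
DEFAULT_HOUSEKEEPING = ("1265750", "1188384", "1372934")


@dataclass
class SizeFactors:
    """Per-sample positive scaling constants."""

    factors: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            bad = self.factors.index[self.factors <= 0]
            raise ValueError(f"non-positive size factor(s) for: {', '.join(map(str, bad))}")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


@dataclass
class HousekeepingSet:
    """Reference genes whose per-condition mean anchors expression tiers."""

    gene_ids: tuple[str, ...] = DEFAULT_HOUSEKEEPING

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        if len(self.gene_ids) < 1:
            raise ValueError("housekeeping set must contain at least one gene")


@dataclass
class ClassificationThresholds:
    """Peak-ratio cutpoints as fractions of the housekeeping mean.

    ``strict=True`` means the comparison is "> threshold" (the default);
    set False for ">=".
    """

    high: float = 0.50
    moderate: float = 0.05
    detectable: float = 0.01
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.detectable < self.moderate < self.high <= 1):
            raise ValueError(
                "thresholds must satisfy 0 < detectable < moderate < high <= 1"
            )


@dataclass
class ExpressionClassification:
    """Per-gene peak ratio and tier; ``frame`` has columns peak_ratio, tier."""

    frame: pd.DataFrame
    thresholds: ClassificationThresholds

    def tier_counts(self, nested: bool = False) -> dict[str, int]:
        """Disjoint tier counts, or nested counts (high ⊂ moderate ⊂ detectable)."""
        tiers = self.frame["tier"]
        disjoint = {t: int((tiers == t).sum())
                    for t in ("high", "moderate", "detectable", "below")}
        if not nested:
            return disjoint
        return {
            "high": disjoint["high"],
            "moderate": disjoint["high"] + disjoint["moderate"],
            "detectable": disjoint["high"] + disjoint["moderate"] + disjoint["detectable"],
            "below": disjoint["below"],
        }


@dataclass
class HeatmapTable:
    """log10-transformed matrix plus the rendering scale end-points.

    Values are not clipped to [floor, ceiling]; the end-points are metadata
    for whatever draws the two-colour scale.
    """

    values: pd.DataFrame
    floor: float = 0.0
    ceiling: float = 10.0

    def __post_init__(self) -> None:
        if self.floor >= self.ceiling:
            raise ValueError("heat-map floor must be below ceiling")


def median_of_ratios_size_factors(raw: CountMatrix) -> SizeFactors:
    """DESeq2-style median-of-ratios size factors.

    The per-gene reference is the geometric mean across samples, computed
    only over genes with strictly positive counts in every sample; adding an
    all-zero gene therefore changes nothing.
    """
    if raw.stage != "raw":
        raise ValueError("size factors are estimated from the raw count matrix")
    arr = raw.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "geometric-mean reference (pseudo-reference fallback is disabled)"
        )
    pos = arr[all_positive]
    log_ref = np.log(pos).mean(axis=1)  # log geometric mean per gene
    log_ratios = np.log(pos) - log_ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return SizeFactors(pd.Series(factors, index=raw.values.columns, dtype=float))


def apply_size_factors(raw: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Divide each sample by its size factor; stage becomes 'normalized'."""
    aligned = factors.factors.reindex(raw.values.columns)
    if aligned.isna().any():
        missing = aligned.index[aligned.isna()]
        raise ValueError(f"no size factor for sample(s): {', '.join(map(str, missing))}")
    return CountMatrix(raw.values / aligned, stage="normalized")


def round_half_away(values, decimals: int = 0):
    """Round half away from zero (spreadsheet-style), elementwise."""
    scale = 10.0 ** decimals
    arr = np.asarray(values, dtype=float) * scale
    rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    out = rounded / scale
    return float(out) if np.ndim(values) == 0 else out


def normalize_and_average(
    raw: CountMatrix,
    sheet: SampleSheet,
    factors: SizeFactors | None = None,
    round_result: bool = True,
) -> CountMatrix:
    """Normalize, average biological replicates per condition, and round.

    Columns of the result are condition labels in sheet order. Conditions
    with a single sample pass through unaveraged (but still rounded).
    """
    if raw.stage != "raw":
        raise ValueError("normalize_and_average expects the raw matrix")
    missing = [s for s in sheet.sample_ids if s not in raw.values.columns]
    if missing:
        raise ValueError(f"sheet sample(s) absent from matrix: {', '.join(missing)}")
    if factors is None:
        factors = median_of_ratios_size_factors(raw)
    normalized = apply_size_factors(raw, factors)
    columns = {}
    for condition in sheet.conditions:
        samples = sheet.samples_for(condition)
        if not samples:
            raise ValueError(f"condition {condition!r} has no samples")
        columns[condition] = normalized.values[samples].mean(axis=1)
    averaged = pd.DataFrame(columns)
    if round_result:
        averaged = pd.DataFrame(
            round_half_away(averaged.to_numpy()),
            index=averaged.index,
            columns=averaged.columns,
        )
    return CountMatrix(averaged, stage="averaged")


def classify_expression(
    avg: CountMatrix,
    housekeeping: HousekeepingSet | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> ExpressionClassification:
    """Tier each gene by its peak expression relative to the housekeeping mean.

    Per condition the reference is the arithmetic mean of the housekeeping
    genes; the per-gene peak ratio is max over conditions of value/reference.
    A silent housekeeping reference (zero mean in any condition) is a data
    problem and raises.
    """
    if avg.stage not in ("normalized", "averaged"):
        raise ValueError("classification runs on the normalized/averaged matrix")
    housekeeping = housekeeping or HousekeepingSet()
    thresholds = thresholds or ClassificationThresholds()
    missing = [g for g in housekeeping.gene_ids if g not in avg.values.index]
    if missing:
        raise ValueError(f"housekeeping gene(s) absent from matrix: {', '.join(missing)}")
    reference = avg.values.loc[list(housekeeping.gene_ids)].mean(axis=0)
    if (reference <= 0).any():
        silent = reference.index[reference <= 0]
        raise ValueError(
            "housekeeping reference is zero in condition(s): "
            + ", ".join(map(str, silent))
        )
    ratios = avg.values.div(reference, axis=1)
    peak = ratios.max(axis=1)

    def exceeds(r: float, cut: float) -> bool:
        return r > cut if thresholds.strict else r >= cut

    def tier(r: float) -> str:
        if exceeds(r, thresholds.high):
            return "high"
        if exceeds(r, thresholds.moderate):
            return "moderate"
        if exceeds(r, thresholds.detectable):
            return "detectable"
        return "below"

    frame = pd.DataFrame({
        "peak_ratio": peak,
        "tier": [tier(r) for r in peak],
    })
    return ExpressionClassification(frame=frame, thresholds=thresholds)


def log10_heatmap(
    matrix: CountMatrix, floor: float = 0.0, ceiling: float = 10.0
) -> HeatmapTable:
    """log10 transform with the zero rule: values below 1 map to 0.

    Values are not clipped; floor/ceiling are recorded for rendering.
    """
    if matrix.stage not in ("normalized", "averaged"):
        raise ValueError("heat maps are drawn from normalized/averaged values")
    if floor >= ceiling:
        raise ValueError("heat-map floor must be below ceiling")
    arr = matrix.values.to_numpy(dtype=float)
    out = np.where(arr >= 1, np.log10(np.where(arr >= 1, arr, 1.0)), 0.0)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return HeatmapTable(values=frame, floor=floor, ceiling=ceiling)


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half away from zero.

    Matches printed-report arithmetic such as "232 of 1114 -> 20.8%".
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    exact = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def category_sum(counts: Iterable[int] | Mapping[str, int]) -> int:
    """Exact integer total of named non-negative category counts."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    for v in values:
        if v < 0:
            raise ValueError("category counts must be non-negative")
    return int(sum(int(v) for v in values))
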