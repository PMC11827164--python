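"""Contiguous co-expressed gene clusters along chromosome coordinates.

A cluster is a maximal run of physically adjacent genes whose expression
profiles correlate across conditions. Detection is a transparent greedy
seed-and-extend scan: a cluster seeds at an adjacent pair with
rho >= rho_threshold and q < alpha, and extends rightward while the next
gene's median rho against the current qualifying members stays at or above
the threshold with a majority of those member pairs individually
significant. Up to ``max_silent_interior`` consecutive non-qualifying genes
are tolerated inside a cluster (they become silent interior members);
silent genes are never cluster edges. Emitted clusters are maximal,
non-overlapping (left-to-right greedy) and need at least ``min_size``
qualifying members.

Significance uses BH-FDR within each chromosome over the set of pairs the
scan actually tests. Because that set depends on the scan and the scan on
the q-values, the two are brought to a fixed point: start from all adjacent
pairs, scan, add newly tested extension pairs, re-adjust, re-scan, until the
tested set stabilizes (it grows monotonically, so this converges; in
practice one extra round suffices).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np

from .containers import CountMatrix, GeneAnnotation
from .network import EdgeRecord, NetworkParams, _edge_frame, make_edge

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "ClusterCall",
    "ConfirmationTable",
    "ClusterSummary",
    "order_genes_by_position",
    "detect_contiguous_clusters",
    "confirm_cluster_coexpression",
    "summarize_clusters",
]


@dataclass(frozen=True)
class ClusterParams:
    """Detection thresholds.

    expression_floor (normalized counts) marks genes whose peak expression
    falls below it as silent regardless of correlation; 0 disables it.
    statistic picks the extension summary over current members ("median"
    default, "mean" available).
    """

    min_size: int = 3
    rho_threshold: float = 0.4
    alpha: float = 0.05
    max_silent_interior: int = 1
    expression_floor: float = 0.0
    statistic: str = "median"

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be at least 2")
        if self.max_silent_interior < 0:
            raise ValueError("max_silent_interior cannot be negative")
        if self.statistic not in ("median", "mean"):
            raise ValueError("statistic must be 'median' or 'mean'")


@dataclass
class ClusterCall:
    """One contiguous cluster: consecutive genes on one chromosome."""

    cluster_id: str
    chromosome_id: str
    members: tuple[str, ...]            # all members, annotation order
    qualifying_members: tuple[str, ...]  # co-expressed members
    silent_members: tuple[str, ...]      # interior, not co-expressed
    span: tuple[int, int]                # base pairs, 0-based half-open

    @property
    def occupancy(self) -> int:
        return len(self.qualifying_members)


@dataclass
class ConfirmationTable:
    """Full pairwise re-test of a cluster; flagged = members with zero
    significant edges inside the cluster."""

    cluster_id: str
    edges: list[EdgeRecord]
    flagged: tuple[str, ...]


@dataclass
class ClusterSummary:
    n_clusters: int
    total_qualifying_genes: int
    occupancy_min: int | None
    occupancy_max: int | None
    occupancy_median: float | None


def order_genes_by_position(annotation: GeneAnnotation) -> dict[str, list[str]]:
    """Per-chromosome gene order: by start, ties by end then gene ID."""
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    frame = annotation.frame.reset_index(names="gene_id")
    ordered: dict[str, list[str]] = {}
    for chrom, sub in frame.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end", "gene_id"], kind="mergesort")
        ordered[str(chrom)] = [str(g) for g in sub["gene_id"]]
    return ordered


def _scan_chromosome(
    genes: list[str],
    usable: set[str],
    qmap: dict[tuple[str, str], tuple[float, float]],
    params: ClusterParams,
    needed: set[tuple[str, str]],
):
    """One greedy left-to-right pass; records every pair it consults."""

    def lookup(a: str, b: str) -> tuple[float, float] | None:
        key = tuple(sorted((a, b)))
        needed.add(key)
        return qmap.get(key)

    def seed_ok(a: str, b: str) -> bool:
        if a not in usable or b not in usable:
            return False
        entry = lookup(a, b)
        if entry is None:
            return False
        rho, q = entry
        return rho >= params.rho_threshold and q < params.alpha

    def qualifies(g: str, members: list[str]) -> bool:
        if g not in usable:
            return False
        rhos, hits = [], 0
        for m in members:
            entry = lookup(g, m)
            if entry is None:
                return False
            rho, q = entry
            rhos.append(rho)
            if rho >= params.rho_threshold and q < params.alpha:
                hits += 1
        summary = median(rhos) if params.statistic == "median" else float(np.mean(rhos))
        return summary >= params.rho_threshold and hits >= math.ceil(len(members) / 2)

    clusters: list[tuple[list[str], list[str]]] = []  # (all members, qualifying)
    i = 0
    while i < len(genes) - 1:
        if not seed_ok(genes[i], genes[i + 1]):
            i += 1
            continue
        qualifying = [genes[i], genes[i + 1]]
        all_members = [genes[i], genes[i + 1]]
        silent_run: list[str] = []
        j = i + 2
        while j < len(genes):
            g = genes[j]
            if qualifies(g, qualifying):
                all_members.extend(silent_run)  # silent genes become interior
                all_members.append(g)
                qualifying.append(g)
                silent_run = []
            else:
                silent_run.append(g)
                if len(silent_run) > params.max_silent_interior:
                    break
            j += 1
        # trailing silent genes in silent_run were never committed: trimmed
        if len(qualifying) >= params.min_size:
            clusters.append((all_members, qualifying))
            i = genes.index(all_members[-1]) + 1
        else:
            i += 1
    return clusters


def detect_contiguous_clusters(
    matrix: CountMatrix,
    annotation: GeneAnnotation,
    params: ClusterParams | None = None,
) -> list[ClusterCall]:
    """Greedy seed-and-extend cluster scan over every chromosome."""
    params = params or ClusterParams()
    if matrix.stage != "averaged":
        raise ValueError("cluster detection runs on the averaged matrix")
    in_matrix = set(map(str, matrix.values.index))
    covered = [g for g in annotation.gene_ids if g in in_matrix]
    if not covered:
        raise ValueError("annotation and matrix share no genes")
    skipped = len(annotation) - len(covered)
    if skipped:
        logger.info("%d annotated gene(s) absent from the matrix: skipped", skipped)
    ordered = order_genes_by_position(annotation)
    calls: list[ClusterCall] = []
    counter = 0
    for chrom in sorted(ordered):
        genes = [g for g in ordered[chrom] if g in in_matrix]
        if len(genes) < 2:
            continue
        values = matrix.values.loc[genes]
        arr = values.to_numpy(dtype=float)
        nonconstant = np.ptp(arr, axis=1) > 0
        expressed = (arr.max(axis=1) >= params.expression_floor
                     if params.expression_floor > 0
                     else np.ones(len(genes), dtype=bool))
        usable = {g for g, ok in zip(genes, nonconstant & expressed) if ok}

        family: set[tuple[str, str]] = {
            tuple(sorted((a, b)))
            for a, b in zip(genes, genes[1:])
            if a in usable and b in usable
        }
        clusters: list[tuple[list[str], list[str]]] = []
        for _ in range(5):
            if family:
                pairs = sorted(family)
                frame = _edge_frame(values.loc[sorted(usable)], pairs)
                qmap = {
                    (r.gene_a, r.gene_b): (float(r.rho), float(r.q))
                    for r in frame.itertuples()
                }
            else:
                qmap = {}
            needed: set[tuple[str, str]] = set()
            clusters = _scan_chromosome(genes, usable, qmap, params, needed)
            # only computable pairs can join the BH family
            new = {p for p in needed - family if p[0] in usable and p[1] in usable}
            if not new:
                break
            family |= new

        for all_members, qualifying in clusters:
            counter += 1
            silent = tuple(g for g in all_members if g not in qualifying)
            starts = annotation.frame.loc[list(all_members), "start"]
            ends = annotation.frame.loc[list(all_members), "end"]
            calls.append(ClusterCall(
                cluster_id=f"cluster_{counter:04d}",
                chromosome_id=chrom,
                members=tuple(all_members),
                qualifying_members=tuple(qualifying),
                silent_members=silent,
                span=(int(starts.min()), int(ends.max())),
            ))
    return calls


def confirm_cluster_coexpression(
    call: ClusterCall,
    matrix: CountMatrix,
    params: NetworkParams | None = None,
) -> ConfirmationTable:
    """Re-test a cluster: full pairwise edge table among all its members.

    Members with zero significant edges (q < alpha and rho above threshold)
    are flagged; constant-profile members cannot carry an edge and are
    flagged automatically. Spurious calls show every member flagged.
    """
    params = params or NetworkParams()
    members = [g for g in call.members if g in matrix.values.index]
    missing = set(call.members) - set(members)
    if missing:
        raise KeyError(f"cluster member(s) absent from matrix: {', '.join(sorted(missing))}")
    values = matrix.values.loc[members]
    arr = values.to_numpy(dtype=float)
    usable = [g for g, ok in zip(members, np.ptp(arr, axis=1) > 0) if ok]
    edges: list[EdgeRecord] = []
    connected: set[str] = set()
    if len(usable) >= 2:
        pairs = [(a, b) for i, a in enumerate(usable) for b in usable[i + 1:]]
        frame = _edge_frame(values.loc[usable], pairs)
        for r in frame.itertuples():
            edges.append(make_edge(r.gene_a, r.gene_b, r.rho, r.p, r.q))
            sig = r.q < params.alpha and (
                r.rho > params.rho_threshold if params.polarity == "positive_only"
                else abs(r.rho) > params.rho_threshold
            )
            if sig:
                connected.update((r.gene_a, r.gene_b))
    flagged = tuple(g for g in call.members if g not in connected)
    return ConfirmationTable(cluster_id=call.cluster_id, edges=edges, flagged=flagged)


def summarize_clusters(calls: Sequence[ClusterCall]) -> ClusterSummary:
    """Cluster count, total qualifying genes, occupancy min/max/median."""
    if not calls:
        return ClusterSummary(0, 0, None, None, None)
    occ = [c.occupancy for c in calls]
    return ClusterSummary(
        n_clusters=len(calls),
        total_qualifying_genes=sum(occ),
        occupancy_min=min(occ),
        occupancy_max=max(occ),
        occupancy_median=float(median(occ)),
    )
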