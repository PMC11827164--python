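"""File-format boundary: count matrices, sample sheets, annotations, cohorts,
and Cytoscape-loadable network exports.

GFF3/GTF coordinates (1-based, end-inclusive) are converted to the internal
0-based half-open convention exactly once, here. SIF relations carry the edge
sign: ``pp`` for positive, ``pn`` for negative Spearman correlations.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import gffutils
import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, GeneCohort, SampleSheet

if TYPE_CHECKING:  # pragma: no cover
    from .network import EdgeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "write_annotation_table",
    "read_cohort",
    "write_network",
    "read_edge_table",
    "write_heatmap_table",
    "write_classification",
    "write_clusters_bed",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _sep_for(path: str | Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if str(path).endswith(".csv") else "tsv"
    if fmt not in _SEPS:
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return _SEPS[fmt]


def read_counts(path: str | Path, format: str | None = None, stage: str = "raw") -> CountMatrix:
    """Read a gene x sample count table (first column gene IDs, header samples).

    Raises a descriptive error on duplicate IDs, negative or non-numeric
    cells, or an empty matrix; row/column order is preserved.
    """
    sep = _sep_for(path, format)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str},
                        float_precision="round_trip")
    if frame.empty:
        raise ValueError("count matrix is empty")
    frame.index = frame.index.astype(str)
    frame.index.name = None  # label is I/O dressing, not part of the matrix
    frame.columns = frame.columns.astype(str)
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna()]
            where = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in sample {col!r} at gene {where!r}"
            )
    return CountMatrix(frame, stage=stage)


def write_counts(matrix: CountMatrix, path: str | Path, format: str | None = None) -> None:
    sep = _sep_for(path, format)
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def read_sample_sheet(path: str | Path, format: str | None = None) -> SampleSheet:
    sep = _sep_for(path, format)
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "condition": str})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_annotation(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> GeneAnnotation:
    """Read gene coordinates from GFF3/GTF or a plain 4/5-column table.

    GFF3/GTF records are 1-based end-inclusive and are converted to 0-based
    half-open. Only features of ``feature_type`` are kept; the gene identifier
    comes from ``id_attribute`` (GTF default would be ``gene_id``; pass it
    explicitly). Features without a parseable ID are skipped with a warning.
    """
    if format == "table":
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = ("gene_id", "chrom", "start", "end")
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
        if "strand" not in frame.columns:
            frame["strand"] = "unknown"
        frame["strand"] = frame["strand"].fillna("unknown")
        frame = frame.set_index("gene_id")
        return GeneAnnotation(frame[["chrom", "start", "end", "strand"]])
    if format not in ("gff3", "gtf"):
        raise ValueError(f"format must be gff3, gtf or table, got {format!r}")
    if format == "gtf" and id_attribute == "ID":
        id_attribute = "gene_id"
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    skipped = 0
    for feat in db.features_of_type(feature_type):
        attrs = feat.attributes.get(id_attribute)
        gene_id = attrs[0] if attrs else None
        if not gene_id:
            skipped += 1
            continue
        start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
        if start0 >= end0:
            raise ValueError(f"gene {gene_id!r}: start >= end after conversion")
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        records.append((gene_id, feat.seqid, start0, end0, strand))
    if skipped:
        logger.warning("skipped %d %s feature(s) without a %r attribute",
                       skipped, feature_type, id_attribute)
    frame = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand"]
    ).set_index("gene_id")
    return GeneAnnotation(frame)


def write_annotation_table(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_cohort(path: str | Path, name: str | None = None) -> GeneCohort:
    """Plain-text cohort list: one gene ID per line, '#' starts a comment."""
    ids: list[str] = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            ids.append(entry)
    return GeneCohort(name=name or Path(path).stem, members=tuple(ids))


_EDGE_COLUMNS = ("gene_a", "gene_b", "rho", "p", "q", "sign")


def write_network(
    edges: Sequence["EdgeRecord"], path: str | Path, format: str = "edge_table"
) -> None:
    """Write edges as Cytoscape SIF ("A pp B" / "A pn B") or a TSV edge table.

    One line per unordered pair, ordered lexicographically for determinism.
    """
    ordered = sorted(edges, key=lambda e: (e.gene_a, e.gene_b))
    path = Path(path)
    if format == "sif":
        lines = [f"{e.gene_a} {'pp' if e.sign == '+' else 'pn'} {e.gene_b}" for e in ordered]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge_table":
        rows = [
            {"gene_a": e.gene_a, "gene_b": e.gene_b, "rho": e.rho,
             "p": e.p, "q": e.q, "sign": e.sign}
            for e in ordered
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"format must be 'sif' or 'edge_table', got {format!r}")


def read_edge_table(path: str | Path) -> list["EdgeRecord"]:
    from .network import EdgeRecord

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip",
                        dtype={"gene_a": str, "gene_b": str, "sign": str})
    return [
        EdgeRecord(row.gene_a, row.gene_b, float(row.rho), float(row.p),
                   float(row.q), row.sign)
        for row in frame.itertuples()
    ]


def write_heatmap_table(matrix: CountMatrix, path: str | Path,
                        floor: float = 0.0, ceiling: float = 10.0) -> None:
    """log10-transform a normalized/averaged matrix and write it as TSV.

    Raw-stage input is rejected: heat maps are drawn from normalized values.
    """
    from .normalize import log10_heatmap

    table = log10_heatmap(matrix, floor=floor, ceiling=ceiling)
    table.values.to_csv(path, sep="\t", index_label="gene_id")


def write_classification(classification, path: str | Path) -> None:
    """TSV with gene_id, peak_ratio, tier (see normalize.classify_expression)."""
    classification.frame.to_csv(path, sep="\t", index_label="gene_id")


def write_clusters_bed(calls, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end (0-based half-open), cluster_id,
    occupancy, comma-joined members, comma-joined silent members."""
    rows = []
    for call in calls:
        rows.append({
            "chrom": call.chromosome_id,
            "start": call.span[0],
            "end": call.span[1],
            "cluster_id": call.cluster_id,
            "occupancy": call.occupancy,
            "members": ",".join(call.members),
            "silent": ",".join(call.silent_members),
        })
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cluster_id", "occupancy",
                       "members", "silent"]
    ).to_csv(path, sep="\t", index=False)
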