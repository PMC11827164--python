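"""Negative-binomial count simulator with planted, ground-truthed structure.

The generator emulates the shape of a bulk RNA-Seq compendium over a wide
condition panel: by default 27 cultivation conditions in biological
duplicate, negative-binomial counts with a shared dispersion, a small set of
stably high housekeeping genes, and per-sample library size factors. Three
kinds of structure can be planted, each with a recorded ground truth so that
every downstream detector has a recovery test surface:

* ``module`` — members share a Gaussian latent condition factor scaled by a
  loading ``l``; the latent (log-mean) correlation between two members is
  ``l**2``, so a loading of ~0.95 targets a population rho near 0.9.
* ``regulator`` — the first member is the regulator; every other member
  couples to the regulator's own condition trajectory with a signed strength
  in [-1, 1] (negative plants a repressor).
* ``contiguous_cluster`` — like a module, but members must be consecutive
  gene indices (the synthetic annotation lays genes on contigs in index
  order with fixed spacing); listed silent positions get a near-zero
  baseline, mimicking a non-expressed gene inside cluster boundaries.

Per gene g and condition c the log mean is
``baseline_g + amplitude_g * effect_gc``, where ``effect_gc`` is standard
normal (independent per gene) unless the gene belongs to a planted
structure. Background genes draw their condition amplitude from a gamma
distribution so that — as in real bulk compendia, and as median-of-ratios
normalization assumes — the typical gene is only mildly condition-dependent
while a tail of genes responds strongly. Planted structures use the fixed
``condition_amplitude`` so their signal strength is controlled by the
loading alone. Counts are NB with mean ``exp(.) * size_factor_s`` and
variance ``mu + dispersion * mu**2``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PlantedStructure",
    "TruthRecord",
    "simulate_dataset",
    "export_fixture",
    "load_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 27 conditions x 2 replicates, NB dispersion 0.05,
    baseline log-means spanning ~20-1800 counts, 3 housekeeping genes."""

    n_genes: int = 200
    n_conditions: int = 27
    replicates_per_condition: int = 2
    nb_dispersion: float = 0.05
    mean_log_range: tuple[float, float] = (3.0, 7.5)
    condition_amplitude: float = 1.5
    housekeeping: int = 3
    housekeeping_log_mean: float = 9.5
    genes_per_contig: int = 100
    gene_length: int = 1500
    gene_spacing: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_conditions < 1 or self.replicates_per_condition < 1:
            raise ValueError("gene, condition and replicate counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.housekeeping > self.n_genes:
            raise ValueError("more housekeeping genes than genes")


@dataclass(frozen=True)
class PlantedStructure:
    """One planted module / regulator coupling / contiguous cluster.

    ``members`` are gene indices into the simulated matrix. ``strength`` is
    the latent-factor loading (module, contiguous_cluster) or the signed
    regulator-target coupling, in [-1, 1]. For regulators the first member
    is the regulator itself. ``silent_positions`` (contiguous_cluster only)
    lists members forced to near-zero expression.
    """

    kind: str
    members: tuple[int, ...]
    strength: float
    silent_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("module", "regulator", "contiguous_cluster"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if abs(self.strength) > 1:
            raise ValueError("|strength| cannot exceed 1")
        if len(set(self.members)) != len(self.members):
            raise ValueError("structure members must be distinct")
        if self.kind == "contiguous_cluster":
            ms = sorted(self.members)
            if any(b - a != 1 for a, b in zip(ms, ms[1:])):
                raise ValueError("contiguous_cluster members must be consecutive indices")
        bad = set(self.silent_positions) - set(self.members)
        if bad:
            raise ValueError(f"silent position(s) not among members: {sorted(bad)}")


@dataclass
class TruthRecord:
    """Everything needed to recompute the expected detection outcome."""

    config: SimulationConfig
    planted: tuple[PlantedStructure, ...]
    gene_ids: tuple[str, ...]
    housekeeping_ids: tuple[str, ...]
    baselines: tuple[float, ...]
    size_factors: dict[str, float]
    seed: int

    def structures_of(self, kind: str) -> list[PlantedStructure]:
        return [s for s in self.planted if s.kind == kind]

    def member_ids(self, structure: PlantedStructure) -> list[str]:
        return [self.gene_ids[i] for i in structure.members]


def _validate_planting(config: SimulationConfig,
                       planted: Sequence[PlantedStructure]) -> None:
    for s in planted:
        if max(s.members) >= config.n_genes or min(s.members) < 0:
            raise ValueError(f"planted member index out of range in {s.kind} structure")
    for kind in ("module", "regulator", "contiguous_cluster"):
        seen: set[int] = set()
        for s in planted:
            if s.kind != kind:
                continue
            if seen & set(s.members):
                raise ValueError(f"overlapping members across {kind} structures")
            seen |= set(s.members)


def simulate_dataset(
    config: SimulationConfig,
    planted: Sequence[PlantedStructure] = (),
) -> tuple[CountMatrix, SampleSheet, GeneAnnotation, TruthRecord]:
    """Draw one seeded dataset; identical seed gives bit-identical output."""
    _validate_planting(config, planted)
    rng = np.random.default_rng(config.seed)
    G, C, R = config.n_genes, config.n_conditions, config.replicates_per_condition

    gene_ids = tuple(f"g{i:05d}" for i in range(G))
    conditions = [f"cond{c + 1:02d}" for c in range(C)]
    samples = [f"{cond}_r{r + 1}" for cond in conditions for r in range(R)]

    lo, hi = config.mean_log_range
    baselines = rng.uniform(lo, hi, size=G)
    hk_idx = np.arange(config.housekeeping)
    baselines[hk_idx] = config.housekeeping_log_mean

    # independent per-gene condition trajectories, then overwrite planted genes
    effects = rng.standard_normal((G, C))
    # heterogeneous responsiveness: most genes mildly condition-dependent
    # (typical log-fold sd ~0.5), a tail strongly so
    amplitudes = rng.gamma(shape=2.0, scale=0.25, size=G)
    amplitudes[hk_idx] = 0.05  # housekeeping: near-constant across conditions
    for s in planted:
        if s.kind in ("module", "contiguous_cluster"):
            factor = rng.standard_normal(C)
            l = s.strength
            for i in s.members:
                noise = rng.standard_normal(C)
                effects[i] = l * factor + np.sqrt(max(0.0, 1 - l * l)) * noise
                amplitudes[i] = config.condition_amplitude
        elif s.kind == "regulator":
            reg, *targets = s.members
            trajectory = effects[reg]  # the regulator keeps its own path
            amplitudes[list(s.members)] = config.condition_amplitude
            c = s.strength
            for i in targets:
                noise = rng.standard_normal(C)
                effects[i] = c * trajectory + np.sqrt(max(0.0, 1 - c * c)) * noise
        if s.kind == "contiguous_cluster" and s.silent_positions:
            for i in s.silent_positions:
                baselines[i] = -4.0  # exp(-4) ~ 0.02 expected counts: silent

    log_mu = baselines[:, None] + amplitudes[:, None] * effects  # G x C
    size_factors = rng.uniform(0.6, 1.6, size=len(samples))
    mu = np.exp(log_mu)  # per condition; replicate means scale by size factor
    counts = np.empty((G, len(samples)), dtype=np.int64)
    r_shape = 1.0 / config.nb_dispersion
    for j, sample in enumerate(samples):
        cond_idx = j // R
        m = mu[:, cond_idx] * size_factors[j]
        p = r_shape / (r_shape + m)
        counts[:, j] = rng.negative_binomial(r_shape, p)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=list(gene_ids), columns=samples), stage="raw"
    )
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": samples,
        "condition": [s.rsplit("_", 1)[0] for s in samples],
        "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
    }))

    gpc, length, spacing = (config.genes_per_contig, config.gene_length,
                            config.gene_spacing)
    rows = []
    for i, gid in enumerate(gene_ids):
        contig = f"contig{i // gpc + 1:03d}"
        start = (i % gpc) * (length + spacing)
        rows.append((gid, contig, start, start + length, "+"))
    annotation = GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        .set_index("gene_id")
    )

    truth = TruthRecord(
        config=config,
        planted=tuple(planted),
        gene_ids=gene_ids,
        housekeeping_ids=tuple(gene_ids[i] for i in hk_idx),
        baselines=tuple(float(b) for b in baselines),
        size_factors={s: float(f) for s, f in zip(samples, size_factors)},
        seed=config.seed,
    )
    return matrix, sheet, annotation, truth


def export_fixture(
    matrix: CountMatrix,
    sheet: SampleSheet,
    annotation: GeneAnnotation,
    truth: TruthRecord,
    outdir: str | Path,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, annotation.tsv and truth.json."""
    from . import io as io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.{'json' if name == 'truth' else 'tsv'}"
             for name in ("counts", "samples", "annotation", "truth")}
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {', '.join(existing)}")
    io_formats.write_counts(matrix, paths["counts"])
    io_formats.write_sample_sheet(sheet, paths["samples"])
    io_formats.write_annotation_table(annotation, paths["annotation"])
    payload = {
        "config": asdict(truth.config),
        "planted": [asdict(s) for s in truth.planted],
        "gene_ids": list(truth.gene_ids),
        "housekeeping_ids": list(truth.housekeeping_ids),
        "baselines": list(truth.baselines),
        "size_factors": truth.size_factors,
        "seed": truth.seed,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def load_truth(path: str | Path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    config = SimulationConfig(**{
        **payload["config"],
        "mean_log_range": tuple(payload["config"]["mean_log_range"]),
    })
    planted = tuple(
        PlantedStructure(
            kind=s["kind"],
            members=tuple(s["members"]),
            strength=s["strength"],
            silent_positions=tuple(s.get("silent_positions", ())),
        )
        for s in payload["planted"]
    )
    return TruthRecord(
        config=config,
        planted=planted,
        gene_ids=tuple(payload["gene_ids"]),
        housekeeping_ids=tuple(payload["housekeeping_ids"]),
        baselines=tuple(payload["baselines"]),
        size_factors={k: float(v) for k, v in payload["size_factors"].items()},
        seed=payload["seed"],
    )
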