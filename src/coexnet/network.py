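"""Spearman co-expression networks with BH-FDR edge calling.

An edge is an unordered gene pair whose Spearman rank correlation passes a
magnitude threshold and whose BH-adjusted p-value passes an FDR level. The
BH family is always exactly the set of pairs computed in one call — a cohort
network, a one-vs-all scan, or a candidate x cohort block — mirroring
per-network significance reporting.

Two threshold presets matter in practice: cohort networks use rho > 0.4 at
FDR < 0.05, and genome-wide top-ten modules use rho > 0.86 at FDR < 1e-6.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneCohort

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "EdgeRecord",
    "Module",
    "RegulatorScore",
    "spearman_rho",
    "correlation_pvalue",
    "bh_adjust",
    "pairwise_edges",
    "all_vs_one",
    "top_k_module",
    "regulator_embedding",
    "count_pairs",
]


@dataclass(frozen=True)
class NetworkParams:
    """Thresholds for edge calling.

    polarity="positive_only" keeps rho > rho_threshold; "signed" keeps
    |rho| > rho_threshold and records the sign on each edge.
    """

    rho_threshold: float = 0.4
    alpha: float = 0.05
    k: int = 10
    polarity: str = "positive_only"

    def __post_init__(self) -> None:
        if not (0 <= self.rho_threshold <= 1):
            raise ValueError("rho_threshold must lie in [0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.polarity not in ("positive_only", "signed"):
            raise ValueError("polarity must be 'positive_only' or 'signed'")

    @classmethod
    def module_preset(cls) -> "NetworkParams":
        """Genome-wide top-ten module thresholds (rho > 0.86, FDR < 1e-6)."""
        return cls(rho_threshold=0.86, alpha=1e-6, k=10, polarity="positive_only")


@dataclass(frozen=True)
class EdgeRecord:
    """One unordered gene pair with rho, raw p, BH q and sign."""

    gene_a: str
    gene_b: str
    rho: float
    p: float
    q: float
    sign: str = "+"

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("EdgeRecord requires gene_a < gene_b; use make_edge")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def make_edge(gene_a: str, gene_b: str, rho: float, p: float, q: float) -> EdgeRecord:
    a, b = sorted((str(gene_a), str(gene_b)))
    return EdgeRecord(a, b, float(rho), float(p), float(q),
                      "+" if rho >= 0 else "-")


@dataclass
class Module:
    """Top-k partners of one focal gene, ranked by rho descending."""

    focal: str
    partners: list[tuple[str, float, float]]  # (gene_id, rho, q)

    def partner_ids(self) -> list[str]:
        return [p[0] for p in self.partners]


@dataclass
class RegulatorScore:
    """Signed embedding of one candidate regulator in a gene cohort."""

    regulator: str
    cohort: str
    n_positive: int
    n_negative: int
    cohort_size: int

    @property
    def embedding(self) -> int:
        return max(self.n_positive, self.n_negative)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson of average ranks).

    Returns NaN — the flagged "not computable" result — when either profile
    is constant, where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.debug("constant profile: Spearman undefined, returning NaN")
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def _exhaustive_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """p = fraction of the n! pairings with |rho| >= |observed rho|."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(_rank_corr(rx, ry))
    total = 0
    extreme = 0
    for perm in itertools.permutations(range(len(ry))):
        total += 1
        if abs(_rank_corr(rx, ry[list(perm)])) >= observed - 1e-12:
            extreme += 1
    return extreme / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def correlation_pvalue(
    rho: float,
    n: int,
    method: str = "t_approx",
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> float:
    """Two-sided p-value for a Spearman coefficient.

    ``t_approx`` uses t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom. ``permutation`` needs the paired profiles and is exhaustive for
    n <= 7, seeded Monte-Carlo otherwise.
    """
    if abs(rho) > 1 + 1e-12:
        raise ValueError("|rho| cannot exceed 1")
    if method == "t_approx":
        if n < 4:
            raise ValueError("t approximation needs n >= 4")
        if 1 - rho * rho <= 0:
            logger.info("|rho| = 1 under t approximation: returning p = 0")
            return 0.0
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        return float(2 * stats.t.sf(abs(t), df=n - 2))
    if method == "permutation":
        if x is None or y is None:
            raise ValueError("permutation method needs the paired profiles x, y")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) <= 7:
            return _exhaustive_permutation_p(x, y)
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(_rank_corr(rx, ry))
        extreme = 0
        for _ in range(n_resamples):
            perm = rng.permutation(len(ry))
            if abs(_rank_corr(rx, ry[perm])) >= observed - 1e-12:
                extreme += 1
        return (1 + extreme) / (1 + n_resamples)
    raise ValueError(f"method must be 't_approx' or 'permutation', got {method!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_pairs(n: int) -> int:
    """Number of unordered pairs among n genes: n(n-1)/2."""
    if n < 0:
        raise ValueError("cohort size cannot be negative")
    return n * (n - 1) // 2


def _usable_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant-profile genes (Spearman undefined) and report them."""
    arr = values.to_numpy(dtype=float)
    constant = np.ptp(arr, axis=1) == 0
    excluded = [str(g) for g in values.index[constant]]
    if excluded:
        logger.warning("excluded %d constant-profile gene(s): %s",
                       len(excluded), ", ".join(excluded))
    return values.loc[~constant], excluded


def _edge_frame(values: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """rho, t-approx p and BH q for an explicit list of gene pairs.

    The BH family is exactly ``pairs``. Profiles are rank-transformed once;
    rho is the Pearson correlation of the rank vectors.
    """
    n = values.shape[1]
    ranks = stats.rankdata(values.to_numpy(dtype=float), axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    row = {str(g): i for i, g in enumerate(values.index)}
    ia = np.array([row[a] for a, _ in pairs], dtype=int)
    ib = np.array([row[b] for _, b in pairs], dtype=int)
    rho = (centered[ia] * centered[ib]).sum(axis=1) / (norms[ia] * norms[ib])
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2))
    q = bh_adjust(p)
    return pd.DataFrame({
        "gene_a": [min(a, b) for (a, b) in pairs],
        "gene_b": [max(a, b) for (a, b) in pairs],
        "rho": rho, "p": p, "q": q,
    })


def _frame_to_edges(frame: pd.DataFrame) -> list[EdgeRecord]:
    return [make_edge(r.gene_a, r.gene_b, r.rho, r.p, r.q)
            for r in frame.itertuples()]


def _passes(frame: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    if params.polarity == "positive_only":
        keep = frame["rho"] > params.rho_threshold
    else:
        keep = frame["rho"].abs() > params.rho_threshold
    return frame[keep & (frame["q"] < params.alpha)]


def pairwise_edges(
    matrix: CountMatrix,
    cohort: GeneCohort,
    params: NetworkParams | None = None,
    return_excluded: bool = False,
):
    """All-pairs cohort network: C(n,2) candidates, BH within the call.

    Cohort genes missing from the matrix are a hard error; constant-profile
    genes are excluded from correlation (and reported) rather than given
    rho = 0 — rank correlation is undefined for them, and in practice such
    silent genes simply fail to connect.
    """
    params = params or NetworkParams()
    missing = cohort.missing_from(matrix)
    if missing:
        raise KeyError(f"cohort gene(s) absent from matrix: {', '.join(missing)}")
    values = matrix.values.loc[list(cohort.members)]
    values, excluded = _usable_rows(values)
    genes = [str(g) for g in values.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 non-constant cohort genes")
    pairs = list(itertools.combinations(genes, 2))
    frame = _edge_frame(values, pairs)
    edges = _frame_to_edges(_passes(frame, params))
    if return_excluded:
        return edges, excluded
    return edges


def all_vs_one(
    matrix: CountMatrix,
    focal: str,
    params: NetworkParams | None = None,
    filtered: bool = True,
) -> list[EdgeRecord]:
    """Edges between one focal gene and every other non-constant gene.

    The BH family is the whole focal-vs-rest set. With ``filtered=False`` the
    full table (no threshold applied) is returned, e.g. for module ranking.
    """
    params = params or NetworkParams()
    focal = str(focal)
    if focal not in matrix.values.index:
        raise KeyError(f"focal gene {focal!r} absent from matrix")
    if np.ptp(matrix.values.loc[focal].to_numpy(dtype=float)) == 0:
        raise ValueError(f"focal gene {focal!r} has a constant profile")
    values, _ = _usable_rows(matrix.values)
    partners = [str(g) for g in values.index if str(g) != focal]
    pairs = [(focal, p) for p in partners]
    frame = _edge_frame(values, pairs)
    if filtered:
        frame = _passes(frame, params)
    return _frame_to_edges(frame)


def top_k_module(
    edges: Sequence[EdgeRecord],
    k: int | None = None,
    params: NetworkParams | None = None,
    focal: str | None = None,
) -> Module:
    """Top-k partners of a focal gene by rho among q < alpha edges.

    Ties at the cut are broken lexicographically by partner ID. Fewer than k
    survivors yield a shorter module with a logged note.
    """
    params = params or NetworkParams.module_preset()
    k = params.k if k is None else k
    if focal is None:
        counts: dict[str, int] = {}
        for e in edges:
            counts[e.gene_a] = counts.get(e.gene_a, 0) + 1
            counts[e.gene_b] = counts.get(e.gene_b, 0) + 1
        if not counts:
            raise ValueError("cannot infer the focal gene from an empty edge list")
        focal = max(counts, key=lambda g: counts[g])
    survivors = []
    for e in edges:
        if focal not in e.pair:
            raise ValueError("top_k_module expects edges from a single focal gene")
        if e.q < params.alpha:
            partner = e.gene_b if e.gene_a == focal else e.gene_a
            survivors.append((partner, e.rho, e.q))
    survivors.sort(key=lambda t: (-t[1], t[0]))
    if len(survivors) < k:
        logger.info("only %d of %d requested partners pass q < %g for %s",
                    len(survivors), k, params.alpha, focal)
    return Module(focal=focal, partners=survivors[:k])


def regulator_embedding(
    matrix: CountMatrix,
    cohort: GeneCohort,
    candidates: GeneCohort,
    params: NetworkParams | None = None,
) -> list[RegulatorScore]:
    """Score candidate regulators by signed edge counts into a cohort.

    For each candidate, cohort genes with rho > rho_threshold (positive) or
    rho < -rho_threshold (negative) at q < alpha are counted; the BH family
    is all candidate x cohort pairs of the call. Candidates overlapping the
    cohort are dropped with a warning; scores are ranked by
    max(n_positive, n_negative) descending.
    """
    params = params or NetworkParams(polarity="signed")
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    overlap = set(candidates.members) & set(cohort.members)
    cand_ids = [c for c in candidates.members if c not in overlap]
    if overlap:
        logger.warning("removed %d candidate(s) overlapping the cohort: %s",
                       len(overlap), ", ".join(sorted(overlap)))
    if not cand_ids:
        raise ValueError("no candidates remain after removing cohort overlap")
    missing = [g for g in (*cand_ids, *cohort.members)
               if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene(s) absent from matrix: {', '.join(sorted(set(missing)))}")
    values = matrix.values.loc[[*cand_ids, *cohort.members]]
    values, excluded = _usable_rows(values)
    usable = set(map(str, values.index))
    usable_cohort = [g for g in cohort.members if g in usable]
    usable_cands = [c for c in cand_ids if c in usable]
    pairs = [(c, g) for c in usable_cands for g in usable_cohort]
    if not pairs:
        raise ValueError("no computable candidate-cohort pairs")
    frame = _edge_frame(values, pairs)
    # gene_a/gene_b are sorted within each pair; recover the candidate column
    frame = frame.assign(candidate=[c for c, _ in pairs])
    scores = []
    for cand in usable_cands:
        sub = frame[frame["candidate"] == cand]
        sig = sub["q"] < params.alpha
        n_pos = int(((sub["rho"] > params.rho_threshold) & sig).sum())
        n_neg = int(((sub["rho"] < -params.rho_threshold) & sig).sum())
        scores.append(RegulatorScore(
            regulator=cand, cohort=cohort.name,
            n_positive=n_pos, n_negative=n_neg,
            cohort_size=len(cohort),
        ))
    scores.sort(key=lambda s: (-s.embedding, s.regulator))
    return scores
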