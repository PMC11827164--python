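"""Gene IDs and re-analysis helpers for the *Fomes fomentarius* compendium.

The published 27-condition normalized matrix (distributed as supplementary
data alongside the study; raw reads under NCBI BioProject PRJNA957595) uses
JGI protein IDs. The IDs below are the published anchor genes: the
housekeeping reference (actin, beta-tubulin, GAPDH), the two positive-control
module seeds (erg11, tubB), the 13-gene cell-wall biosynthesis cohort, and
the regulator genes named in the study. Given a local copy of that matrix,
:func:`reproduce_study_networks` recomputes the headline network numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import CountMatrix, GeneCohort
from .network import NetworkParams, all_vs_one, pairwise_edges, top_k_module
from .normalize import (ClassificationThresholds, HousekeepingSet,
                        classify_expression)

__all__ = [
    "ACTA", "TUBB", "GPDA", "ERG11", "CACA", "CALA", "CALB",
    "CELL_WALL_COHORT", "StudyNetworkSummary", "reproduce_study_networks",
]

ACTA = "1265750"   # actin (act1/actA)
TUBB = "1188384"   # beta-tubulin (tub2/tubB)
GPDA = "1372934"   # glyceraldehyde-3-phosphate dehydrogenase (gpd1/gpdA)
ERG11 = "1348887"  # lanosterol 14-alpha demethylase
CACA = "15608"     # cell-wall-associated Zn(2)-Cys(6) transcription factor
CALA = "240859"    # predicted activator of lignin-modifying enzymes
CALB = "821366"    # predicted repressor of lignin-modifying enzymes

#: 13 conserved cell-wall biosynthesis genes: alpha-1,3-glucan synthase agsA,
#: beta-1,3-glucan synthases fksA/fksB, nine chitin synthases, and rhoA.
CELL_WALL_COHORT = GeneCohort("cell_wall", (
    "1363000",            # agsA
    "1313161", "1370413",  # fksA, fksB
    "1364985", "1367937", "1258680", "1397629", "1316987",
    "1374350", "1303258", "1370108", "682709",  # chitin synthases
    "1396228",            # rhoA
))


@dataclass
class StudyNetworkSummary:
    """Headline numbers recomputed from the published normalized matrix."""

    cell_wall_positive_pairs: int
    n_high: int            # genes > 50% of the housekeeping mean (nested)
    n_detectable: int      # genes > 1% of the housekeeping mean (nested)
    erg11_module_min_rho: float
    tubb_module_min_rho: float


def reproduce_study_networks(matrix: CountMatrix) -> StudyNetworkSummary:
    """Recompute the cohort network, expression tiers and module floors.

    ``matrix`` must be the published normalized, replicate-averaged
    27-condition table (stage 'averaged'), indexed by JGI protein ID.
    """
    cohort_params = NetworkParams(rho_threshold=0.4, alpha=0.05,
                                  polarity="positive_only")
    edges = pairwise_edges(matrix, CELL_WALL_COHORT, cohort_params)
    n_pairs = sum(1 for e in edges if e.sign == "+")

    classification = classify_expression(
        matrix,
        HousekeepingSet((ACTA, TUBB, GPDA)),
        ClassificationThresholds(),
    )
    nested = classification.tier_counts(nested=True)

    module_params = NetworkParams.module_preset()
    floors = []
    for focal in (ERG11, TUBB):
        edges = all_vs_one(matrix, focal, module_params, filtered=False)
        module = top_k_module(edges, k=10, params=module_params, focal=focal)
        floors.append(min(rho for _, rho, _ in module.partners))
    return StudyNetworkSummary(
        cell_wall_positive_pairs=n_pairs,
        n_high=nested["high"],
        n_detectable=nested["detectable"],
        erg11_module_min_rho=floors[0],
        tubb_module_min_rho=floors[1],
    )
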