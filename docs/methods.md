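# Methods

This note documents the statistical procedures implemented in `coexnet`,
the choices made where the design was genuinely open, and what the
simulation-based tests do and do not demonstrate.

## Normalization and replicate averaging

Library-depth correction uses the median-of-ratios estimator: for each gene
with strictly positive counts in every sample the reference is its geometric
mean across samples, and each sample's size factor is the median over those
genes of count/reference. Genes containing any zero are excluded from the
reference, so adding silent genes changes nothing. The estimator assumes the
typical gene is not differentially expressed between samples; it identifies
size factors only **up to one global constant** (scaling every factor by c
and every normalized count by 1/c is unobservable). Recovery tests therefore
compare estimated to injected factors after rescaling both to geometric mean
one. Dispersion estimation and differential testing are deliberately not
implemented — downstream rank statistics consume only the normalized counts.

Normalized counts are averaged within each condition (conditions with a
single library pass through) and rounded **half away from zero** to whole
numbers, the spreadsheet convention. Rounding is configurable off
(`round_result=False`).

## Expression tiers

Per condition, the reference is the arithmetic mean of the housekeeping
genes (defaults: actin `1265750`, beta-tubulin `1188384`, GAPDH `1372934`).
A gene's peak ratio is its maximum value/reference across conditions, and
its tier is the highest threshold the peak ratio **strictly** exceeds:
high > 50%, moderate > 5%, detectable > 1%, else below. Strictness is
configurable (`ClassificationThresholds(strict=False)`); per-condition
references (rather than one global mean) are used because tiers are defined
by expression "in at least one condition". Both disjoint tiers and nested
counts (high ⊂ moderate ⊂ detectable) are reported, since a headline count
like "detectably expressed" is naturally the nested one.

Heat-map export applies log10 with a zero rule — values below 1 map to 0
rather than −∞, matching a rendering floor of 0 — and records, but does not
clip to, the colour-scale floor/ceiling.

## Co-expression networks

Spearman's rho is the Pearson correlation of average-ranked profiles
(ties get midranks). Constant profiles have no defined rank correlation and
return NaN / are excluded from network construction rather than being
assigned rho = 0; empirically such silent genes simply fail to connect.

Raw p-values default to the t approximation,
t = rho·sqrt((n−2)/(1−rho²)) on n−2 degrees of freedom — the standard choice
in the R ecosystem and reliable at the default design size of n = 27
conditions. For small n a permutation p-value is available: exhaustive over
all n! pairings for n ≤ 7, seeded Monte-Carlo (with the +1 correction)
otherwise. |rho| = 1 under the t approximation returns p = 0 with a logged
note.

Benjamini–Hochberg adjustment is applied **within each call's computed pair
set**: a cohort network adjusts over its C(n,2) pairs, a one-vs-all scan
over its G−1 pairs, a regulator screen over all candidate × cohort pairs.
This matches per-network significance reporting and keeps each analysis
self-contained. Edge retention requires rho > rho_threshold (positive-only
mode) or |rho| > rho_threshold (signed mode) and q < alpha. Two presets
matter: cohort networks at rho > 0.4, FDR < 0.05, and genome-wide top-ten
modules at rho > 0.86, FDR < 1e-6. An FDR of 0.5 is reachable through
configuration but is not a default anywhere.

Top-k modules filter first (q < alpha), then rank by rho descending; ties at
the cut keep the lexicographically smaller partner ID, for determinism
across platforms. Regulator embedding counts, per candidate, cohort genes
with a significant positive (rho > thr) or negative (rho < −thr) edge and
ranks candidates by max(n_positive, n_negative); a symmetric negative
threshold is used because no separate negative cutoff is defined anywhere.

## Contiguous cluster detection

Genes are ordered per chromosome by start coordinate (ties: end, then ID;
internal coordinates are 0-based half-open). Detection is a greedy
seed-and-extend scan, stated fully so it is testable:

1. **Seed** at an adjacent pair with rho ≥ rho_threshold and q < alpha.
2. **Extend** rightward: a candidate gene joins if the median of its rhos
   against the current qualifying members is ≥ rho_threshold **and** a
   majority (≥ ⌈k/2⌉) of those member pairs are individually significant.
   The majority rule operationalizes "median rho … and significant": a
   median of correlations has no p-value of its own.
3. **Silent tolerance**: up to `max_silent_interior` (default 1) consecutive
   non-qualifying genes may sit inside a cluster; they are recorded as
   silent members only when a later gene qualifies, so silent genes can
   never be cluster edges.
4. **Emit** maximal non-overlapping clusters left to right with at least
   `min_size` (default 3) qualifying members.

The BH family is the set of pairs the scan actually tests on that
chromosome. Because that set depends on the scan and the scan on the
q-values, the two are iterated to a fixed point: start from all adjacent
pairs, scan, add newly consulted extension pairs, re-adjust, re-scan. The
family grows monotonically so the loop terminates (capped at 5 rounds; one
extra round suffices in practice). The median statistic is swappable for
the mean via `ClusterParams(statistic="mean")`.

`confirm_cluster_coexpression` re-tests any call with a full pairwise edge
table among its members and flags members without a single significant
edge — artificially grouped random genes flag everyone, so the confirmation
step rejects spurious calls. This algorithm is this package's own
re-specification of contiguous-cluster scanning; it does not claim to
replicate any external tool's catalogue.

## Synthetic data

The generator emulates a diverse bulk RNA-Seq compendium: 27 conditions in
biological duplicate, NB counts with shared dispersion 0.05
(variance = mu + 0.05·mu²), per-sample size factors uniform on [0.6, 1.6],
baseline log-means uniform on [3.0, 7.5] (≈20–1800 counts), and three
housekeeping genes with high baseline (e^9.5) and near-zero condition
effect. Background genes draw an individual condition amplitude from
Gamma(shape 2, scale 0.25) natural-log units — the typical gene varies
mildly (≈1.6-fold sd), a tail strongly, which is both what real compendia
look like and what median-of-ratios assumes. A shared dispersion (no
per-gene mean–dispersion trend) suffices because rank statistics are
insensitive to that fine structure.

Planted structure uses latent factors, not copulas: module and cluster
members get effect = l·f + sqrt(1−l²)·noise with a shared factor f, so the
latent (log-mean) correlation between members is l²; a loading of 0.95
plants population rho ≈ 0.9, which NB sampling attenuates to an observed
Spearman of roughly 0.75–0.9 at n = 27. Regulator targets couple to the
regulator's own trajectory with a signed strength (−0.8 plants a repressor).
Planted genes use a fixed amplitude of 1.5 so signal strength is controlled
by the loading alone. Silent cluster positions get baseline e^−4 ≈ 0
counts. Everything derives from one `numpy` generator seeded from the
config, so a seed reproduces the dataset bit for bit.

What passing recovery tests show: the detectors find the structure they are
designed for at realistic signal strength and the study's sample size, and
stay quiet on structure-free data. What they do not show: performance on
real data with batch effects, per-gene dispersion trends, correlated
background modules, or annotation errors — none of which the generator
imitates.

## Problem sizes in the shipped checks

The simulation-based checks run at deliberately modest scale — 120–500
genes per dataset, 50–100 seeded replicates for rate estimates, 2,000 genes
for size-factor recovery — chosen as the smallest sizes at which the
statistical properties under test (FDR control, ≥95% recovery rates, ≤5%
factor error) are informative rather than noise-dominated.

## Known limitations

* The supplementary 27-condition matrix is not bundled; the reproduction of
  the published network numbers runs only when a local copy is provided
  (see `tests/test_acceptance.py::test_study_matrix_reproduction`).
* Greedy left-to-right cluster maximality is order-dependent by design
  (deterministic, but a differently anchored scan could split ties
  differently).
* The t-approximation p-value is approximate under heavy ties; use the
  permutation method when that matters.
* No weighted-network methods (soft thresholding, eigengenes), no GO
  enrichment, no differential expression.
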