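# Methods

This note documents the statistical procedures implemented in `ncycle`, the
choices made where the methodology was genuinely open, and what the bundled
synthetic generator does and does not emulate.

## Inputs and resolution

The unit of annotation is the KEGG Orthology term (KO). Annotation platforms
report, per metagenome, one row per predicted protein-coding gene (GeneID)
with its KO assignment and an *Estimated Copy* value — the expected number
of sequences for that gene. Some KOs cover several paralogous genes
indistinguishably (K00370 is narG/narZ/nxrA); all statistics are therefore
computed per KO, and gene symbols are carried only as report aliases.
Estimated Copy is accepted as any positive real (annotation pipelines emit
non-integers); a value ≤ 0 is rejected at ingest, since a recorded GeneID
implies at least one expected sequence.

The packaged catalog covers 36 KOs in 20 protein complexes across six
pathways (nitrogen fixation, nitrification, denitrification, dissimilatory
nitrate reduction DNR, assimilatory nitrate reduction ANR, anammox). One
catalog row (NirS) inherits its pathway set from the preceding row of the
source table, whose pathway cell is a continuation blank; this matches
KEGG module membership for K15864.

## Gene metrics

Per (sample, KO): abundance = Σ Estimated Copy; richness = number of
distinct GeneIDs; variance = sample variance of the Estimated Copy values.

* **Variance denominator.** n−1 (the default of the common statistical
  environments used for this kind of analysis). Variance is *undefined* —
  stored as missing, never as 0 — when richness < 2, and undefined cells
  are excluded pairwise from correlations rather than imputed.
* **Zero rows.** Every (sample, catalog KO) cell exists, so absences are
  explicit (abundance 0, richness 0) and prevalence denominators are the
  full sample set.
* **Presence threshold.** A KO is "found" iff richness ≥ 1. No abundance
  cutoff is applied because none is defined by the source methodology.
* **Operon completeness.** A protein is present iff every KO of its operon
  is found; partial operons are absent. This is deliberately conservative:
  it reflects the genetic *potential* to express the complex.
* **Percentages** are printed to one decimal with ties rounded away from
  zero (21.875 → 21.9), matching the reporting style of survey papers.

## Correlation screen

Pearson r with the two-sided p-value from t = r√((n−2)/(1−r²)) on n−2
degrees of freedom (via `scipy.stats.pearsonr`). Missing data are handled
pairwise-complete and the per-pair n is reported; pairs with n < 3 or a
constant vector are undefined and excluded. Significance is flagged at raw
p < 0.05 by default, mirroring the masking convention of correlogram
figures in this literature; no multiple-testing correction is applied unless
the `bh_adjust` flag is set, in which case Benjamini–Hochberg-adjusted
p-values drive the flag. Gene–gene correlations default to the raw scale;
any transform (e.g. log1p) is the caller's choice before the call.

## Discretization and association rules

* **Quantile semantics.** The category boundaries "30 %/70 %" (and the
  median for two bins) are *empirical quantiles of the observed per-variable
  distribution*, computed with linear interpolation between order
  statistics. A value tied with the lower cut goes to the lower bin; values
  at or above the upper cut go to the upper bin. Cut points are reported
  alongside the categories (the partition table). Constant variables are
  flagged degenerate and excluded from mining. Default is 3 bins; a
  per-variable mapping can assign 2 bins (recommended for sparse counts).
* **Transactions.** One per sample: its category items plus one
  `Protein=Present`/`Protein=Absent` item per catalog protein. Whether
  absence is an explicit item or just a missing presence item is a switch
  (`absence_items`), since published rules mention both "lower values" and
  "absence" without fixing the encoding. Missing covariates emit no item.
* **Apriori** is implemented from scratch (level-wise candidate generation
  with prefix join and downward-closure pruning) and is validated against
  exhaustive enumeration of the item-set lattice in tests. Support,
  confidence and lift are exact transaction-count ratios, so
  `confidence = support/support(antecedent)` and
  `lift·support(consequent) = confidence` hold to machine precision.
* **Thresholds.** Defaults min_support = 0.1, min_confidence = 0.8, rules
  ranked by lift then support. The antecedent length is capped (default 10)
  to bound the lattice; the cap is logged. Real surveys keep only a curated
  set of "most significant" rules by unreported criteria, so no specific
  rule *count* is treated as reproducible.

## Spatial interpolation

"Linear interpolation for irregularly spaced data" is implemented as
Delaunay triangulation plus piecewise-planar barycentric interpolation
(this is exactly what the classical irregular-grid linear interpolators
perform; the smooth bicubic variant is out of scope). Properties used as
test oracles: affine fields are reproduced exactly, values are bounded by
their triangle's vertex values, sample nodes reproduce the inputs, and
nodes outside the convex hull are missing. Cocircular degeneracies are
broken by processing points in lexicographic order, which makes the simplex
listing deterministic; interpolated values near shared edges may still
differ between triangulators, which is documented rather than hidden.
Default grid: 200 × 200 over the bounding box with a 2 % margin. Rasters
are written as ESRI ASCII grid text (north-up rows, NODATA −9999).
Coordinates must be pre-projected planar meters; no geographic projection
handling is attempted.

## Synthetic generator

The generator emulates the *structure* of a 32-site soil metagenome survey;
it is not fit to any real dataset.

* **Gene records.** Per KO, detection is Bernoulli with a per-KO prevalence
  (defaults evenly spaced over [0.15, 1.0] across the catalog so that
  ubiquitous nasAB-like and rare hzs-like regimes are both exercised);
  detected KOs receive 1 + NegBin(size = 2, mean = 2) GeneIDs; Estimated
  Copy is log-normal(μ = 0, σ = 0.5).
* **Planted correlations** use a Gaussian copula: the target metric's
  normal scores (average ranks for ties, so zero-inflation does not dilute
  the signal) are mixed with independent noise at weight ρ, then scaled to
  the covariate's units. Because the coupling is on scores rather than raw
  values, realized Pearson correlations attenuate somewhat (about −0.51
  realized for a planted −0.6 on a moderately zero-inflated richness
  target at n = 32); the realized value for every covariate is stored in
  the truth record. Defaults plant pH ρ = −0.6 on nirK richness, soil water
  ρ = +0.6 on nosZ richness, nitrogen ρ = +0.5 on nifH abundance, plus an
  independent covariate and a spatial-gradient covariate.
* **Planted rules** are enforced after covariate generation: for every
  sample in the antecedent category (discretized exactly as the miner
  does), the consequent operon is completed (or deleted) with the stated
  obedience probability. Default: {soil water > 70 %} ⇒ NosZ present,
  obedience 1.
* **Coordinates** are a jittered 4-cluster layout in a 10 km region;
  spatial covariates decay as a Gaussian bump (length 3 km) around the
  first cluster center.
* Everything derives from a single integer seed; identical configs and
  seeds produce byte-identical files.

What passing tests on synthetic data show — and do not show: they verify
the pipeline's algebra (metrics, mining, screening, interpolation) and its
power to recover planted structure of stated strength at n = 32; they say
nothing about biological effect sizes, spatial autocorrelation of real
soils, compositionality or sequencing-depth artifacts, none of which the
generator models (no depth normalization is applied anywhere, matching the
raw-Estimated-Copy convention of the source methodology).

## Problem sizes and numerics

Test and acceptance runs use: 200 random databases (≤ 12 items × ≤ 40
transactions) for Apriori-vs-enumeration; 10,000 null replicates for
type-I calibration (accepted band 0.05 ± 0.01); 1,000 random tables for
metric conservation/oracle equivalence (relative tolerance 1e−9); 100
random layouts for interpolation exactness (absolute tolerance 1e−10); 500
seeds for sign recovery (≥ 95 % required). Rule statistics are exact
rationals evaluated in double precision; identities among them are asserted
at 1e−12.

## Known limitations

* KO-level resolution cannot separate paralogs sharing a KO, nor archaeal
  vs bacterial amoA variants.
* Presence calls ignore abundance, so one low-copy GeneID per subunit
  suffices for an operon call.
* The correlation screen is a screen: with dozens of variables at raw
  α = 0.05, some flagged pairs are expected false positives unless
  `bh_adjust` is enabled.
* Apriori is exponential in the worst case; with many near-ubiquitous items
  the antecedent cap, support threshold and consequent filter are the
  practical controls.
* Interpolated fields are not defined outside the convex hull and no
  uncertainty is attached to them.
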