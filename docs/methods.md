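# Methods

## Data model

A *marker matrix* holds binary presence calls for one TE family: rows are
SSAP loci (scored gel fragments, each marking one insertion junction),
columns are accessions, and every cell is 0 or 1 — dominant scoring admits
no missing values, and heterozygotes are indistinguishable from presence
homozygotes. A *taxon scheme* maps accessions to taxa and fixes the roles:
one maternal diploid, one paternal diploid, and an ordered list of
polyploid taxa. Taxon-level presence is defined as "at least one accession
carries the band", with no frequency threshold: with 4–6 accessions per
taxon a dominant band segregating at any appreciable frequency is almost
surely seen at least once, and a threshold would make results depend on
the (unequal) sampling per taxon. Loci absent from every accession are
retained but flagged, so locus indices stay stable across accession
subsets; all downstream computations skip them.

## Additivity scoring

The predicted profile of a polyploid is the union of the two diploid
taxon-level presence vectors — taxon-level, not per-accession, because
with multiple accessions per taxon only the taxon profile is defined.
Each (locus, polyploid) pair then receives exactly one label:
additive-present, missing (parental band absent from the polyploid), new
(band absent from both diploids), or absent-everywhere. Non-additive
bands fall into the sharing category given by the exact subset of
polyploid taxa showing the deviation; with k polyploids there are 2^k−1
non-empty subsets (the familiar 7-way table layout at k = 3: all three,
three pairs, three singletons).

Percentage conventions mirror the printed-table arithmetic they
reproduce, which is deliberately asymmetric: the "in all polyploids"
percentage is relative to the parental band total in both blocks;
per-taxon percentages are relative to the block's "in all" count for new
bands but to the parental total for lost bands; category percentages are
always relative to the block's "in all" count.

Losses of progenitor-specific bands are attributed to that progenitor;
losses of shared-parental bands are unattributable and are reported
separately but excluded from the paternal fraction and its 1:1 test.
The source tables do not state how shared-parental losses were handled;
excluding them is the only choice that keeps the fraction a genuine
binomial proportion over events of known origin.

A per-taxon *deviation proportion* is defined as
(new + missing)/(parental total + new): the share of all bands relevant
to that taxon that depart from additivity. The printed deviation
proportions in the source study use denominators that cannot be
reconstructed from any printed count, so this package defines its own
quantity and does not attempt to match those cells.

## Diversity estimation

With full inbreeding (F_IS = 1) every individual is homozygous, so the
probability that an accession shows no band equals the null-allele
frequency q, and the count of band-free accessions is Binomial(n, q).
The Bayesian estimator uses a Beta(a, b) prior fitted by moments to the
among-locus distribution of observed absence fractions
(a = m(m(1−m)/v − 1), b = (1−m)(m(1−m)/v − 1); uniform fallback when the
moments are degenerate), giving posterior mean q̂ = (n₀+a)/(n+a+b). The
prior is fitted per taxon per TE family, with presence-monomorphic loci
contributing absence fraction 0 — those loci carry real information about
the frequency spectrum. For F_IS < 1 the absence probability becomes
q² + F_IS·q(1−q) and the posterior mean is computed by adaptive
quadrature; the F_IS = 1 closed form is the package default and matches
the fully-selfing setting of the reproduced study.

Nei's gene diversity is reported as expected heterozygosity
H = mean over loci of 2q̂(1−q̂), with SE the among-locus standard
deviation over √L — the convention of standard dominant-marker software,
retained even though F_IS = 1 implies no actual heterozygotes, so H here
measures allele-frequency evenness rather than realized heterozygosity.
A locus is polymorphic when min(q̂, 1−q̂) ≥ the threshold (default 0.05).
Estimates are refused for single-accession taxa. How between-taxon
significance brackets on such diversity values should be computed is not
standardized; the package exposes H ± SE and leaves testing to the
caller.

## Inference procedures

All tests are implemented from their defining formulas; scipy supplies
only reference distributions.

- *Yates chi-square* (2×2 association and two-count ratio goodness of
  fit): per-cell correction max(0, |o−e|−0.5). The "one-sided" p follows
  the legacy statistics-package convention: half the chi-square(1) upper
  tail when the observed direction matches the stated alternative,
  otherwise 1 − half.
- *Fisher exact*: hypergeometric tail in the observed direction;
  two-sided p sums all tables with point probability ≤ the observed.
- *Wilson score interval* for a single proportion (the interval method
  recommended for band-count proportions); endpoints are the roots of
  (p̂−p)² = z²p(1−p)/n, returned exactly 0/1 at k = 0/k = n.
- *Holm step-down* ("sequential Bonferroni"): reject while
  p₍ᵢ₎ ≤ α/(m−i+1); adjusted p-values are the running maximum of
  (m−i+1)p₍ᵢ₎ capped at 1.
- *One-way ANOVA* with Tukey HSD using the studentized-range distribution
  at the within-group df and the Tukey–Kramer harmonic-mean adjustment.
  F is invariant to positive rescaling and common shifts, so proportions
  and percentages give identical statistics.
- *Mantel test*: Pearson correlation of lower triangles with simultaneous
  row/column permutations; the identity is included in the reference set,
  so p ≥ 1/(n_perm+1). When n! ≤ n_perm the full permutation group is
  enumerated and the p-value is exact. Default 9999 permutations, seeded.

The printed per-family chi-square statistics comparing progenitor-
specific band proportions could not be reconstructed under any standard
2×2 layout; the pipeline reports a specific-vs-rest construction without
asserting equality to those printed values.

## NeighborNet

Distances are uncorrected-P: the fraction of loci at which two accession
profiles differ. The circular ordering follows the published
agglomerative NeighborNet: clusters are chains carrying one or two active
representative nodes; each step selects the cluster pair minimizing the
neighbor-joining Q-criterion on cluster-averaged distances, then the
representative pair minimizing the same criterion with the two clusters'
nodes treated as singletons alongside the remaining clusters, links them,
and reduces the merged chain back to two representatives (the 3→2
reduction replacing a path x–y–z by u, v with
d(u,·) = ⅔d(x,·)+⅓d(y,·), d(v,·) = ⅔d(z,·)+⅓d(y,·),
d(u,v) = (d(x,y)+d(x,z)+d(y,z))/3). Ties break at the lowest index, so
the ordering is deterministic. Split weights are estimated by active-set
nonnegative least squares over all n(n−1)/2 splits compatible with the
circular ordering; exact zeros are dropped. Three-taxon inputs use the
closed-form star decomposition. On additive tree metrics the result is
the tree (splits = bipartitions, weights = branch lengths); on
circular-decomposable inputs the fitted distances reproduce the input to
numerical precision. The implementation was checked against an
independent R implementation during development and is tested against
forward-constructed split systems.

Bootstrap supports resample loci with replacement; a split's support is
the fraction of replicate networks containing the same bipartition. The
"confidence network" is implemented as a support-threshold filter
(default 0.95) on the original network's splits. An alternative reading
of a bootstrap confidence network — accumulating all splits appearing in
95% of replicates — exists; the filter was chosen because it annotates
exactly the estimated network and is the construction users of bootstrap
supports expect. Planar (equal-angle) embedding is out of scope; the
NEXUS SPLITS output renders in standard viewers.

## Simulator

The generator emulates the study's data structure: two diploid progenitor
taxa, three polyploid taxa on a ((REP,ISL),NUD) topology, and per-family
locus counts in three origin classes (shared, maternal-specific,
paternal-specific). The polyploid ancestor inherits the union of the
parental band sets. Five branches carry events, applied stem → internal →
terminals:

- *Losses* act on taxon-level band sets (whole-locus excision — what
  band disappearance can actually detect). Shared-origin and gained
  bands are lost independently with the branch rate λ. For
  progenitor-specific bands a Binomial(n_present, λ) number of loss
  events is drawn and each event removes a paternal-specific band with
  probability β (the paternal loss bias), a maternal one otherwise; an
  event whose side is exhausted is skipped, keeping the origin
  distribution of realized losses exactly at β (so β = 1 yields a
  paternal fraction of exactly 1).
- *Gains* are Poisson(γ·burst) on the stem and Poisson(γ) elsewhere and
  always create brand-new loci, never resurrect lost ones — an SSAP
  fragment marks a specific insertion junction.

Within every taxon each band in the band set segregates: a
presence-allele frequency is drawn from Beta(4, 1) (mean 0.8 — most
bands common but a visible minority segregating, consistent with highly
selfing material) and accessions are sampled as homozygous carriers
(F_IS = 1), with one carrier forced per band so taxon-level profiles
equal the logged band sets exactly. That forcing is what makes the
no-event limit exactly additive end to end and keeps the event log
replayable against pipeline output; its cost is that taxon-level
sampling noise (a segregating band missed in every sampled accession) is
not modeled, so simulated deviation counts are noise-free at the taxon
level in a way real resampled data would not be.

Default sampling sizes are the study's (4, 6, 5, 6, 4 accessions for the
maternal, paternal and three polyploid taxa). The seven default family
parameterizations reuse the printed per-family parental locus counts and
qualitatively contrast the families: higher gain means for the
amplification-prone SINE/LTR families (TS-, Tnt2-like), low gain and
higher loss for the ancient families (Au-, TRIM-like), and paternal loss
bias β between 0.55 and 0.75 throughout, strongest where losses were
reported as nearly exclusively paternal. Loss rates of 0.22–0.30 per
branch put the overall share of parental bands lost somewhere near
three-quarters, the regime the reproduced tables describe. These defaults
are illustrative study conditions, not fitted estimates.

What passing tests show: the pipeline recovers the generating β within
Wilson 95% bounds at realistic event counts, stem-only losses land
entirely in the shared-by-all category, gains and new-band calls
correspond one-to-one when not subsequently lost, and the no-event limit
is exactly additive. What they do not show: robustness to scoring error,
band homoplasy (co-migrating non-homologous fragments), or within-taxon
sampling noise, none of which the generator emulates.

## Numerical choices and problem sizes

Exact integer arithmetic is used for all count identities; percentage
comparisons against printed values allow half a unit in the last printed
decimal. NNLS uses scipy's active-set solver; split weights below 1e-10
are treated as zero. The ANOVA reproduction builds 7 groups × 7 family
proportions from the packaged counts and matches the printed F
statistics to ~0.2% (tolerance 0.5% relative; between-group SS to
3 decimals). Property tests run NeighborNet recovery on 5–8 taxon
metrics, Fisher/Mantel enumeration oracles on tables with N ≤ 12 and
4-taxon matrices, and the β-recovery simulation at 100 seeded replicates
of ~500 attributable losses each; bootstrap tests use 10–30 replicates
on 20–30 locus matrices, sizes chosen so the whole suite stays fast
while every contract is exercised at meaningful scale.

## Known limitations

- Band counts, not copy numbers: SSAP dominance hides zygosity, and the
  package never attempts to infer it.
- The parental-origin fraction conditions on progenitor-specific bands;
  if shared-parental losses were biased, that signal is invisible by
  construction.
- Whether a deviation arose in the polyploids or in the sampled diploid
  descendants after divergence from the true progenitors cannot be
  distinguished from these data, and the package does not try.
- The printed-table fixture reproduces published counts; six printed
  percentage cells and one printed chi-square set are internally
  inconsistent with their own counts and are annotated as such rather
  than matched.
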