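# ssapkit

Analysis of transposable-element (TE) insertion polymorphisms scored as
dominant markers (SSAP/AFLP-style presence/absence bands) in allopolyploid
species complexes.

An allopolyploid arises from hybridization between two diverged diploids
plus genome doubling, so its marker profile is expected to be *additive*:
the union of the band sets of its maternal and paternal progenitor taxa.
Departures from additivity — bands present in a polyploid but in neither
diploid ("new"), or parental bands absent from a polyploid ("missing") —
track the restructuring of TE genome fractions during diploidization.
`ssapkit` is aimed at researchers with per-family binary band matrices
(loci × accessions) and a taxon scheme naming the two progenitor taxa and
one or more derived polyploid taxa.

## What it computes

Given a band matrix `X ∈ {0,1}^{L×A}` and taxon-level presence
`P_t(l) = 1 iff ≥1 accession of taxon t carries locus l`:

- **Parental classification** — each locus is shared between the diploids,
  maternal-specific, paternal-specific, or absent from both; the predicted
  additive profile is `P_mat ∨ P_pat`.
- **Deviation scoring** — per polyploid taxon each locus is
  additive-present, missing, new, or absent everywhere; non-additive bands
  are partitioned into *sharing categories* (the subset of polyploid taxa
  carrying the deviation; 2^k−1 categories for k polyploids), and lost
  progenitor-specific bands are attributed to a parent, giving a paternal
  fraction of losses tested against 1:1.
- **Diversity** — per-locus null-allele frequencies `q̂` by the Bayesian
  dominant-marker estimator (Beta prior fitted by moments to among-locus
  absence fractions; with F_IS = 1 the posterior is
  Beta(a+n₀, b+n−n₀), q̂ = (n₀+a)/(n+a+b)), the proportion of polymorphic
  loci at the 5% level, and Nei's gene diversity H = mean 2q̂(1−q̂) ± SE.
- **Inference** — Yates-corrected one-sided chi-square (association and
  ratio goodness-of-fit), Fisher exact tests, Wilson score confidence
  intervals, Holm sequential-Bonferroni correction, fixed-effects one-way
  ANOVA with Tukey HSD, and Mantel permutation tests.
- **Split networks** — uncorrected-P distances between accession profiles,
  NeighborNet circular orderings, nonnegative-least-squares split weights,
  locus bootstrap supports and a support-threshold confidence network,
  exported as SplitsTree-compatible NEXUS.
- **Simulation** — an explicit generative model of parental band sets,
  union inheritance, biased band loss and gain bursts along a
  ((REP,ISL),NUD)-style polyploid subtree, with a replayable event log for
  parameter-recovery checks.

The package also ships a transcription of the printed count tables from a
published SSAP survey of an allopolyploid tobacco section (7 TE families,
5 taxa, 25 accessions) so that every derivable statistic can be recomputed
exactly; raw matrices for that study were never deposited.

## Worked example

Recompute the printed-table statistics from the packaged counts:

```
$ ssapkit tables
ANOVA (new bands): F=4.990 df=(6,42) p=0.0006151
ANOVA (lost bands): F=44.049 df=(6,42) p=1.447e-16
207 printed cells checked; 201 match, 6 whitelisted, 0 unexplained mismatches
```

The two F statistics test whether new (resp. lost) non-additive bands are
evenly spread across the 7 sharing categories: per TE family, the category
counts are divided by the family's "in all polyploids" count, and the 7
resulting proportions per category form one ANOVA group. Both are highly
significant — deviations concentrate in particular categories (for losses,
chiefly the shared-by-all-polyploids category, i.e. events early on the
common polyploid stem). The six whitelisted cells are printed values with
documented rounding slips that the comparison annotates rather than flags.

Simulate a study-shaped dataset and analyse one family:

```
$ ssapkit simulate --seed 3 --out demo/
$ ssapkit diversity --matrix demo/matrix_Au.tsv --scheme demo/taxa.tsv --te Au
SYL: bands=50 P%=18.8 H=0.1108 +/- 0.0146
TRI: bands=52 P%=26.7 H=0.1301 +/- 0.0158
NUD: bands=55 P%=33.7 H=0.1768 +/- 0.0166
REP: bands=42 P%=18.8 H=0.0929 +/- 0.0145
ISL: bands=45 P%=18.8 H=0.1125 +/- 0.0149
$ ssapkit network --matrix demo/matrix_Au.tsv --te Au --bootstrap 1000 \
      --threshold 0.95 --seed 1 --out demo/au.nex
```

`H` is Nei's gene diversity with its among-locus standard error; `P%` the
share of loci polymorphic at the 5% level; the NEXUS outputs open directly
in split-network viewers. The full chain (`ssapkit run --mode simulate`
or `--mode matrices`) writes the parental-distribution, deviation-block,
diversity, loss-origin and ANOVA tables as CSV plus per-family networks.

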