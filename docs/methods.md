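# Methods

This note documents the models, conventions, numerical choices, and open
design decisions behind `enhancerscan`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinates and interval conventions

All coordinates are 0-based, half-open (`[start, end)`), the native BED
convention. GTF input (1-based, closed) is converted on read; nothing
downstream ever sees 1-based coordinates. Overlap is strict half-open
overlap: abutting intervals do not overlap. "Upstream" and "downstream" in
all neighbour searches mean left and right in reference coordinates,
ignoring gene strand — the behaviour of common nearest-gene annotation tools
(`intervals.NEIGHBOR_DIRECTION` records the convention). Ties in neighbour
searches (two genes ending at the same coordinate) break to the
lexicographically smaller gene id, for determinism.

The promoter mask is `[tss − flank, tss + flank + 1)` per gene (default
flank 5 kb), clipped to the chromosome; the extra base makes the mask
symmetric around the TSS base itself. One TSS per gene is the default; GTF
transcript records are retained so `promoter_regions(per_transcript=True)`
can emit one interval per transcript start site instead.

## Fragments and coverage

Fragments are reconstructed from mate coordinates as the outermost span
(`[min, max)`), matching pipelines that elongate paired-end reads to the
original insert before counting. Pairs longer than the maximum insert
(default 2000 bp, the accessibility-mapping ceiling) or with mates on
different chromosomes are dropped with logged counts. Deduplication keeps
one fragment per exact `(chrom, start, end)` triple, mirroring
single-coordinate-pair PCR-duplicate removal.

Coverage counts whole-fragment overlap per bin: a fragment contributes 1 to
every bin it touches. This is deterministic, cheap, and matches
BEDTools-style fragment coverage on elongated reads; it is not per-base
pileup averaging. Summits are leftmost-maximal bins at bin resolution;
zero-coverage peaks return their midpoint and log a low-confidence warning.
Signal matrices zero-pad at chromosome edges rather than truncating, so
heatmap exports stay rectangular.

## Differential accessibility

The detector realizes a windowed likelihood-ratio (G) test between one
pooled fragment library per condition:

* windows: 1000 bp, step 100 bp (both configurable); a fragment counts in
  every window it overlaps;
* per window, the 2×2 table `{a, total_a − a; b, total_b − b}` gives
  `G = 2 Σ O ln(O/E)` with expectations from the margins and `0·ln 0 ≡ 0`;
  no continuity correction; both counts zero short-circuits to
  `(G, p) = (0, 1)`;
* p-values are Benjamini–Hochberg adjusted across all tested windows
  (delegated to `statsmodels.stats.multitest.multipletests`, cross-checked
  in the tests against a hand-coded step-up);
* windows pass at `q ≤ 0.05` and library-size-normalized fold `≥ 2`. The
  fold uses a pseudocount of 0.5 on each count — only for the fold estimate,
  never for G;
* significant windows of the same direction merge when their gap is below
  one step; opposite directions never merge. Merged regions carry the union
  span, the smallest q (with its p), the largest G, and the
  largest-magnitude log2 fold.

Normalization is by total deduplicated fragments. A consequence worth
knowing: strong planted (or real) signal in one condition inflates that
library's total, which shifts every background window slightly toward the
other direction ("composition bias"). At the fixture's signal density this
produces occasional opposite-direction false calls; the fold filter removes
most of them, and the planted-recovery test measures the residual FDR
honestly rather than hiding it. No replicate dispersion is modeled — the
supported design is one pooled library per condition.

Fragment shifting is deliberately absent: inputs are already elongated
full-length fragments.

## Binding categories and enhancer calling

Peaks from the three sources are clustered by transitive overlap (a sorted
sweep; equivalent to union–find over pairwise overlaps, which the tests
assert). The 7 non-empty flag triples map to categories 1–7. The default
map is anchored where the category analysis pins it — category 3 = all
three sources, 5 = T_NotoP + Foxa2, 7 = Foxa2 only, 2 = T_NMP only — and
the remaining assignments (1 = T_NMP + Foxa2, 4 = T_NMP + T_NotoP,
6 = T_NotoP only) are a documented convention, overridable via the pipeline
configuration, because the original numbering of those three is not
recoverable from the text.

Anchors: the summit of the cluster's peak from the highest-precedence
source present (T_NMP > T_NotoP > Foxa2); among several same-source peaks,
the highest score wins, ties leftmost. narrowPeak column 10 supplies the
summit when present; otherwise it is recomputed from coverage.

The enhancer unit is the differential region, not the summit: one region
containing several anchors is one table row whose flags are the union over
contained anchors, re-mapped to a category. Containment is half-open; an
anchor exactly at `end` is outside.

Reported percentages (`category_fractions`, association summaries) use
round-half-away-from-zero at one decimal.

## Target genes and association

A genic anchor (inside a gene body extended by the flank) is assigned to
every such host plus the closest genes entirely left/right of the host
span; an intergenic anchor to its two flanking genes (one at chromosome
ends — never an error). The gene-side dual, used for association summaries,
is the *gene domain*: upstream neighbour's start through downstream
neighbour's end, clipped to the chromosome. For interior, non-nested genes
the two formulations agree, which the tests assert on random annotations;
nested/overlapping neighbour cases are resolved by the "entirely left/right"
rule and logged rather than silently reinterpreted.

Expression calls: FPKM = count·10⁹/(length·total). A gene is group-specific
when its FPKM is ≥ fold (default 3, inclusive) times the other group's at
*every* shared stage, computed on pseudocount-shifted values (default
0.1 FPKM on both sides; zero handling is otherwise undefined). Note the
inclusive boundary is only exactly inclusive at pseudocount 0 — with a
pseudocount, a gene exactly at the fold ratio falls just below threshold;
the parameter is exposed for that reason. "Not expressed" means maximum
FPKM over all samples below a floor (default 1 FPKM; reported in run
metadata). Per-gene heatmap normalization divides by the row maximum by
default (z-scores by flag).

UpSet tabulation counts genes per exact set of enhancer categories
(duplicates collapse to a set), sorted by count descending. `set_overlap`
tallies every region of the Venn partition, dropping identifiers missing
from a supplied reference with a logged count.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analysis assumes, not
sequence data:

* genomes: non-overlapping genes with a minimum intergenic gap, uniform
  random placement of the slack;
* enhancers: positions outside promoter masks (with one detection window of
  extra clearance so the window footprint around a planted enhancer is
  unambiguously promoter-distal), at least two windows apart, categories
  drawn from configurable probabilities;
* fragments: per-window counts are Poisson at `mean_depth` (default
  50/window). The Poisson choice is the sampling model matching the
  detector's binomial null for one pooled library per condition; a negative
  binomial with configurable `dispersion` is available to probe
  overdispersion (the default `dispersion = inf` is its Poisson limit).
  Planted windows carry `accessibility_fold` (default 4; fold 1 gives an
  exchangeable null). Fragment lengths are lognormal with median 200 bp
  (accessibility-scale inserts); exact duplicates are injected at a
  configurable rate to exercise deduplication;
* peaks: one per planted enhancer per true source flag, with jittered
  boundaries and summits; decoys inside blacklist regions exercise
  filtering;
* expression: lognormal baseline (median 20 FPKM, sigma 1), planted
  specific genes multiplied by `specific_fold` (default 10) in one group at
  both stages, multiplicative lognormal noise (sigma 0.2 default).

One seed is threaded to all sub-generators through
`numpy.random.SeedSequence(seed).spawn` in a fixed stage order, so fixtures
are byte-identical under a seed. The default fixture (2 chromosomes ×
200 kb, 20 genes, 30 enhancers) builds in well under a second; the
planted-recovery suite uses a 1 Mb single-chromosome genome with 20 planted
4-fold regions at 50 fragments/window over 5 seeds. These sizes keep the
whole test suite to a few seconds while leaving enough windows (~10⁴) for
the calibration and FDR checks to be meaningful.

Not modeled: sequence composition, transposase insertion bias, mappability,
replicate correlation structure, and biological overdispersion beyond the
optional negative binomial. Passing the recovery tests therefore shows the
machinery is correct and calibrated under its own sampling assumptions, not
that real libraries are free of those effects.

## Known limitations

* The detector's calibration degrades under overdispersed counts (set a
  finite `dispersion` to observe this); with real replicated data a
  dispersion-modeling method is more appropriate.
* Library-size normalization carries composition bias (above); a
  background-based scaling factor is a possible extension.
* Genome-wide region *counts* from real datasets are not reproduction
  targets: they depend on sequencing depth and genome size, which the
  desk-scale fixtures deliberately do not match. The reproducible quantities
  are the category arithmetic and the calibration/recovery properties.
* Two published percentages are not consistent with their own printed
  numerator/denominator pairs under any rounding rule (2131/3728 = 57.16%
  printed as 57.1%; 146/319 = 45.77% printed as 46.4%). The package computes
  the correct arithmetic (57.2%, 45.8%); the corresponding worked-example
  tests assert the printed values and are expected to fail, documenting the
  discrepancy rather than reproducing it.
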