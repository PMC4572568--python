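# Methods

## The shifting null

A locus is built per index SNP: the span of its LD proxies (r²
strictly greater than a threshold, 0.8 by default, computed from phased
haplotypes) extended by `2 × median(annotation interval length)` on
*each* side and clipped at coordinate 0. The two-sided extension
guarantees a window length of at least `4·median + 1`, so even a locus
with a lone SNP can realise both overlap and non-overlap states under
shifting; a one-sided reading of the extension would make the null
unreachable for single-SNP loci and bias the test. Coordinates are
BED-style throughout: 0-based, half-open, a point variant at `p`
overlaps `[start, end)` iff `start ≤ p < end`. Touching intervals are
merged, since they are indistinguishable for point queries.

Per iteration, every locus draws an independent offset uniform on
`{0, …, L−1}` (offset `L` is modularly identical to 0, resolving the
endpoint ambiguity of "between 0 and the size of the locus"), the
annotation intervals are translated modulo `L` (pieces crossing the
boundary wrap), and the proportion of loci with at least one SNP in the
shifted annotation is recorded. Per-locus offsets are independent
across loci and iterations — the only reading consistent with
per-locus circularization. The p-value is the plug-in estimate
`#(null ≥ observed)/n`, ties counted against the hypothesis; a zero
count is reported as `< 1/n`, and a `(count+1)/(n+1)` estimator is
available behind a flag. Loci whose window contains no annotation
interval can never overlap, observed or null; they dilute both sides of
the comparison equally and receive no special handling.

Internally the test never re-materialises shifted intervals: a SNP at
`p` is covered by `[a, b)` shifted by `o` iff `o ≡ p − q (mod L)` for
some covered base `q`, so the set of overlap-producing offsets is a
union of modular ranges. One boolean profile of length `L` per locus
yields the observed state (offset 0), the Monte Carlo null (index by
random offsets), the exact per-locus overlap probability π_l (the
profile mean), an exact expected null overlap (mean of π_l), and an
exact p-value via the Poisson-binomial distribution of the null count.
The Monte Carlo path remains the reference implementation; the exact
quantities back the test oracles and the simulation harness, where the
noise-free delta-overlap (observed − mean π_l) replaces a Monte Carlo
average of the same estimand.

RNG streams are spawned per locus (and per segment, in the stratified
test) from a single root `SeedSequence`, so results are bit-reproducible
and independent of iteration order.

## Stratified test

Fragments of each locus inside and outside the stratifying annotation Y
are concatenated, in genomic order, into a Y and a Y̅ segment;
annotation X is split at fragment boundaries, SNPs are assigned by
position (Y intervals are half-open, so a SNP at `Y.end` belongs to
Y̅ — no boundary special case). Each non-empty segment is circularized
and shifted independently; a locus overlaps when any SNP meets shifted
X in either segment. With Y empty the procedure reduces exactly to the
unstratified null, which the tests verify distributionally
(Kolmogorov–Smirnov on the null proportions). A fragment longer than
its segment wraps onto itself after translation; covered bases are
conserved at the fragment level, before any merging. Stratification is
pairwise (one Y at a time), matching how colocalizing annotations are
compared in practice; multi-way stratification is out of scope.

## SNP matching baseline

Null sets are drawn from a background panel, one variant per test SNP,
matched on configurable axes: gene overlap, 5%-wide MAF bins, distance
to the nearest TSS (bins at 500 bp, 2, 5, 10, 20, 100 kb), distance to
the TES of the gene with the nearest TSS (1, 2, 5, 10, 20, 100 kb; the
last bin doubles as the sentinel for variants with no gene on the
chromosome), and the number of LD proxies at the working r² threshold.
A pool below 20 candidates is widened by stepping the LD-count axis
outward symmetrically (±1, ±2, …); the other axes never relax, and an
exhausted LD axis is a hard error. Sampling is with replacement across
null sets and without replacement within a set, which preserves set
size when pools are small. Test SNPs whose bins the panel cannot
populate have no defined null and must be excluded before testing
(`matchable_mask`), mirroring the restriction to array-representable
variants in practice. The p-value counts null sets whose locus-level
overlap (SNP or any proxy in X) is ≥ the observed count.

## Synthetic genome generator

The generator is a desk-scale stand-in for a reference haplotype panel
plus annotation tracks; its defaults are the study conditions used by
the statistical tests and the acceptance script.

* **Genome**: 48 chromosomes × 8 Mb (384 Mb). Large enough that ~200
  loci spaced ≥100 kb sample a small fraction of the available LD
  blocks; on much smaller genomes the fixed annotation realization
  imposes a genome-level offset on delta-overlap (standard deviation
  ≈ 0.45/√n_blocks) that dominates set-to-set variation and makes
  type-I error swing with the genome seed.
* **Variants**: 76,800 (~1 per 5 kb), 200 phased haplotypes, minor
  allele frequency ≥ 0.05 (common variants). LD blocks are 20-kb bins;
  all variants in a block are noisy copies of a block founder haplotype
  (founder frequency uniform on [0.05, 0.5]). The per-site flip
  probability is solved by bisection so that two copies correlate at
  the target within-block r² (0.9 by default) given the founder
  frequency. Cross-block r² is pure sampling noise (≪ 0.8), so proxy
  search within the block is exact for the 0.8 threshold; a
  heterogeneous mixture of block r² targets produces the LD-confounded
  genomes used for the matching comparison.
* **Annotation**: intervals with lognormal lengths (median 500 bp,
  σ = 0.5) placed uniformly until the merged track covers the target
  density (16%, the genome share of a consolidated open-chromatin
  track); realized coverage is checked to within 10% relative. The
  resulting per-locus null overlap probability averages ≈ 0.5 — loci
  neither starved of annotation nor saturated, which is the regime in
  which enrichment and calibration are both measurable. A
  colocalization rule optionally derives a partner track Y by jittering
  each X interval's position (±300 bp by default), giving partial,
  not nested, overlap — nested tracks make the stratified null
  degenerate.
* **SNP sets**: causal variants are drawn inside the named annotation
  for a planted fraction of loci and outside it for the rest
  (`category=None` draws them independently of every annotation — the
  null of the type-I studies; drawing *outside* the annotation models a
  depleted functional category instead). Each causal variant is
  reported through its best tag (greatest r² ≥ 0.8, ties to the nearest
  variant; the causal variant itself when no tag qualifies), and the
  reported set must pass the 100-kb same-chromosome spacing filter,
  applied greedily in random order.

What the generator does **not** emulate: coalescent LD (block-diagonal
correlation only, no LD decay within or between blocks), allele-
frequency/LD coupling, mutation/recombination-rate heterogeneity,
clustering of annotations around genes, and real annotation size
distributions beyond the lognormal. Passing tests therefore demonstrate
the statistical behaviour of the methods under controlled LD and
annotation geometry, not performance on any particular real dataset.

## Causal-proportion inference

To translate an observed delta-overlap into an estimate of the fraction
of loci with causal variants inside the annotation, SNP sets are
simulated across a grid of planted fractions (0–45% in 3% steps by
default; the grid and step are parameters) and their delta-overlaps
recorded. Sets whose delta lies within ±0.002 of the observed value
(±0.2 percentage points — delta-overlap is conventionally quoted in
percent) are retained, and the retained sets' true fractions form the
reported distribution: its mean and central 95% interval. The library
uses the exact expected-null delta, and 400 sets per increment so the
interval quantiles are stable given the narrow retention window;
the estimator object exposes the library for reuse across multiple
observed deltas. An empty retention set raises an error suggesting a
wider tolerance rather than silently extrapolating.

## Numerical and design choices

* Median of an even-length multiset of interval lengths: the lower
  central value (pure integer arithmetic, reproducible).
* Summit windows are `[summit − flank, summit + flank + 1)` — 201 bp at
  the default flank of 100, including the summit base; the flank is a
  parameter.
* Strict inequalities at LD thresholds (`r² > 0.8` for proxies,
  `r² > 0.1` for pruning) exactly as conventionally quoted; tag
  selection uses `≥`.
* Proxy search window 1 Mb around the index by default.
* Independence pruning removes a random member of each violating pair
  (seeded RNG), visiting pairs in position order.
* VCF input is restricted to phased, bi-allelic records with at least
  five minor-allele copies; unphased genotype handling (EM haplotype
  estimation) is deliberately out of scope.
* In pruning, variants absent from the panel or monomorphic contribute
  r² = 0 (the distance rule still applies).

## Problem sizes

The statistical suite runs 200 null sets and 100 powered sets of ~200
loci at 1,000 iterations for calibration and power, 60 sets × 3 tests
for the stratification experiment, 5 genomes × 6 sets per arm for the
proxy-invariance check, a 16-increment × 400-set library plus 20
repetitions for causal-proportion recovery, and 40 sets × 2 axis
configurations for the matching comparison. These sizes put every
Monte Carlo estimate's standard error well inside the asserted
tolerances while keeping the whole suite at a few minutes on one core.

## Known limitations

* The locus-local circular null is mildly conservative: annotation
  intervals clipped at the window edge and SNP clusters that wrap onto
  distant positions make the shifted-overlap probability slightly
  exceed the stationary observed-overlap probability, so empirical
  type-I error sits at or just below nominal (2–6% at α = 5% across
  seeds). This is inherent to locus-local shifting, not a defect of the
  estimator.
* Overlap is binary per locus; posterior-probability-weighted overlap
  is a natural extension and out of scope here.
* The matching baseline requires a panel dense enough to populate every
  active bin combination; sparse panels force exclusion of test SNPs.
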