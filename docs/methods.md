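# Methods

## Coordinates and data model

All internal coordinates are 1-based and fully inclusive `[start, end]`; the
only conversion to 0-based half-open happens when reading or writing BED.
Chromosomes are kept in first-appearance order with positions strictly
ascending within each chromosome — no lexical sort is imposed, since
chromosome naming differs across references and every operation here is
per-chromosome anyway.

The multi-sample container (`MethylationMatrix`) stores one beta and one
coverage value per (site, sample), with the invariant that beta is missing
exactly where coverage is zero. Sites are used as given by the caller: +/−
calls are not collapsed into dinucleotide units, because destranding is an
upstream (aligner/caller) decision and collapsing here would silently change
positions.

When uniting per-sample coverage files, entries below the per-sample minimum
coverage (default 10 reads) are treated as missing; the optional coverage
filter additionally masks entries above the sample's 0.999 coverage quantile
(PCR-duplicate guard). Both defaults follow common practice for
tiling-window RRBS pipelines and are exposed in the run config. Whether the
site list is then intersected across samples (default) or kept as a union is
likewise configurable; intersection is the default because the
within-region SD is only comparable across samples computed over the same
sites.

## Tile refinement

Fixed tiles are anchored at coordinate 1 with step = window size by default
(contiguous non-overlapping grid); only windows containing at least one
sequenced CpG are kept, because the pair distances below are undefined on
empty tiles.

For an adjacent pair (right tile starting exactly one bp after the left tile
ends), with A/B the first/last CpG of the left tile and C/D those of the
right, the distances are AD = D − A and BC = C − B, plain differences of
1-based positions. Decision rule, with L the tile size:

1. AD < L → merge into `[A, D]` (provenance `merged`);
2. else BC < L → replace by the best length-L window inside `[A, D]`
   (provenance `repositioned`);
3. else leave both tiles unchanged.

Numerical conventions worth stating because the rule text alone does not fix
them:

* **Strict inequalities.** The boundary AD == L falls through to the
  repositioning test, never to the merge. Likewise BC == L leaves the pair
  unchanged. Distances are end-exclusive differences (D − A), not span
  lengths (D − A + 1); the choice only matters at these exact boundaries and
  is asserted by the boundary-case tests.
* **Window scan.** Candidate starts run over `A ≤ s ≤ D − L + 1`, so windows
  stay inside the CpG span (no extension past the last sequenced CpG). The
  implementation enumerates only starts at CpG positions plus the rightmost
  admissible start; this is exact because the CpG count as a function of s
  only strictly drops one past a CpG position, so the most downstream
  maximiser is always one of these candidates. The test suite proves
  equivalence with a 1-bp exhaustive scan on random spans.
* **Tie-break.** "Most downstream" = largest start coordinate. Strand is
  ignored here (a tile has no strand), so downstream means rightward.
* **Greedy single pass.** The pass walks left to right; a transformed pair is
  consumed and its result is not re-paired within the pass. Chaining a merged
  region with the next tile is not performed by default — the rule is defined
  on pairs of original tiles — but an `iterate_to_convergence` flag repeats
  whole passes until a fixpoint for users who want chained behaviour. In
  practice extra passes change little: merged/repositioned regions end at
  CpG positions and are rarely exactly contiguous with their neighbour.

These choices guarantee three structural invariants, asserted over hundreds
of random landscapes: every output region is ≤ L bp (merged regions because
AD < L, repositioned ones by construction); a merged region contains exactly
the union of its pair's CpGs; and a transformed region's CpG density is at
least the maximum of its two inputs' densities (merge: more CpGs in ≤ L bp;
reposition: at least max count in exactly L bp). The density-improvement
direction of the method — optimized regions are denser on average, and a
"> 5 CpGs" filter removes a smaller fraction of them than of fixed tiles —
follows from these invariants and is checked on the synthetic landscapes.

The "> n CpGs" region filter uses a strict inequality (a region with exactly
n CpGs is removed), matching the usual phrasing of such filters.

## Variability, InfoScore, flagging

Within-region variability is the standard deviation of a sample's non-missing
betas over the region's CpGs, with the n−1 denominator (the usual unbiased
choice; the defining rule does not pin a denominator, so this is stated
explicitly). A region/sample with fewer than two informative CpGs has an
*undefined* SD — propagated as missing, never coerced to zero, because a
silent zero would rank unmeasurable regions as maximally consistent.

Group aggregation of per-sample SDs defaults to the mean over member samples;
median and pooled (variance-weighted) alternatives are selectable, since
"variability across samples or replicates" legitimately admits all three
readings.

InfoScore = density / SD. With the default `sd_floor = 0`, a zero SD maps to
+infinity — such regions genuinely rank highest; a finite floor (e.g. 0.01)
is available when finite rankings are needed, but an invented constant is
opt-in, not default. At fixed density the InfoScore ordering is exactly the
reverse SD ordering.

The high-variability flag defaults to a relative threshold — the 0.9
genome-wide SD quantile per group, implemented as "flag the
`ceil(n·(1−q))` highest-SD regions among the n regions with defined SD, ties
to earlier regions" — because an absolute beta-scale cutoff would be an
asserted constant the method itself does not supply. An absolute threshold
mode exists. Flagged regions are always retained in every output.

## Annotation overlaps

Percent overlap is normalised by the *region* length (the feature-normalised
percentage is emitted as a secondary column): the question asked is "how much
of this methylation region lies in the feature", not the converse. CpGs in
overlap counts the region's mapped CpGs inside the coordinate intersection.
Overlap joins use an interval tree; equivalence with a brute-force all-pairs
scan is asserted on random instances. Promoters derive from gene TSSs with a
strand-aware window (default 2000 bp upstream / 200 bp downstream, a common
convention, overridable), clipped at coordinate 1; unstranded genes are
skipped with a warning. Filtering on (min percent AND min CpG count) uses
≥ semantics on both.

## Synthetic data generator

The generator emulates the RRBS regime the method targets: CpG-dense islands
(geometric within-island spacing, mean 10 bp; lengths uniform 300–1500 bp)
on a sparse background (geometric spacing, mean 1000 bp) along a 2 Mb
chromosome with 40 islands; 4 samples in 2 groups. Clean islands are
uniformly unmethylated (mean beta 0.05), background CpGs methylated (0.85),
per-sample truncated-normal noise sd 0.02. Two adverse regimes carry ground
truth: with probability 0.15 an island is *heterogeneous* (per-CpG means
i.i.d. uniform on [0.1, 0.9]); with probability 0.02 a background CpG is a
*SNP-like outlier*, forced to beta 0 in all samples. Observed betas are
binomially resampled at negative-binomial coverage (mean 30, dispersion 5),
so shallow sites are noisier. All randomness flows from one seed through
spawned generators, so the landscape is reproducible independently of the
beta draw. These defaults were fixed up front as the package's study
conditions.

What the generator does *not* model — and hence what passing recovery tests
do not show about real data: bisulfite conversion error, strand-specific
counts, read-length and mapping artefacts, correlated methylation decay
along the genome, cell-type mixtures, and batch structure between samples.
The recovery tests demonstrate that the machinery does what it claims under
its stated assumptions, not that those assumptions hold for any particular
library.

Scenario-recovery checks evaluate the flag over regions with at least two
mapped CpGs, because the within-region SD — and therefore the flag — is
undefined on singleton regions: a lone outlier CpG in an otherwise empty
tile cannot exhibit *intra-region* variability by definition. The
"clean island region" set for the InfoScore-ranking check is restricted to
regions whose CpGs all lie inside one clean island: a repositioned window
that straddles an island edge mixes unmethylated island CpGs with methylated
background CpGs and is, by construction, genuinely heterogeneous content
rather than a clean-island case.

## Problem sizes

The test suite runs the full default generator (2 Mb, ~5700 sites) for the
seeded end-to-end checks, and a scaled-down configuration (150 kb, 6
islands) for loops over 100 landscapes; the structural invariants being
checked are size-free. The window-scan oracle comparison uses 1000 random
spans with L ∈ {500, 1000, 2000} and 2–50 CpGs; the overlap oracle uses 1000
random region/feature sets.

## Known limitations

* The greedy pass is order-dependent by design (left to right); a different
  scan order could pair tiles differently. This mirrors the pairwise
  definition of the rule rather than a global optimisation.
* Repositioned windows can mix island and background CpGs when a cluster
  sits near a tile boundary; such regions are dense but heterogeneous and
  will (correctly) be flagged rather than ranked highly.
* Overlapping tilings (step < window) are supported for tiling and mapping,
  but the refinement pass requires non-overlapping input regions.
* The CLI's `score` command recomputes the site intersection from coverage
  files; entering with regions computed from a different site set silently
  changes CpG counts.
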