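# Methods

This note records the models, decision rules and numerical choices behind
`d2finemap`, and what the synthetic-data generators do and do not emulate.

## Genetic model

The target is a single recessive locus (`d`/`D`, dwarf allele recessive) in
an F2 population obtained by selfing a fully heterozygous F1.  Each F2 plant
is the union of two independent F1 gametes; crossovers occur independently
in each marker interval (no interference), with the recombination fraction
obtained from the map distance by the Haldane function
`r = ½(1 − e^(−2d/100))`.  Kosambi is available as a configuration option,
but with no interference model the Haldane function is the consistent
default, and at the distances relevant here (≤ a few cM) the two are nearly
identical.  Genotype calls use `A` for the dwarf-parent allele; a dominant
locus collapses `AA`/`AB` to `A-`.  Internally a genotype is the count of
tall-parent chromosomes (0/1/2), so the minimum number of recombinant
gametes separating two loci in one plant is `|count₁ − count₂|`.

## Recombinant screen and distance estimate

A plant is *informative* iff its two-locus genotype cannot be formed from
two parental gametes; `AA/BB`-type plants carry two recombinant chromosomes,
all other informative types one.  Plants formed from two *complementary*
recombinant gametes have genotype `AB/AB` and are undetectable, so the
expected detected fraction of recombinant chromosomes is `f = r − r²/2`,
slightly below `r`.  `map_distance` reports

* `cm` — the plain estimate `100·c/2N` (the quantity a screening experiment
  publishes; 29 chromosomes in 915 plants gives 1.585 → "1.6 cM"), with a
  binomial SE on 2N chromosomes, capped at 100 with a warning; and
* `cm_mapfn` — a detection-corrected, map-function-inverted estimate
  (`r = 1 − √(1 − 2f)`, then the inverse Haldane function), which is the
  right quantity for parameter-recovery checks at larger distances where
  `100·r ≠ d`.

Plants missing either flanking call are excluded from the denominator and
reported; plants with non-parental alleles are dropped entirely.

## Progeny-test genotype caller

Thresholds (defaults): dwarf-median 90 cm, tall-median 135 cm, short-plant
cutoff 110 cm, α = 0.05 per family (a Bonferroni switch exists but is off by
default, matching single-family testing practice).  The χ² test is the
uncorrected Pearson goodness-of-fit against (¼, ¾) with 1 df — the continuity
-corrected statistic would give ≈0.118 rather than 0.071 for a 21:2 family
and is deliberately not used.  The 90–135 cm band is deliberately wide
(`tall_unresolved`) because tall-family medians are dragged around by other
segregating height loci and environment; the band is closed on both ends.
A family whose short fraction is significantly *above* 25% is labelled `Dd`
with a warning rather than silently `DD`.  Families phenotyped in several
batches are classified per batch and merged by consensus; disagreeing
batches downgrade to `tall_unresolved`.  One decision-rule consequence worth
noting: a tall family with a single short plant can test significantly below
25% and be called `DD` even when an experimenter might have labelled it
`Dd`; the packaged family panel contains such a case and the rule-consistent
call is what the caller (and its tally of 5/5/9/3/1) reports.

## Clustering, trait placement, double-recombinant flags

Codominant loci merge when their genotype vectors agree wherever both are
non-missing; dominant loci attach to the unique compatible cluster (several
compatible clusters ⇒ recorded ambiguous; none ⇒ unplaced).  Clusters are
ordered by exhaustive permutation (≤8 clusters; greedy nearest-neighbour
beyond) minimizing the sum of adjacent minimum recombination-event counts,
with the flanking loci pinned to the ends; ties break lexicographically on
the sequence of first member locus names, which makes the order
deterministic and stable under allele relabelling.  Counts touching
dominant-only clusters are reported as (min, max) ranges since `A-` is
compatible with two chromosome counts.

The trait is inserted at the slot minimizing the added recombination events,
all distances restricted to plants with resolved (`dd`/`Dd`/`DD`) calls;
`tall_unresolved` and `no_data` plants are excluded rather than treated as
missing-at-random.  Tied slots are reported as an interval — a trait that
cosegregates with a cluster is genetically indistinguishable from either
adjacent slot.  A plant is flagged as a putative double recombinant when the
host cluster and both neighbouring clusters carry the same genotype while
the trait call differs; the suggested re-call removes both implied events
and is annotated with the family's segregation P-value when available.

## Height mixture in the generator

F3 heights are drawn from a two-component Gaussian mixture plus additive
family and batch effects shared within a family/batch:

| parameter | default | rationale |
|---|---|---|
| `mu_dwarf` / `sd_dwarf` | 70 / 14 cm | dwarf family medians in the 60–90 cm range; within-family SDs 12–18 cm |
| `mu_tall` / `sd_tall` | 165 / 24 cm | tall medians ~150–210 cm; within-family SDs in the low-to-mid 20s |
| `family_effect_sd` | 5 cm | between-family spread beyond the locus itself |
| `batch_effect_sd` | 3 cm | families grown concurrently share conditions |

Two constraints pin these choices: the marginal dwarf tail above the 110-cm
cutoff must stay below 2% (here 0.4%), and a true-`dd` family of ≥13 plants
must be called `dd` essentially always (miscall probability <1% at the
smallest family size).  The mixture is a deliberate simplification: real
tall-plant heights reflect several other segregating height loci, so real
tall families are over-dispersed and occasionally contain a short plant —
at these defaults P(no plant of 25 below 110 cm | DD parent) ≈ 0.76, i.e. a
homozygous-tall family shows a stray short plant roughly a quarter of the
time, consistent with observed panels.  Heights are floored at 1 cm
(physical positivity).  Passing tests on this generator demonstrates the
decision rule's behaviour under the stated mixture, not under arbitrary
real-world height architectures.

## Haplotype scan

`assess_locus` is column-local and depends only on the partition of allele
labels: dwarfs uniform and no tall sharing ⇒ `discriminating`; at most
`max_exceptions` tall lines sharing while at least one differs ⇒
`exception`; dwarfs non-uniform or too many talls sharing ⇒ `broken`; a
class with no data ⇒ `uninformative` (ignored, never breaking a block —
missing calls are not imputed).  `delineate_block` finds the contiguous
window with the most discriminating-plus-exception loci subject to a
*per-block* exception budget of `max_exceptions` (default 1) and a
`break_run` of consecutive broken loci to terminate (default 1).  The budget
is the load-bearing choice: one isolated tall-line sharing (plausible
homoplasy, e.g. allele-size coincidence) is tolerated inside the block, but
a second sharing locus terminates it, so a near-isogenic tall line whose
proximal segment reverts to the dwarf background ends the block exactly at
the first locus of that segment.  Boundaries are reported as the nearest
informative locus beyond the block on each side, named rather than
interpreted, with `None` flagging an open end.

## Synteny chaining

Anchors are filtered at E < 1e−5 with at most the 4 best hits per query
gene (ties broken by subject id).  Chain score: `min{−log₁₀E, 50}` per pair
minus a continuous gap penalty of 1 per 10 kb, the gap between consecutive
pairs being the **max** of the two genomic distances (conservative and
symmetric; min/mean/sum and the unit are configurable — which genome's
distance the original scheme used is not determinable, so the symmetric
choice is the default).  Chains are strictly monotone in both genomes,
ascending and descending computed independently; non-overlapping blocks are
extracted greedily by score until none exceeds the score threshold
(default > 300).  No block-level E-value filter is applied: score filtering
alone determines retention.  Because a long collinear chain can absorb a
single anchor of a reverse-orientation segment without violating
monotonicity, a boundary-refinement pass re-homes anchors between blocks
whenever that increases the summed block score; this restores exact
breakpoint gaps at inversion edges.  Inversions are `−` blocks whose nearest
block-assigned anchors on both sides (per genome) belong to `+` blocks or
chromosome ends; breakpoint intervals are the gaps between terminal anchors.
Coordinates are 1-based inclusive internally; BED output converts to 0-based
half-open.

## Problem sizes and determinism

Every generator takes an explicit seed and reproduces byte-identical output
tables.  The test suite and the acceptance script use: 1000 replicate
screens of 915 plants for the informative-count calibration; 2×10⁵ gametes
for map-function calibration; n = 5000 plants for distance recovery at
0.5–10 cM; 100 seeded instances of ≤10 anchors for the exhaustive-chain
oracle; and 100 seeded 200-gene tables with one planted 10–30-gene
inversion (plus 3 unanchored insertions per genome) for breakpoint
recovery.  These sizes give Monte-Carlo errors well below the tested
tolerances while keeping the default run in the minutes range.

## Known limitations

* Two-point analysis only; no multipoint likelihood map, no interference.
* The height model is a single-locus mixture with Gaussian noise; it does
  not model the multi-locus tall-height architecture, measurement rounding,
  or mortality.
* The haplotype scan assumes the dwarf class is the introgression carrier
  (dwarfs must be uniform; talls may vary) and reports patterns, not
  identity-by-descent inference.
* Synteny blocks are chained from precomputed anchor tables; the homology
  search itself, whole-genome alignment and published genome-scale block
  coordinates are out of scope.
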