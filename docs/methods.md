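# Methods

## Element model

An intact LTR retroelement is modelled as

```
TSD  LTR  internal-region(gag-pol ORF: ... RT ...)  LTR'  TSD
```

where LTR' is a second copy of the terminal repeat — identical at insertion
time and diverging with age — and the 4–6 bp TSD is host sequence
duplicated on both sides of the insertion site. Classic groups (gypsy,
copia, BEL) carry *direct* repeats whose similarity proxies insertion age;
DIRS elements carry much shorter *inverted* terminal repeats and a tyrosine
recombinase (YR) in place of an integrase. A repeat unit that begins `TGT`
and ends `ACA` keeps those termini under reverse complementation, so
terminal-motif logic is shared between the two modes.

All coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 and reports. `N` never matches anything — in seeds, extensions or TSD
windows — so assembly-gap runs cannot fabricate repeat pairs.

## Detection

1. **Seeding.** All exact matches of length `seed_length` (default 20)
   whose start separation lies in
   `[min_element_len − max_ltr_len, max_element_len]`; in inverted mode the
   second seed must equal the reverse complement of the first. At seed 20
   the expected number of chance hits in a desk-scale genome is ≪ 1, which
   is what keeps the false-positive rate at zero on random backgrounds.
2. **Chaining.** Seeds are collinear when their diagonals (j − i direct,
   i + j inverted) drift ≤ 20 bp and their positions are within
   `max_ltr_len`; each chain becomes one anchor block. The 20 bp drift
   tolerance absorbs small indels between the two copies.
3. **Refinement.** Block ends are extended ungapped while the trailing
   11 bp window stays ≥ 60% identical, then trimmed back to the furthest
   matching position whose own window still clears the floor (an isolated
   chance match beyond the repeat edge is not kept). Boundaries snap to
   `TGT`/`ACA` (then `TG`/`CA`) if the motif occurs within 15 bp. The two
   copies are then globally aligned (match +2, mismatch −3, gap open −5,
   extend −2) and similarity is matches / alignment columns × 100 — gaps
   count as columns, so one ~20 bp insert in a 250 bp LTR reads as ~92.6%,
   not as many point mutations.
4. **Filters.** LTR lengths, element span and similarity (default floor
   80%) must pass; the TSD is the longest 6→4 bp flanking word pair with ≤
   `max_tsd_mismatch` mismatches (0 by default). Flank motif and TSD are
   *recorded* by default and only enforced when `require_flank_motif` /
   `require_tsd` is set, because real elements sometimes lack them.
   Overlapping candidates at one locus are resolved by similarity, then
   element length.

Default windows: LTR 100–2000 bp and element 3–15 kb (direct);
LTR 60–300 bp and element 3.5–6.5 kb (DIRS mode), bracketing the published
per-group ranges with margin.

## Internal-region validation

ORFs are maximal stop-to-stop runs ≥ 200 residues in all six frames; an
initiator ATG is not required because retroelement *pol* is routinely
expressed by frameshift or readthrough, and gag-pol fusions occur as a
single ORF. Each ORF is scored against a small reference peptide panel
(headers `id|DOMAIN|GROUP`) by local alignment under BLOSUM62 (gap open 11,
extend 1); the best reference per domain is retained at raw score ≥ 80, a
threshold far above the scores reached by composition-matched shuffled
peptides (tested) and far below a genuine domain hit even at 30%
divergence. RT is required everywhere; YR additionally for DIRS. Profile
HMMs would be the natural upgrade, but a panel keeps the artifact
download-free and its behaviour fully testable; the threshold is config and
printed in the run log.

## Families, groups, naming

Group is the panel group of the best-scoring RT reference; inverted-repeat
structure overrides any homology call to DIRS, and a direct-repeat element
whose best RT is the DIRS reference is dropped as contradictory. Families
are single-linkage connected components of the element graph with edges at
LTR similarity **strictly** > 80% (same aligner as detection, for internal
consistency). The 5' LTR represents each element; whether to use 5', 3' or
both is genuinely open, and 5' is the documented, configurable choice.
Family numbers are assigned per group by descending family size, then the
genomically smallest member, so runs are reproducible; element indices
count intact elements per scaffold in genomic order.

Composition tables report per-group counts, integer-rounded percentages
and the copia:gypsy element-count ratio (2 decimals); the transcribed
variant truncates its ratio to 2 decimals.

## Phylogeny

Progressive alignment: pairwise local-alignment identities give distances
1 − identity; a neighbor-joining guide tree fixes the merge order; profiles
merge under affine Gotoh DP (BLOSUM62, open 10, extend 0.5) with
sum-of-pairs column scores (gaps contribute zero). Distances between
aligned rows use **pairwise deletion** (sites where both rows are residues)
and the Poisson correction d = −ln(1 − p), which assumes equal substitution
rates across sites and no back-substitution saturation; p ≥ 0.95 is clamped
with a warning because the correction diverges at p → 1. Neighbor joining
is Saitou–Nei with explicit lexicographic tie-breaking; a negative branch
length is clamped to zero with the deficit moved to its sibling. Bootstrap
resamples columns with replacement under a seeded generator; supports are
the percentage of replicate trees containing each internal bipartition.
Everything is bit-reproducible under a fixed seed.

## Transcription overlap

A TAR is an interval with a condition label and a log2 intensity ≥ 0; the
default condition set is female, male, metal(+control),
kairomone(+control). An element is transcribed when it shares ≥ 1 bp
(configurable) with ≥ 1 TAR in ≥ 1 condition, with half-open interval
semantics. Per-condition overlapped totals are computed on the *union* of
overlapping TARs clipped to the element, so stacked TARs are never counted
twice; the long-TAR rule (> 500 bp) is applied per condition — whether it
should instead apply to the cross-condition union is unstated in the
assay's description, and per-condition is the stricter, documented choice.

## Transposon display

Presence requires a peak in ≥ 2 of 3 replicates (`presence_min_replicates`
exposes the stricter =3 reading); exactly one replicate is a putative
somatic insertion — DNA pools 5–10 individuals, so a somatic event should
not replicate — and zero is absence. Loss rate per line is absent ancestral
loci / (ancestral loci × generations), the published unit (per element per
generation); generations default to 45. Somatic gains are per element:
single-replicate calls at non-ancestral loci / scored loci. Treatments are
compared with Welch's unequal-variance t, one-sided (sexual > asexual) by
default since that is the directional hypothesis; two-sided is available.
Population summaries count occupied (isolate, locus) pairs, polymorphic
loci (occupied in ≥ 1 but not all isolates of a treatment — an
interpretation, documented) and singletons (exactly one isolate).
`welch_from_summary` computes t from printed means/SEs; it will not exactly
match statistics computed from unrounded per-line data, and the package
reports its own statistic rather than forcing agreement.

The segregational-loss expectation is simply n·p with p = 1/4: a selfed
Aa parent leaves aa (insertion lost) offspring in a quarter of cases.

## Synthetic data

`generate_panel` builds one random RT ancestor per group (180–280 aa),
members at 5% divergence, plus YR for DIRS; random ancestors are ~95%
divergent pairwise, far beyond the 40% between-group floor.
`generate_genome` plants elements with per-group LTR/element length ranges
taken from the published per-group summaries (e.g. DIRS LTRs 88–170 bp,
elements 4313–5501 bp), on an i.i.d. background at the requested GC.
Element divergence d is realized as d/2 exact-count substitutions per LTR
copy (terminal tri-nucleotides protected) and rate-d substitutions on the
planted domain peptides before back-translation with uniform synonymous
codon choice; this keeps planted ORFs stop-free by construction.
`simulate_td` (defaults: 46 + 47 lines, 7 ancestral loci, 4 heterozygous,
45 generations, selfing loss probability 0.25, somatic rates
0.0036/0.0016 per locus) is the TD generating process, with every event in
the truth manifest.

What the generator does **not** emulate: nested or fragmented elements,
solo LTRs, codon bias, non-uniform base composition, sequencing error, or
TAR signal processing (TARs are consumed as called intervals). Passing
recovery tests therefore demonstrate correctness of the algorithms on
clean insertions, not robustness to assembly artifacts or repeat nesting.

## Problem sizes used in the test suite

The planted-genome fixtures use 10 elements on 150 kb (unit tests) and 100
elements — 20 BEL, 29 copia, 6 DIRS, 45 gypsy, divergence drawn 0–5% — on
900 kb with a 100 kb random negative control (recovery suite); bootstrap
calibration uses 12 taxa × 200 columns × 200 replicates; TD recovery uses
the full 93-line default design. These sizes make every suite a desk-scale
computation while keeping each estimate's sampling error well inside the
asserted tolerances.

## Known limitations

* No solo-LTR / fragmented-element homology census, nested-element
  resolution, or PBS/PPT detection.
* Frameshift-tolerant domain search is out of scope: intact elements are
  assumed to have intact ORFs.
* The intact-element similarity floor (80%) is a configurable default; the
  published pipelines print only the family-clustering threshold.
* NJ/Poisson phylogenies are distance methods: no rate heterogeneity, no
  ML/Bayesian alternatives.
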