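# Methods

This note records the models, parameter choices and numerical conventions
behind each `pirnascan` stage, the design decisions that were genuinely
open, and the limits of what the synthetic-data results establish.

## Coordinates, alphabets, conventions

All coordinates are 0-based half-open internally; GFF3 output converts to
1-based inclusive. All comparisons run in the DNA alphabet: RNA input (U)
is normalized to T at parsing and the molecule type retained for display.
Ambiguity handling is deliberately minimal: `N` never matches anything —
including another `N` — and IUPAC codes beyond N are rejected. The
conservative N rule means a window containing N can still be reported but
is penalized; homology is never fabricated from ambiguous bases.

## Spliced alignment (`align`)

Model: a transcript is a concatenation of genomic exons from one locus,
diverged from the genome by substitutions only — no exonic indels. This is
the right model for transcript sets that are > 97 %-identical clones of a
multi-copy locus, and it is what the synthetic generator produces. The
procedure:

1. **Anchors** — all maximal exact matches ≥ `anchor_k` (default 18 nt;
   the floor of 4 exists only for toy genomes) between the transcript and
   both genome strands, found by k-mer seeding and extension.
2. **Chaining** — per chromosome/strand, a DP over colinear anchors.
   A link is exonic when the genomic and transcript gaps are equal, and
   intronic when their difference Δ lies in [`min_intron`, `max_intron`]
   (defaults 30 and 50 000 nt). Score = anchor coverage − 2 per intron;
   ties prefer the smaller total intron span, which suppresses chimeric
   chains stitched across locus copies.
3. **Boundary fill** — each intronic gap admits a family of splits j of
   the unaligned transcript bases between the upstream and downstream
   exon. Candidates are restricted to canonical GT..AG placements when any
   exists (CT..AC on the genome for minus-strand chains), then ranked by
   exon identity, then leftmost. This realizes "shift within ±window to
   the nearest canonical site" as an exact, deterministic rule.
4. **Multi-copy extraction** — best chain out, overlapping anchors
   removed, repeat; every chain with identity ≥ `identity_threshold`
   (default 0.97, the locus-assignment stringency) is reported. Unplaced
   transcripts are reported as such, never dropped.

Identity is matching bases / transcript length. Locus grouping: a
transcript surviving at exactly one locus joins a shared-locus component
with all single-locus transcripts whose best placements overlap;
transcripts surviving at several loci are "multi". Copy count = number of
surviving chains.

## Junctions and splicing events (`splicing`)

Donor/acceptor dinucleotides are read on the transcribed strand; canonical
means GT (donor) and AG (acceptor) — the consensus often written "AG/GT"
in acceptor/donor order. Event classification compares two chains: exact
interval matches anchor the comparison, runs of unmatched exons form
difference regions, and regions split into overlap components so adjacent
independent events decompose separately. Patterns, in order: exon
skipping (one chain's exon absent from the other, flanks shared), alt
5′/3′ splice site (one boundary moved, the other shared; donor vs
acceptor side decided by strand), intron retention (one exon spanning the
other chain's exon–intron–exon), mutually exclusive exons (one disjoint
exon per chain with no catalog exon wholly between them — this pattern
deliberately stays whole rather than being read as two skips). Any
residual difference is one "complex" event; "complex" is defined here as
*not decomposable into the five elementary types*, a choice the source
taxonomy leaves open. Pure terminal truncations move no intron boundary
and are reported as `end_variation`, outside the six categories, because
fixed amplification primers pin transcript ends in the isoform surveys
this serves. Note the mutually-exclusive relation can only hold between
two isoforms each lacking one exon of the pair — never against a
reference that contains both — so event truth in the generator records
explicit isoform pairs.

## Homology scanning (`scan`, `scan_oracle`)

A hit is a maximal pair of equal-length substrings with Hamming distance
≤ k and length within [ℓ_min, ℓ_max]; maximal means any 1-nt extension
would break the budget, the cap, or a sequence end. Two parameter modes:
`deregulated` (10–16 nt, k = 1) and `utrdb` (16–30 nt, k = 2), both
orientations by default. Because no published BLAST parameterization can
see 10-nt matches, the maximal-hit definition above *is* the method, and
two independent implementations keep it honest: a pigeonhole-seeded
scanner (exact seeds of length ⌊ℓ_min/(k+1)⌋ locate every candidate
diagonal; maximal windows are then enumerated from the mismatch positions)
and an exhaustive numpy oracle that scores every window of the full
mismatch matrix. Their hit-for-hit agreement on random pairs is an
acceptance property.

Post-processing: overlapping maximal hits of one (query, target,
orientation) sharing ≥ half the shorter hit's query interval are merged
(longest, then fewest mismatches, then leftmost survives) — this
collapses the trivially shifted variants that the length cap necessarily
produces. Unique stretches are keyed by the query-strand substring (the
most literal reading of "unique homologous stretches"; alternative keys
would be by locus or by query–target pair). A stretch is
junction-spanning if any member hit covers an exon–exon boundary with
≥ `junction_min_overhang` nt (default 1; no minimum is stated anywhere,
so it is exposed) on each side.

## Small-RNA mapping (`smallrna`)

piRNAs are defined operationally: 22–35 nt (configurable) and 100 %
identity over the full read length. Every genomic occurrence on either
strand is a placement; copy count collapses palindromic double-counting
(a self-reverse-complementary read matching both strands at one position
is one physical copy) and a strand-resolved count is emitted alongside,
since published copy ranges may count either way. Overlapping tandem
occurrences all count. Chromosome exclusivity is relative to a named
target chromosome. The mapper uses a prefix k-mer index with full-length
verification; the generator's truth counts come from independent naive
scanning, so index and truth check each other.

## qPCR quantification (`qpcr`)

Livak 2^−ΔΔCt with efficiency fixed at perfect doubling, as the method
assumes — no standard-curve or efficiency correction (that would be a
different estimator). ΔCt is computed within replicate when replicate ids
pair target and reference wells. Group comparison is an unpaired t-test
on per-replicate ΔCt values; Welch's unequal-variance form is the default
(the source only says "unpaired"), Student's by flag. Zero variance in
both groups with equal means returns p = 1 by convention. Fewer than two
replicates per group suppresses statistics with a warning rather than
failing.

## Synthetic data (`simulate`)

The generator emulates the study-shaped inputs at desk scale; every
output is a pure function of `(config, seed)` and ships with sufficient
ground truth.

* **Genome** — one main chromosome carrying `n_locus_copies` copies
  (default 3) of a base locus: six exons of 50–75 nt, introns of 55–80 nt,
  copies separated by 4 kb spacers and substitution-mutated at
  `copy_mutation_rate` (default 0.01, matching > 97 % inter-copy
  identity; recovery tests use 0), plus a decoy chromosome. Intron
  structure is `GT xx GT … AG yy AG`: the inner GT/AG pair provides
  canonical secondary splice sites 4 nt inside each intron so
  alternative-site and complex isoforms remain canonical.
* **Junction validation** — every junction variant any isoform can
  realize (reference, shifted donor, shifted acceptor, skipped-exon) is
  rejection-sampled until its identity-maximal canonical boundary
  placement is unique; exon neighbourhoods are additionally rejected when
  a junction-straddling window is near-self-similar (e.g. palindromic) in
  a way that would defeat exact plant recovery. Alignment recovery being
  *exact* at mutation rate 0 depends on these constructions.
* **Isoforms** — 8 by default, one event each drawn from the mix
  (skip 0.25, alt5 0.15, alt3 0.15, mxe 0.15, retention 0.15, complex
  0.15; an mxe draw emits the partner pair). One junction (default the
  second) is reserved — untouched by all events — so junction-spanning
  plants have identical context in every isoform.
* **UTR plants** — uniform-background UTRs (10 × 150 nt) with 8 exonic +
  2 junction stretches planted from the reference isoform, lengths 10–16,
  0–1 mismatches, both orientations. A plant must be maximal by
  construction (mismatches equal to the mode budget, or length at the
  cap) and its flanks are forced to mismatch — otherwise the scanner
  would rightfully extend it and exact-coordinate recovery would be
  ill-posed. Chance 10-nt near-matches are *dense* in uniform random
  sequence (per aligned position, P ≈ 3 × 10⁻⁵ of a ≤ 1-mismatch
  10-window), so a clean background cannot happen by luck at any
  realistic size: with `clean_background` (default) the generator
  repair-mutates background hits (and re-places plants whose windows
  attract unrepairable foreign matches) until the unique-stretch summary
  equals the planted truth. With `clean_background=False` the background
  stays untouched uniform, for studying the chance-hit regime itself.
* **Reads** — 30 piRNA-length (22–35 nt; published estimates range from
  ~26–30 nt northern signals to 22–35 nt database matches, so the range
  is config, not a fixed distribution) substrings sampled within single
  exons by default, plus 5 decoys rejection-sampled until absent from
  genome and transcripts on both strands.
* **Ct tables** — reference gene Ct 20, target Ct 24 in control; the test
  group's target Ct is shifted by −log₂(fold) with Gaussian noise
  (default fold 1/3, sd 0.2 cycles, 4 replicates). `data/` contains one
  frozen sheet (`synthetic_ct_table_standin.tsv`, labelled synthetic)
  emulating a raw genomic-copy-number qPCR export: true 3-fold reduction,
  noise 0.2, n = 6 replicates — the replicate count used for the
  comparable published qPCR comparisons.

### What the synthetic results do and do not show

Passing recovery at 100 % establishes that the implementations compute
their definitions exactly: the scanner equals exhaustive enumeration, the
aligner inverts the generator's splicing under its stated model, copy
counts equal direct occurrence counts. It does **not** show that real
accession data would reproduce published counts: real genomes have repeat
families, compositional bias and assembly-version drift; real UTR
databases are redundant and unversioned here; the original analyses used
BLAST parameterizations that are not recoverable. The real-data analyses
run through the same file interfaces but their headline counts should be
treated as version-sensitive.

## Problem sizes and determinism

The default test suite and `scripts/acceptance.py` use desk-scale sizes
chosen as the package's own operating point: 400 scanner-oracle pairs
(≤ 300 nt), 50–100 generator seeds for plant recovery, 40–60 seeds for
chain recovery, locus copy numbers 1–10, 500 Monte-Carlo Ct tables. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; rerunning any stage with the same config and
seed is byte-identical, including file outputs.

## Known limitations

* No exonic indels in the alignment model; diverged-paralog alignment is
  out of scope.
* Splice-site strength scoring and quantitative isoform usage are not
  modelled; junctions are canonical/non-canonical only.
* The scanner's dedup key (query substring) is one of several defensible
  readings of "unique stretches"; counts under other keys differ.
* Small-RNA mapping is exact-match only — no mismatch-tolerant mapping,
  adapter trimming, or biogenesis signatures (1U/10A, ping-pong).
* The qPCR module implements the Livak estimator only; efficiency-
  corrected (Pfaffl-type) quantification is deliberately excluded.
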