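# Methods

This note records the models, rules and numerical choices behind `segdiff`,
including every point where the design was genuinely open.

## Scope and coordinate model

The package compares exactly two genomes at a time.  All internal
coordinates are 0-based half-open on the forward strand of the linearised
sequence; conversion to 1-based inclusive coordinates happens only when
writing GFF3 or GenBank-style reports, and converting forth and back is the
identity.  Circular chromosomes are linearised at the origin given in the
input record and the comparison does not wrap across it — callers comparing
circular genomes should rotate both records to a common ring-opening first.
Lowercase input is upper-cased on read; IUPAC ambiguity codes other than N
become N, and N always counts as a mismatch, which biases statistics
conservatively rather than optimistically.

## Run/connector mapper

For near-identical pairs the mapper finds all k-mers occurring exactly once
in each genome (k = `min_run`, default 20), pairs equal k-mers, collapses
anchors adjacent on a shared diagonal into blocks, and chains blocks by
weighted dynamic programming maximising matched bases, with strictly
increasing coordinates in both genomes, bounded overlap between neighbours
(up to k bases, later trimmed), and leftmost-in-a tie-breaking.  Chained
blocks are maximally extended base-by-base, overlaps between consecutive
runs are resolved by trimming the later run, runs shorter than `min_run`
are dissolved into connectors, and shared prefixes/suffixes of connectors
at least `min_run` long are peeled back into runs.  Reconstruction of both
inputs from the interleaved pieces is asserted after every decomposition.

`min_run = 20` balances two pressures: long enough that chance matches
inside divergent material are vanishingly rare in a ~40% GC genome, short
enough that two events 200 bp apart always have an anchored run between
them.  If no common run exists the whole pair becomes a single connector —
a defined result, not an error.

Connector typing applies, in order: tandem copy-number variation (the extra
material is a whole multiple of a 7–16 bp unit whose minimal period is at
least 7, tiling the locus with at most 10% mismatches, with copy counts
extended through the flanks and at least 2 copies on one side); point
mutation (1↔1); one-base indel (0↔1); inversion (both sides at least 7 bp
and reverse-complement identity ≥ 90% by edit distance); long indel (one
side empty, other side > 50 bp); and few-base difference as the remainder.
Consecutive connectors separated by runs of at most 100 bp are merged when
the merged sides form one inversion, covering inversions whose interior
contains a short chance forward match.  The 50 bp long-indel boundary and
the 90% inversion identity are package choices: the literature this
approach comes from names the categories but not numeric boundaries.

## Alignment engine

`align_pair` produces a global affine-gap alignment (match +1, mismatch -2,
gap open -5, gap extension -1; a gap run of length L costs open+(L-1)·ext).
Inputs up to 25·10⁶ DP cells are solved exactly with the Needleman-Wunsch-
Gotoh implementation in Bio.Align.PairwiseAligner.  Larger inputs are
anchored with the run/connector decomposition and only the connectors are
aligned: exactly (DP) when their product is within the ceiling, otherwise
by an edit-distance path (edlib), which is exact for unit costs and an
adequate stand-in for the near-identical material this package targets.
After assembly, every gap run is slid left while the rotated base pairs
identically at both ends, so equal inputs always yield byte-identical
alignments; the stored score is recomputed from the emitted columns, making
it engine-independent.  The test suite checks the engine against an
independent full-matrix Gotoh oracle.

## matchSEG/divSEG segmentation

Pass 1 walks both genomes in chunks (default 200 000 bp).  Each chunk pair
is aligned and the next chunk starts at the beginning of the last matching
stretch of at least 50 identical aligned bases — the length floor keeps the
restart anchor out of the spurious 1–2 base matches a global aligner
scatters when one window tail has no true counterpart.  When that stretch
starts at the chunk start (the chunk matched end to end), the next chunk
starts at the chunk end instead and the continuing segment is fused later;
without this rule a fully matching chunk would never advance.

Pass 2 concatenates the chunk contributions into one draft alignment and
cuts it at (a) gap runs longer than 100 bp and (b) regions where a sliding
1 kb window exceeds 5% divergence.  The window rule is this package's
stated, testable replacement for a visual-inspection step: 5% is far above
the ~1% divergence of genuine matching segments and far below the ~75%
apparent divergence of unrelated sequence, so the decision is insensitive
to the exact value.  Windows with fewer than 100 countable (m+mm+go)
columns are skipped to avoid ratios of small numbers inside long gaps.
Every draft matchSEG is trimmed so its first and last column is an
identical base pair.

Pass 3 iterates to a fixed point (at most 10 rounds; in practice 2): every
matchSEG is re-aligned from its genomic intervals, split at internal indels
over 100 bp (`--max-internal-indel`), re-trimmed, and consecutive matchSEGs
separated by fewer than 100 bp in both genomes (`--fuse-below`) are fused
and re-aligned.  Because the fuse threshold (< 100) cannot create an indel
over the split threshold (> 100), the two rules do not oscillate, and
`refine` is idempotent (tested).  The partition invariant — every position
of each genome in exactly one segment — is validated on every result.
matchSEGs above 1% divergence are flagged for review and retained;
`convert_flagged` demotes them to divSEGs instead.  One consequence worth
stating: a copy-number change whose extra material is under 100 bp stays
inside a matchSEG as an ordinary internal gap, by design.

## Column statistics and position correlation

Each column is match, mismatch, gap open or gap extension; the first
column of every maximal gap run in either row is the single go, the rest
ge.  Divergence is (mm+go)/(m+mm+go); ge never enters, and cumulative
statistics are computed by summing counts across segments, never by
averaging per-segment fractions.  Divergence is undefined (an error, not
0) when no countable column exists.

The position-correlation map classifies every base of both genomes as
mapped (inside a matchSEG, opposite a base), gap (inside a matchSEG,
opposite a gap) or strain-specific (inside a divSEG), with partner
coordinates for mapped bases.  The mapped relation is a strictly increasing
partial bijection; this is asserted at construction.

## divSEG categories

Decision order: tandem CNV, indel (one side empty — the insert has an
exact position), approximate insert (the shorter side at most 10 bp of
unaligned bases), replacement (fallback; aligned identity of the two sides
reported, with a warning tag at ≥ 95% since such a segment may belong in a
matchSEG).  The tandem-unit bounds are 7–16 bp, merging the ranges observed
in the two comparisons that motivated the category; the 90% coverage and
10% mismatch tolerances for unit detection are package choices, as is the
rejection of candidate units whose own minimal period is below 7 bp (so a
poly-ATG run is not reported as a 9-mer repeat).  Inserts matching
elsewhere in their own genome at ≥ 90% identity over ≥ 80% of their length
(edit-distance search of the full insert and of its central 80%) are
tagged `InternallyRepeated`.

## ORF correlation

Terminus positions are strand-aware single coordinates (C-terminus: last
transcribed base).  Correlation runs in two passes over all ORFs — first
C-terminal, then N-terminal for the leftovers — which makes the pairing
independent of gene order and symmetric under swapping the genomes.
Equivalence of two termini means the position map pairs the coordinates
exactly, with no slack: allowing slack would let adjacent gene fragments
steal each other's partners.  A pair is perfect when both termini map into
the same matchSEG and the product names are identical; correlation is
possible at all only if at least one terminus lies in a matchSEG.

Protein-level verification translates with the bacterial genetic code
(table 11, initiator always Met).  Equal-length proteins must be identical;
for inconsistent start-codon assignments the C-terminal fragments must be
identical over the shorter length, after converting the longer protein's
internal Val/Leu to Met when the shorter ORF starts with GTG/TTG.
Untranslatable CDSs are flagged and excluded rather than failing.

Disrupted genes are reported when a correlated pair is pseudo-flagged on
exactly one side, or when 2–3 non-pseudo fragments of one genome map (by
their termini) inside the span of one regular gene of the other.  The
strain-specific filter removes candidates with a cross-proteome homolog at
≥ 75% identity (5-mer prescreen, then global protein alignment; identity =
matches / aligned length excluding terminal gaps) and candidates whose
product name contains a configurable keyword (default: transposase,
integrase, phage, prophage); candidates under 150 nt with no cross-proteome
hit at all are rated spurious.  External-database lookups are out of scope,
so keyword and length heuristics stand in for curation against reference
proteomes — counts from real curated comparisons will differ accordingly.

## Gene-level diagnostics

`compare_cds` compares codon-by-codon (indel-free orthologs expected;
unequal lengths are flagged and compared over the common prefix), counting
per-base point mutations and classifying affected codons silent or
non-silent, with replacements numbered on the genome-a protein.
`matchseg_event_counts` defines genome-wide totals: point mutations =
mismatch columns, frameshifts = internal gap runs whose length is not a
multiple of 3.

The MITE census seeds candidate loci with exact 14-mers of the consensus on
both strands, verifies each with a banded infix alignment, and snaps hits
back to full consensus length when a mismatching terminal base shortened
the local alignment (otherwise terminal SNPs systematically shift the
recorded boundaries and hide target-site duplications).  "Complete" means
span ≥ 0.9 × consensus length at ≥ 0.8 identity — stated thresholds, since
a census is only reproducible with explicit ones.  Copies are selected
non-overlapping, best identity first.  The consensus builder takes a
per-column majority over equal-length copies with ties broken A<C<G<T and
returns the frequency matrix for logo rendering.

In-silico PCR locates the forward primer and the reverse primer's reverse
complement downstream on the same strand (both orientations searched); the
product spans from the forward primer's 5' base through the far end of the
reverse site, so implanting primers with D bp between them yields
len(F)+D+len(R).  Default matching is exact; up to 3 mismatches may be
allowed, but a 3'-terminal mismatch never is, mimicking polymerase
extension requirements.  Products are capped at 5 000 bp.

## Synthetic data generator

The generator's defaults describe a desk-scale analogue of a real
strain-pair comparison: 500 kb chromosomes at 43% GC (enterobacterial),
25 SNPs + 5 one-base indels for the near-identical regime, and explicit
counts for structural events — mobile-element insertions with duplicated
target sites (the built-in 123 bp MITE-like element has 25 bp terminal
inverted repeats and a TA target-site duplication), inversions of 1–4 kb
bounded by 35–84 bp inverted repeats, tandem arrays with 7–16 bp units and
10–49 copies, and 0.5–5 kb prophage-like blocks.  Events are placed at
least 200 bp apart (configurable) so each falls into its own
connector/divSEG and truth-table recovery is exact rather than flaky; a
packing that cannot satisfy the spacing raises an error naming the
constraint.  An optional gene grid plants CDSs (ATG/GTG/TTG starts at
0.8/0.15/0.05, genetic code 11, random strand) every 2.4 kb; frameshift
events split a planted CDS into two in-frame fragment annotations with no
pseudo flag, so disruption must be inferred positionally, and
strain-specific gene events insert novel or near-duplicate (~90% identity)
CDSs inside new blocks.  All randomness flows through numpy's PCG64 with
explicit seed sequences, so fixtures are byte-reproducible across
platforms (GenBank output pins a fixed date stamp for the same reason).

What the generator does not emulate: substitution-rate heterogeneity,
phylogenetically realistic mutation spectra, overlapping or nested events,
rearrangements other than single inversions, and annotation noise (wrong
starts, missed calls).  Passing the recovery tests therefore demonstrates
correctness of the comparison logic under clean, well-separated events —
not performance on adversarial real data, where manual review of flagged
high-divergence segments remains part of the workflow.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` run entirely on generated data:
500 kb for the mapper battery, 200–300 kb for segmentation, 150 kb
annotated pairs for ORF work, 200 randomised 2 kb pairs for partition
invariants.  These sizes were chosen so every stage runs at interactive
speed while remaining large relative to event footprints; all headline
behaviours (recovery, partitioning, idempotence) are size-independent
properties.  The full-scale comparison of the published ~5.5–5.7 Mb
chromosomes is wired into `tests/test_acceptance.py` and activates when the
three public sequences are placed under `data/genomes/`; its totals for
point mutations, frameshifts, coverage and segment counts are additionally
sensitive to this package's stated replacements for manual-curation steps
(the 5%/1 kb window rule, keyword-based gene exclusions), so modest
deviations from published curated totals are expected and documented here.
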