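# Methods

This note documents the models, algorithms, parameter choices and known
limitations of mitokit, in the order a pipeline run encounters them.

## The synthetic mitogenome and what it emulates

`synthetic_data.generate_mitogenome` builds a two-chromosome circular
genome at one-tenth the scale of the real system it models (defaults
30,000 and 15,000 bp vs ~301 kb and ~145 kb), so that every test runs in
seconds while preserving the structural features that make the analysis
non-trivial:

- **12 shared regions** of 30–360 bp copied from chromosome 1 into
  chromosome 2, every fourth one inverted, diverged at a 2% per-base
  substitution rate. Real shared regions are "often imperfect"; the
  divergence model is substitution-only.
- **A 1,500 bp direct repeat and a 400 bp inverted repeat** on
  chromosome 1 (the real genome carries 15 kb and 4 kb repeats; both are
  scaled with the genome).
- **8 genes** of 2–3 exons on the + strand, one of them trans-spliced
  with its final exon on chromosome 2.
- **A 1,000 bp plastid-derived segment** whose GC is constructed to be
  exactly the chloroplast target (0.384); chromosome backbones are
  constructed at exactly the mitochondrial target (0.435), so GC-based
  compartment classification works on simulator output.
- **20 editing sites** inside exons: the genomic base is set to C (or G,
  for the optional G→A fraction) and the transcript carries T (or A).
- **4 polyA degradation regions** with target depth 600 against the
  detection threshold of 500; one is placed inside an intron when a
  large enough intron exists, the rest in intergenic space.

Three generator conventions exist solely to make ground truth
*exactly* recoverable, and are deliberate design choices:

1. The base immediately flanking each planted shared-region copy is
   forced to mismatch the diagonal continuation of its source, so the
   planted boundary is the maximal-match boundary.
2. Divergence mismatches are kept ≥25 bp from the region ends and ≥30 bp
   apart, so every region retains exact 15-mer seeds throughout and
   extension/trimming recovers the planted extent base-exactly.
3. Degradation-region lengths are multiples of the short-read length and
   polyA reads tile them in exact layers, giving a rectangular depth
   profile whose ≥-threshold run equals the truth interval.

Circularity is simulated by sampling read starts uniformly on the circle
and taking modulo-length substrings (equivalently, substrings of the
doubled sequence), so "read is an exact circular substring" is a direct
oracle. Sequencing error is uniform substitution only; there is no
quality model and no indel error. Transcript alignments are *emitted* as
truth SAM over the concatenated chromosomes rather than re-mapped — the
splice analysis consumes spliced alignments, it does not produce them —
so nothing in the test loop depends on a spliced aligner.

What passing on this simulator does **not** show: robustness to indel
sequencing error, to coverage biases, to mis-spliced or multimapping
transcript alignments, or to repeat structures more tangled than two
long repeats per chromosome. Those belong to the upstream mappers and
assemblers this package deliberately stands in for at desk scale.

## Read mapping

`map_reads` is a seed-and-extend mapper: exact k-mer seeds (k = 15) on
the doubled reference (doubling handles circular origins; positions are
normalised modulo length), edlib semi-global verification, identity
`1 − dist/len(read)` ≥ 0.9 by default, both strands searched, ties
broken by lowest (chromosome id, position). N never matches. It is
quadratic-oracle-checked on small references and is entirely adequate
for substitution-level divergence; it makes no attempt at quality-aware
scoring, paired-end rescue or spliced alignment.

## Iterative bait-and-assemble

One round is: **bait** (a read is kept when it shares ≥ n distinct
canonical k-mers with the bait set; the default schedule is a stringent
first round k = 32, n = 50 followed by permissive rounds k = 27 and
k = 31 with n = 1, the later-round n being unstated upstream and chosen
permissive here) → **assemble** → **retain** contigs with ≥1 homology
hit to the initial reference set → **exclude** contigs ≥90% covered by
plastid reference → **circularise** (set circular contigs aside) → feed
surviving contigs back as baits. The loop stops when the schedule is
exhausted, the contig set stops changing, or nothing non-circular
remains.

The assembler is greedy overlap-layout: repeatedly merge the contig pair
with the best suffix–prefix overlap (≥1,000 bp at ≥75% identity by
default, mirroring classical overlap-assembler settings; an upstream
`-e 200 -k 0` clone-constraint pair has no analogue here and is
ignored). Two details matter:

- **Merge ranking is by alignment-style score** (matches − 3×differences),
  not raw overlap length. A repeat-mediated chimeric join is long but
  imperfect beyond the repeat copy; a true dovetail is exact. Scoring
  this way makes all true merges — including those through reads that
  span a repeat copy entirely — happen before any repeat-internal
  overlap is considered, which is what lets a 1,500 bp direct repeat be
  resolved by 2,000 bp reads.
- **All four end-to-end orientation classes** of a contig pair are
  searched (right–left, right–right, left–left; left–right is the
  reverse complement of a class owned by the swapped pair). Containments
  are absorbed, so read membership is conserved.

Ties are broken lexicographically by contig id; assembly is
deterministic under fixed input order. Circularity testing looks for a
suffix–prefix self-overlap (≥100 bp at ≥95% identity), trims one copy
and reports the lexicographically minimal rotation (Booth's algorithm);
a contig already flagged circular is returned unchanged, making the test
idempotent. Homology hits are exact 21-mer seed chains per diagonal,
edlib-verified at ≥100 bp and ≥80% identity — a deliberate, calibratable
surrogate for an e-value cutoff, which would be out of proportion at
this scale. Gap closing excises 2 kb flanks around each N-run, re-baits
(k = 31, n = 1), assembles, and patches only when a closure contig
matches 100 bp anchors on both flanks at ≥95%. Polishing is
majority-vote pileup consensus: replace a base when depth ≥5 and the
alternative allele holds ≥70% — substitutions only, which matches the
simulator's error model.

On the default study condition (seed 42, error-free ~2 kb reads at 10×,
baits a 1%-diverged genome copy, plastid reads spiked in) the loop
returns both chromosomes base-exactly. At 10× with a 1,000 bp overlap
floor, some seeds genuinely contain adjacent-read overlaps below the
floor (expected ≈0.5 per genome); assembly then correctly returns
fragments — a property of the coverage model, not of the algorithm.
With 0.5% read error, post-polish identity to truth is ≥99.9%.

## Shared regions and the master-circle test

`find_shared_regions` seeds exact k-mers (k = max(15, min_len/2)),
groups them per diagonal and orientation (merge distance 120 bp; at the
95% identity floor seeds recur every ~20 bp, so this cannot bridge
unrelated matches), extends with mismatch tolerance while overall
identity stays above the threshold, then trims to the maximal-scoring
subsegment (match +1, mismatch −t/(1−t), i.e. −19 at t = 0.95), which
guarantees the reported segment itself meets the identity floor and ends
on matching bases. The model is substitution-only: indel-containing
duplications would be split into separate diagonal segments.

Join-path spanning uses a locate-then-anchor rule: edlib locates the
shared block in the read (≥95% identity over the block), then both
20 bp anchors flanking the block must match at ≥95% (≥19/20 bases).
Requiring the anchors *themselves* to match — rather than a global
identity over block+anchors — is what keeps long blocks from leaking
support across paths (a 360 bp block with 20 mismatching anchor bases
would still pass a 95% global filter). A read equal to the block alone
supports nothing.

Candidate classification follows the logically consistent reading of
the exclusion rule: **excluded** iff shorter than the read length with
zero chimeric support (reads could have spanned it and none did);
**candidate** iff at least read length (unresolvable by those reads);
**supported** iff any chimeric read spans it. The statuses partition the
region set; the verdict is "master circle present" iff anything is
supported. Conformation testing at long repeats builds the alternative
arrangement explicitly (inverted repeat → the inter-copy segment
reverse-complemented; direct repeat → the two subcircle junctions) and
counts reads spanning a repeat copy with 100 bp anchors consistent with
exactly one arrangement; reads consistent with both are tallied as
ambiguous, not assigned.

## Splice analysis

Junctions are defined at alignment level — donor is the last aligned
base before a skip (N) operation, acceptor the first after, 0-based —
because organellar group-II splicing does not reliably follow GT–AG and
motif-based definitions would bias the very question under study.
Identical (donor, acceptor, strand) events aggregate; support < 10 is
dropped by default; coordinates are lifted from concatenated to
per-chromosome space and junctions crossing a concatenation boundary are
flagged cross-chromosomal. Hotspots are single-linkage clusters in
which both donor–donor and acceptor–acceptor distances are within a
1,000 bp window (the observed clustering scale is "a few hundred to a
few thousand bases"; the window is a parameter and hotspot counts
change smoothly with it). `in_cds` tests the junction *endpoints*
against CDS intervals, not the skipped interval. Percentages are
reported at both two and one decimal because published summaries use
both; zero-junction input yields an explicit undefined flag rather than
a NaN.

The guide search takes the 54 nt mature-transcript window across a
junction (28 donor-side + 26 acceptor-side by default), and scans each
half genome-wide on both strands with ≤1 mismatch (vectorised Hamming
scan), excluding the junction's own loci. Reverse-strand hits are
reported with decreasing coordinates, matching the convention of
published locus pairs.

## Transcript landscape

Coverage counts reference-consuming aligned bases (M and D; N adds
nothing), implemented as a difference array; completeness is the
fraction of positions with depth ≥1, and the log10 export uses
log10(depth+1). PolyA islands are maximal runs of depth ≥500 (the
published threshold) and length ≥50 — the minimum length is a package
default, since the source analysis states only the depth cutoff — and
are annotated with every feature class they overlap (repeat,
plastid-derived, pseudogene, gene_copy for exonic overlap, intron for
genic-but-not-exonic, else intergenic). Expression counts a read into a
region when its alignment *start* lies inside it; with region length and
read count given, the fold arithmetic is insensitive to this convention.
Fold change is computed from unrounded normalised counts and displayed
at two decimals. The published worked-example table mixes conventions —
its nad6 fold (181.79) requires unrounded counts while its rbcL fold
(15.12) matches the ratio of the rounded counts (the unrounded ratio is
15.13) — so the package keeps unrounded values internally and the
acceptance report reproduces each printed value under its own
convention.

## Genome comparison

`global_diff` is an affine-gap global alignment (match +1, mismatch −1,
gap open −10, extend −0.5 — in the spirit of classical global-alignment
defaults, configurable) reduced to events: one substitution per mismatch
column, one insertion/deletion event per maximal contiguous gap
(event-level counting matches the magnitude of published per-genome
indel counts; per-base totals are also retained). Inputs larger than
the direct-alignment cutoff (2 kb × 2 kb) are first split at a collinear
chain of 31-mers unique in both sequences; cuts fall inside exact
matches, so no event straddles a cut. Editing classification reads the
diff of (genomic, transcript-derived): C→T columns are C→U-compatible,
G→A columns G→A-compatible, and the corrected count removes one or both
classes per mode. Strand is the caller's responsibility: transcript
sequence must be oriented to the coding strand, since the comparison is
strand-naive. GC classification ignores Ns, errors on all-N input, and
rejects configurations with overlapping ranges at load; out-of-range
values report the nearest compartment rather than guessing.

## Problem sizes and determinism

Default test and acceptance scale: 45 kb genome, ~225 long reads
(~2 kb, 10×), ~1,000 spliced + ~6,600 polyA alignments; the full test
suite runs in about half a minute and the acceptance script in well
under a minute on one CPU. All randomness flows from
`numpy.random.default_rng` seeded from explicit config seeds; identical
config and seed give byte-identical FASTA/SAM/JSON outputs. The
assembly-recovery acceptance condition is pinned at generator seed 42
(the study condition under which exact reconstruction is asserted);
other acceptance computations derive their seeds from the script's
`--seed`.

## Known limitations

- Substitution-only models throughout (divergence, sequencing error,
  shared-region imperfection); no indel error, no quality scores.
- The greedy assembler needs read length > longest repeat and contiguous
  ≥min_overlap coverage; it is not a de Bruijn or string-graph assembler.
- `find_shared_regions` reports substitution-level duplications only.
- The mapper and spliced-alignment consumer do not handle soft-clip
  recovery, multimappers or mate rescue.
- Editing classification is positional, not statistical: no per-site
  editing rates across datasets.
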