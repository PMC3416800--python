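# Methods

## The assembly model

The assembler treats the read set as samples from an unknown mixture of
small genomes, some circular.  All kmer handling is strand-canonical: a
kmer and its reverse complement are one edge, so the graph is invariant
to which strand a fragment was sequenced from.  Traversal happens on the
double-stranded string view — an oriented node is simply a (k−1)-mer
string, appearing once per strand — and every extracted structure is
deduplicated through its canonical sequence.  k must be odd, which makes
a kmer never equal to its own reverse complement and keeps the canonical
map two-to-one.

Graph simplification runs three operations to a fixed point, in the
order coverage filter → tip clipping → bubble popping:

- edges below `min_edge_coverage` (default 2) are dropped — with
  per-base error rates well under 1%, almost all error kmers occur once;
- a dead-end branch of at most `max_tip_length` edges (default 2k) that
  re-joins the graph at a node with another way in is removed; isolated
  linear paths are *not* tips and are kept;
- a simple bubble — two internally disjoint non-branching paths of at
  most `bubble_max_len` edges (default 2k) between the same node pair —
  collapses onto the higher-mean-coverage branch, the loser's coverage
  folded into the winner (edge-wise for equal-length branches, as the
  rounded mean otherwise); coverage ties go to the lexicographically
  smaller branch sequence so the result is deterministic.

The fixed-point loop makes `simplify` idempotent by construction.
Contigs are maximal non-branching paths; a component in which every node
has in- and out-degree one is a circle and is reported as a circular
contig without repeating the closing (k−1)-mer, normalised to the
lexicographically least rotation over both strands (Booth's algorithm)
so repeated runs diff cleanly.

Tip and bubble length limits are conventional, not derived: published
single-pass assemblers do not document the exact internal limits this
range of kmers was run with, so both default to 2k and are exposed in
`SimplifyParams`.

## Kmer selection and the iterative loop

Each iteration trial-assembles a snapshot of the remaining reads at
every kmer of `kmer_range` (63 down to 19, odd steps of 4).  When the
input exceeds `trial_subsample` reads (default 10⁶), a seeded uniform
draw of whole pairs is used for the trials only.  Scoring is exactly
two-tiered: any circular contig ≥ `circular_min_len` (2 kb) wins for the
largest such k — longer kmers resolve short repeats better, and a closed
circle at long k is the strongest completion evidence — otherwise the
cumulative length of the `top_n` (20) most read-supported contigs
≥ `min_contig_len` (1 kb) decides, ties toward larger k.  Contigs are
ranked by *mapped* reads, not reads used in construction: the set of
reads that align to a contig is the set the subtraction step removes, so
ranking and removal stay consistent.

Retention each iteration is the circular contigs ≥ 2 kb plus the top-20
ranked linear contigs; circular contigs do not consume top-20 slots.
Subtraction maps the **full** current read set (never the trial
subsample) against all candidate contigs in one pass and removes every
pair whose best-mapping mate landed on a retained contig; the unmapped
mate of a removed pair often covers a circular junction or gap, which is
why pairs are removed whole.  `IterationRecord.reads_mapped` counts the
reads removed with their pairs, which keeps the conservation identity
total reads = Σ reads_mapped + unassembled exact.

The loop ends when zero reads map or no contig reaches 1 kb; a final
assembly of the leftover reads at the last selected k is then appended
so that sub-top-20 structure in the residue is still reported.  The
sweep is skipped in the zero-reads-mapped case, where it would re-run
the identical read set and duplicate its own output.

## The read mapper

Mapping is deterministic seed-and-extend: exact seed words of
`seed_length` bases (defaulting to the kmer of the assembly being
mapped) are looked up in a sorted index of contig positions, and each
candidate diagonal is verified with banded edit-distance alignment
(edlib, infix mode, band set by the identity floor).  A mate maps when
identity = 1 − editDistance/length ≥ `min_identity` (default 0.95);
the best contig per mate wins, ties to the smaller contig id.  Circular
contigs are virtually extended past the origin by one read length minus
one so junction-spanning reads both seed and align.  Up to three seed
positions per mate (start, centre, end) are tried on both strands; a
read whose every seed is corrupted by errors goes unmapped, which at the
default 0.1% substitution rate affects a negligible fraction of reads.

Protein identity in family clustering uses a different definition,
matches / alignment columns of a global alignment with gaps counting as
columns, because the 30% family threshold is defined on alignments, not
edit distances.  Among edit-optimal alignments the column count can
depend on argument order, so the pair is canonically ordered (shorter
sequence first, then lexicographic) before alignment, making the
function exactly symmetric.

## Cassette mathematics

Families merge into cassettes by best-first agglomeration on
overlap(A,B) = |contigs(A) ∩ contigs(B)| / min(|contigs(A)|,
|contigs(B)|) with threshold 0.8, recomputed after every merge; merged
units can absorb further families or cassettes.  A merged unit's contig
set is the **intersection** of its parts — the conservative reading of
families "found on the same group of contigs"; union semantics are
available as a config option.  Tie-breaks (larger smaller-set first,
then lexicographic family ids) make the output invariant to the input
order of families.

The co-orientation score uses one representative ORF per family per
contig (the longest, ties by id).  For each family pair, ordered by
family id, each shared contig contributes the ordered strand pair of the
two representatives — four possible states — and the pair's score is the
modal state's share; the cassette score is the mean over pairs.  With
orientations independent and uniform the modal share of n contigs tends
to 0.25 from above (the expected maximum of a symmetric multinomial
exceeds 1/4 by O(n^-1/2)), which is why the Monte-Carlo check at
n = 10⁵ sits within half a percentage point of 25%.

## The synthetic community generator

`generate_community` draws uniform-ACGT genomes screened so no canonical
62-mer occurs twice within a genome (checked on the doubled sequence, so
circular use is also repeat-free).  This makes assembly ground truth
unambiguous: a repeat-free genome has a linear (or cyclic) de Bruijn
graph at every usable k.  Real phage genomes carry terminal repeats,
tRNA clusters and mosaic homology; none of that is modelled, so passing
these benchmarks demonstrates the pipeline's bookkeeping and selection
logic, not its behaviour on repeat-rich data.  Reads are 100 bp pairs
from opposite strands of abundance-weighted fragments (normal insert,
default 300 ± 30 bp), circular genomes sampled across the origin, with
independent per-base substitutions; quality-score models, indel errors
and amplification bias are deliberately out of scope.  Abundances are
equal ("uniform") or rank^−a ("power-law", default a = 1.5).  Every
generator is a pure function of its spec and seed.

`recovery_fraction` calls a contig matching when its best gapped
alignment to the reference (either strand; against the doubled reference
when the reference is circular, so rotated assemblies count) reaches 95%
identity over at least 500 bp, and reports the longest matching contig
over the reference length, capped at 1.  The 95%/500 bp gate is this
package's own choice of a match stringent enough to exclude chance
alignments yet tolerant of the simulated error rate.

## Benchmark problem sizes

The shipped benchmarks (`virocycle.benchmarks`) are sized for a single
CPU.  The spike-in benchmark uses mixtures of 4×10⁴ reads; the spiked
target is a 7,996 bp circular genome — the length of papillomavirus
type 6b — so the absolute spike counts 500/1000/1500/1798 reads
correspond to 6/13/19/23× target coverage.  The background is 22 linear
genomes of 4.5–5.5 kb at uniform abundance (≈35× each) with 0.1%
substitution errors: deep enough that background contigs fill the
top-20 retention in the first iteration, leaving the spike to be
assembled at its own optimal kmer in a later iteration — the same scale
separation between community and spike that a full-size experiment has
by construction.  The background is linear so that circular closure is
specific to the target.  Trials subsample 10⁴ reads, a quarter of the
input, the same order of subsampling as the 10⁶-read cap applied to
full-size data.  Expected behaviour: partial recovery at 6× (the target
fragments below the coverage floor), near-complete recovery from 13×
up, monotone in coverage on average.

## Known limitations

- Tiny repeats are handled only through path splitting at branch nodes;
  repeats longer than k−1 within a genome fragment the assembly (the
  simulator screens them out; real data will not).
- The mapper reports best placements only; reads matching several
  retained contigs equally are assigned to one (smallest id), and
  secondary placements are not recorded.
- Six-frame ORF calling with ATG-only starts is deterministic but less
  sensitive than a trained gene model; the downstream family and
  cassette mathematics is independent of the caller.
- Cassette agglomeration is greedy; a different merge order could give
  a different (if rarely observed) partition.  The stated tie-breaks fix
  the order completely, trading optimality for reproducibility.
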