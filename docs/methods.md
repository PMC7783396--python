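# Methods

This note records the models, parameter choices and numerical conventions
behind `oligopaint`, and what the synthetic fixtures do and do not
demonstrate.

## Coordinates and formats

All coordinates are 0-based half-open internally (BED convention). Reports
that print Mb convert as bp / 1e6, so a published "4–4.5 Mb" site is stored
as [4,000,000, 4,500,000). FASTA/FASTQ parsing goes through Biopython;
sequences are uppercased and every character outside {A,C,G,T} becomes N on
input. An N poisons any candidate window overlapping it (ambiguity
discard): the design operates on assembled, unambiguous sequence, and how
assembly gaps inside target regions should otherwise be treated is
undefined, so the conservative discard is used.

## Probe geometry and GC filter

Candidates are forward-strand windows of length L (default 47 nt) tiled
with period L + gap (default 3 bp); a trailing window shorter than L is
never emitted because probes must be synthesizable at exactly L nt. An
N-free region of length n therefore yields ⌊(n − L)/(L + gap)⌋ + 1
candidates (10,000 per 500 kb at defaults). No reverse-strand tiling:
hybridization is strand-agnostic downstream, and one strand suffices.

The GC window (default 30–66%) is inclusive at both ends and evaluated as
an exact rational comparison (`gc_min·L ≤ 100·n_GC ≤ gc_max·L`), never via
rounded floating-point percentages. Whether the bounds are strict is not
specified by the published design; the inclusive reading is the permissive
one and is what the tests pin down.

## Repeat screening

The de novo repeat reference emulates building a repeat library from raw,
unassembled reads: every k-mer (default k = 32) is counted canonically — a
k-mer and its reverse complement share a count keyed by the
lexicographically smaller, since repeats hybridize irrespective of strand —
and the `repeat_top_n` (default 5,000) most abundant are concatenated in
rank order. Ties at the cut are broken lexicographically for determinism.
Reads are used as-is (no quality filtering; k-mers containing N are
skipped).

"Maps to ≥ ~28 bases of the repeat reference" is operationalized as: the
longest exact substring shared between the oligo (either strand) and the
concatenated reference is ≥ `repeat_overlap_min` (default 28 nt). This is
deterministic and oracle-testable; a mismatch-tolerant mapping criterion
would introduce aligner parameters the design does not fix. Matches
spanning the junction of two concatenated k-mers are allowed to count — the
reference is screened as one string. The query runs on a suffix automaton
of the reference (exact longest-common-substring in O(|oligo|) per query);
a quadratic dynamic-programming oracle verifies it in the tests. Known
repeats (rDNA, organellar, published families, or an external clustering
output supplied as FASTA) are screened the same way and, when both classes
match, the recorded discard reason names the known class.

## Specificity mapping

The internal mapper replaces an external short-read aligner with an
ungapped seed-and-verify search: every seed-length substring of the oligo
(both strands) is looked up in a sorted 2-bit k-mer index of the genome and
candidate placements are verified by exact Hamming distance. Gaps are not
modeled — an indel inside a ~47-mer probe effectively abolishes
hybridization, so ungapped alignment is the standard oligo-design
assumption.

For the self-genome pass (defaults: seed 18, ≤ 5 mismatches) the seed
length is automatically capped at ⌊L/(m+1)⌋ for mismatch budget m (7 for
47/5): by pigeonhole every alignment within budget then contains an exact
seed, making the search lossless; the tests verify equality with a
brute-force full-genome Hamming scan for budgets 0–9. An oligo is
off-target, and discarded, when any hit is not fully inside its *own*
target region — hits in other target regions of the same design also count,
because each band must remain specific to its chromosomal region to serve
as a barcode element. Duplications entirely within the oligo's own target
are tolerated. A user-supplied SAM of hits can replace the internal mapper.

The cross-species pass (defaults: seed 13, ≤ 9 mismatches ≈ 80% identity
over 47 nt, approximating FISH stringency at 0.1×SSC/42 °C) keeps its
13-mer seed as a sensitivity heuristic rather than reducing it to the
lossless 4-mer bound, which would be computationally prohibitive and is
unnecessary: at the divergences where probes still hybridize, a clean
13-mer window survives in nearly every probe, and block calling needs only
a quorum of hits. Hits are grouped per source region and target chromosome
and clustered greedily with inter-hit start gaps ≤ `block_gap_max`
(default 500 kb); clusters with < `block_min_hits` hits (default 20) are
noise. These defaults leave the weakest published transferred site
(653 oligos over 500 kb) passing by a wide margin. Block orientation is the
Spearman rank correlation between oligo origin order and hit order:
> +0.5 forward, < −0.5 reverse, otherwise mixed (also returned for blocks
with < 3 usable hits, where a sign is not meaningful).

## Hybridization simulation and rearrangement calls

Hits are binned per chromosome at `bin_size` (default 100 kb); bins with
≥ `peak_min_hits_per_bin` hits (default 5) are signal, and adjacent signal
bins merge into one peak across at most one sub-threshold gap bin, so a
biological band is not split by a binning artifact. Peak intensity is the
number of contributing hits (conserved: intensities over a genome sum to
the clustered hits), position the hit-weighted mean midpoint, width the
bin-aligned span. The published peak-calling procedure behind the coverage
figures is unstated; all three knobs are config-exposed.

Genome comparison works per source region on the peak sets, in this
priority: no destination peak → deletion, guarded by the raw cross-mapping
hit count when available (≥ `block_min_hits` residual hits is logged as a
weak signal, not called deleted — distinguishing divergence from absence);
more than one destination peak → duplication (which deliberately
pre-empts translocation, so an ectopic extra copy is reported once);
a single peak on an unexpected chromosome → translocation; reverse
orientation → reorientation. The expected chromosome of each source
chromosome is the majority destination of its regions' peaks, ties broken
by the region nearest the chromosome start; two source chromosomes sharing
one expected destination is a fusion. When more than one block survives
for a region (e.g. paralogous whole-genome-triplication segments), all are
reported rather than silently adjudicated.

## Dot plots

Dots are shared exact k-mers (default k = 15, matching the visual
granularity of genome-scale similarity plots while staying fast); reverse
-complement sharing plots on the anti-diagonal. Chaining is greedy over
matches sorted by (x, y): a match joins the open chain of equal strand with
the nearest diagonal offset within `max_gap`, provided it also lies within
`max_gap` of the chain tail along x (so chains do not leap across an
intervening inversion or deletion); chains shorter than `min_len`
matches are dropped, and every match belongs to at most one segment.
Between consecutive forward segments, the offset difference Δy − Δx is
reported as an insertion in the target (positive) or query (negative),
accurate to about ±k bp.

## Immortalization

Constructs are `5'site (20 nt) + insert (L nt) + 3'site (20 nt)`, 87 nt at
L = 47. The shipped 3' site is the published
`GATCTCTGCATCTAGTAATG`; the 5' site defaults to the canonical T7 primer
20-mer, which is named but not printed in the published design and is
therefore configurable. Sau3AI is modeled as cutting immediately 5' of each
`GATC` on the top strand — the 4-nt 5' overhang is metadata, since product
length is what matters for probe prediction — so a GATC-free insert yields
a 67-nt labeled product plus a 20-nt unlabeled tail, and an internal GATC
predicts (and warns about) a truncated product at build time. PCR is
modeled only as sequence replication; the touchdown thermal profile is
stored as protocol metadata. The primer audit compares the forward primer
to the 5' site and the reverse complement of the reverse primer to the 3'
site per base and flags disagreements without "fixing" either sequence: the
published reverse primer is in fact not the exact reverse complement of the
published 3' site (the Sau3AI half-site agrees; downstream bases differ),
and the toolkit surfaces that rather than guessing which sequence is
authoritative.

## Synthetic fixtures: what they emulate and what they don't

`default_fixture_spec` defines the desk-scale study conditions used across
the tests and the acceptance script: six chromosomes (0.9 Mb + 4 × 0.4 Mb +
0.6 Mb, ~2.9 Mb total — roughly a thousandth of a Brassica genome), seven
single-copy target regions of 30–40 kb at plant-like GC (0.38), one 18-kb
tandem array (180-bp monomer × 100) planted *inside* a target so the repeat
screen has real work to do, one dispersed 300-bp family (60 copies), and a
1-kb known-repeat insert inside another target that only the known-repeat
screen can catch (its read abundance is background-level). Reads are
error-free, uniform, 150 bp at 4× coverage: the k-mer stage is about
abundance ranking, not error correction, so an error model is deliberately
omitted. The sister genome carries 3% substitutions and 2×10⁻⁴/bp small
indels plus exactly one translocation, inversion, deletion and duplication
into recorded coordinates; seeds 1–5 are the documented seed list.

Random background is single-copy by construction, so target uniqueness is
guaranteed rather than selected for; real genomes add paralogy,
triplicated blocks, and assembly errors that the fixtures do not model.
Passing the recovery tests therefore shows the pipeline's logic is correct
under its stated assumptions — not that any particular real genome will
yield the same retention rates. Fixture sizes were chosen so the full
five-seed recovery suite and the acceptance script each run in a few
minutes on one core.

## Numerical conventions

Report densities print to 1 decimal with half-up rounding (the published
table's precision); library sizes sum source-genome rows only, since
transferred rows re-use the same synthesized oligos; distinct source sites
are counted by coordinates, because one site can be shared by two
libraries. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); k-mers pack 2 bits/base into uint64 (k ≤ 32);
ranking ties break lexicographically; and every file the pipeline writes is
byte-reproducible given identical inputs and parameters.
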