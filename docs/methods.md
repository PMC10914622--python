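# Methods

## Model

A de Bruijn assembler using largest k-mer size maxK terminates contigs at
graph branchings, duplicating the branch k-mer region on every contig that
touches it. Consequently two contigs that were adjacent in a genome share an
exact end sequence of length L — maxK for metaSPAdes and MEGAHIT, maxK − 1
for IDBA_UD. The joiner treats each shared end as a *candidate* adjacency
and promotes it to a join only when two independent signals agree:

* **Coverage compatibility.** Fragments of one genome are sequenced at the
  same rate, so the candidate's mean depth must lie within a ratio window of
  the query's depth, `lo ≤ cov_candidate / cov_query ≤ hi`, inclusive.
  Default window (0.5, 2.0): a symmetric two-fold band wide enough to absorb
  depth estimation noise on short contigs yet narrow enough to reject
  low-abundance strain variants (which typically sit several-fold below the
  dominant subpopulation). A zero-depth query is compatible only with a
  zero-depth candidate. Configurable via `--cov-ratio`.
* **Paired-read spanning.** At least `min_spanning_pairs` (default 1) read
  pairs must have one mate mapped to each of the two contigs, every mate a
  primary alignment with at most `mm_max` (default 2) mismatches by its NM
  tag; soft-clipped bases are not mismatches. Linkage is contig-level: mate
  position and insert orientation within the contigs are not constrained.
  Reads lacking an NM tag fail the filter by default.

### End classification

Ends are matched reverse-complement-aware, but only geometrically joinable
pairs are kept: opposite sides (one right end, one left end) must carry the
same L-mer; same sides must carry reverse-complement L-mers (the candidate
is then entered through its reverse complement). Two right ends with the
same L-mer merely read into a common successor and are never each other's
partners. An end is `one_path_end` with exactly one partner,
`two_paths_end` when its two partners B and C partner exclusively with it,
and `multi_path_end` otherwise (including two-partner configurations that
fail the exclusivity condition — those arise from 2×2 repeat ambiguities
where no join can be certified). End L-mers containing N never match:
an ambiguous base cannot certify an exact overlap.

### Self-circularity

Two routes. **Case 1:** the contig's left and right ends are each other's
exclusive partners at length L — the signature an assembler leaves on a
circular genome, whose valid terminal overlap is exactly L. **Case 2:**
neither end has any partner, but the contig carries an exact direct terminal
repeat (DTR) of length d ≥ minK. The repeat is found as the longest border
of the sequence (prefix = suffix) via the KMP failure chain in O(n),
ignoring borders longer than half the sequence. Note that a genuine DTR of
length d ≠ L produces *no* end-index match at L — for a linearized circle
`C + C[:d]`, prefix-L equals suffix-L only when d = L exactly — so case 2
must accept repeats both shorter *and longer* than L; restricting it to
d < L would silently miss every genome whose natural terminal repeat
(commonly 100–200 bp) exceeds the assembler k-mer. The repeat must be exact;
a single mismatch disqualifies. One repeat copy is trimmed from the reported
circular sequence, so the output length equals the circular genome length.

### Extension and categories

Extension is depth-first and single-path: from each of the query's two ends
the walk advances one accepted contig at a time and never branches. A stop
(no partner, or multi-path end) ends that direction quietly; a failed
validation records its reason. Revisiting a contig already in the walk stops
the direction — unless the walk re-enters the query itself in forward
orientation from the far side, which closes the circle
(`extended_circular`). A `two_paths_end` where *both* candidates pass
validation fails the join rather than picking one: with two defensible
paths, the join is not unique, and uniqueness is the contract. Queries are
processed in descending length then id, making output deterministic and
independent of input file order.

Category assignment: any accepted extension without circularization is
`extended_partial`; no partners at either end (and not self-circular) is
`orphan_end`; partners exist but no join validated anywhere is
`extended_failed`.

### Cross-query uniqueness

After all walks are built, two global checks run. (a) If a contig appears in
two walks whose member sets differ, the path was only seemingly unique and
every involved query becomes `extended_failed`; walks with identical member
sets are the same final sequence seen from different queries and are left
alone. (b) If a query's left-side extension and right-side extension pulled
in distinct contigs that are near-duplicates of each other, both ends
converged into closely related (typically strain-variant) sequence and the
query becomes `extended_failed`. Near-duplication is estimated Mash-style
from canonical k-mer containment, identity ≈ containment^(1/k) with k = 16,
threshold 0.95 — at k = 16 a 1%-diverged variant pair still shares ~85% of
its k-mers (estimated identity 0.99) and a 5%-diverged pair ~44% (0.95),
while unrelated contigs share essentially none, so the threshold separates
species-level relatives from chance repeats. A plain containment cut-off at
a single value cannot cover the 1–5% divergence range because containment
decays geometrically with k times the divergence.

### Joining and gap checking

Merging a walk drops one copy of each internal L-overlap (linear length
Σ lengths − (n−1)·L; circular joins additionally trim the closing overlap)
and re-verifies every junction, treating a mismatch as an internal error.
The gap check recomputes per-base coverage of joined sequences from primary
alignments with ≤ 2 mismatches and replaces every maximal zero-coverage
interval with exactly ten Ns — a fixed-width marker, deliberately not
length-preserving, flagging an unsupported region without asserting its
size. Intervals touching a sequence end are also replaced and flagged in the
report.

## Synthetic communities

The generator emulates the conditions that matter for the joiner:

* **DTR genomes** — random circular genomes of 5–50 kb (the typical phage
  size range; tests use 5–20 kb to keep runtimes in seconds) linearized
  with an exact 100–200 bp terminal repeat.
* **Subpopulations** — parent genomes paired with copies mutated at 1%, 3%
  or 5% of positions (substitutions only, positions drawn without
  replacement, all substitutions equiprobable), plus trios of parent + 3% +
  5% mutants. Parents are retained, so category sizes
  (500, 500, 500, 500, 300) give 500 + 500·2·3 + 300·3 = 4,400 genomes.
* **Fragmentation** — each genome is cut so adjacent fragments share exactly
  the L-length end sequence; mutants reuse their parent's breakpoints, as
  real assemblies break both subpopulations at divergence-flanked loci.
  Optionally a duplicated segment is planted with breakpoints at both
  copies, creating genuinely ambiguous shared ends. Circular genomes are
  either left whole (a self-circular fixture) or cut around the ring so the
  fragment chain closes. Breakpoint placement is idealized: real assembler
  breakpoints come from the graph, not from a coordinate draw.
* **Reads** — error-free 126 bp pairs, Gaussian inserts (mean 350, sd 30),
  uniform placement per genome at its 10–100× depth. Alignments are emitted
  directly from the known placements (exact NM tags, soft-clips where a
  read overhangs its contig) rather than through an external aligner, and
  the coverage table is computed from the same placements.

What the fixtures deliberately do **not** model: sequencing error,
GC-coverage bias, chimeric contigs, reads cross-mapping between
subpopulations (each genome's reads are placed only on its own contigs,
which slightly flatters the linkage signal for variants), or a natural
community background. Passing tests therefore demonstrate the correctness
of the joining logic under its own assumptions, not performance on real
assemblies.

## Benchmark evaluation

A group (join or bin) whose member contigs all best-match one reference is
*good*; split across references with all pairwise ANI ≥ 70% it is
*problematic*; any pair below 70% makes it *contaminated*. For non-good
groups the contamination rate is
`((Total_len − Max_len)/Total_len) / ((Num_polished − 1)/Num_polished)`,
which is 0 when the dominant reference holds all length and exactly 1 when
length splits evenly across all matched references. ANI values and per-contig
best matches are inputs, not computed here; for synthetic communities the
ANI between a parent and its p%-mutant is supplied analytically as
100·(1−p). Confusion metrics use the standard pairwise clustering
convention: over all unordered pairs of contigs appearing in either
partition, a pair is positive when predicted co-grouped; undefined ratios
are reported as 0. RPKM follows
`N_mapped / (genome_len/1000) / (N_sample/1e6)`.

## Numerical and design notes

* Coordinates are 0-based half-open throughout; sequences are uppercased on
  load; iteration follows input FASTA order and partner sets are sorted
  (contig id, side), so all outputs are deterministic.
* Palindromic end L-mers match once, not twice.
* Contigs shorter than L stay in the contig set (usable as orphan-end
  queries) but contribute no ends.
* Round-trip tests run 20-genome communities (5–20 kb, depth 20–100×) over
  three seeds — small enough for seconds-scale runs, large enough for every
  structural case (linear chains, rings, single-contig DTRs) to appear.

## Limitations

Queries at very low depth rarely acquire spanning pairs and fail extension;
the tool reads only one sample's mapping, so evidence from related samples
is unused; chimeras already present in input contigs are neither detected
nor repaired; and the two-path tie-break (fail when both candidates pass)
trades recall for precision by construction.
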