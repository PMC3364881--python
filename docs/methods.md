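# Methods

This note records the models, estimators, numerical choices and known
limitations behind `dscamscan`, in the order the pipeline applies them.

## Conserved-block extraction

An annotated alignment couples a protein multiple alignment with
per-sequence exon-boundary positions (0-based, in ungapped coordinates,
boundary *b* falling before residue *b*). "Highly conserved region" is
formalized as a column window maximizing mean per-column conservation,
where a column's conservation is the majority-residue count divided by the
number of sequences (gaps score 0). Candidate windows range over all
lengths in `[min_len, max_len]` (defaults 25–50 columns) and are discarded
if, mapped to any member's ungapped coordinates, they contain one of that
member's exon boundaries — a window crossing a boundary could never match
a single translated genomic segment, because introns interrupt
translation. Selection is greedy by score with ties broken by leftmost
start and then shorter window; chosen windows never overlap. The procedure
is deterministic; re-running it reproduces identical blocks.

The original region choice this formalizes was manual; mean
majority-residue identity with greedy non-overlapping selection is the
simplest reproducible surrogate, and window lengths stay user-supplied
because no published criterion exists to reproduce.

## Profile HMMs

Each block becomes a Plan7-lite profile: alignment columns with gap
fraction < 0.5 are match states; the rest feed insert states. Match
emissions use background-proportional pseudocounts,
(count + α·bg) / (n + α) with α = 1 by default; transitions are counted
from per-sequence state paths with a uniform pseudocount of the same total
weight; sequence weighting is uniform (training sets here have 3–7
sequences). The background is the Robinson–Robinson residue frequency
vector (uniform available). Insert states emit the background
(log-odds 0). Alignment is local: uniform entry over match states, free
exit, single-hit. Multi-hit dynamic programming, biased-composition
filters and DNA-space models are out of scope. The stop symbol is never
scored; scanning operates on stop-free segments only. `X` (and any unknown
residue) emits the background in both match and insert states, so all-N
stretches can never score above 0 bits.

Viterbi (best path) and forward (all paths, log-sum) recursions run in a
numba-compiled kernel over uint8-encoded residues, in bits, with the
forward ≥ Viterbi invariant holding by construction. Viterbi additionally
propagates the local-path start index through the DP so hit intervals come
out of the same pass.

## E-value calibration

Significance uses the classical extreme-value law for optimal local
alignment scores: P(S > s) = 1 − exp(−exp(−λ(s − μ))), with
E = db_size · P(S > s) and db_size = the number of translated segments in
the search at hand (a per-search convention; thresholds are configuration,
defaulting to 0.001 for the gene blocks, 0.01 for the longer whole-gene
profile set, 0.001 for exon scans).

Calibration scores `n_samples` (default 1,000) i.i.d. background sequences
of `sample_len` (default 100) residues with Viterbi and fits (μ, λ) within
the Gumbel family by minimum Cramér–von Mises distance, initialized at the
maximum-likelihood estimate (Nelder–Mead; deterministic under the seed).
Minimum-distance estimation is used instead of raw ML because an E-value
is a statement about the null CDF: under the mild residual misspecification
that remains at finite profile length, ML optimizes density fit and
systematically distorts the CDF, which measurably degrades the uniformity
of null p-values. Two empirical regularities serve as built-in sanity
checks, both exercised by the test suite:

- the fitted λ lands on ≈ ln 2 per bit, the theoretically exact Gumbel
  slope for probabilistic local alignment, which makes the deep-tail
  extrapolation used at genome scale (p ≈ 10⁻⁹ after a 3-million-segment
  Bonferroni) trustworthy — the 30 Mb random-genome control yields zero
  hits at E < 0.01;
- fresh-null p-values are approximately uniform: pooled over the ten block
  profiles (100 fresh samples each), the KS statistic at n = 1,000 is
  ≈ 0.03.

Two caveats are intentional. First, the extreme-value law is asymptotic:
with very short profiles (≲ 20 match states) built from near-identical
training rows, null Viterbi scores collapse onto a coarse lattice and no
two-parameter continuous fit is uniform — block extraction defaults and
the synthetic family's realism settings keep profiles out of that regime.
Second, calibration at a fixed 100-residue length makes E-values for the
typically shorter stop-free segments of random DNA (mean ≈ 21 residues)
slightly conservative, which is the safe direction for a detection screen.

## Six-frame scanning

Scaffolds are uint8-encoded; each of the six frames is translated by a
64-entry codon-index lookup (standard genetic code by default, any NCBI
table id accepted), with N-containing codons becoming `X`. Frames are
split at stop codons into segments; a segment of *a* residues always maps
to exactly 3*a* nucleotides on the forward strand, and every hit records
scaffold, strand, frame, amino-acid and nucleotide intervals, bit score
and E-value. Every (segment, profile) pair is scored — one kernel call
per (frame, profile) keeps the Python overhead negligible — and per
(scaffold, profile) the top-m passing hits are retained (m = 2 by
default, generalizing best-two-hits-per-frame annotation practice to the
genome-wide scan). Scan output is sorted and independent of scaffold order
in the input; the E-value database size (total segments) is also
order-independent.

## Ordered k-of-n candidate calling

"Matched in the correct order" is formalized per scaffold and strand:
among each block's retained hits, find the subset maximizing the number of
blocks whose hits are collinear — strictly increasing nucleotide midpoints
with increasing block index on the + strand, strictly decreasing on −.
Midpoints avoid the ambiguity of comparing unequal-length intervals. The
optimum is a heaviest-increasing-subsequence dynamic program over hits
sorted by block index (count as weight, total bit score as tie-break),
verified against exhaustive enumeration on instances up to 12 hits. A
candidate is emitted when the best subset covers ≥ k_min blocks (default
6 of 10; the whole-gene profile set defaults to > 10 of 37, reading "more
than 10" strictly). Cross-strand mixing is disallowed by default
(configurable): hits from different frames on the same strand may combine,
since exons need not share frame. Ties anywhere break by higher bit score,
lower start coordinate, lower block index.

Chaining into a gene model maximizes Σ(bit score) − penalty·Σ(inter-hit
gaps) subject to block order, collinearity and non-overlap (default
penalty 10⁻⁴ bits/nt — small enough that plausible intron spans are never
rejected, nonzero so equal-score alternatives resolve toward compactness).
The stitched protein concatenates matched residues in chain order; the
stitched mRNA concatenates the genomic slices on the gene's strand. Blocks
absent from the chain are reported in a gapped-model warning.

## Exon-variant discovery

Intronic regions between consecutive anchor exons of each cluster (Ig2,
Ig3, Ig7) are six-frame translated and scanned with the cluster's
profile(s); scanning both strands is what lets an inverted variant be
detected, and hits on the strand opposite the host gene carry an
`inverted` flag. Because a tandem array can place several variants into
one stop-free segment (a spacer is stop-free in a given frame with
probability ≈ 0.13 at 40 codons), the scanner takes the best local hit of
a segment and recurses into the flanking sub-intervals until nothing
passes the cutoff — hits within a segment are therefore non-overlapping by
construction. Across frames, overlapping hits are resolved greedily by
ascending E-value, discarding any hit that overlaps a kept one by more
than 50% of the shorter interval. Hit boundaries are local-alignment
boundaries, not spliced-exon boundaries; no splice-site refinement is
attempted. The default cutoff is 0.001; the stricter 0.0001 variant seen
in some reports of this analysis style is reachable via configuration.

Representative-sequence selection for profile training cuts a rooted,
branch-length-annotated guide tree at cumulative root distance
(tree height − h): every subtree hanging below the cut (and every leaf
above it) is a cluster, and the cluster's representative is its medoid —
the leaf with the smallest mean patristic distance to the other members,
ties lexicographic. h = 0 returns every leaf; h ≥ tree height returns a
single representative; cluster count is non-increasing in h. Tree
inference itself stays external; only the picking rule is implemented.

## Synthetic data: what it emulates, what it does not

All generators are pure functions of (spec, seed) and byte-reproducible.

- **Random genomes**: i.i.d. nucleotides with P(G or C) = gc (default
  0.5), the negative-control composition. Desk-scale default is 1,000
  scaffolds × 30,000 nt; the order-of-magnitude-larger published control
  (55,000 scaffolds) is configuration-reachable.
- **Planted genes**: the source protein is reverse-translated with
  uniform synonymous codon choice (no codon-usage bias by default; a
  bias hook exists because composition bias is a known phylogenetic
  confounder, though detection does not use it). Exons follow the stated
  exon plan; introns begin `GT`, end `AG`, and contain an in-frame stop
  within their first 6 nt, formalizing why block profiles terminate at
  exon boundaries. Substitutions are applied per-nucleotide at the stated
  rate, uniformly over the three alternatives, and counted in the truth
  record.
- **Exon-variant arrays**: n independent copies of a base exon, each
  mutated at the divergence rate with stop-introducing substitutions
  resampled, separated by random spacers. Truth lists every variant
  interval.
- **The block family** (`make_block_family`): an ancestor protein of ten
  40-residue conserved blocks separated by 12-residue linkers; members
  carry substitutions at rate 0.15 in blocks and 0.6 in linkers
  (≈ 72% / 25% pairwise identity), emulating training sets of
  cross-species paralogs; exon boundaries sit mid-linker. These rates and
  lengths are on the scale of real Ig/FN-domain family alignments; they
  also keep profiles long and heterogeneous enough for the extreme-value
  law (see calibration caveats).

What the synthetic genomes do *not* emulate: repeat families, assembly
gaps, GC heterogeneity, codon-usage bias, splice-site sequence context
beyond the GT/AG dinucleotides, and real intron length distributions.
Passing the benchmark therefore demonstrates the detection logic and its
statistics under the stated null, not performance against repeat-rich or
biased real assemblies.

## Problem sizes and determinism

The shipped benchmarks use: 1,000 × 30 kb for the negative control
(~3.2 M translated segments, ~4 minutes on one core), 50 × 30 kb for the
cut-off sweep, 12/48/33-variant arrays of a 55-residue exon for the
cluster recovery, 1,000 random ≤ 12-hit instances for the enumeration
oracles, and 1,000 calibration samples of 100 residues per profile. Every
random draw flows from an explicit seed; pipelines log the resolved
configuration and seed as their first entries, and re-running any stage
with the same inputs is byte-identical (log timestamps are confined to the
log).

## Known limitations

- Single-hit local alignment per segment in the genome scan: a segment
  containing two copies of the same block (e.g. a perfect tandem
  duplication with no intervening stop) yields one hit; the exon scanner's
  split-and-recurse strategy is applied only where tandem copies are
  expected.
- E-values are per-search and calibration-dependent; they are not
  comparable to values produced by other engines' database conventions,
  and thresholds are exposed as configuration for exactly that reason.
- The k-of-n rule is evaluated per scaffold: a gene split across two
  scaffolds can fall below k_min on each (the published analysis hit the
  same limit and resolved it by manual merging).
- Back-translation requires the CDS to match the protein exactly under
  the standard code (one trailing stop tolerated); it does not handle
  selenocysteine read-through or frameshifted pseudogene input.
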