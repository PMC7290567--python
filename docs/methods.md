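# Methods

## Scope and data model

All coordinates are 1-based against a single circular reference of length L
(default 16,569 bp, the size of the human mitochondrial genome); positions
reduce modulo L, and reads, k-mers and alignments may wrap through the
origin. The packaged reference (`data/synthetic_mt.fa`) is a random
sequence, not the human rCRS: nothing in the package depends on real
sequence content, and tests never require it.

## Synthetic library generator

The generator's purpose is to reproduce the *statistical structure* of
single-cell mtDNA libraries, not any particular real dataset.

**Genotypes.** A cell is a haplogroup (node of a Phylotree-style toy tree,
whose cumulative root-to-node variants are homoplasmic) plus private
homoplasmic variants and heteroplasmic SNPs with fractions h ∈ (0, 1).
Homoplasmic variants (including indels) are written into the haplotype
sequence; heteroplasmic sites are realized per read as independent
Bernoulli(h) draws, the model for a well-mixed pool of mutant and wild-type
mtDNA molecules. Heteroplasmic indels are not supported.

**Coverage bias.** Read starts are drawn from a protocol-specific positional
weight field over the circle:

| protocol | model | default parameters |
|---|---|---|
| BULK | uniform | duplicate rate 0.02 |
| MDA | smoothed lognormal field | σ = 0.8, 300 bp smoothing, dup 0.05 |
| eWGA | smoothed lognormal field | σ = 0.5 (milder than MDA), dup 0.05 |
| DOP | weight concentrated in windows | 8 × 600 bp windows, background 0.05, dup 0.10 |
| MALBAC | windows + genome dropout | 6 × 500 bp, background 0.02, dropout 0.5, dup 0.10 |
| ATAC | uniform, duplication-heavy | duplicate rate 0.30 |

No published quantitative bias parameters exist for these protocols at the
mtDNA scale; the magnitudes above are package choices, fixed once, selected
so the *ordering* of coverage unevenness (MALBAC, DOP ≫ MDA, eWGA > bulk)
matches what protocol comparisons consistently show. Measured mean Gini over
20 seeds at 50×: MALBAC 0.87, DOP 0.64, MDA 0.42, eWGA 0.28, ATAC 0.10,
BULK 0.08. Curve shapes are not calibrated to any real dataset.

**Reads.** Exactly `round(depth · L / mean_length)` reads are emitted.
Fragment lengths are drawn uniformly from [read_length − 10, read_length]
(real libraries are not fixed-length; without this, the coordinate-keyed
duplicate removal would collapse genuinely independent fragments at high
depth). A `duplicate_rate` fraction of reads are PCR duplicates: copies of
another fragment's coordinates and alleles, re-sequenced with independent
errors. Sequencing errors are i.i.d. substitutions (default 0.1%); quality
scores are drawn Q ∈ [25, 40] for correct bases and Q ∈ [2, 20] for
erroneous ones, a deliberately separable design so the pileup's Q ≥ 30
filter does visible, testable work. Paired-end structure is not modelled —
nothing downstream uses pairing.

**NUMT decoys.** Contiguous (circularly extracted) segments of the cell's
haplotype, mutated i.i.d. at a divergence rate (default 3%, the scale of
human NUMT divergence), overwrite recorded intervals of a random nuclear
background contig. Decoy reads are labelled `numts` when at least half the
read lies inside an insertion, else `nuclear`, enabling truth-based
evaluation of the filter.

## Alignment and NUMT filtering

One internal aligner serves both of the selective alignment rounds of the
read-rescue strategy. The index stores exact 15-mers of the doubled mtDNA
(so origin-spanning seeds exist, canonicalized mod L) and of the decoys.
Per strand, seed k-mers are sampled every k bases plus the read's final
k-mer; candidate diagonals are ranked by seed votes (up to 8 per
reference). Each candidate gets an ungapped pass (best-scoring contiguous
segment, i.e. local alignment without gaps); a full affine-gap local DP
(Gotoh) over a ±15 bp banded window is run only when the ungapped score
leaves room for a gap to improve it — with match +1 / mismatch −1 / open −2
/ extend −1 a gapped alignment can never beat an ungapped score of
read_length − 2, so reads with ≤ 1 mismatch skip the DP. The DP's row
recurrence is vectorized; the within-row horizontal-gap dependency is
resolved in closed form as a running maximum. Equal-best placements keep
the lowest coordinate and are flagged ambiguous.

On reads whose corruption stays in the generator's regime (a few
substitutions/indels per read), the best score equals an exhaustive
Smith–Waterman over both strands and the doubled reference (tested against
an independent DP implementation). Like any seed-based mapper, the aligner
has no anchor for reads mutated so densely that no exact 15-mer survives;
such reads are outside the simulator's error model.

PCR duplicates are collapsed by exact (start, end, strand); the highest
base-quality sum wins, ties to the lexicographically smallest read id — an
idempotent rule. The NUMT filter then keeps a read iff its best mtDNA score
strictly exceeds its best nuclear score; ties and nuclear-only reads are
discarded. Measured on truth-labelled simulations (~100 bp reads): at 3%
divergence ≥ 96% of mtDNA reads are retained and ~100% of NUMT reads
removed; at 0% divergence the copies are informationally indistinguishable
and the strict rule sacrifices the overlapping mtDNA reads too — the
designed behaviour, since such reads genuinely cannot be assigned.

## Pileup, calls, consensus

Only aligned, non-clipped bases with Q ≥ 30 are tallied. Insertions are
recorded at their left-anchor position (and require every inserted base to
pass the quality threshold); deletions are length-tagged alleles at the
anchor, with supporting depth counted there — one convention had to be
fixed for testability. The filtered depth at a position is the sum of its
base tallies.

A non-reference allele with support ≥ 5 becomes a call with
AF = support / filtered depth (a plain point estimate; no confidence
interval machinery). An indel is dropped unless at least one supporting
read places it ≥ 5 bp from both read ends. Multiple alternates at one site
yield one call each; the consensus applies the single most frequent
alternate only if it alone reaches the 0.8 threshold. Positions with
filtered depth < 5 are non-callable: they split contigs and are omitted
(not written as N); a BED of callable intervals accompanies the consensus
FASTA, and VCF v4.2 output uses left-anchored indel records (deletion: POS
at the anchor, REF = anchor + deleted bases, ALT = anchor).

## Haplogroup scoring

`P_Hg = Nph / Nph_exp`, where Nph_exp counts a haplogroup's cumulative
defining SNPs **restricted to callable intervals** and Nph those observed
(calls with depth ≥ 5 and AF ≥ 0.8). Restricting the expectation means
missing coverage is not punished as mismatch — completeness is reported
separately through breadth, and genomes under 10% callable breadth are
flagged unresolved rather than scored. Only SNPs count; indels and
back-mutations are handled in the tree representation (a later entry at an
already-variant position overrides it; restoring the original allele
removes the position from the defining set). Ranking is by P_Hg, then
larger Nph_exp (the more specific clade wins ties along a lineage), then
name. With all path variants observed and callable, a descendant therefore
always outranks its ancestors.

## Coverage uniformity

The Lorenz curve is computed over **all** genome positions, zeros included
(a `covered_only` flag restricts to covered positions, since either
convention appears in practice); Gini = 1 − 2 × trapezoidal AUC of the
discrete polyline, the standard empirical estimator — deterministic and
oracle-checkable (e.g. depth vector [0,0,0,10] gives exactly 0.75, and the
one-position limit tends to (L−1)/L).

## Concordance analytics

Variant identity is the exact (pos, ref, alt) key. Pairwise statistics
follow the published table conventions: percentages to two decimals;
homoplasmic means AF strictly above 0.95 (in both replicates for pairwise
counts, in the per-assay mean for multi-cell tables); "shared by the
majority" means strictly more than half the cells; table summaries round
half-up to integers. Bulk confirmation filters the bulk call set at the
same AF/depth thresholds as the cells, while the raw bulk AF is carried
separately — the only reading consistent with bulk sites that are real but
under-covered. PPV treats replicate-shared calls as true positives. The
threshold sweep covers AF 1–10% × depth {10, 30, 50, 100, 500, 1000}; the
degenerate no-common-variants case reports 0 with a flag.

## Problem sizes and numerical choices

Deep-coverage studies (replicate concordance at 500×, heteroplasmy recovery
at 1000×) run on shortened 2–4 kb circular genomes: the properties under
test depend on site depth, not genome length, and this keeps a full test
run in minutes. Coverage-bias, haplogroup and end-to-end studies use the
full 16,569 bp genome. Heteroplasmy-recovery checks compare |AF − h|
against three binomial standard errors computed at the *observed* filtered
site depth — the estimator's real sample size after duplicate removal and
the Q ≥ 30 filter (which by construction retains ~11/16 of correct bases).
All randomness flows from explicit integer seeds; every generator function
is a pure function of (inputs, seed).

## Limitations

* The bias models are minimal: no GC-content coupling, no MDA chimera
  formation, no real amplicon chemistry — passing tests show the pipeline
  handles coverage fields of the right *shape and unevenness*, not that it
  reproduces any protocol's exact curves.
* Simulated replicates share the identical molecule pool statistics, so
  concordance and PPV at deep coverage come out near 100%, cleaner than
  real amplified replicates.
* Heteroplasmy is binomial (no allelic-dropout overdispersion); error rates
  carry no strand or context structure, and erroneous bases are always
  low-quality, so the Q-filter is more cleanly separable than in real data.
* No structural variants, no base-quality recalibration, no mapping-quality
  model, no pathogenicity annotation; single-end logic throughout.
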