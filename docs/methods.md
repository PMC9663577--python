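# Methods

`polytereg` implements the bespoke computations of a polyploid cistrome
analysis: given per-TF binding peaks, gene/TE annotations and
whole-genome alignment blocks for a three-subgenome (A/B/D) genome, it
classifies regions by subgenome homology, calls high-occupancy target
(HOT) regions, scores promoter binding affinity and homoeolog balance,
measures TE-subfamily enrichment, detects degenerated-TE relics, and
dates TE insertions. A synthetic-data generator with planted ground
truth makes every stage testable end to end.

## Coordinate conventions

All coordinates are 0-based half-open (BED-native); GFF3 is converted at
the boundary and round-trips exactly. The subgenome of a feature is
parsed from the chromosome-name suffix (`...A/B/D`, configurable regex).
The TSS is the interval start on `+` and the last base on `-`.

## Homology classification

A base on subgenome X is *aligned to* subgenome Y iff it lies in the
intersection of the X→Y block footprint and the back-projected Y→X
footprint — the strictest symmetric reading of "reciprocal alignment" —
within a contiguous run longer than `min_len` (default 400 bp). Bases
aligned to both other subgenomes are `homo3`, to exactly one `homo2`, to
none `specific`; `homo3` runs inside a synteny block are additionally
reported as `homoeo3`. Adjacent blocks are merged with zero gap
tolerance before the run-length rule. Features are assigned to classes
by their midpoint (deterministic for straddling features); a
majority-overlap alternative is provided.

## HOT regions and bin correlation

Peak intervals from all TFs are unioned into maximal disjoint merged
sites; ≥1 bp overlap merges, bookended intervals do not (half-open
convention). A merged site is HOT when strictly more than `threshold`
(default 12, i.e. ≥13) **distinct TFs** overlap it — a TF with two peaks
in one site counts once. TF co-binding is summarized by tiling each
chromosome into consecutive 2-kb bins anchored at coordinate 0 (trailing
partial bin kept), binarizing per-TF occupancy, and taking Pearson
correlations; constant vectors give NaN (reported missing, never 0).
Display order comes from average-linkage clustering of 1−r.

## Promoter affinity and balance patterns

The TF affinity score of gene g for one TF is

    TFAS(g) = Σ_k rpkm_k · exp(−d_k / 2000)

over the peaks whose **summit** lies in the 5-kb promoter centered on
the TSS, with d_k the summit–TSS distance; genes without a qualifying
peak score 0. Triads where all three genes score < 0.25 are filtered;
otherwise the three scores are normalized to proportions and assigned to
the nearest (Euclidean) of seven standards: (1/3,1/3,1/3) balanced,
(½,½,0)-type two-subgenome patterns, and (1,0,0)-type single-subgenome
patterns. Standards use exact thirds; ties are broken by the fixed
priority ABD > AB > AD > BD > A > B > D (a measure-zero event, but
reachable on exact inputs — e.g. (0.75, 0.25, 0) is equidistant from AB
and A).
The minimum distance between standards is √(1/6) ≈ 0.40825, so any
proportion vector within 0.204 of a standard is provably classified to
it.

Regulatory divergence of a homoeolog pair is Σ_TF |log2 fold-change| of
promoter scores over TFs where either gene exceeds 0.25; expression
divergence is the |log2 fold-change| of TPM. A pseudocount (default 0.5)
is added on both sides unconditionally, keeping the statistic symmetric
and finite at zero; it is configurable because published analyses rarely
state their handling of zeros. DHS balance is the Euclidean distance of
the promoter-openness proportion vector from (1/3,1/3,1/3).

## TE-subfamily enrichment

Subfamilies covering more than 0.1% of the genome are scored:

    ES = (query bp in subfamily / total query bp)
         / (subfamily bp / total TE bp)

with all lengths measured on flattened footprints (same-subfamily
overlaps collapsed, avoiding double counting). The degenerated-TE
variant computes the two background lengths from non-degenerated
annotations only.

## Degenerated-TE (relic) detection

For each triad with a TE-embedded binding site (peak summit inside both
the promoter and an annotated TE) in one or two subgenomes, the TE
sequence is aligned — Smith–Waterman, match +1 / mismatch −2 / gap open
−5 / extend −2, both orientations — against each sister promoter lacking
an annotated copy of that element. Alignments overlapping any annotated
TE are discarded; those with alignment length > 50 bp (BLAST column
convention, internal gaps counted) and ≥60% identity are reported as
dTEs. The score/identity floor is a deterministic substitute for a
database-size-dependent E-value cutoff and is exposed as a parameter.
The binding-site window is projected through the alignment columns and
called conserved at ≥70% identity over ≥70% of its length, the same
thresholds used for TFBS pair similarity.

The permutation control re-pairs each TE sequence with the promoter of a
randomly chosen *different* triad, n_perm times (default 1000), under
identical cutoffs. Because the draw space is the finite set of
(query, promoter) pairs, outcomes are memoized per pair; the returned
null distribution is unchanged. On data where triads share no element
the null is essentially zero. On the full synthetic genome the null is
*not* near zero by construction: all copies of a family descend from one
consensus, so relic promoters of different triads genuinely share
sequence — a known departure from real TE families, whose copies carry
deep copy-specific divergence.

## K2P distances, dating, expansion profiles

The Kimura two-parameter distance is computed from transition proportion
p and transversion proportion q over gap-free, unambiguous columns:
d = −½ln(1−2p−q) − ¼ln(1−2q). Saturated inputs (either log argument
≤ 0) raise a distinct error from empty comparisons. Pairwise distances
between unaligned sequences go through a global alignment (match +1 /
mismatch −1 / gap open −5 / extend −1) computed per pair rather than
through a multiple alignment: for two sequences the pairwise optimum is
deterministic and needs no external aligner.

A full-length LTR retrotransposon is dated by the K2P distance between
its 5′ and 3′ LTRs: age = d / (2μ) with μ = 1.3×10⁻⁸
substitutions/site/year by default. Expansion events appear as modes in
pairwise-distance distributions; modes are local maxima of a
Silverman-bandwidth Gaussian KDE with prominence ≥5% of the peak
density — an explicit stand-in for reading "apparent peaks" off a plot.
Cross-lineage profiles concatenate each copy's two LTRs, skip lineages
with fewer than 25 full-length copies, subsample the largest lineage to
`n_sample` and the others proportionally to their copy totals, and
compare between-lineage distance distributions: a family expanded before
lineage divergence shows one shared mode (relative spread < 20%) across
all lineage pairs; a lineage-private family leaves no shared mode.

## Synthetic data

The generator builds a common ancestor chromosome per triad locus
(spacer / 2.5-kb promoter / gene), inserts ancestral-epoch TE copies
(promoter and spacer), then evolves three subgenome copies independently
for `divergence_time_years` (default 5×10⁶ yr) under an exact K2P
substitution process (κ = 2, rate μ = 1.3×10⁻⁸/site/yr, no indels — so
distances have closed-form expectations and the dating estimator's
assumptions hold). Within an element the two LTRs mutate independently,
so 5′/3′ divergence encodes total copy age; ancestral copies carry an
extra pre-divergence age uniform on [0, T/2], lineage copies an age
uniform on [0, T]. A fraction of deletable spacer segments is lost per
lineage (creating homo2 regions); lineage-epoch families insert into one
subgenome only (creating specific regions). Alignment blocks are emitted
from the known homologous coordinates — homology classification, not
alignment, is the unit under test — and the region-class truth applies
the same >400-bp run rule to per-base presence masks, an implementation
independent of the interval-arithmetic classifier.

A configured fraction of ancestral promoter TE copies becomes a relic: a
randomly chosen keeper subgenome retains the annotation; in the other
two, bases outside the motif-centered 60-bp window are hypermutated
(substitution probability 0.35/site), the annotation row is dropped, and
a dTE truth row is written. Relic triads are planted balanced for the
family's TF, reproducing the structure in which relics complete balanced
triads.

Peaks are emitted directly (no read simulation; peak calling is out of
scope): per (TF, triad), a planted pattern drawn from `balance_mixture`
is perturbed uniformly within a Euclidean disc of radius `noise_radius`
(default 0.15, inside the 0.204 recoverability bound) on the proportion
simplex, and per-subgenome densities are proportion × `total_signal`
(default 10) at a shared summit offset, so recovered proportions equal
planted ones exactly. TE-embedded peaks sit at motif centers with
lognormal densities; background peaks are confined to zones outside all
promoter windows so they cannot distort planted patterns. Expression is
TPM = 2 × (summed promoter density) × lognormal(0, 0.25) noise — the
monotone binding–expression coupling; the noise model is our choice, as
is lognormal DHS noise (×lognormal(0, 0.15)). Genes are all `+`-strand;
minus-strand TSS handling is exercised by the I/O unit tests.

What the generator does **not** emulate: indels and rearrangements,
copy-specific family substructure (all copies of a family descend from
one consensus), realistic karyotypes, read-level noise, and genuine
peak-calling artifacts. Passing tests therefore demonstrate algorithmic
correctness and calibrated recovery under the stated model, not
performance on real genomes, where alignment quality, annotation error
and family substructure dominate.

## Problem sizes and numerical choices

Default simulation size is 3 × 2 Mb subgenomes, 300 triads, 5 TFs — a
desk-scale stand-in for a 14-Gb genome; unit tests use 150–300 kb
configurations, and the distance-distribution analyses subsample (25–500
sequences) since all-vs-all alignment is quadratic. Determinism: every
stochastic step flows from one `numpy` Generator seed; sorted output
orders everywhere; KDE grids are fixed (512 points). Degenerate inputs:
empty peak files give empty lists; all-zero DHS triples, zero-length
background classes, saturated alignments and missing alignment
directions raise typed errors rather than silent zeros.
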