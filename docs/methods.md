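# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `amplihap`, in the order the pipeline runs them.

## Study design being emulated

The package targets amplicon resequencing of a self-pollinating diploid
grass: three gibberellin-pathway genes (a DELLA growth repressor, the
gibberellin receptor GID1 and the F-box protein GID2), each amplified as
overlapping 1.1–2.0 kb products covering the promoter and the complete
coding sequence, in 24 accessions with two plants per accession (48
plants). Because the species selfs, accessions are modelled as fully
homozygous: both plants of an accession carry the same haplotype of every
gene, and a single consensus sequence per plant suffices. Heterozygosity
is deliberately out of model; sites with intermediate allele balance at
the final polishing iteration are flagged in the iteration report as
possible contamination but still resolved to the majority base.

## Synthetic data generator

`synthetic_data.preset_study()` fixes three gene models (2,700, 2,400 and
2,094 bp; single-exon for the DELLA gene, two exons with an intron for the
other two) with promoter, exon and CDS annotations, and haplotype panels
of 7, 13 and 8 alleles. Panel frequencies are in units of 1/24 and encode
the observed frequency spectrum (most-common allele at 10/24, 6/24 and
8/24 respectively); coding differences are placed so that the panels yield
4, 2 and 2 protein isoforms, with the landmark variants at CDS position
1000 (Gly→Ser at residue 334), CDS position 926 (Gly→Ala at residue 309)
and CDS positions 470/473 (Glu157→Gly, Arg158→Gln). Promoter and intron
variants (SNS, short insertions/deletions up to 19 bp, and an 18 bp intron
deletion) differentiate synonymous alleles. All indel variants are placed
in contexts where their left-aligned representation is unique, so variant
enumeration is exact. The gene sequences themselves are random but fixed
by internal constant seeds: they are study inputs, not samples.

Genotypes are drawn by **quota allocation**: the number of accessions per
joint isoform combination follows the joint weights by largest-remainder
rounding, and allele identities within an isoform follow the panel
frequencies the same way; the run seed only permutes which accession
receives which genotype. The finite sample therefore realizes the intended
frequency tables and the structural zeros of the joint distribution
exactly — mirroring the fact that the observed tables *are* the study
condition — while remaining seed-deterministic. Combinations with zero
weight are never sampled.

Reads are 250 bp paired-end from ~500±50 bp fragments at 50× per amplicon.
Fragment start positions run past the amplicon ends and are clipped, so
terminal bases are covered (as they are for sheared PCR products); the
expected pair count per amplicon is `coverage · L / (2 · read_length)`.
Errors are i.i.d. substitutions at 1% per base; indel sequencing errors
are not modelled (short-read error profiles are substitution-dominated,
and this bounds the pileup caller's scope). The quality model draws Phred
scores from N(20, 3²) clipped to [2, 41]: a mean of Q20 makes the
Phred-implied error rate equal the injected 1%, so the QUAL statistic
below is calibrated. Plant heights are isoform mean + Gaussian noise; the
preset uses equal means (100 cm, SD 10), i.e. the no-association null.

What the generator does **not** emulate: PCR chimeras and primer dimers,
indel sequencing errors, quality miscalibration, coverage biases along the
amplicon beyond the end-clipping geometry, barcode cross-talk, and
within-accession heterozygosity. Passing end-to-end tests therefore shows
correctness of the pipeline's logic under a clean error model, not
robustness to every artifact of real libraries.

## Reconstruction

**Assembly.** A greedy overlap–layout–consensus assembler for
substitution-only reads: candidate suffix/prefix overlaps are proposed by
shared 16-mers in both orientations, verified gaplessly (minimum overlap
40 bp, minimum identity 0.9), and merged best-overlap-first under a
union-find of rigid read placements; contig bases are per-column
majorities. Assembly runs on a systematic ~15× subsample of the reads: the
draft only seeds polishing, which always uses the full read set.

**Layout and draft consensus.** Contigs are locally aligned to the
reference gene with affine gaps (match weight proportional to m = 40, gap
costs proportional to g = 1) in their better orientation; a contig is kept
if its alignment identity is ≥ p = 70% *and* covers at least half the
contig. Accepted alignments are projected into one reference-coordinate
MSA with explicit insertion columns. The consensus then removes the
reference row: per column, bases and (within a contig's extent) gaps vote;
the majority base wins, a gap majority deletes the column, a column
covered only by the discarded reference emits N, and ties resolve toward
the reference base. Tie and N policy are this package's declared choices.

**Polishing.** Up to 6 iterations of: seed-and-extend read mapping (exact
16-mer seeds vote for a diagonal; gapless verification; banded
edit-distance fallback around the seed diagonal; reads below 80% identity
dropped) → haploid pileup calling → filtering → right-to-left application
of the kept calls. The caller emits, per column, the top non-reference
base; maximal runs where a deletion is the plurality as one left-aligned
deletion; and recurring identical insertions. `QUAL` is
`-10·log10 P(X ≥ k)` for `X ~ Binomial(depth, e)` with
`e = 10^(-meanPhred/10)` taken from the read set, capped at 1000. `AB` is
alt support over spanning depth. Filtering keeps `QUAL > 20` (strict)
always and `AB > 25%` (strict) on the last two iterations only. With 50×
coverage and calibrated Q20 qualities, isolated error pile-ups
occasionally pass the QUAL gate in early iterations; they fail the AB gate
later and any applied one is reverted by the resulting high-AB
back-mutation — which is exactly the role of the late AB filter. If a
pre-AB iteration yields zero kept calls the loop fast-forwards to the
first AB-filtered iteration (mapping identical reads to an identical
reference reproduces the same empty call set, so the skipped rounds are
no-ops); early stop ends the loop after an AB-filtered iteration with zero
kept calls, making 6 iterations an upper bound.

## Typing

Finished sequences are globally aligned to the reference
(Needleman–Wunsch/Gotoh; match 2, mismatch −3, gap open −7, extend −2,
where a gap of length L costs `open + (L−1)·extend`). Adjacent substituted
columns merge into one MNS; substitutions separated by even one conserved
base stay separate. Gap runs become left-aligned InDels; the frameshift
flag applies the mod-3 rule only to InDels anchored inside the CDS, and
region assignment (promoter / exon-CDS / intron / UTR) uses the anchor
position. CDS extraction lifts the annotated spans through the alignment,
including insertions strictly interior to a span; a lifted CDS lacking the
start, the stop, frame, or containing N raises a flagged error with the
partial sequence attached. Translation uses the standard code; internal
stops appear as `*` in the protein (candidate loss of function, reported
rather than dropped).

Byte-identical sequences form one allele. Registry matches keep their
published names; novel alleles are named in descending frequency order,
either by the next lowercase letters or by integers continuing the
registry's numbering. Frequency ties break by first occurrence in the
sample input order. Both per-plant (n = 48) and per-accession (n = 24)
frequencies are reported: co-occurrence statistics count plants, while
table-style reports use accessions. Reported frequencies round half-up to
2 decimals; internal arithmetic keeps full precision.

Isoforms group alleles by identical protein and are lettered A, B, … by
summed member frequency, ties by first occurrence in the
descending-frequency allele catalog. Note one consequence: when two
isoforms tie exactly (the DELLA gene's two common isoforms at 11/24 each),
the letter assignment follows the catalog order and is not otherwise
meaningful; comparisons in the test-suite therefore match isoform
partitions, not letters. Amino-acid variant labels (`refAA`+position+`altAA`)
are called against a supplied external reference protein (the bread-wheat
homolog in the motivating study), not against the study's own most
frequent isoform.

## Statistics

Fisher's exact test uses the point-probability two-sided rule: with
margins fixed, the p-value sums the probabilities of all tables whose
probability is at most the observed table's (relative tie tolerance 1e-7),
computed in log space. The 2×2 case enumerates the one free cell; the r×c
generalization enumerates all tables with the observed margins (guarded to
totals ≤ 200). This rule reproduces the motivating study's three printed
p-values at 4-decimal rounding. Exact tests follow the study's restriction
convention: rare isoforms may be excluded from the tested table while the
full table is kept for reporting. No multiple-testing correction is
applied, matching the original analysis. One-way ANOVA is computed from
classical sums of squares with p from the F distribution; empty groups are
dropped.

## Phylogenetics

Entire gene sequences including promoters are analysed. Allele sets are
near-identical, so a star alignment through the most frequent allele
(each sequence globally aligned to it and projected into common columns)
is adequate; columns containing gaps or N in any row are then eliminated
before any likelihood computation. The substitution model is plain HKY85 —
empirical base frequencies (floored at 1e-6 and renormalized), a single
transition/transversion ratio κ, no rate heterogeneity — with the rate
matrix normalized to one expected substitution per unit branch length and
analytic transition probabilities (verified against the matrix
exponential). Likelihoods use Felsenstein pruning over compressed site
patterns. κ initializes from the pairwise transition/transversion count
ratio scaled by its κ = 1 expectation and is refined by bounded 1-D ML
optimization on log κ.

Tree search: ≤ 5 taxa, every unrooted topology is scored (15 topologies at
5 taxa); larger sets start from neighbor joining on pairwise ML distances
and hill-climb with nearest-neighbor interchanges until no rearrangement
improves the log-likelihood by more than 1e-6. Branch lengths are
optimized per edge by bounded Brent on the edge's conditional likelihood
(outside × transition × inside), swept to convergence. The exhaustive
cutoff at 5 taxa (a parameter) keeps 500-replicate bootstraps tractable;
the heuristic path is verified against the exhaustive path on 5-taxon
data. Bootstrap supports are percentages of column-resampled replicate
trees (each re-searched with the same protocol, base frequencies and κ
fixed to the original fit) containing each bipartition. Rooting places the
root at the midpoint of the edge separating a designated monophyletic
outgroup; a non-monophyletic outgroup is an error that names the smallest
containing clade. The preset provides ~3%-diverged homeolog sequences as
outgroups. The demo uses 100 bootstrap replicates per gene as its
desk-scale default; the `tree` and `run` commands default to 500.

## Numerical and degenerate-input choices

* Binomial tails via `scipy.stats.binom.sf`; QUAL capped at 1000;
  log-space hypergeometric sums via `gammaln`.
* Majority ties in assembly resolve to the lexicographically first base;
  consensus ties resolve toward the current reference.
* Overlapping variant calls are resolved by keeping the higher-QUAL call.
* Pairwise ML distances for identical sequences floor at 1e-8; NJ branch
  lengths clamp at ≥ 1e-9; branch-length optimization is bounded to
  [1e-9, 10] substitutions/site.
* All randomness flows from one run seed through named substreams
  (population, heights, per-plant reads keyed by CRC of plant and gene,
  bootstrap), so outputs and manifest hashes are reproducible.

## Problem sizes

The default test suite and the acceptance script run the full preset study
(144 plant–gene reconstructions per seed; three seeds in the recovery
test) and desk-scale phylogenies (≤ 14 taxa; tens of bootstrap replicates
in tests). These sizes are the package's reference configuration for
reproducible verification; all of them are parameters.

## Known limitations

* Haploid calling only; heterozygous or pooled samples are out of scope.
* The assembler assumes substitution-only read errors; indel-rich long
  reads would need a different overlap verifier.
* The r×c exact test is limited to small totals by design; restrict to
  2×2 for larger tables.
* Star alignment is inappropriate for deeply diverged sequence sets; it is
  chosen for allele sets at ≪ 5% divergence plus a close outgroup.
* Bootstrap supports on near-identical alleles are dominated by the few
  informative columns and should be read accordingly.
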