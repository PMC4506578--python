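# Methods

## Germline model and coordinates

All coordinates are 0-based half-open. A V segment carries the offset of its
Cys104 codon, a J segment the offset of its Phe/Trp118 codon; the CDR3 is
defined *exclusive* of both anchor codons but — matching how expressed δ1
junction peptides are conventionally written — includes the V-encoded
residues 105+ (junctions start `ALG…` for TRDV1) and the J-encoded residues
through 117 (`…KLI` for TRDJ1). Reverse primers are stored 5′→3′ as
synthesized and matched as their reverse complement on the plus strand.

The built-in reference is a synthetic scaffold sized for this assay: the
three real TRDD core sequences (`GAAATAGT`, `CCTTCCTAC`, `ACTGGGGGATACG`)
and the published chain/constant primer sequences are embedded in
invented-but-realistic V/J/C context. TRDJ1's head (`ACACCGATAAACTCATC` +
`TTT…`) is chosen to be consistent with the `…AYTDKLI` endings of the known
public junction peptides, and the constant-region geometry is calibrated so
a 51-nt junction yields a 183 bp Vδ1 fragment. All four J segments place 12
framework nucleotides after the anchor, so in-frame junctions always differ
by whole codons across J choices and the fragment ladder has period 3.
Allele-level nomenclature and gapped IMGT numbering of the full V region are
out of scope; users can load their own IMGT-derived FASTA/TSV reference.

## Annotation

Segment assignment is an affine-gap semi-global alignment (query = germline
segment aligned end-to-end; read free at both ends) with match +1,
mismatch −1, gap open −2, gap extend −1. Minimum accepted scores are 20 (V)
and 10 (J): amplicon primers guarantee high-identity flanks, so these only
reject garbage; the J threshold is lower because the J portion of the
amplicon is short. Two performance shortcuts never change results: (i) when
the invariant part of a segment (everything outside the junction-trimmed
region) occurs exactly once in a read, the alignment decomposes into that
exact core plus an anchored extension over the trimmed remainder; (ii) a
candidate whose score upper bound `m − 2·editDistance` (edlib, infix mode)
cannot reach the current best is skipped — every edit costs at least 2 score
units under this scoring, so the bound is sound. Ties break to the
lexicographically smaller segment id. Reads are scanned on the given strand
only; the amplicon protocol is strand-defined and the simulator emits
plus-strand reads.

D segments are reported when a germline run of ≥ `min_d_match` = 5 nt occurs
in the junction (greedy left-to-right, longest match first, each D at most
once). Five is the shortest length with acceptable random-hit probability
over a ~30 nt junction (expected hits ≈ 30·4⁻⁵·3 < 0.1); it is exposed as
configuration, and because real D and V sequences share short runs (the
TRDV1 tail `…TGGGG` overlaps TRDD3, and `TTCCT` of TRDD2 occurs inside one
known public junction), D calls should be read as *junction content under
this rule*, not as a certificate of which segments recombined. The
simulator's ground-truth `d_ids` therefore apply the same rule, keeping
truth and annotation keys consistent; the segments actually recombined are
retained separately as `d_used`.

A junction is productive iff its length is divisible by 3 and its
translation contains no stop. Frequencies downstream use productive,
successfully annotated reads as denominator — the analysis enumerates
expressed clonotypes.

## Clonotyping

The clonotype key is (V call, CDR3 residues 105–108 at the amino-acid
level, ordered D identities, J call). Keying criterion 1 on amino acids
rather than nucleotides follows from the observation that a single clonotype
spans thousands of distinct junction nucleotide sequences; the per-clonotype
nucleotide spectra are retained so a nucleotide-level re-keying is a one-flag
reanalysis. Dominance is strict (> 1 %), and the "percent of total" summary
is the summed read frequency of dominant clonotypes. The public matrix takes
the union of per-sample dominant keys; an entry is the key's true frequency
wherever the key occurs at all (0 only when absent), and rows/columns are
ordered by average-linkage hierarchical clustering on Euclidean distances
(the clustering defaults are a package choice; both are configurable).
Modal-CDR3 ties break lexicographically.

## Spectratyping

Fragment length = forward chain primer 5′ end through the last base of the
labelled reverse primer's plus-strand footprint, inclusive. Lengths are
integer bp (capillary sizing treated as exact; a ±1 bp binning tolerance for
real electropherograms would live in the readers, and absolute lengths are
validated only on synthetic data because instrument dye-offset conventions
vary). Peak areas are normalized within each (sample, chain); the matrix
builder unions observed lengths, fills absences with 0, renormalizes rows,
and clusters samples as above. The ladder QC flags lengths not congruent to
the modal residue class mod 3 together with their fraction mass.

## Primer derivation and screening

For a target CDR3 peptide, nucleotide encodings are ranked per sample by
read count (dense ranks, ties lexicographic); the primer is the encoding
that is rank 1 in the most samples, spanning the full CDR3 — exactly the
construction used for clone-specific forward primers in practice. An
outright tie is surfaced as an error for the caller to resolve. Screening is
a Hamming-window substring scan over junction sequences or reads
(`max_mismatch` = 0, `min_support` = 1 by default); how many mismatches a
wet-lab PCR would tolerate is unknowable, so exact matching is the stated
default, and the headline output is binary presence mirroring a
non-quantitative PCR readout.

## Flow statistics

Inputs are per-sample CD3⁺ subset percentages for two compartments (brain
infiltrate and paired blood), with CD69⁺ fractions expressed per subset.
Ratio summaries use the standard median and range. The Wilcoxon signed-rank
test drops zero differences, midranks ties, and computes the two-sided p by
exact enumeration of the 2ⁿ sign assignments whenever n ≤ 25 — implemented
as a dynamic program over doubled midranks, which are always integers, so
ties stay exact — and otherwise by the tie-corrected normal approximation
(no continuity correction). The correlation panel reports Pearson r with a
Fisher-z interval (variance 1/(n−3)) and a t-test p; Spearman's ρ is
computed alongside because which coefficient a given figure used is often
ambiguous, but Pearson is the default surface since a Fisher-style CI
implies it.

## The generator: what it emulates, and what it does not

The simulator provides everything patient data would: rearrangements,
multi-sample repertoires, reads, peak tables, flow tables. Junctional
diversity is the simplest standard model — per-junction-end geometric
trimming (`trim_geom_p` = 0.25, mean 3 nt) and Poisson-length insertions
(`n_ins_lambda` = 4) uniform over ACGT. J-head trims deeper than 8 nt are
resampled: they would erase the germline evidence the J aligner needs at its
score threshold, and they are correspondingly rare in expressed junctions.
Infeasible trims are resampled *per draw* rather than per rearrangement so
segment-usage statistics stay at their configured distributions. Background
clone sizes follow a power-law (rank-frequency slope −1/(α−1), α = 3), and
dominant clones are implanted at fixed frequencies: by default 3 public
clones carrying the known recurrent δ1 junction peptides (8/6/5 %, two
nucleotide encodings each at 0.7/0.3 — convergent recombination) plus 9
private dominants per sample, giving the characteristic "12 clonotypes
above 1 % summing to 79 %" per-sample shape. Reads are emitted pre-merged
(amplicons of ~180–210 bp fit inside a single 250 bp read, so overlap
merging contributes nothing); substitution errors are binomial per base,
with no indels or chimeras. Identical reads are deduplicated before
annotation, which is what makes error-free study-scale runs fast.

Default problem sizes are 14 samples, 2000 background clonotypes per sample
and 10⁵ reads per sample. Real specimens would show "several thousand"
clonotypes; 2000 preserves the analysis-relevant structure (a heavy dominant
layer over a long tail) at convenient cost, and no per-sample depth is
standard for this assay — 10⁵ is an order-of-magnitude-typical choice, not a
measured value. One integer seed drives everything through
`SeedSequence([seed, stage, index])` streams (0 shared clones, 1 per-sample
repertoires, 2 reads, 3 peaks, 4 flow), so fixtures are bit-reproducible.

The flow generator draws truncated normals (Gaussian copula for the CD69
pair) around compartment targets chosen so the *population* medians and
correlation equal the cohort statistics this package is designed to report:
BIL γδ 34 % of CD3⁺ (αβ:γδ median ≈ 1.9), PBMC γδ 11.05 % (ratio ≈ 7.7),
CD69⁺ medians 42 %/47 % after truncation, latent ρ = 0.96 giving sample
r ≈ 0.954 at n = 14. Percentages are percentages of gated CD3⁺ (CD69 per
subset); CD69 staining covers 14 of 20 samples, emulating markers measured
on a cohort subset.

What passing tests on these data do **not** show: robustness to indel
sequencing errors, chimeric reads, PCR amplification bias across the nested
cycles, capillary sizing offsets, allele-level germline variation, or
flow-compensation artifacts — none of which the generator models.

## Numerical and degenerate-input choices

Frequencies are exact rational read fractions; per-sample totals are checked
to 1e-9. Zero-area peak sets, all-zero paired differences, zero-variance
correlates, single-compartment flow tables and duplicate (sample,
compartment) rows are hard errors; a zero-denominator ratio excludes the
sample and reports it. The cohort report tolerates a degenerate CD69
correlation (e.g. noise-free synthetic input) by recording NaN rather than
failing. Clustering of a single row is the identity ordering.

## Known limitations

The annotator is a local, assay-scale stand-in for full junction-analysis
portals: no gapped V numbering, no allele calls, no somatic-hypermutation
handling, plus-strand only. D identification by substring evidence cannot
distinguish a genuine short D remnant from a convergent N-insertion, and its
sensitivity to `min_d_match` should be reported alongside results rather
than assumed. Read-level frequencies stand in for molecule-level clone sizes
(the protocol has no UMIs). The exact Wilcoxon enumeration is O(n·Σrank)
and is capped at n = 25 by design.
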