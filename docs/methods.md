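# Methods

`otugrad` reimplements a paired-amplicon survey analysis for brackish
salinity gradients: 16S (V3–V4, primers 341F/805R) and 18S (V4–V5,
primers 574*F/1132R) reads are turned into OTU tables, classified, and
analysed for beta/alpha-diversity trends along the gradient and for
chloroplast–nuclear linkage between the two markers. This note records
the models, the parameter choices that matter, and the places where the
design was genuinely open.

## Read preparation

Reads are Sanger Phred+33 FASTQ. Per pair: the primer is trimmed off
each 5' end under IUPAC degeneracy (anchored at position 0, zero
mismatches beyond degeneracy by default — no allowance is prescribed by
the protocol, and the parameter is exposed); a fixed tail (40 bases for
16S, 44 for 18S) is cut from the reverse read's 3' end; each read is
truncated at the first base whose Phred score falls below the profile's
threshold. "Cut at the first sub-threshold base" is the only
deterministic rule that guarantees every remaining base meets the
threshold.

16S pairs overlap and are merged: the overlap length maximizing the
number of matching bases is chosen by exhaustive search (implemented as
four per-base cross-correlations, so it is exact and cheap), ties going
to the longer overlap. A pair is rejected when the best overlap is
shorter than 100 bases, carries more than 3 mismatches, or merges to
fewer than 300 bases; each rejection carries a reason code
(`overlap` / `mismatches` / `length`) written to a TSV audit file. In
the overlap, conflicting bases resolve toward the higher Phred score
(forward wins ties) and the merged quality is the maximum of the two —
the protocol is silent here and this is common practice.

18S amplicons are too long for the pairs to overlap, so trimmed pairs
are concatenated as `fwd + revcomp(rev)` with the junction index (the
forward length) carried through clustering and classification. Whether
the reverse read should be reverse-complemented before joining is not
prescribed; the choice is isolated in `concatenate_pair` and the
classifier is agnostic to it because each half is aligned on both
strands.

Two preparation profiles feed the two clustering passes: Q >= 25 for
building centroids, Q >= 20 for the reads mapped back onto them. For
concatenated (18S) markers the pipeline uses Q >= 20 for *both* passes:
per-read quality truncation changes the forward length, which would move
the junction between passes and misalign centroid and mapping-pass
sequences position by position. (Constant-length trimming keeps the two
passes coordinate-compatible; this is a package design choice.)

## OTU construction

Identity between two sequences is the fraction of matching columns in a
semi-global (end-free) alignment: the shorter sequence is aligned as an
infix of the longer (edlib), so terminal length differences — mapping
reads are shorter than centroids by construction — cost nothing.
Identity is evaluated on the minimum-edit-distance path; at high
divergence this reads slightly above the per-position (Hamming)
identity because gapped paths explain clustered substitutions more
cheaply, which is the behaviour of alignment-based identity generally.

Centroid pass: exact dereplication, sort by total count (ties broken
lexicographically), then greedy first-fit clustering at 99% identity —
each unique joins the first centroid it matches at or above the
threshold, else founds a new OTU. First-fit against centroids in
abundance order (rather than best-fit) matches the documented behaviour
of the standard greedy clustering tools and is deterministic given the
sort. The pipeline drops singleton uniques before clustering
(`min_unique_size = 2`): the stringent pass exists to avoid artificial
OTUs, and sequencing-error variants would otherwise found thousands of
spurious singleton centroids. The library function defaults to keeping
everything so the behaviour is a visible, tested parameter.

Mapping pass: every read (dereplicated first, counts flowing through)
is assigned to the centroid of maximal identity if that identity is
>= 99%, ties toward the earlier (more abundant) centroid — the
tie-break is not prescribed and is recorded here as a package decision.
The scan is banded (edlib `k` set from the threshold) and stops early
when a read sits within edit distance 1 of a centroid: centroids are
mutually > 1% apart, so no later centroid can beat such a hit.
Assigned + unassigned counts equal the prepared read count per sample.

## Consensus taxonomy

Concatenated centroids are split at the junction; each half is aligned
to every reference on both strands. The aligner computes the end-free
(full-query) path and trims it to its best-scoring contiguous segment
(match +1, mismatch −2, gap column −2.5; maximum-sum over the path), so
hit length and identity behave like local-alignment statistics; hits
shorter than 90% of the query (250/210 columns at the native read
lengths) are dropped. Bit-scores use the Karlin–Altschul form
(λ·raw − ln K)/ln 2 with λ = 1.28, K = 0.46; only ratios to the best
sum enter the decision rule, so the constants are configurable and
non-critical.

Candidates are references hit by both halves. Paired identity is
min(forward, reverse) — the conservative reading; the mean would be the
alternative and the combination lives behind one function. Per-rank
identity cutoffs (defaults 90% for kingdom..family, 97% genus, 99%
species; "meets the cutoff" is inclusive, since the cutoffs are round
percentages applied to discretized identities) give each candidate an
allowed depth; candidates failing even the kingdom cutoff are dropped.
A single surviving candidate donates its lineage truncated to its
allowed depth. With several, candidates within 95% of the best summed
bit-score are retained and the lineage is the deepest rank at which all
retained candidates agree, truncated to the overall allowed depth.
Merged (16S) centroids follow the same rules with single-sequence
identities.

A property worth knowing: raising cutoffs at ranks 2–8 can only shallow
an assignment (the candidate set is fixed and both the allowed depth
and the consensus can only shrink), and the test suite asserts this.
Raising the *kingdom* cutoff, however, can eject a conflicting
low-identity candidate from the candidate set entirely and thereby
deepen the consensus — consensus classifiers are inherently
non-monotone in their admission threshold.

Manual overrides (curated lineages for OTUs of special interest) only
replace the automatic call when both coverage and identity exceed 99%;
every application is logged.

## Cutoff calibration

`calibration` holds out n references, excises an error-free read pair
from each at the primer coordinates, classifies them against the
remaining references over a grid of cutoff schemes (default flat
schemes at 0.80/0.85/0.90/0.95/0.97/0.99; alignments are computed once
and shared), and reports per rank: sensitivity (fraction of test reads
assigned at that depth or deeper) and precision (fraction of those
whose name at the rank matches the truth; undefined — NaN, distinct
from 0 — when nothing reaches the rank). "Correct" means rank-name
equality given assignment at the depth; correctness of the full 8-rank
string would be the stricter alternative. `select_cutoffs` takes per
rank the lowest cutoff whose precision meets a floor and forces the
scheme monotone non-decreasing.

## Community statistics

Beta-diversity: d(i,j) = 1 − Spearman ρ between the samples' OTU
frequency vectors (mid-ranked ties), range [0, 2]; the additive
constant does not affect the ordination's ordering of samples. PCoA is
classical scaling (double-centering of −D²/2, `eigh`), positive
eigenvalues only, axes sign-fixed so the first nonzero coordinate is
positive, variance explained relative to the positive-eigenvalue total.
The PC1–salinity association is Spearman's ρ with a seeded two-sided
permutation p-value; the Mantel test is Spearman over the lower
triangles with label permutations of the second matrix (one-sided).
Hierarchical clustering is average linkage (unstated in the source
protocol; exposed as a flag), exported as newick. All permutation
p-values here use (count + 1)/(N + 1) so p is never zero; the
chloroplast shuffle test below deliberately uses p = n/N instead, as
that is how that statistic is defined.

Alpha-diversity: seeded subsampling without replacement to a common
depth (the minimum per-sample total per marker), 1000 repetitions by
default; observed richness and Shannon–Wiener H = −Σ p ln p (natural
log, the ecology-toolkit convention). Per-phylum variants restrict to
one phylum (PR2 division, level 3), drop samples with fewer than 1000
reads of it, and subsample to the minimum remaining total, so the
phylum's relative abundance does not bias its diversity. Samples in
the horohalinicum (salinity 5–8, inclusive bounds) are contrasted
against the rest with two-sided exact Wilcoxon rank-sum tests,
Benjamini–Hochberg adjusted across phyla within each metric (the
adjustment family is a package choice).

## Cross-marker linking

All 16S OTUs are Spearman-correlated against all 18S OTUs on relative
abundances; pairs with ρ >= 0.8 are kept (zero-variance OTUs skipped
with a log note). Among pairs whose 16S OTU is flagged chloroplast
(lineage contains "Chloroplast"), a match is an identical class-level
(PR2 level 4) name on both sides; pairs missing either class are not
evaluable. The shuffle test permutes the class labels over the distinct
correlated 18S OTUs (default: the annotated ones; shuffling over all
correlated OTUs is available), recounts matches per shuffle, and
reports p = n/N with N = 10^6 by default. An exact enumeration over
all distinct label arrangements (each equally likely under a uniform
permutation of the multiset) serves as the oracle for populations of up
to ten OTUs. The "population = the ρ >= 0.8 pair set" reading of
"significantly correlated" is an interpretation and is switchable.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
at desk scale, from one seed (all outputs byte-identical per seed).

*Reference*: a root amplicon (primer site + core + primer site; primer
sites stay unmutated so reads can be excised at them) is mutated down
an 8-rank tree. Per-rank identity targets (defaults 0.75, 0.79, 0.83,
0.87, 0.91, 0.945, 0.975, 0.995 from kingdom to species) specify the
expected whole-amplicon identity of two leaves whose deepest shared
rank is r; per-edge mutation counts are derived by inverting the
collision-corrected expectation p = 2f − (4/3)f² and rescaling for the
conserved flanks, with positions drawn without replacement along each
root-to-leaf path. Realized mean identities land within ±1% of the
targets. The within-genus target 0.975 puts sibling species safely
apart at 99% clustering while still below the species cutoff — the
regime in which the consensus classifier's genus/species distinction is
actually exercised.

*Communities*: 21 stations evenly spaced over salinity 2–30. Each
taxon gets a Gaussian niche response (optimum uniform over the range;
tolerance lognormal around 6 salinity units; lognormal baseline) times
lognormal station-level noise (σ = 0.8): without overdispersion, any
two taxa with nearby optima correlate at ρ ≈ 1 and cross-marker pair
extraction degenerates; real plankton counts carry large residual
variance. Lognormal rRNA copy-number multipliers (σ = 0.5) bias read
counts but not the truth matrix, keeping the distinction testable; a
"metazoan spike" option multiplies a few taxa heavily.

*Linked markers*: a configurable fraction (default 0.5) of eukaryotic
taxa each contribute a chloroplast 16S taxon whose abundance profile is
a fixed multiple of the host's realized (noisy) 18S profile and whose
class-level annotation is the host's class — mirroring how plastid 16S
sequences classify to their host lineage. Chloroplast taxa total ~5% of
the 16S community. A `scramble` option decouples chosen chloroplast
taxa (independent profile, host-class annotation kept) to emulate
coincidental correlation.

*Reads*: multinomial per station over abundance × copy number; reads
are the amplicon's first/last 300 bases; substitution errors are drawn
per base from a linearly ramping quality profile (Q 36 → 24) rescaled
so the mean per-base error rate equals the configured 0.001, with
Phred scores consistent with the rates used. The 16S geometry (core
390) leaves a >100-base overlap after trimming (mergeable); the 18S
geometry (core 560) leaves an inner gap (concatenation only).

## Problem sizes and determinism

The default survey is 21 stations × 5×10^4 pairs per sample and marker
(~2.1M read pairs end to end), the scale at which the full-pipeline
tests and the acceptance script run; the per-module test fixtures use
hundreds to thousands of reads. Every randomized stage draws from
generators spawned off a single seed (`SeedSequence` children per
marker/sample/stage), so a fixed configuration reproduces its output
bundle exactly; run logs record parameters only, never timings.

## What passing tests do and do not show

The synthetic survey has equal-depth samples, substitution-only errors,
length-invariant amplicons, no chimeras (the pipeline deliberately does
no chimera detection) and a balanced reference covering every taxon.
Passing the end-to-end checks therefore demonstrates that the
algorithms recover structure they are designed for — smooth
compositional turnover, linked markers, rank-dependent classification
depth — not that real surveys, with uneven depth, indels, chimeras and
incomplete references, would behave as cleanly. Quantities that depend
on a specific reference snapshot (absolute OTU counts, realized
precision/sensitivity at each rank) are properties of the synthetic
conditions, not predictions for any real data set.
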