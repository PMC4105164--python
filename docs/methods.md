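# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `plastcomp`. It is written for a reader who wants to know
exactly what each number the pipeline reports means and what the synthetic
tests do and do not demonstrate.

## Coordinate and orientation conventions

All coordinates are 0-based, half-open, on the forward strand. GenBank's
1-based closed locations are converted at the parsing boundary. Features that
wrap the circular origin are stored as two intervals. The canonical
orientation of a plastome places the first LSC base at position 0 with the
order LSC, IRb, SSC, IRa along the forward strand; of the two strand choices
satisfying that order, the lexicographically smaller sequence is taken, which
makes the canonical form invariant to how the input was rotated or
strand-flipped.

## Quadripartite detection

The inverted repeat is defined as the maximal-length pair of disjoint,
exactly reverse-complementary segments on the circle, subject to a minimum
length `min_ir` (default 10 kb — long enough to exclude dispersed repeats,
comfortably below the ~26 kb IRs of real plastomes). Candidates are found by
exact 25-mer matching between the doubled sequence and its reverse
complement, grouping matches by diagonal, and extending each seeded run
maximally by direct comparison. Because the matches are exact, the procedure
is deterministic and equals a brute-force all-diagonal scan (verified in the
tests on toy genomes). Mismatch-tolerant IR detection is out of scope: the
IR copies of the genomes this pipeline targets are identical by concerted
evolution, and the synthetic generator enforces the same.

Junction coordinates name the first base of the downstream region (JLB =
first base of IRb, and so on). Gene-to-junction distances are the minimal
circular distance from the nearer gene end, negative when the gene span
covers the junction; the convention is recorded in the junction-report
metadata because published border figures do not state which side of the
junction they measure from.

## Dispersed repeats

A hit is a pair of disjoint copies, each at least `min_len` bp (default 30),
whose Hamming distance after transforming the second copy is at most
`min(max_mismatch, length // 10)` — both printed REPuter-style constraints
(an absolute cap of 3 mismatches and ≥90 % identity) hold simultaneously.
Direct copies are untransformed, palindromic copies reverse-complemented,
reverse copies reversed without complementation. A hit is *maximal* when
extending either end by one base violates the mismatch budget; hits whose
copies overlap are discarded (tandem arrays are SSR territory), hits longer
than `max_len` (default 5 kb) are discarded (this excludes the genome-scale
IR pair), and hits contained in a longer reported hit of the same type are
suppressed.

Candidates are generated from exact seed matches. The seed length is derived
as `(min_len − mm) // (mm + 1)` with `mm = min(max_mismatch, min_len // 10)`
and capped at 12 — by pigeonhole, every valid hit contains an exact run at
least that long, so seeding is lossless. (A fixed 12-bp seed would not be:
a 30-bp hit with three evenly spaced mismatches has no exact run longer
than 8.) Along each seeded diagonal the local mismatch profile is explored
out to `max_mismatch + 1` mismatches on each side and every window flanked
by mismatches or sequence ends is tested for validity and maximality. The
test suite proves equality with an exhaustive all-window scan on sequences
up to 2 kb.

One consequence of mismatch-tolerant maximality worth knowing: a perfect
29-bp duplication *can* surface inside a longer valid window once flanking
near-matches are absorbed (29 matches in a 31-bp window is 93 % identity).
The sharp "30 bp found / 29 bp never" threshold therefore holds exactly when
the mismatch budget is zero, and the tests assert it in that regime with
flank-guarded plants.

Repeat analysis runs on the genome with one IR copy removed (LSC+IRb+SSC in
canonical orientation), as is standard, to avoid counting everything in the
IR twice. Shared-repeat accounting across genomes keys each hit by (type,
length, ordered pair of homologous region names): present in all genomes →
shared; in exactly one → unique.

## SSRs

Only perfect tandem runs are reported, at the conventional chloroplast
thresholds: ≥10 units for mononucleotide motifs, ≥6 di-, ≥5 tri-, ≥4 tetra-,
≥3 penta- and hexanucleotide. A run is reported only at its primitive
(smallest) period and trimmed to whole units; reported loci never overlap
(longer locus wins, then smaller unit, then position). The scan wraps the
circular origin. Motifs are named strand-independently as `REP/REVCOMP(REP)`
with REP the lexicographically smallest rotation over both strands; the
tests verify this is constant on every rotation/reverse-complement class of
all 1–6 bp motifs exhaustively. Compound or interrupted SSRs are reported as
separate simple loci, and imperfect repeats are not detected — the summary
table tallies simple perfect motifs only.

## Pairwise alignment and event counting

The internal aligner is a vectorised Gotoh global alignment with affine gap
costs (match +2, mismatch −3, gap open −8 charged on the first gapped base,
extend −1 per additional base). The horizontal-gap state is resolved with a
prefix-max identity so each DP row is pure numpy; traceback matrices cap the
practical input at 20 kb, which is why whole genomes are compared
region-wise (see below). Optimality is tested against exhaustive enumeration
of all affine-gap alignments of short random pairs.

Event counting defines one *indel event* as one maximal run of gap columns
with a constant gapped-row pattern — a 7-bp gap is one event, and in a
multi-row alignment a gap block shared identically by several rows counts
once (an indel inherited by descent is one mutation). Terminal gap runs are
excluded by default since region boundaries, not mutations, usually cause
them. Substitution columns are typed by unordered base pair; columns with N
are excluded from substitution counting but remain in the aligned length L.
The S/I ratio is NS/ID, reported to two decimals; the per-region variability
statistic is (NS + ID)/L × 100. Rounding happens only at the reporting
layer.

Whole-genome pairwise counts are computed by annotation-guided region-wise
alignment and summation: homologous regions are matched by name (gene,
intron and spacer names are conserved in the genomes this targets), aligned
individually, and the counts summed. An import path for externally produced
whole-genome alignments (aligned FASTA) exists for parity work. Pairs of
sequences are canonicalised (sorted) before alignment so divergence(a,b) =
divergence(b,a) exactly.

Multiple alignments of three or more region sequences are delegated to
MAFFT, the standard tool for the task; two sequences use the internal
aligner.

## Marker screen and partition ratios

The hotspot screen computes the variability statistic for every region
shared by all genomes and keeps non-coding regions strictly above a fixed
1.5 % threshold, ranked descending. No multiple-testing correction is
applied: the threshold is a fixed descriptive screen, not a test. Divergence
ratios between compartments (CDS : intron : IGS, and IR : LSC : SSC) are
computed per partner genome as pooled (NS+ID)/L over the compartment's
regions, averaged over partners, normalised to the first compartment, and
reported to one decimal.

## Indel characters and Fitch mapping

Each distinct gap block in a region alignment becomes a binary
presence/absence character; a character is flagged informative when the gap
is present in ≥2 and absent in ≥2 taxa. Characters are mapped onto a
user-supplied newick tree (tree inference is out of scope) rooted at a
designated outgroup. The minimum change count is standard Fitch parsimony
with missing states as wildcards — tested against the exhaustive minimum
over all ancestral assignments on trees up to 8 taxa. One most-parsimonious
reconstruction is reported, with ties broken toward changes near the root
(accelerated transformation) and the root held to the outgroup state when
that costs nothing. Classes follow the minimum-change rule: one change on an
internal branch is a synapomorphy, on a terminal branch an autapomorphy, two
or more changes a homoplasy. Polarity is read off the reconstruction:
gaining the gap relative to the ancestral state is a deletion ('−'), losing
it an insertion ('+'), ambiguous ancestors '±'. Published synapomorphy
counts that additionally filter on bootstrap support are a stricter notion;
this package reports the pure parsimony classes and leaves support
filtering to the user.

## The synthetic plastome generator

The generator is first-class, tested code: it is how every stage of the
pipeline is validated without downloads.

**Ancestor.** Defaults build a ~157 kb circle (LSC 86,600, SSC 18,280, IR
26,090 bp) at GC 0.373 with IRa constructed as the exact reverse complement
of IRb. The annotation plan places real plastid gene names at ~55 % gene
density per partition: LSC protein and tRNA genes interleaved, an IR gene
set duplicated with mirrored coordinates, SSC genes, intron-bearing genes
(including two two-intron genes), the psbD/psbC 52-bp and atpB/atpE 3-bp
overlapping pairs, and a ycf1 analog that starts in the SSC and runs
1,068 bp into IRa. Planted features are scaled proportionally for smaller
configs. SSR loci (A/T mononucleotides at 10–14 units, hexanucleotide
AAAAAG-type at 3 units) and dispersed repeats (30–60 bp, 0–2 mismatches, all
three types) are planted in intergenic space with guard bases so each
planted locus is exactly maximal.

Two honesty constraints make truth tables exact. Background sequence caps
homopolymer runs below the mononucleotide SSR threshold (a 157 kb genome at
37 % GC would otherwise contain ~1–2 accidental poly-A loci); accidental
higher-period SSRs and accidental ≥30 bp dispersed repeats have expected
counts ≪ 1 at these sizes (binomial tail estimates: ~10⁻² to 10⁻³ per
genome) and are additionally excluded by guard bases around plants. Junction
guard bases prevent the maximal IR match from extending past the planted
boundaries by a chance complementary flank.

**Evolution.** Tips evolve along a user newick tree. Substitutions follow a
single-parameter transition bias (κ = 2) at per-site rate = branch length ×
region multiplier ({IR 1, LSC 3, SSC 3} — the IR evolves more slowly, as
observed in real plastomes). Indel events occur at 1/3 the substitution
rate (so the planted S/I is 3, inside the published 2.67–5.00 range), with
lengths from a mixture dominated by 1-bp and then 5–6-bp events
({1: 0.45, 2: 0.08, 3–4: 0.10, 5–6: 0.22, 7–10: 0.10, >10: 0.05} — a
qualitative match to the published spectrum shape, not a fitted
distribution). Insertions copy the adjacent upstream sequence with
probability 0.8, reflecting the adjacent-duplication origin of most real
plastome insertions. Planted SSR loci mutate only by slippage (±1 unit at a
small per-locus rate); other indels are rejected off SSR spans. With
concerted evolution on (default), every IRb mutation is mirrored into IRa
(complemented, coordinate-mirrored), so IRa = revcomp(IRb) holds at every
tip; annotations and region boundaries are lifted over through every indel.
Every event is recorded with its position at application time, so replaying
the truth table against the ancestor reproduces each tip byte-for-byte —
an invariant the tests assert.

**What the generator does not emulate.** Codon structure and selection
(regions are neutral background), base-composition heterogeneity along the
genome, IR expansion/contraction (boundaries move only by local indels),
rearrangements and inversions, and sequencing error. Passing tests
demonstrate the *detectors and statistics* are correct on data with the
assumed structure; they do not validate biological conclusions about any
real genome.

## Statistical choices in validation

Parameter-recovery tests simulate 50 replicate pairs at divergence matching
the regime real congeneric plastome comparisons occupy (tens of events per
pair; indels kilobases apart). Two effects matter at other settings and are
worth documenting. First, at event densities an order of magnitude higher,
the affine aligner merges neighbouring gaps into single events and S/I is
systematically overestimated (several percent at one indel per ~200 bp) —
the indel-underestimation-with-divergence effect known from real distant
comparisons; region-wise S/I values from this pipeline inherit it. Second,
the mean of per-replicate NS/ID ratios is upward-biased when ID is small
(Jensen's inequality, roughly ×(1 + 1/ID)), so recovery is assessed on
pooled counts with a Poisson delta-method confidence interval on the log
ratio.

Problem sizes used by the test suite are chosen to keep each oracle
exhaustive: 200 synthetic genomes of 5–160 kb for structure detection,
≤2 kb sequences for the all-window repeat oracle, all 5,460 motifs for the
SSR canonical form, ≤8-bp pairs for alignment enumeration, 1,000
character×tree cases at ≤8 taxa for Fitch, and 50 replicate pairs at ~12 kb
for rate recovery. The acceptance script runs the full pipeline at the
generator's full ~157 kb defaults.

## Known limitations

- IR detection requires exact copies; a genome with diverged IRs raises
  "no quadripartite structure" rather than guessing.
- Region-wise whole-genome counts depend on annotation-name homology; genes
  renamed or missing in one genome drop out of the comparison.
- Exact REPuter output-count parity is a validation goal, not a guarantee:
  maximality semantics match, but tie handling in third-party tools is not
  specified.
- The marker screen reports descriptive variability; it makes no claim of
  statistical significance.
- Junction distances for genes wrapping the origin use the merged gene span
  and can be misleading; in canonical orientation no annotated gene wraps.
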