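# Methods

## Repeat catalog

All coordinates are 0-based half-open; the gap between consecutive repeats
is `next.start − prev.end`, so immediately adjacent elements have gap 0 and
"at most 300 nucleotides apart" is an inclusive threshold. Clustering is
single-linkage chaining along each chromosome: consecutive elements join one
cluster iff their gap is ≤ `max_gap` (default 300 nt, the Alu length
scale). Overlapping RepeatMasker records — occasionally emitted as
fragmented hits of one insertion — are treated as gap 0 and therefore always
merged, never split.

Orientation classes are defined for clusters of exactly two elements, read
in genomic order: same strand → dSINE (tandem); (+,−) → tiSINE, because the
3′ ends of the two elements point toward each other (tail-to-tail); (−,+) →
hiSINE (head-to-head). Clusters of three or more count toward the clustered
fraction but get no orientation class: with more than one neighbor the
pairwise geometry is ambiguous, so pair statistics are restricted to
elements with exactly one partner within the threshold. All fractions in
`CatalogSummary` are proportions of the total element count, which makes
them additive: dSINE + iSINE = in-pairs, hiSINE + tiSINE = iSINE.

Two neighbor-gap statistics have genuinely open definitions, and both
readings are implemented. The median neighbor gap is the median of
consecutive same-chromosome gaps (overlaps clamped to 0). The "fraction
within the median" defaults to counting *elements* whose nearest-neighbor
gap is at most that median — the only reading that can exceed 50 % and
therefore carry information; counting *gaps* (trivially ≈ 50 %) is available
via `within_stat="gaps"` for comparison.

A useful pair of symmetries, both enforced by tests: flipping every strand
(or, equivalently, mirroring all coordinates) swaps hiSINE ↔ tiSINE and
leaves tandem pairs and cluster structure unchanged, while doing both at
once — the reverse-complement view of the genome — preserves every class,
since head-to-head and tail-to-tail are geometric notions independent of
which strand the genome is read from.

## Genome partition and Aluome enrichment

Gene models come from GENCODE-style GTF restricted to Pol II gene types
(the 22-type allow-list from protein_coding through antisense; configurable).
UTR features are split into 5′/3′ by position relative to the CDS span and
strand; when absent they are derived as exons minus CDS. `stop_codon`
features are folded into the CDS.

Projection is hierarchical and strand-blind (partitions describe genomic
territory): a base is genic iff covered by any gene span and exonic iff
covered by any exon of any isoform. Within the exonic territory,
conflicting isoform claims are resolved by the precedence coding > utr5 >
utr3 > noncoding — CDS being the most specific claim — and the order is a
configurable argument because no canonical choice exists for, e.g., a base
that is coding in one isoform and 3′UTR in another.

The Aluome is the merged union of Alu intervals; its nucleotides are
apportioned to labels by exact base-wise intersection, so an element
straddling a boundary contributes pro rata rather than whole-element by
midpoint. Fractions are normalized within each level to the level's parent
territory (level 1: genome; level 2: genic; level 3: exonic), which makes
genome and Aluome fractions each sum to 1 per level; enrichment is their
ratio. Cluster-level genic/intergenic stratification, by contrast, assigns
each *cluster* once, by the label at its span midpoint, since a cluster is
the unit of the configuration statistics.

## Transcript configurations

Only Alus fully contained within a single exon are considered: anything
straddling a splice site does not survive in the mature mRNA as an intact
element. Contained elements are mapped through the spliced exon chain
(cumulative exon offsets; reversed for minus-strand genes) and ordered
5′→3′ along the transcript; relative orientation is sense iff repeat strand
equals gene strand. Adjacent pairs in transcript order are tandem (equal
orientations), tail_tail (sense, antisense — the elements' 3′ ends face) or
head_head (antisense, sense). Transcript categories: noSINE (0 elements),
single (1), tandem (≥2, all adjacent pairs tandem), iAlu (≥1 inverted
adjacent pair); head_head/tail_tail are sub-labels of iAlu used when every
adjacent pair agrees. Unlike genomic clustering, transcript-level neighbors
have no distance bound — within one mature RNA any inverted pair can
base-pair. Categories are per transcript (expression data are per
transcript), not per gene; the tandem class requires ≥2 elements since
single-element transcripts are classed separately.

## Expression analysis

Transcripts are kept when FPKM ≥ 3 (inclusive) in every cell line — a
robust-expression filter, not a normalization. Pools contain one
observation per surviving transcript per cell line, so a category's n
counts transcript × cell-line occurrences; the "all" pool is the union of
surviving transcripts. Means are reported on the raw FPKM scale (a log
transform would change means but not rank-sum p-values).

Pairwise comparisons use the Wilcoxon rank-sum / Mann–Whitney test via
`scipy.stats.mannwhitneyu`: exact null enumeration when both pools have
n ≤ 25 and the pooled data are tie-free, otherwise the normal approximation
with midrank tie correction and continuity correction. The reported
statistic is the rank sum of the first group; the one-sided alternative
defaults to "first group lower", matching the directional question of
whether inverted-configuration transcripts are repressed. No
multiple-testing correction is applied across the category grid by default
(raw p-values are reported); a Bonferroni option exists.

Calibration, checked by the acceptance suite: under the null
(repression factor 1) the rejection rate at α = 0.05 over 1000 simulated
cohorts stays within 0.05 ± 0.02, and a planted 0.6-fold repression with
200 transcripts per group across 15 cell lines is detected at p < 0.01 in
≥ 95 of 100 cohorts.

## Analog design

A design template splits a UTR into spacer segments (kept byte-identical)
and designable segments (replaced). The target is the template's own fold:
MFE structure, MFE, and EFE = −kT ln Z. The search is seeded stochastic
hill-climbing: designable positions are filled uniformly at random, then
mutated one nucleotide at a time; a mutation is kept when the pair
(base-pair distance of the current MFE structure to the target, |ΔMFE|)
does not get lexicographically worse; 150 steps without improvement, or a
recorded structure match, trigger a random restart. A sequence is accepted
when its MFE structure equals the target exactly, |ΔMFE| and |ΔEFE| are
within ±0.5 kcal/mol each (one thermodynamic-parameter quantum; "identical"
energies across different sequences are unattainable), and its global
alignment identity to the replaced content is ≤ 0.6. Identity is computed
over the concatenated designable segments only — spacers are identical by
construction and would dilute the measure — with unit match/mismatch/gap
scoring (matches / alignment columns). Accepted candidates are ranked by
`gc_weight·|ΔGC| + bpp_weight·bpp_distance` (both weights default 1), where
bpp_distance is the Frobenius norm of the upper-triangular difference of
base-pair probability matrices divided by sequence length.

Folding engines are pluggable behind one contract. Production uses the
ViennaRNA bindings (Turner parameters, kcal/mol). The test engine is a
base-pair maximization model — energy −1 per canonical pair (AU, GC, GU),
kT = 1, minimum hairpin loop 3 — with MFE from the Nussinov recursion
(deterministic traceback: ties leave the 3′ base unpaired, then take the
5′-most partner) and Z/EFE/bpp from an exact inside–outside computation on
the same model. Everything the toy engine emits is re-derivable by
exhaustively enumerating structures, which the test suite does
independently for sequences up to ~14 nt; design runs against it are
therefore fully oracle-checkable. The toy engine is a test instrument, not
a thermodynamic model: its EFE lies far below its MFE because every pair
contributes the same weight, and its structure predictions should not be
interpreted biologically.

## Synthetic data

The generators plant known structure and return truth tables alongside.
Repeat units (singles, tandem/inverted pairs, ≥3-clusters) use 300-nt
elements, within-cluster gaps drawn from [20, 300] (at or below the
clustering threshold) and inter-unit separations of at least 1000 nt
(strictly above it), so the planted labels are unambiguous and recovery
must be exact, not approximate — parameter validation rejects any setting
that breaks this. Gene models get a 220-nt first exon (120 nt 5′UTR),
150-nt internal CDS exons, a terminal exon with 100 nt CDS plus a 1.5–2.5-kb
3′UTR (long enough to host planted configurations), introns of 400–900 nt,
alternating strands, and one exon-skipping second isoform to exercise
hierarchical projection. FPKM values are log-normal — exp(N(3.0, 0.8)) per
transcript per cell line, putting the bulk of values above the 3-FPKM
cutoff — with the expectation of inverted-category transcripts multiplied
by a repression factor (default 0.6, the scale of the repression the
expression analysis is meant to detect). The default cell-line panel is the
15 ENCODE lines the expression stage emulates.

What the simulations do not emulate: real Alu sequence content (only
coordinates and strands are generated — sufficient for every genomic and
transcript stage), read-level noise or FPKM estimation error beyond the
log-normal surrogate, correlated expression across cell lines, overlapping
genes beyond the single isoform case, and chromosome-scale heterogeneity of
repeat density. Passing tests therefore demonstrate correctness of the
algorithms under clean planted conditions, not robustness to every artifact
of real annotation tracks.

## Numerical and degenerate-input conventions

Empty catalogs report NaN fractions rather than dividing by zero. Features
extending past chromosome ends are clipped with a warning; Alus on
chromosomes absent from a partition are skipped with a warning. A cluster
straddling a genic/intergenic boundary is assigned once, by midpoint, and
logged. Empty expression pools are an error for testing but merely dropped
from the pairwise grid. Design searches that exhaust their budget return an
empty list with a logged diagnostic instead of raising. All generators and
the design loop are deterministic given their seed; written outputs are
byte-identical across runs.

## Problem sizes

Default test and acceptance runs use 2–3 chromosomes of 10 kb–500 kb,
~85–115 planted repeats, ≤ 12 genes, 1000 null cohorts of 25 transcripts ×
5 cell lines and 100 effect cohorts of 200 transcripts × 15 cell lines, and
16-nt design templates with 2500-step search budgets — sizes chosen so the
per-nucleotide and enumeration oracles stay exact while each stage still
exercises its full code path.
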