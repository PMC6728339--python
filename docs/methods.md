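# Methods

## Coordinates and the data model

All features live in 0-based half-open intervals on the forward strand;
conversion from GenBank (1-based inclusive) and GFF3 happens only at the
I/O boundary. A gene's "five-prime" coordinate is the genome position of
the first base of its start codon (`start` on the plus strand, `end − 1` on
the minus strand), which makes the distance and window arithmetic
strand-symmetric. Genes spanning the origin of circular contigs cannot be
represented in this scheme and are dropped with a warning; the synthetic
generator keeps a spacer at the origin so the situation never arises in
generated data.

## Intergenic distances and classes

The signed distance runs from the upstream stop codon to the downstream
start codon in translation order: `down.start − up.end` on the plus strand,
`up.start − down.end` on the minus strand. ATGA-type shared codons give −4,
TGATG-type give −1, direct adjacency gives 0. Classes: `overlapping`
(d < 0), `close10` (0 ≤ d ≤ 9), `medium50` (10 ≤ d ≤ 50), and for d > 50
`lead` when a gene on the opposite strand has its start coordinate strictly
inside the gap, else `far`. Distance 0 is grouped with the short gaps
(`close10`): adjacency behaves like a minimal-gap junction for
reinitiation, and the class bounds would otherwise leave it unassigned.
Nested genes (downstream entirely inside the upstream) are classified
`overlapping` with the distance as computed; no special case.

Pairing is nearest-neighbor per strand: each CDS is paired with the closest
same-strand CDS downstream of it in translation order, so opposite-strand
genes in between do not break a pair, every gene is the downstream partner
of at most one pair, and pairs are not formed across the origin.

"Leading genes" — where initiation must be de novo — are a separate set
from the `lead` distance class: a gene is leading when its nearest
co-directional upstream gene ends at least `leading_gene_min_gap`
(default 200 nt) before its start. On circular contigs the distance wraps;
on linear contigs a gene with no upstream partner qualifies. Both notions
are kept because they answer different questions (a distance label for
pairs versus a control set for SD statistics), and the thresholds differ
(50 versus 200 nt).

## The hybridization energy model

SD presence is scored as the minimum free energy of an RNA:RNA duplex
between the 12-nt window immediately 5′ of the start codon (strictly
positions −12…−1; pairing never extends into the start codon) and the
anti-SD. The model is deliberately minimal: contiguous helices only, no
bulges, internal loops or dangling ends. The energy of a helix of `L ≥ 2`
pairs is

    ΔG = ΔG_init + Σ stacks + terminal penalties

with Watson–Crick stacking parameters of Xia et al. (1998), GU wobble
stacks of Mathews et al. (1999), ΔG_init = +4.09 kcal/mol, and +0.45
kcal/mol for each helix end closed by an AU or GU pair. All registrations
of the two strands and all sub-helices are scanned; the reported value is
the minimum, or 0 when no helix is favorable. The parameters live in
`src/retescan/data/rna_stacks.tsv` (one orientation of each stack; the
loader derives the symmetric partner) and alternate tables can be passed to
`load_energy_model`.

Class thresholds are strict inequalities: ΔG < −3.5 kcal/mol ⇒ `sd`,
ΔG < −8.4 kcal/mol ⇒ `strong_sd`; −3.5 and −8.4 exactly are *not* inside
the classes. Windows that do not exist (insufficient flank on a linear
contig) or contain ambiguity characters score as `none` — the model is
defined on A/C/G/U only, and guessing bases would bias energies downward.

A note on an intuitive property that does *not* hold: with GU pairing
enabled, the exact complement of a sequence is not always its strongest
binder among single-substitution variants, because an A→G substitution
turns a terminal A:U into G:U and some GU stacks are marginally stronger
than the AU stacks they replace. The property holds in the
Watson–Crick-only model, and the test suite asserts it there. The
implementation itself is pinned by an independent brute-force enumeration
oracle, so the parameter choice and the scanning code are validated
separately.

The anti-SD is found by scanning the final 13 nt (configurable) of the
annotated 16S rRNA for the minimum-Hamming-distance match to ACCUCC, with
ties broken toward the 3′ terminus (where the biological anti-SD sits),
then extending 1 nt on each side to 8 nt. The extension may draw on 16S
sequence 5′ of the tail; at the 3′ terminus it is clipped with a warning.

## Homology and start re-annotation

Clustering replaces an external all-vs-all search engine with greedy
length-sorted incremental clustering: sequences are sorted by length
(descending), and each joins the first cluster whose representative it
matches at or above the tier threshold (90% tight, 50% loose), else founds
a new cluster. Identity is global-alignment identity — matches divided by
total alignment columns, so gaps count against identity — computed from an
edlib Needleman–Wunsch alignment. Where several alignments are co-optimal
under edit distance, identity follows the alignment edlib reports; this
only matters for very diverged pairs. Tight-cluster representatives are all
members of the reference genome set, or the longest member when none is;
loose clusters without reference members are discarded. Homolog sets
require *more than* 10 qualifying hits (identity-ranked in internal mode,
with a 30% identity floor standing in for an e-value cutoff; hits identical
to the query or to each other are dropped) and keep the best 10.

Start scanning slides a 3-column window over the query-vs-homologs protein
alignment and counts homolog rows (never the query) whose first residue
falls inside. Windows with support ≥ 5 qualify; among qualifying windows
the one nearest the query's annotated start column wins (ties: higher
support, then lower column), and the consensus column is the most-voted
column of that window (ties: nearest the query start). This two-step
reading — qualify by support, then choose by proximity — is isolated in
`scan_consensus_start` so it can be revised independently.

Mapping the consensus column to nucleotides: downstream of the annotated
start, the offset counts the query's non-gap residues between the two
columns; upstream of the query's first residue the query row is all gaps
and each alignment column counts as one codon (exact when the homolog rows
are ungapped there, as in the generator's families). The annotated start
then moves to the in-frame start codon (default set {ATG, GTG, TTG},
configurable) closest to the annotation within the interval bounded by the
consensus — minimizing the sequence extension when the consensus is
upstream, the residue loss when downstream. No qualifying codon, a
consensus at the annotation, or a consensus mapping off the contig leave
the annotation unchanged. Stops never move, so re-annotation preserves the
frame and the 3′ end by construction.

## Per-genome and per-group statistics

`f_overlap_pairs` divides overlapping-pair counts by the total CDS count —
the convention under which a ~15% pair fraction corresponds to ~30% of
genes sitting in overlaps — and `f_genes_in_overlaps` (distinct genes in
overlapping pairs / genes) is emitted alongside, so both denominators are
always available. SD fractions condition on the relevant set (downstream
genes of overlapping pairs; leading genes), and the quotient
`f_sd_overlap / f_sd_leading` measures the relative importance of the SD
for reinitiation versus de novo initiation. Ratios with zero denominators
are missing values, never zeros; group aggregation (mean, sample standard
deviation with n−1, configurable) excludes missing values per metric and
reports the contributing count. A single-genome group reports sd = 0.

## Reporter translational efficiencies

TE is the activity/transcript quotient per biological replicate, averaged;
the empty-vector control's TE is subtracted (after which near-zero values
may legitimately be slightly negative — they are reported with a flag, not
clamped), and mutants are normalized to their unmutated control, which is
exactly 1 by definition. Replicate spread is propagated first-order: the
corrected sd adds sample and control sds in quadrature, the normalized sd
combines relative errors. The propagation scheme is a documented choice,
not an attempt to reproduce any particular error model.

## The synthetic generator

`generate_genome` emulates the layout features the pipeline measures, not
sequence realism: circular contigs of co-directional runs on alternating
strands (geometric run lengths, mean 20 genes), gene bodies of random
non-stop codons (20–50 codons), ATG starts and TGA stops, a 16S rRNA whose
final 13 nt carry an exact canonical anti-SD tail, and intergenic gaps that
are geometric (mean 40 nt) with a configurable point mass of ≥ 200-nt gaps
(default 15% of gap junctions) to plant leading genes. Overlap planting is
exact, not binomial: `round(f · n_genes)` junctions of each overlap type
are assigned to co-directional junctions by seeded permutation, so the
planted overlap histogram is recovered exactly and the recovered pair
fraction equals the planted fraction by construction. Junction sequence
constraints (the shared A of ATGA, the TGATG run) are imposed during ORF
writing; SD windows are then overlaid with fixed-position and
reading-frame guards so planted windows never disrupt coding sequence.

Every gene's −12…−1 window is rejection-sampled to its planted SD class
(default mix 0.3 none / 0.4 sd / 0.3 strong) with a ±0.5 kcal/mol margin
from both thresholds, which makes classification recovery exact; the
margin is configurable to stress boundary behavior. Strong-SD windows need
a ≥ 7-bp complementary core; when an upstream stop codon would sit in the
middle of the window (gaps of 3–6 nt) no such core fits, so the generator
redraws those gap lengths for strong-SD downstream genes — a physical
constraint of the 12-nt window, not a sampler limitation.

`generate_homolog_family` plants a conserved true start: `concordant`
homolog rows start at the true column, the rest scatter at mutually
distant columns (≥ 3 apart, ≥ 5 from the true start) so no spurious window
ever qualifies; the query's annotated start is displaced by a multiple of
3 nt, and the companion nucleotide locus has an in-frame ATG at the true
position and no competing start codon in between, making recovery
well-defined. Rows are substitution-only mutants of a master sequence
(90% identity), with leading gaps as the only gap structure.

What the generator does **not** emulate — realistic codon usage or GC
content, rRNA secondary structure, internal alignment gaps, overlapping
reading frames longer than the junction motifs, leaderless transcripts —
bounds what passing tests show: they validate the measurement machinery
and selection logic, not performance on the quirks of any particular
taxon's real genomes (which enter through the GenBank/GFF3 readers).

## Problem sizes and determinism

The test suite and the acceptance script use a 2000-gene genome for
recovery statistics (the planted-fraction standard-error bound is
computed at that n), 200 homolog families for re-annotation recovery, 200
random sequence pairs (length ≤ 6) for the energy-oracle equivalence, and
a 150-gene shared fixture for structural properties. Generation is a pure
function of (parameters, seed): the same seed yields byte-identical
GenBank output. All randomness in tests is seeded; hypothesis-based
property tests run derandomized.

## Known limitations

- The energy model ignores bulges, internal loops and dangling ends; ΔG
  values are comparable within the model, not against folding programs.
- Internal-mode homolog search collapses the large/small cluster
  validation split that an external search engine would support; adapters
  for external tools are the intended extension point.
- Upstream consensus offsets assume one codon per alignment column in the
  region where the query is all gaps; families with heavy indel structure
  upstream of the annotated start would need realignment.
- Circular-contig support excludes origin-spanning genes rather than
  re-rotating the contig.
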