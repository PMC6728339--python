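"""Co-directional gene pairs and intergenic-distance classes.

The signed intergenic distance runs from the last base of the upstream stop
codon to the first base of the downstream start codon, in translation order:
0 means directly adjacent, negative means the codons share nucleotides
(ATGA = -4, TGATG = -1). Pairs fall into five classes:

    overlapping  distance < 0
    close10      0..9 nt      (distance 0 grouped with the short gaps)
    medium50     10..50 nt
    far          > 50 nt, no opposite-strand gene start inside the gap
    lead         > 50 nt with an opposite-strand gene start inside the gap

Separately, "leading genes" — where reinitiation can be ruled out and
initiation must be de novo — are genes at least ``leading_gene_min_gap``
(default 200) nt downstream of the end of their nearest co-directional
upstream gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import GeneRecord, Genome

CATEGORIES = ("overlapping", "close10", "medium50", "far", "lead")


@dataclass
class DistanceConfig:
    leading_gene_min_gap: int = 200

    def __post_init__(self):
        if self.leading_gene_min_gap <= 50:
            raise ValueError("leading_gene_min_gap must exceed 50 nt")


@dataclass
class GenePair:
    upstream: str
    downstream: str
    strand: str
    distance: int
    category: str | None = None


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """Signed stop-to-start distance in translation order."""
    if upstream.strand != downstream.strand:
        raise ValueError("genes are on different strands")
    if upstream.strand == "+":
        return downstream.start - upstream.end
    return upstream.start - downstream.end


def classify_pair(distance: int, opposite_strand_start_in_gap: bool = False) -> str:
    if distance < 0:
        return "overlapping"
    if distance <= 9:
        return "close10"
    if distance <= 50:
        return "medium50"
    return "lead" if opposite_strand_start_in_gap else "far"


def enumerate_codirectional_pairs(genome: Genome,
                                  classify: bool = True) -> list[GenePair]:
    """Pair each CDS with its nearest same-strand neighbour in translation order.

    Opposite-strand genes lying between two co-directional genes do not break
    the pair. Each gene appears as the downstream partner of at most one
    pair. Pairs are not formed across the origin of circular contigs.
    """
    pairs: list[GenePair] = []
    for strand in ("+", "-"):
        genes = [g for g in genome.cds if g.strand == strand]
        genes.sort(key=lambda g: g.start)
        if strand == "-":
            genes.reverse()  # translation order is descending coordinate
        for up, down in zip(genes, genes[1:]):
            d = intergenic_distance(up, down)
            pair = GenePair(up.gene_id, down.gene_id, strand, d)
            if classify:
                opp = (d > 50) and _opposite_start_in_gap(genome, up, down)
                pair.category = classify_pair(d, opp)
            pairs.append(pair)
    pairs.sort(key=lambda p: p.upstream)
    return pairs


def _opposite_start_in_gap(genome: Genome, up: GeneRecord,
                           down: GeneRecord) -> bool:
    """Does a gene on the other strand start strictly inside the gap?"""
    if up.strand == "+":
        lo, hi = up.end, down.start
        other = "-"
    else:
        lo, hi = down.end, up.start
        other = "+"
    for g in genome.cds:
        if g.strand != other:
            continue
        if lo < g.five_prime() < hi - 1:
            return True
    return False


def identify_leading_genes(genome: Genome,
                           config: DistanceConfig | None = None) -> list[str]:
    """Genes whose nearest co-directional upstream gene ends >= min_gap away.

    Genes with no co-directional upstream gene on a linear contig qualify
    (nothing can couple to them); on circular contigs the distance wraps.
    """
    config = config or DistanceConfig()
    min_gap = config.leading_gene_min_gap
    n = len(genome.sequence)
    leading: list[str] = []
    for strand in ("+", "-"):
        genes = [g for g in genome.cds if g.strand == strand]
        genes.sort(key=lambda g: g.start)
        if strand == "-":
            genes.reverse()
        for i, g in enumerate(genes):
            if i > 0:
                gap = intergenic_distance(genes[i - 1], g)
            elif genome.topology == "circular" and len(genes) > 1:
                gap = intergenic_distance(genes[-1], g) % n
            elif genome.topology == "circular" or not genes:
                gap = None  # single gene on a circle: no upstream partner
            else:
                gap = None
            if gap is None or gap >= min_gap:
                leading.append(g.gene_id)
    return sorted(leading)


def overlap_length_histogram(pairs: list[GenePair]) -> dict[int, int]:
    """Counts of overlap lengths (positive nt) among overlapping pairs."""
    hist: dict[int, int] = {}
    for p in pairs:
        if p.distance < 0:
            hist[-p.distance] = hist.get(-p.distance, 0) + 1
    return hist
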