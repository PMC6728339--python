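"""Homolog selection and translation-start re-annotation.

Two-tier greedy identity clustering stands in for a full all-vs-all search
engine: proteins are first grouped at >= 90% identity (tight clusters),
cluster representatives are then grouped at >= 50% identity (loose
clusters), and per-query homolog sets of exactly 10 sequences are drawn
from the loose clusters. Identity is global-alignment identity, defined as
matches divided by total alignment columns, so gaps count against identity.

Start re-annotation scans the query-vs-homologs protein alignment with a
3-column sliding window, accepts windows where at least five homologs place
their first residue, maps the winning column back to the query nucleotide
sequence, and moves the annotated start to the nearest in-frame start codon
between the annotated and consensus positions — minimizing the extension
(consensus upstream) or the loss of residues (consensus downstream).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib

from .annotation_io import (START_CODONS, GeneRecord, Genome, MsaFamily,
                            reverse_complement)

log = logging.getLogger(__name__)

DEFAULT_START_CODONS = START_CODONS
INTERNAL_MIN_IDENTITY = 0.30  # stands in for the e-value cutoff of an
                              # external search engine in internal mode


def global_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) alignment identity: matches / columns."""
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    columns = 0
    for length, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length)
        columns += length
        if op == "=":
            matches += length
    return matches / columns


@dataclass
class ProteinCluster:
    cluster_id: str
    tier: str  # "tight" or "loose"
    members: list[str]
    representative: str


@dataclass
class HomologSet:
    query_id: str
    homologs: list[tuple[str, float]]  # (protein id, identity score)

    def __post_init__(self):
        if len(self.homologs) != 10:
            raise ValueError("a homolog set holds exactly 10 homologs")


@dataclass
class ConsensusStart:
    query_id: str
    window_columns: tuple[int, int, int]
    support: int
    consensus_column: int
    query_start_column: int
    query_aligned: str = field(repr=False, default="")
    remapped_nt: int | None = None


# ---------------------------------------------------------------------------
# Clustering


def _cluster_greedy(proteins: list[tuple[str, str]], identity: float,
                    tier: str) -> list[ProteinCluster]:
    # length-descending greedy incremental clustering; each sequence joins
    # the first existing cluster whose representative it matches
    ordered = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[ProteinCluster] = []
    reps: list[str] = []
    for pid, seq in ordered:
        placed = False
        for cl, rep_seq in zip(clusters, reps):
            if global_identity(seq, rep_seq) >= identity:
                cl.members.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(
                cluster_id=f"{tier[0].upper()}C{len(clusters):05d}",
                tier=tier, members=[pid], representative=pid))
            reps.append(seq)
    return clusters


def cluster_tight(proteins: list[tuple[str, str]],
                  identity: float = 0.90) -> list[ProteinCluster]:
    """Greedy clustering at the tight (90%) identity threshold."""
    return _cluster_greedy(proteins, identity, "tight")


def select_representatives(clusters: list[ProteinCluster],
                           rep720_ids: set[str],
                           sequences: dict[str, str]) -> list[str]:
    """Per tight cluster: all reference-set members, else the longest member."""
    out: list[str] = []
    for cl in clusters:
        in_ref = [m for m in cl.members if m in rep720_ids]
        if in_ref:
            out.extend(sorted(in_ref))
        else:
            out.append(max(cl.members, key=lambda m: (len(sequences[m]),
                                                      _neg_lex(m))))
    return out


def _neg_lex(s: str):
    # ties on length break toward the lexicographically smallest id
    return tuple(-ord(c) for c in s)


def cluster_loose(representatives: list[tuple[str, str]],
                  rep720_ids: set[str],
                  identity: float = 0.50) -> list[ProteinCluster]:
    """Cluster representatives at 50% identity; drop clusters with no
    reference-set member."""
    clusters = _cluster_greedy(representatives, identity, "loose")
    kept = [c for c in clusters if any(m in rep720_ids for m in c.members)]
    dropped = len(clusters) - len(kept)
    if dropped:
        log.info("discarded %d loose clusters without reference members",
                 dropped)
    return kept


def rank_hits(query_id: str, candidates: list[tuple[str, str]],
              query_seq: str,
              min_identity: float = INTERNAL_MIN_IDENTITY
              ) -> list[tuple[str, float]]:
    """Identity-ranked, deduplicated hit list for a query (internal mode).

    Sequences identical to the query or to an earlier hit are excluded, as
    are hits below ``min_identity``.
    """
    seen = {query_seq}
    scored = []
    for pid, seq in candidates:
        if pid == query_id or seq in seen:
            continue
        ident = global_identity(query_seq, seq)
        if ident < min_identity:
            continue
        seen.add(seq)
        scored.append((pid, ident))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def select_homolog_set(query_id: str,
                       scores: list[tuple[str, float]]) -> HomologSet | None:
    """Keep the 10 best hits; queries with <= 10 qualifying hits are rejected."""
    if len(scores) <= 10:
        return None
    return HomologSet(query_id=query_id, homologs=scores[:10])


# ---------------------------------------------------------------------------
# Consensus start scanning


def scan_consensus_start(family: MsaFamily, min_support: int = 5,
                         window: int = 3) -> ConsensusStart | None:
    """Find the consensus start column supported by homolog first residues.

    Homolog rows (the query row is excluded from counting) vote with the
    alignment column of their first residue. Among windows with support >=
    ``min_support`` the window nearest the query's annotated start column
    wins (ties: higher support, then lower column); the consensus column is
    the column in that window holding the most votes (ties: nearest the
    query start column).
    """
    q_col = family.start_column[family.query_id]
    votes: dict[int, int] = {}
    for rid, _ in family.rows:
        if rid == family.query_id:
            continue
        col = family.start_column[rid]
        votes[col] = votes.get(col, 0) + 1

    ncol = family.n_columns
    candidates = []
    for c in range(max(0, ncol - window + 1)):
        cols = range(c, c + window)
        support = sum(votes.get(col, 0) for col in cols)
        if support >= min_support:
            dist = min(abs(col - q_col) for col in cols)
            candidates.append((dist, -support, c))
    if not candidates:
        return None
    _, neg_support, c = min(candidates)
    cols = tuple(range(c, c + window))
    consensus_col = min(cols, key=lambda col: (-votes.get(col, 0),
                                               abs(col - q_col), col))
    return ConsensusStart(
        query_id=family.query_id, window_columns=cols,
        support=-neg_support, consensus_column=consensus_col,
        query_start_column=q_col, query_aligned=family.row(family.query_id))


# ---------------------------------------------------------------------------
# Remapping to nucleotide coordinates


def _codon(genome: Genome, gene: GeneRecord, k: int) -> str | None:
    """Codon at offset ``k`` (in codons) from the annotated start, in gene
    orientation; None when it falls outside the contig."""
    seq, n = genome.sequence, len(genome.sequence)
    if gene.strand == "+":
        lo = gene.start + 3 * k
        if lo < 0 or lo + 3 > n:
            return None
        return seq[lo:lo + 3]
    hi = gene.end - 3 * k
    if hi > n or hi - 3 < 0:
        return None
    return reverse_complement(seq[hi - 3:hi])


def _five_prime_at(gene: GeneRecord, k: int) -> int:
    if gene.strand == "+":
        return gene.start + 3 * k
    return gene.end - 3 * k - 1


def consensus_codon_offset(consensus: ConsensusStart) -> int:
    """Signed codon offset of the consensus column from the annotated start.

    Downstream of the annotated start, offsets count the query's non-gap
    residues between the two columns; upstream of the query's first residue
    the query row is all gaps, and each alignment column counts as one codon
    of extension.
    """
    q, c = consensus.query_start_column, consensus.consensus_column
    if c == q:
        return 0
    if c > q:
        row = consensus.query_aligned
        return sum(1 for ch in row[q:c] if ch != "-")
    return -(q - c)


def remap_start(genome: Genome, gene: GeneRecord, consensus: ConsensusStart,
                start_codons: tuple[str, ...] = DEFAULT_START_CODONS
                ) -> int | None:
    """New five-prime coordinate for ``gene``, or None when unchanged.

    Searches in-frame start codons between the annotated start and the
    consensus position (inclusive of the consensus end) and picks the one
    closest to the annotated start. The returned coordinate is the genome
    position of the first base of the new start codon.
    """
    d = consensus_codon_offset(consensus)
    if d == 0:
        return None
    ks = range(1, d + 1) if d > 0 else range(-1, d - 1, -1)
    for k in ks:
        codon = _codon(genome, gene, k)
        if codon is None:
            log.warning("gene %s: consensus maps outside the contig; "
                        "annotation kept", gene.gene_id)
            return None
        if codon in start_codons:
            return _five_prime_at(gene, k)
    return None


def reannotate_genome(genome: Genome, families: dict[str, MsaFamily],
                      min_support: int = 5, window: int = 3,
                      start_codons: tuple[str, ...] = DEFAULT_START_CODONS
                      ) -> list[dict]:
    """Run consensus scanning + remapping for every gene with a family.

    Returns one report record per evaluated gene with keys gene_id,
    old_start, new_start, support, direction (upstream/downstream/unchanged).
    """
    report = []
    by_id = {g.gene_id: g for g in genome.cds}
    for gene_id, family in sorted(families.items()):
        gene = by_id.get(gene_id)
        if gene is None:
            log.warning("family %s has no matching CDS; skipped", gene_id)
            continue
        consensus = scan_consensus_start(family, min_support=min_support,
                                         window=window)
        old5 = gene.five_prime()
        rec = {"gene_id": gene_id, "old_start": old5, "new_start": old5,
               "support": consensus.support if consensus else 0,
               "direction": "unchanged"}
        if consensus is not None:
            new5 = remap_start(genome, gene, consensus, start_codons)
            if new5 is not None:
                rec["new_start"] = new5
                d = consensus_codon_offset(consensus)
                rec["direction"] = "downstream" if d > 0 else "upstream"
        report.append(rec)
    return report
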