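"""Genome and alignment I/O.

Reads annotated genomes (GenBank or GFF3 + FASTA) into a minimal internal
data model with 0-based half-open coordinates on the forward strand, and
reads aligned-FASTA protein families. All coordinate conversion happens at
this boundary; downstream modules never see 1-based or strand-relative
coordinates.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature; coordinates 0-based half-open, forward strand."""

    gene_id: str
    kind: str  # "CDS", "rRNA_16S", "other"
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genome coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    def coding_sequence(self, genome_seq: str) -> str:
        s = genome_seq[self.start:self.end]
        return reverse_complement(s) if self.strand == "-" else s


@dataclass
class Genome:
    """A single contig with its annotated features.

    Genes are kept sorted by start coordinate. Genes spanning the origin of
    circular contigs are excluded at parse time (with a warning).
    """

    id: str
    sequence: str
    topology: str = "linear"  # "circular" or "linear"
    genes: list[GeneRecord] = field(default_factory=list)
    rrnas: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")
        self.genes.sort(key=lambda g: (g.start, g.end))
        n = len(self.sequence)
        for g in list(self.genes) + list(self.rrnas):
            if g.end > n:
                raise ValueError(
                    f"{g.gene_id}: end {g.end} exceeds genome length {n}")

    @property
    def cds(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.kind == "CDS"]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class MsaFamily:
    """A query protein aligned with its homologs (aligned FASTA).

    ``start_column`` maps each row id to the alignment column of its first
    non-gap character.
    """

    query_id: str
    rows: list[tuple[str, str]]
    start_column: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: rows differ in length")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        if not self.start_column:
            self.start_column = {
                rid: _first_residue_column(s) for rid, s in self.rows}

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s
        raise KeyError(rid)


def _first_residue_column(aligned: str) -> int:
    for i, c in enumerate(aligned):
        if c != "-":
            return i
    raise ValueError("alignment row is all gaps")


# ---------------------------------------------------------------------------
# Readers


def read_genome(path: str | Path, format: str = "genbank",
                fasta: str | Path | None = None) -> Genome:
    """Read an annotated genome into the internal model.

    Parameters
    ----------
    path : path to a GenBank flat file, or to a GFF3 file when
        ``format="gff3"`` (then ``fasta`` must give the sequence).
    format : ``"genbank"`` or ``"gff3"``.
    fasta : FASTA path for the GFF3 route.
    """
    path = Path(path)
    if format == "genbank":
        genome = _read_genbank(path)
    elif format in ("gff3", "gff3+fasta"):
        if fasta is None:
            raise ValueError("GFF3 input requires a companion FASTA path")
        genome = _read_gff3(path, Path(fasta))
    else:
        raise ValueError(f"unknown format {format!r}")
    genome = _drop_origin_spanning(genome)
    if not genome.cds:
        log.warning("genome %s contains no CDS features", genome.id)
    return genome


def _is_16s(feature_type: str, product: str | None) -> bool:
    # GenBank annotations mark the small-subunit rRNA by product string.
    return feature_type == "rRNA" and bool(product) and "16S" in product


def _read_genbank(path: Path) -> Genome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    genes: list[GeneRecord] = []
    rrnas: list[GeneRecord] = []
    counter = 0
    for feat in record.features:
        if feat.type not in ("CDS", "rRNA"):
            continue
        counter += 1
        quals = feat.qualifiers
        gid = (quals.get("locus_tag") or quals.get("gene")
               or quals.get("protein_id") or [f"feat{counter:05d}"])[0]
        product = (quals.get("product") or [None])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        start = int(feat.location.start)
        end = int(feat.location.end)
        if feat.type == "CDS":
            genes.append(GeneRecord(gid, "CDS", start, end, strand, product))
        elif _is_16s(feat.type, product):
            rrnas.append(
                GeneRecord(gid, "rRNA_16S", start, end, strand, product))
    return Genome(id=record.id, sequence=str(record.seq),
                  topology="circular" if topology == "circular" else "linear",
                  genes=genes, rrnas=rrnas)


_GFF_COLS = 9


def _read_gff3(gff_path: Path, fasta_path: Path) -> Genome:
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in FASTA {fasta_path}")
    genes: list[GeneRecord] = []
    rrnas: list[GeneRecord] = []
    contig_id = None
    topology = "linear"
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                if "circular=true" in line:
                    topology = "circular"
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise ValueError(
                    f"{gff_path}:{lineno}: expected {_GFF_COLS} columns, "
                    f"got {len(parts)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "rRNA"):
                continue
            contig_id = contig_id or seqid
            attr = _parse_gff_attributes(attrs)
            gid = attr.get("ID") or attr.get("locus_tag") or f"line{lineno}"
            product = attr.get("product")
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{gff_path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{gff_path}:{lineno}: bad strand {strand!r}")
            if ftype == "CDS":
                genes.append(GeneRecord(gid, "CDS", s0, e0, strand, product))
            elif _is_16s(ftype, product):
                rrnas.append(GeneRecord(gid, "rRNA_16S", s0, e0, strand, product))
    if contig_id is None:
        contig_id = next(iter(seqs))
    if contig_id not in seqs:
        raise ValueError(f"GFF3 seqid {contig_id!r} not found in FASTA")
    return Genome(id=contig_id, sequence=seqs[contig_id], topology=topology,
                  genes=genes, rrnas=rrnas)


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = urllib.parse.unquote(v.strip())
    return out


def _drop_origin_spanning(genome: Genome) -> Genome:
    # A feature stored with end > contig length (or GenBank join across the
    # origin collapsing to the full span) cannot be represented in forward
    # half-open coordinates; the analysis skips it.
    n = len(genome.sequence)
    kept = []
    for g in genome.genes:
        if g.end > n:
            log.warning("dropping origin-spanning gene %s", g.gene_id)
            continue
        kept.append(g)
    genome.genes = kept
    return genome


def read_msa(path: str | Path) -> MsaFamily:
    """Read an aligned protein FASTA into an :class:`MsaFamily`.

    The first record is taken as the query row.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError(f"{path}: alignment needs at least 2 rows")
    rows = [(r.id, str(r.seq).upper()) for r in records]
    return MsaFamily(query_id=rows[0][0], rows=rows)


# ---------------------------------------------------------------------------
# Writers


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i:i + width] + "\n")


def _gff_escape(value: str) -> str:
    return re.sub(r"[;=&,\t\n%]",
                  lambda m: "%%%02X" % ord(m.group(0)), value)


def write_gff3(genome: Genome, path: str | Path,
               extra_attrs: dict[str, dict[str, str]] | None = None) -> None:
    """Write all features as GFF3 (1-based inclusive coordinates)."""
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        if genome.topology == "circular":
            fh.write("# circular=true\n")
        feats = sorted(genome.genes + genome.rrnas, key=lambda g: g.start)
        for g in feats:
            ftype = "rRNA" if g.kind == "rRNA_16S" else g.kind
            attrs = {"ID": g.gene_id}
            if g.product:
                attrs["product"] = g.product
            attrs.update(extra_attrs.get(g.gene_id, {}))
            attr_s = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
            fh.write("\t".join([
                genome.id, "retescan", ftype, str(g.start + 1), str(g.end),
                ".", g.strand, "0" if g.kind == "CDS" else ".", attr_s]) + "\n")


def write_genbank(genome: Genome, path: str | Path) -> None:
    """Write the genome as a GenBank flat file via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic genome",
                    annotations={"molecule_type": "DNA",
                                 "topology": genome.topology})
    for g in sorted(genome.genes + genome.rrnas, key=lambda x: x.start):
        ftype = "rRNA" if g.kind == "rRNA_16S" else g.kind
        quals = {"locus_tag": [g.gene_id]}
        if g.product:
            quals["product"] = [g.product]
        rec.features.append(SeqFeature(
            FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
            type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def apply_reannotation(genome: Genome,
                       changes: Sequence[tuple[str, int]]) -> Genome:
    """Return a genome with start coordinates moved per ``changes``.

    Each change is ``(gene_id, new_five_prime)`` where ``new_five_prime`` is
    the genome coordinate of the first base of the new start codon (so for a
    minus-strand gene it is ``new_end - 1``). The stop codon never moves.
    """
    by_id = {g.gene_id: g for g in genome.genes}
    new_genes = dict(by_id)
    for gid, new5 in changes:
        g = by_id[gid]
        if g.strand == "+":
            new_start, new_end = new5, g.end
        else:
            new_start, new_end = g.start, new5 + 1
        if not (0 <= new_start < new_end <= len(genome.sequence)):
            raise ValueError(f"{gid}: new start {new5} out of bounds")
        if (new_end - new_start) % 3 != 0:
            raise ValueError(f"{gid}: new start {new5} breaks reading frame")
        new_genes[gid] = replace(g, start=new_start, end=new_end)
    return Genome(id=genome.id, sequence=genome.sequence,
                  topology=genome.topology, genes=list(new_genes.values()),
                  rrnas=list(genome.rrnas))


def write_reannotated(genome: Genome, changes: Sequence[tuple[str, int]],
                      path: str | Path) -> Genome:
    """Write a GFF3 with re-annotated starts and provenance attributes.

    The emitted ``original_start`` attribute records the original 1-based
    GFF start/end field that moved. Returns the updated genome.
    """
    updated = apply_reannotation(genome, changes)
    provenance: dict[str, dict[str, str]] = {}
    by_id = {g.gene_id: g for g in genome.genes}
    for gid, _new5 in changes:
        old = by_id[gid]
        field_name = "start" if old.strand == "+" else "end"
        old_val = old.start + 1 if old.strand == "+" else old.end
        provenance[gid] = {"original_start": f"{field_name}:{old_val}"}
    write_gff3(updated, path, extra_attrs=provenance)
    return updated
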