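"""Per-genome fractions and per-group aggregate statistics.

For each genome the module counts co-directional pairs by distance class,
SD usage at downstream genes of overlapping pairs versus at leading genes,
and the quotient of the two SD fractions — the relative importance of the
SD motif for reinitiation versus de novo initiation. Group-level tables
report means and sample standard deviations across member genomes.

Fractions of pairs are reported against the total CDS count (the convention
under which ~15% overlapping pairs corresponds to ~30% of genes sitting in
overlaps); the fraction of distinct genes participating in overlaps is
emitted alongside. Undefined ratios (zero denominators) propagate as
missing values and are excluded from group means, never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import Genome
from .pair_classifier import CATEGORIES, GenePair
from .sd_energy import SdCall

_SD_CLASSES = ("sd", "strong_sd")

METRICS = ("f_overlap_pairs", "f_genes_in_overlaps", "f_leading",
           "f_sd_overlap", "f_strong_sd_overlap", "f_sd_leading",
           "f_strong_sd_leading", "quotient_sd", "quotient_strong_sd")


@dataclass
class GenomeSummary:
    genome_id: str
    n_genes: int
    n_pairs_by_category: dict[str, int]
    n_overlap_pairs_with_sd: int
    n_overlap_pairs_with_strong_sd: int
    n_leading: int
    n_leading_with_sd: int
    n_leading_with_strong_sd: int
    f_overlap_pairs: float | None = None
    f_genes_in_overlaps: float | None = None
    f_leading: float | None = None
    f_sd_overlap: float | None = None
    f_strong_sd_overlap: float | None = None
    f_sd_leading: float | None = None
    f_strong_sd_leading: float | None = None
    quotient_sd: float | None = None
    quotient_strong_sd: float | None = None


@dataclass
class GroupSummary:
    group_id: str
    n_genomes: int
    means: dict[str, float | None] = field(default_factory=dict)
    sds: dict[str, float | None] = field(default_factory=dict)
    n_defined: dict[str, int] = field(default_factory=dict)


def _ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or den == 0:
        return None
    return num / den


def summarize_genome(genome: Genome, pairs: list[GenePair],
                     sd_calls: list[SdCall],
                     leading: list[str]) -> GenomeSummary:
    """Counts and fractions for one genome.

    ``sd_calls`` must cover every downstream gene of an overlapping pair and
    every leading gene.
    """
    n_genes = len(genome.cds)
    by_cat = {c: 0 for c in CATEGORIES}
    for p in pairs:
        if p.category is None:
            raise ValueError(f"pair {p.upstream}->{p.downstream} unclassified")
        by_cat[p.category] += 1

    sd_by_gene = {c.gene_id: c.sd_class for c in sd_calls}

    def sd_of(gene_id: str) -> str:
        if gene_id not in sd_by_gene:
            raise ValueError(f"missing SD call for gene {gene_id}")
        return sd_by_gene[gene_id]

    overlap_pairs = [p for p in pairs if p.category == "overlapping"]
    n_overlap = len(overlap_pairs)
    n_ov_sd = sum(1 for p in overlap_pairs
                  if sd_of(p.downstream) in _SD_CLASSES)
    n_ov_strong = sum(1 for p in overlap_pairs
                      if sd_of(p.downstream) == "strong_sd")
    genes_in_overlaps = {g for p in overlap_pairs
                         for g in (p.upstream, p.downstream)}
    n_lead = len(leading)
    n_lead_sd = sum(1 for g in leading if sd_of(g) in _SD_CLASSES)
    n_lead_strong = sum(1 for g in leading if sd_of(g) == "strong_sd")

    s = GenomeSummary(
        genome_id=genome.id, n_genes=n_genes, n_pairs_by_category=by_cat,
        n_overlap_pairs_with_sd=n_ov_sd,
        n_overlap_pairs_with_strong_sd=n_ov_strong,
        n_leading=n_lead, n_leading_with_sd=n_lead_sd,
        n_leading_with_strong_sd=n_lead_strong)
    s.f_overlap_pairs = _ratio(n_overlap, n_genes)
    s.f_genes_in_overlaps = _ratio(len(genes_in_overlaps), n_genes)
    s.f_leading = _ratio(n_lead, n_genes)
    s.f_sd_overlap = _ratio(n_ov_sd, n_overlap)
    s.f_strong_sd_overlap = _ratio(n_ov_strong, n_overlap)
    s.f_sd_leading = _ratio(n_lead_sd, n_lead)
    s.f_strong_sd_leading = _ratio(n_lead_strong, n_lead)
    s.quotient_sd = _ratio(s.f_sd_overlap, s.f_sd_leading)
    s.quotient_strong_sd = _ratio(s.f_strong_sd_overlap, s.f_strong_sd_leading)
    return s


def summaries_to_frame(summaries: list[GenomeSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"genome_id": s.genome_id, "n_genes": s.n_genes,
               "n_leading": s.n_leading}
        for c in CATEGORIES:
            row[f"n_{c}"] = s.n_pairs_by_category.get(c, 0)
        for m in METRICS:
            v = getattr(s, m)
            row[m] = math.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_groups(summaries: list[GenomeSummary],
                     group_map: dict[str, str],
                     ddof: int = 1) -> list[GroupSummary]:
    """Group means and sample standard deviations of each defined metric.

    Genomes with an undefined metric are excluded from that metric's
    aggregation; the count of contributing genomes is reported per metric.
    A single-genome group reports sd = 0.
    """
    unmapped = [s.genome_id for s in summaries if s.genome_id not in group_map]
    if unmapped:
        raise ValueError(f"genomes not in group map: {unmapped}")
    frame = summaries_to_frame(summaries)
    frame["group"] = [group_map[g] for g in frame["genome_id"]]
    out = []
    for gid, sub in frame.groupby("group", sort=True):
        gs = GroupSummary(group_id=gid, n_genomes=len(sub))
        for m in METRICS:
            vals = sub[m].dropna()
            gs.n_defined[m] = len(vals)
            if len(vals) == 0:
                gs.means[m] = None
                gs.sds[m] = None
            else:
                gs.means[m] = float(vals.mean())
                gs.sds[m] = 0.0 if len(vals) <= ddof else float(
                    vals.std(ddof=ddof))
        out.append(gs)
    return out


def groups_to_frame(groups: list[GroupSummary]) -> pd.DataFrame:
    rows = []
    for g in groups:
        row: dict = {"group": g.group_id, "n_genomes": g.n_genomes}
        for m in METRICS:
            row[f"{m}_mean"] = (math.nan if g.means[m] is None
                                else g.means[m])
            row[f"{m}_sd"] = math.nan if g.sds[m] is None else g.sds[m]
            row[f"{m}_n"] = g.n_defined[m]
        rows.append(row)
    return pd.DataFrame(rows)
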