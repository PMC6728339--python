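"""Synthetic genomes and homolog families with planted ground truth.

The generator emulates the layout features the pipeline measures on real
prokaryotic genomes: circular contigs of co-directional gene runs on
alternating strands, stop/start codon overlaps of 4 nt (ATGA) and 1 nt
(TGATG) planted at exact per-genome counts, geometric intergenic gaps with
a point mass of long (>= 200 nt) gaps that plant leading genes, a 16S rRNA
carrying an exact anti-SD tail, and a 12-nt window upstream of every start
codon rejection-sampled to a target SD class with a safety margin from the
free-energy thresholds. Homolog families plant a conserved true start among
concordant rows and perturb the query's annotated start.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import (START_CODONS, STOP_CODONS, GeneRecord, Genome,
                            MsaFamily)
from .sd_energy import (EnergyModel, classify_sd, default_energy_model,
                        duplex_delta_g, SD_THRESHOLD, STRONG_SD_THRESHOLD)

DNA = "ACGT"
RNA = "ACGU"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# DNA tail whose RNA form GAUCACCUCCUUA carries the canonical anti-SD core
DEFAULT_16S_TAIL = "GATCACCTCCTTA"
DEFAULT_ANTI_SD = "CACCUCCU"

_SAFE_A_CODONS = ["GCA", "AAA", "CAA", "GGA", "CGA", "ACA", "GAA", "CCA"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# SD window sampling


class InfeasibleTarget(RuntimeError):
    pass


def _class_band(target_class: str, margin: float) -> tuple[float, float]:
    # (lo, hi) open interval the delta-G must fall in
    if target_class == "none":
        return (SD_THRESHOLD + margin, 1.0)
    if target_class == "sd":
        return (STRONG_SD_THRESHOLD + margin, SD_THRESHOLD - margin)
    if target_class == "strong_sd":
        return (-1e9, STRONG_SD_THRESHOLD - margin)
    raise ValueError(f"unknown SD class {target_class!r}")


def _revcomp_rna(s: str) -> str:
    return s.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def sample_sd_window(target_class: str, anti_sd: str = DEFAULT_ANTI_SD,
                     model: EnergyModel | None = None, seed=0,
                     width: int = 12, margin: float = 0.5,
                     fixed: dict[int, str] | None = None,
                     validator=None, max_tries: int = 10000) -> str:
    """Rejection-sample a window whose hybridization energy hits a class.

    For ``sd`` and ``strong_sd`` targets a complementary core of the anti-SD
    is seeded at a random position before rejection against the free-energy
    band; the ``margin`` (kcal/mol) keeps sampled energies away from both
    class boundaries so classification recovery is exact. ``fixed`` pins
    window positions to given RNA bases (used when a window overlaps fixed
    genome features); ``validator`` may veto candidates for caller-specific
    constraints. Raises :class:`InfeasibleTarget` after ``max_tries``.
    """
    model = model or default_energy_model()
    rng = _rng(seed)
    fixed = fixed or {}
    lo, hi = _class_band(target_class, margin)
    core_lens = {"none": (), "sd": (5, 6), "strong_sd": (7, 8)}[target_class]
    for _ in range(max_tries):
        chars = list(rng.choice(list(RNA), size=width))
        if core_lens:
            clen = int(rng.choice(core_lens))
            a0 = int(rng.integers(0, len(anti_sd) - clen + 1))
            core = _revcomp_rna(anti_sd[a0:a0 + clen])
            p0 = int(rng.integers(0, width - clen + 1))
            chars[p0:p0 + clen] = list(core)
        for idx, base in fixed.items():
            chars[idx] = base
        window = "".join(chars)
        dg = duplex_delta_g(window, anti_sd, model)
        if not lo < dg < hi:
            continue
        if validator is not None and not validator(window):
            continue
        return window
    raise InfeasibleTarget(
        f"no {target_class} window against {anti_sd} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Genome generation


@dataclass
class PlantedJunction:
    upstream: str
    downstream: str
    kind: str  # "overlap4", "overlap1", "gap"
    distance: int


@dataclass
class TruthManifest:
    seed: int
    n_genes: int
    f_overlap4: float
    f_overlap1: float
    gap_mean: float
    lead_gap_fraction: float
    sd_mix: dict[str, float]
    sd_margin: float
    sd_class_by_gene: dict[str, str] = field(default_factory=dict)
    junctions: list[PlantedJunction] = field(default_factory=list)
    leading_gene_ids: list[str] = field(default_factory=list)

    @property
    def overlap_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for j in self.junctions:
            if j.distance < 0:
                hist[-j.distance] = hist.get(-j.distance, 0) + 1
        return hist

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "n_genes": self.n_genes,
            "f_overlap4": self.f_overlap4, "f_overlap1": self.f_overlap1,
            "gap_mean": self.gap_mean,
            "lead_gap_fraction": self.lead_gap_fraction,
            "sd_mix": self.sd_mix, "sd_margin": self.sd_margin,
            "sd_class_by_gene": self.sd_class_by_gene,
            "junctions": [vars(j) for j in self.junctions],
            "leading_gene_ids": self.leading_gene_ids,
        }


@dataclass
class _GeneSpec:
    gene_id: str
    n_codons: int
    sd_class: str
    junction: str | None = None  # junction to the NEXT gene in the run
    gap: int = 0


def _write_codon(arr: list[str], c: int, rng, write_from: int,
                 forbid: tuple[str, ...] = STOP_CODONS) -> None:
    """Randomize the free bases of codon [c, c+3), avoiding ``forbid``."""
    free = [i for i in range(c, c + 3) if i >= write_from]
    if not free:
        return
    for _ in range(100):
        for i in free:
            arr[i] = DNA[int(rng.integers(4))]
        if "".join(arr[c:c + 3]) not in forbid:
            return
    raise RuntimeError("could not place a non-forbidden codon")


def _build_run(specs: list[_GeneSpec], rng, anti_sd: str,
               model: EnergyModel, sd_margin: float
               ) -> tuple[str, list[tuple[int, int]]]:
    """Build one co-directional run in local forward orientation.

    Returns the run sequence (DNA, includes a 12-nt leader holding the first
    gene's SD window) and local (start, end) coordinates per gene.
    """
    width = 12
    # layout
    coords: list[tuple[int, int]] = []
    pos = width
    for g in specs:
        L = 3 * g.n_codons
        coords.append((pos, pos + L))
        e = pos + L
        if g.junction == "overlap4":
            pos = e - 4
        elif g.junction == "overlap1":
            pos = e - 1
        elif g.junction == "gap":
            pos = e + g.gap
        else:
            pos = e
    run_len = coords[-1][1]
    arr = [DNA[int(b)] for b in rng.integers(4, size=run_len)]

    # ORFs, in translation order
    for i, (s, e) in enumerate(coords):
        write_from = s if i == 0 or specs[i - 1].junction == "gap" \
            else coords[i - 1][1]
        arr[s], arr[s + 1], arr[s + 2] = "A", "T", "G"
        for c in range(s + 3, e - 3, 3):
            _write_codon(arr, c, rng, write_from)
        if specs[i].junction == "overlap4":
            # junction needs the last body codon to end in A (the shared
            # base of the downstream ATG)
            arr[e - 6:e - 3] = list(
                _SAFE_A_CODONS[int(rng.integers(len(_SAFE_A_CODONS)))])
        arr[e - 3:e] = list("TGA")

    # SD windows, after all coding sequence is in place
    for i, (s, e) in enumerate(coords):
        wstart = s - width
        fixed: dict[int, str] = {}
        validator = None
        if i > 0:
            ps, pe = coords[i - 1]
            for p in range(max(pe - 3, wstart), min(pe, s)):
                fixed[p - wstart] = arr[p].replace("T", "U")

            def validator(window: str, _ps=ps, _pe=pe, _w=wstart, _s=s):
                scratch = arr[:]
                scratch[_w:_s] = list(window.replace("U", "T"))
                for c in range(_ps + 3, _pe - 3, 3):
                    if c + 3 > _w and c < _s \
                            and "".join(scratch[c:c + 3]) in STOP_CODONS:
                        return False
                return True

        window = sample_sd_window(specs[i].sd_class, anti_sd, model, rng,
                                  width=width, margin=sd_margin, fixed=fixed,
                                  validator=validator)
        arr[wstart:s] = list(window.replace("U", "T"))
    return "".join(arr), coords


def _revcomp_dna(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_genome(n_genes: int = 2000, f_overlap4: float = 0.15,
                    f_overlap1: float = 0.05, gap_mean: float = 40.0,
                    lead_gap_fraction: float = 0.15,
                    sd_mix: dict[str, float] | None = None,
                    seed: int = 0, sd_margin: float = 0.5,
                    mean_run_length: int = 20,
                    codon_range: tuple[int, int] = (20, 50),
                    lead_gap_min: int = 200,
                    model: EnergyModel | None = None
                    ) -> tuple[Genome, TruthManifest]:
    """Generate a circular genome with planted overlaps and SD classes.

    Planted overlap counts are exact: ``round(f_overlap4 * n_genes)``
    junctions carry the 4-nt ATGA overlap and ``round(f_overlap1 *
    n_genes)`` the 1-nt TGATG overlap; the remaining co-directional
    junctions draw geometric gaps (mean ``gap_mean``), a fraction
    ``lead_gap_fraction`` of which are long (>= ``lead_gap_min``) gaps that
    plant leading genes. Every gene's -12..-1 window is sampled to its
    planted SD class against the genome's own anti-SD with ``sd_margin``
    kcal/mol clearance from both thresholds.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if f_overlap4 + f_overlap1 > 1:
        raise ValueError("overlap fractions exceed 1")
    sd_mix = sd_mix or {"none": 0.3, "sd": 0.4, "strong_sd": 0.3}
    model = model or default_energy_model()
    rng = _rng(seed)

    # strand runs of geometric length, alternating strands
    run_lengths: list[int] = []
    remaining = n_genes
    while remaining > 0:
        r = min(remaining, 1 + int(rng.geometric(1.0 / mean_run_length)))
        run_lengths.append(r)
        remaining -= r
    n_junctions = n_genes - len(run_lengths)
    n_ov4 = round(f_overlap4 * n_genes)
    n_ov1 = round(f_overlap1 * n_genes)
    if n_ov4 + n_ov1 > n_junctions:
        raise ValueError(
            f"cannot place {n_ov4}+{n_ov1} overlaps in {n_junctions} "
            "co-directional junctions; lower the overlap fractions or "
            "raise mean_run_length")
    junction_kinds = (["overlap4"] * n_ov4 + ["overlap1"] * n_ov1
                      + ["gap"] * (n_junctions - n_ov4 - n_ov1))
    junction_kinds = [junction_kinds[i]
                      for i in rng.permutation(n_junctions)]

    classes = list(sd_mix)
    probs = np.array([sd_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    gene_classes = [classes[i]
                    for i in rng.choice(len(classes), size=n_genes, p=probs)]

    anti_sd = DEFAULT_ANTI_SD
    specs_by_run: list[list[_GeneSpec]] = []
    gid = 0
    jidx = 0
    for rlen in run_lengths:
        specs: list[_GeneSpec] = []
        for k in range(rlen):
            g = _GeneSpec(gene_id=f"g{gid:05d}",
                          n_codons=int(rng.integers(*codon_range)),
                          sd_class=gene_classes[gid])
            gid += 1
            if k < rlen - 1:
                kind = junction_kinds[jidx]
                jidx += 1
                g.junction = kind
                if kind == "gap":
                    # gaps of 3-6 nt put the upstream stop codon mid-window,
                    # leaving no room for the >= 7-bp helix a strong SD
                    # needs; redraw when the downstream gene plants one
                    downstream_strong = gene_classes[gid] == "strong_sd"
                    while True:
                        if rng.random() < lead_gap_fraction:
                            g.gap = lead_gap_min + int(
                                rng.geometric(1.0 / 60.0))
                        else:
                            g.gap = int(rng.geometric(1.0 / gap_mean))
                        if not (downstream_strong and 3 <= g.gap <= 6):
                            break
            specs.append(g)
        specs_by_run.append(specs)

    # assemble: spacer, 16S, then alternating-strand runs with spacers
    def spacer() -> str:
        n = int(rng.integers(80, 200))
        return "".join(DNA[int(b)] for b in rng.integers(4, size=n))

    parts: list[str] = [spacer()]
    offset = len(parts[0])
    body16s = "".join(DNA[int(b)] for b in rng.integers(4, size=147))
    seq16s = body16s + DEFAULT_16S_TAIL
    rrna = GeneRecord("rrs16S", "rRNA_16S", offset, offset + len(seq16s),
                      "+", product="16S ribosomal RNA")
    parts.append(seq16s)
    offset += len(seq16s)

    genes: list[GeneRecord] = []
    manifest = TruthManifest(
        seed=seed if isinstance(seed, int) else -1, n_genes=n_genes,
        f_overlap4=f_overlap4, f_overlap1=f_overlap1, gap_mean=gap_mean,
        lead_gap_fraction=lead_gap_fraction, sd_mix=dict(sd_mix),
        sd_margin=sd_margin)
    leading: set[str] = set()
    for run_idx, specs in enumerate(specs_by_run):
        strand = "+" if run_idx % 2 == 0 else "-"
        sp = spacer()
        parts.append(sp)
        offset += len(sp)
        run_seq, coords = _build_run(specs, rng, anti_sd, model, sd_margin)
        rl = len(run_seq)
        if strand == "+":
            parts.append(run_seq)
            for g, (s, e) in zip(specs, coords):
                genes.append(GeneRecord(g.gene_id, "CDS", offset + s,
                                        offset + e, "+"))
        else:
            parts.append(_revcomp_dna(run_seq))
            for g, (s, e) in zip(specs, coords):
                genes.append(GeneRecord(g.gene_id, "CDS", offset + rl - e,
                                        offset + rl - s, "-"))
        offset += rl
        # planted truth for this run
        leading.add(specs[0].gene_id)  # spacers guarantee >= 200 nt upstream
        for g, nxt in zip(specs, specs[1:]):
            dist = {"overlap4": -4, "overlap1": -1, "gap": g.gap}[g.junction]
            manifest.junctions.append(
                PlantedJunction(g.gene_id, nxt.gene_id, g.junction, dist))
            if g.junction == "gap" and g.gap >= lead_gap_min:
                leading.add(nxt.gene_id)
        for g in specs:
            manifest.sd_class_by_gene[g.gene_id] = g.sd_class
    parts.append(spacer())
    genome = Genome(id=f"synth{manifest.seed}", sequence="".join(parts),
                    topology="circular", genes=genes, rrnas=[rrna])
    manifest.leading_gene_ids = sorted(leading)
    return genome, manifest


# ---------------------------------------------------------------------------
# Homolog families


@dataclass
class FamilyTruth:
    genome: Genome
    query_gene_id: str
    true_five_prime: int
    annotated_five_prime: int
    true_start_column: int
    query_start_column: int
    perturbation_nt: int


def generate_homolog_family(n_homologs: int = 10, concordant: int = 8,
                            perturbation_nt: int = 6, seed: int = 0,
                            n_columns: int = 60, true_start_column: int = 12,
                            identity: float = 0.9
                            ) -> tuple[MsaFamily, FamilyTruth]:
    """A query + homologs alignment with a planted conserved start.

    ``concordant`` homolog rows place their first residue at the true start
    column; the rest scatter. The query's annotated start is displaced by
    ``perturbation_nt`` (positive: annotation downstream of the true start,
    i.e. a truncated annotation). The companion mini-genome carries the
    query CDS with an in-frame start codon at the true position and no
    competing start codon between the true and annotated starts.
    """
    if concordant > n_homologs:
        raise ValueError("concordant exceeds n_homologs")
    if perturbation_nt % 3 != 0:
        raise ValueError("perturbation_nt must be divisible by 3")
    rng = _rng(seed)
    dp = perturbation_nt // 3
    t = true_start_column
    q = t + dp
    if not (0 <= q < n_columns - 5):
        raise ValueError("perturbation pushes the annotated start out of "
                         "the alignment")

    master = [AA_ALPHABET[int(i)]
              for i in rng.integers(len(AA_ALPHABET), size=n_columns)]
    master[t] = "M"
    master[q] = "M"

    def mutate(row: list[str]) -> list[str]:
        out = row[:]
        for i in range(len(out)):
            if out[i] != "-" and rng.random() > identity:
                out[i] = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        return out

    rows: list[tuple[str, str]] = [
        ("query", "-" * q + "".join(master[q:]))]
    # discordant starts sit well clear of the true window and >= 3 columns
    # apart, so no 3-column window ever accumulates spurious support
    scatter = [c for c in range(0, n_columns - 8, 3) if abs(c - t) > 4]
    scatter = [scatter[i] for i in rng.permutation(len(scatter))]
    if n_homologs - concordant > len(scatter):
        raise ValueError("too many discordant homologs for this alignment "
                         "width")
    for h in range(n_homologs):
        if h < concordant:
            start = t
        else:
            start = scatter[h - concordant]
        body = mutate(master[start:])
        body[0] = "M"
        rows.append((f"hom{h:02d}", "-" * start + "".join(body)))
    family = MsaFamily(query_id="query", rows=rows)

    # companion nucleotide context for remapping
    flank = 60 + 3 * abs(dp)
    s_a = flank  # annotated start (plus strand)
    prot_len = n_columns - q
    e = s_a + 3 * prot_len + 3
    seq = [DNA[int(b)] for b in rng.integers(4, size=e + 30)]
    s_true = s_a - 3 * dp

    def put(pos: int, codon: str) -> None:
        seq[pos:pos + 3] = list(codon)

    # body codons: no stops; between true and annotated starts also no
    # competing start codons, so the remap target is unique
    for c in range(s_a, e - 3, 3):
        _write_codon(seq, c, rng, 0)
    put(e - 3, "TGA")
    lo, hi = sorted((s_a, s_true))
    for c in range(lo, hi, 3):
        _write_codon(seq, c, rng, 0,
                     forbid=STOP_CODONS + START_CODONS)
    put(s_true, "ATG")
    put(s_a, "ATG")
    gene = GeneRecord("query", "CDS", s_a, e, "+")
    genome = Genome(id=f"family{seed}", sequence="".join(seq),
                    topology="linear", genes=[gene])
    truth = FamilyTruth(genome=genome, query_gene_id="query",
                        true_five_prime=s_true, annotated_five_prime=s_a,
                        true_start_column=t, query_start_column=q,
                        perturbation_nt=perturbation_nt)
    return family, truth
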