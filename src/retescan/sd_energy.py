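"""Shine-Dalgarno detection by anti-SD hybridization free energy.

The anti-SD is located as the best match to the canonical core ACCUCC in the
3' tail of the 16S rRNA, extended by 1 nt on each side to 8 nt. SD presence
at a gene is then scored as the minimum hybridization free energy between
the 12-nt window immediately 5' of the start codon and the anti-SD, under a
nearest-neighbor RNA:RNA duplex model restricted to contiguous helices
(Watson-Crick stacks of Xia et al. 1998, GU wobble stacks of Mathews et al.
1999, duplex initiation +4.09 kcal/mol, +0.45 kcal/mol per terminal AU or
GU pair; no bulges or internal loops). Classes follow the published
free-energy thresholds:

    delta_G < -3.5 kcal/mol  ->  sd
    delta_G < -8.4 kcal/mol  ->  strong_sd

both strict; anything else (including genes with no scoreable window) is
class ``none``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .annotation_io import GeneRecord, Genome, reverse_complement

log = logging.getLogger(__name__)

CANONICAL_ANTI_SD_CORE = "ACCUCC"
SD_THRESHOLD = -3.5  # kcal/mol, strict
STRONG_SD_THRESHOLD = -8.4  # kcal/mol, strict

_WC_PAIRS = {"AU", "UA", "CG", "GC"}
_GU_PAIRS = {"GU", "UG"}
_TERMINAL_PENALIZED = {"AU", "UA", "GU", "UG"}


def transcribe(seq: str) -> str:
    """DNA (coding strand) to RNA."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class AntiSdMotif:
    sequence: str  # 8-nt RNA
    offset_from_3prime: int  # nt between motif 3' end and tail 3' terminus
    mismatches_to_canonical: int

    def __post_init__(self):
        if self.offset_from_3prime < 0:
            raise ValueError("offset_from_3prime must be >= 0")


@dataclass(frozen=True)
class SdCall:
    gene_id: str
    window: str | None  # 12-nt RNA, or None when no window exists
    delta_g: float | None  # kcal/mol
    sd_class: str  # none / sd / strong_sd


@dataclass
class EnergyModel:
    """Nearest-neighbor stack table plus helix-level penalties.

    ``stack_table`` maps (pair1, pair2) -> kcal/mol where each pair is a
    2-char string (mRNA base, anti-SD base) and pair2 stacks 3' of pair1 on
    the mRNA strand.
    """

    stack_table: dict[tuple[str, str], float]
    init_penalty: float = 4.09
    terminal_au_penalty: float = 0.45
    allow_gu: bool = True

    valid_pairs: set[str] = field(init=False)

    def __post_init__(self):
        self.valid_pairs = set(_WC_PAIRS)
        if self.allow_gu:
            self.valid_pairs |= _GU_PAIRS

    def is_pair(self, x: str, y: str) -> bool:
        return x + y in self.valid_pairs


def load_energy_model(path: str | Path | None = None,
                      allow_gu: bool = True) -> EnergyModel:
    """Load the packaged stack table (or an alternate TSV of the same shape).

    The file stores one orientation of each stack; the loader fills in the
    symmetric partner (a duplex read from the other end is the same duplex).
    """
    if path is None:
        source = resources.files("retescan.data").joinpath("rna_stacks.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    stacks: dict[tuple[str, str], float] = {}
    init_penalty = 4.09
    terminal_au = 0.45
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("step"):
            continue
        key, value = line.split("\t")
        value = float(value)
        if key == "init":
            init_penalty = value
        elif key == "terminal_au":
            terminal_au = value
        else:
            top, bottom = key.split("/")
            p1, p2 = top[0] + bottom[0], top[1] + bottom[1]
            stacks[(p1, p2)] = value
            # symmetric partner: reverse both strands
            stacks[(p2[::-1], p1[::-1])] = value
    return EnergyModel(stack_table=stacks, init_penalty=init_penalty,
                       terminal_au_penalty=terminal_au, allow_gu=allow_gu)


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# Anti-SD location


def find_anti_sd(tail: str, core: str = CANONICAL_ANTI_SD_CORE) -> AntiSdMotif:
    """Best match to the canonical anti-SD core in a 16S 3'-tail.

    Scans every 6-mer for the minimum Hamming distance to ``core``; ties are
    broken toward the 3' terminus, where the biological anti-SD sits. The
    match is extended by 1 nt on each side to 8 nt; extension beyond the
    tail is clipped with a warning (pass more context to avoid clipping).
    """
    tail = transcribe(tail)
    k = len(core)
    if len(tail) < 8:
        raise ValueError(f"tail of length {len(tail)} is shorter than 8 nt")
    best_pos, best_mm = None, k + 1
    for i in range(len(tail) - k + 1):
        mm = sum(a != b for a, b in zip(tail[i:i + k], core))
        if mm <= best_mm:  # <= prefers later (more 3') positions
            best_pos, best_mm = i, mm
    lo, hi = best_pos - 1, best_pos + k + 1
    if lo < 0 or hi > len(tail):
        log.warning("anti-SD extension clipped at tail boundary")
        lo, hi = max(lo, 0), min(hi, len(tail))
    return AntiSdMotif(sequence=tail[lo:hi],
                       offset_from_3prime=len(tail) - hi,
                       mismatches_to_canonical=best_mm)


def anti_sd_from_16s(seq_16s: str, tail_length: int = 13) -> AntiSdMotif:
    """Locate the anti-SD in the 3' tail of a full 16S sequence.

    Only the final ``tail_length`` nt are scanned, but the 1-nt extension may
    draw on the adjacent 16S sequence instead of clipping.
    """
    rna = transcribe(seq_16s)
    if len(rna) < tail_length:
        raise ValueError("16S sequence shorter than the requested tail")
    tail_start = len(rna) - tail_length
    k = len(CANONICAL_ANTI_SD_CORE)
    best_pos, best_mm = None, k + 1
    for i in range(tail_start, len(rna) - k + 1):
        mm = sum(a != b
                 for a, b in zip(rna[i:i + k], CANONICAL_ANTI_SD_CORE))
        if mm <= best_mm:
            best_pos, best_mm = i, mm
    # the +-1 extension may draw on 16S sequence 5' of the tail
    lo, hi = best_pos - 1, best_pos + k + 1
    if lo < 0 or hi > len(rna):
        log.warning("anti-SD extension clipped at 16S boundary")
        lo, hi = max(lo, 0), min(hi, len(rna))
    return AntiSdMotif(sequence=rna[lo:hi],
                       offset_from_3prime=len(rna) - hi,
                       mismatches_to_canonical=best_mm)


# ---------------------------------------------------------------------------
# Upstream windows


def upstream_window(genome: Genome, gene: GeneRecord,
                    width: int = 12) -> str | None:
    """The ``width`` nt immediately 5' of the start codon, as RNA.

    Returns None when a linear contig leaves fewer than ``width`` nt of
    flank; circular contigs wrap.
    """
    seq, n = genome.sequence, len(genome.sequence)
    if gene.strand == "+":
        lo, hi = gene.start - width, gene.start
        if lo < 0:
            if genome.topology != "circular":
                return None
            window = seq[lo % n:] + seq[:hi]
        else:
            window = seq[lo:hi]
    else:
        lo, hi = gene.end, gene.end + width
        if hi > n:
            if genome.topology != "circular":
                return None
            window = seq[lo:] + seq[:hi % n]
        else:
            window = seq[lo:hi]
        window = reverse_complement(window)
    return transcribe(window)


# ---------------------------------------------------------------------------
# Duplex free energy


def duplex_delta_g(window: str, anti_sd: str,
                   model: EnergyModel | None = None) -> float:
    """Minimum free energy over all contiguous-helix duplexes (kcal/mol).

    Both strings are 5'->3' RNA; the duplex is antiparallel, so window[i+k]
    pairs with anti_sd[j-k]. Every registration and every sub-helix of >= 2
    base pairs is considered; the energy of a helix is the sum of its
    nearest-neighbor stacks plus the initiation penalty plus a terminal
    penalty for each closing AU or GU pair. Returns 0.0 when no helix is
    favorable.
    """
    model = model or default_energy_model()
    w, a = window.upper(), anti_sd.upper()
    for s, name in ((w, "window"), (a, "anti_sd")):
        bad = set(s) - set("ACGU")
        if bad:
            raise ValueError(f"non-RNA characters in {name}: {sorted(bad)}")
    lw, la = len(w), len(a)
    best = 0.0
    # each diagonal d: window[i] pairs anti_sd[d - i]
    for d in range(lw + la - 1):
        i_lo, i_hi = max(0, d - la + 1), min(lw - 1, d)
        run: list[str] = []  # consecutive valid pairs along the diagonal
        for i in range(i_lo, i_hi + 2):
            pair = w[i] + a[d - i] if i <= i_hi else ""
            if i <= i_hi and pair in model.valid_pairs:
                run.append(pair)
                continue
            if len(run) >= 2:
                best = min(best, _best_subhelix(run, model))
            run = []
    return best


def _terminal(pair: str, model: EnergyModel) -> float:
    return model.terminal_au_penalty if pair in _TERMINAL_PENALIZED else 0.0


def _best_subhelix(run: list[str], model: EnergyModel) -> float:
    """Minimum energy over all sub-helices of a maximal run of valid pairs."""
    n = len(run)
    best = 0.0
    for u in range(n - 1):
        e = model.init_penalty + _terminal(run[u], model)
        for v in range(u + 1, n):
            e += model.stack_table[(run[v - 1], run[v])]
            best = min(best, e + _terminal(run[v], model))
    return best


def classify_sd(delta_g: float | None) -> str:
    """Map a hybridization free energy to its SD class (strict thresholds)."""
    if delta_g is None:
        return "none"
    if delta_g < STRONG_SD_THRESHOLD:
        return "strong_sd"
    if delta_g < SD_THRESHOLD:
        return "sd"
    return "none"


def call_sd(genome: Genome, anti_sd: str | None = None,
            model: EnergyModel | None = None, width: int = 12,
            tail_length: int = 13) -> list[SdCall]:
    """Per-CDS SD calls for a genome.

    When ``anti_sd`` is not given it is located in the genome's first
    annotated 16S rRNA. Windows containing ambiguity characters are scored
    as class ``none`` (the energy model is defined on A/C/G/U only).
    """
    model = model or default_energy_model()
    if anti_sd is None:
        if not genome.rrnas:
            raise ValueError(f"genome {genome.id} has no 16S rRNA annotation")
        r = genome.rrnas[0]
        seq16 = r.coding_sequence(genome.sequence)
        anti_sd = anti_sd_from_16s(seq16, tail_length=tail_length).sequence
    calls = []
    for gene in genome.cds:
        window = upstream_window(genome, gene, width=width)
        if window is None:
            calls.append(SdCall(gene.gene_id, None, None, "none"))
            continue
        if set(window) - set("ACGU"):
            log.warning("gene %s: ambiguity in SD window, scored as none",
                        gene.gene_id)
            calls.append(SdCall(gene.gene_id, window, None, "none"))
            continue
        dg = duplex_delta_g(window, anti_sd, model)
        calls.append(SdCall(gene.gene_id, window, dg, classify_sd(dg)))
    return calls
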