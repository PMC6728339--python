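"""Identity clustering, homolog-set selection, consensus starts, remapping."""

import numpy as np
import pytest

from retescan.annotation_io import GeneRecord, Genome, MsaFamily
from retescan.homology import (ConsensusStart, cluster_loose, cluster_tight,
                               consensus_codon_offset, global_identity,
                               rank_hits, reannotate_genome, remap_start,
                               scan_consensus_start, select_homolog_set,
                               select_representatives)
from retescan.synthetic import generate_homolog_family

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=100):
    return "".join(AA[i] for i in rng.integers(20, size=n))


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = AA[(AA.index(out[p]) + 1) % 20]
    return "".join(out)


def _hamming_identity(a, b):
    # independent oracle for equal-length, substitution-only pairs: a global
    # alignment of such pairs is gapless, so identity = matching positions
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestGlobalIdentity:
    def test_matches_hamming_oracle_on_substitution_pairs(self):
        # sparse substitutions keep the gapless alignment uniquely optimal;
        # dense ones admit equal-cost alignments that trade two mismatches
        # for an indel pair, where identity is alignment-dependent
        rng = np.random.default_rng(1)
        for _ in range(20):
            base = _random_protein(rng)
            k = int(rng.integers(0, 9))
            mutant = _mutate(base, rng.choice(100, size=k, replace=False))
            assert global_identity(base, mutant) == pytest.approx(
                _hamming_identity(base, mutant))

    def test_gaps_count_against_identity(self):
        # 3 aligned columns, 1 deletion: 3 matches / 4 columns
        assert global_identity("MKTA", "MKT") == pytest.approx(3 / 4)


class TestClustering:
    def test_identical_sequences_form_one_cluster(self):
        cl = cluster_tight([("a", "MKTLLV"), ("b", "MKTLLV")])
        assert len(cl) == 1 and sorted(cl[0].members) == ["a", "b"]

    def test_95_percent_pair_joins_at_tight_threshold(self):
        rng = np.random.default_rng(2)
        base = _random_protein(rng)
        near = _mutate(base, rng.choice(100, size=5, replace=False))
        cl = cluster_tight([("a", base), ("b", near)])
        assert len(cl) == 1

    def test_80_percent_pair_splits_at_tight_threshold(self):
        rng = np.random.default_rng(3)
        base = _random_protein(rng)
        far = _mutate(base, rng.choice(100, size=20, replace=False))
        cl = cluster_tight([("a", base), ("b", far)])
        assert len(cl) == 2

    def test_60_percent_pair_joins_loose(self):
        rng = np.random.default_rng(4)
        base = _random_protein(rng)
        mid = _mutate(base, rng.choice(100, size=40, replace=False))
        cl = cluster_loose([("a", base), ("b", mid)], rep720_ids={"a"})
        assert len(cl) == 1

    def test_loose_cluster_without_reference_members_discarded(self):
        rng = np.random.default_rng(5)
        base = _random_protein(rng)
        other = _random_protein(rng)
        cl = cluster_loose([("a", base), ("b", other)], rep720_ids={"a"})
        assert all("a" in c.members for c in cl)
        assert not any("b" in c.members for c in cl)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        prots = [(f"p{i}", _random_protein(rng, int(rng.integers(60, 120))))
                 for i in range(15)]
        c1 = cluster_tight(prots)
        c2 = cluster_tight(list(prots))
        assert [(c.representative, c.members) for c in c1] == \
               [(c.representative, c.members) for c in c2]

    def test_members_meet_threshold_to_representative(self):
        # clustering contract checked with the hamming oracle on
        # substitution-only synthetic families of equal length
        rng = np.random.default_rng(7)
        prots = []
        for fam in range(4):
            base = _random_protein(rng)
            prots.append((f"f{fam}base", base))
            for j in range(3):
                k = int(rng.integers(0, 9))
                prots.append((f"f{fam}m{j}", _mutate(
                    base, rng.choice(100, size=k, replace=False))))
        seqs = dict(prots)
        for cl in cluster_tight(prots, identity=0.90):
            rep = seqs[cl.representative]
            for m in cl.members:
                assert _hamming_identity(seqs[m], rep) >= 0.90


class TestRepresentatives:
    def test_all_reference_members_emitted(self):
        from retescan.homology import ProteinCluster
        cl = ProteinCluster("c", "tight", ["a", "b", "c", "d"], "a")
        reps = select_representatives([cl], {"a", "b", "c"},
                                      {m: "M" * 10 for m in cl.members})
        assert reps == ["a", "b", "c"]

    def test_longest_member_when_no_reference(self):
        from retescan.homology import ProteinCluster
        cl = ProteinCluster("c", "tight", ["x", "y"], "x")
        reps = select_representatives([cl], set(),
                                      {"x": "M" * 120, "y": "M" * 140})
        assert reps == ["y"]

    def test_singleton_cluster_emits_its_member(self):
        from retescan.homology import ProteinCluster
        cl = ProteinCluster("c", "tight", ["only"], "only")
        assert select_representatives([cl], set(), {"only": "MKT"}) == ["only"]


class TestHomologSet:
    def test_twelve_hits_keep_best_ten(self):
        hits = [(f"h{i:02d}", 0.95 - 0.01 * i) for i in range(12)]
        hs = select_homolog_set("q", hits)
        assert [h for h, _ in hs.homologs] == [f"h{i:02d}" for i in range(10)]

    def test_exactly_ten_hits_rejected(self):
        hits = [(f"h{i}", 0.9) for i in range(10)]
        assert select_homolog_set("q", hits) is None

    def test_no_hits_rejected(self):
        assert select_homolog_set("q", []) is None

    def test_rank_hits_drops_identical_sequences(self):
        rng = np.random.default_rng(8)
        base = _random_protein(rng)
        near = _mutate(base, [0, 1])
        ranked = rank_hits("q", [("dup", base), ("h1", near), ("h2", near)],
                           query_seq=base)
        assert [r for r, _ in ranked] == ["h1"]  # dup == query, h2 == h1


def _family(rows, query="q"):
    return MsaFamily(query_id=query, rows=rows)


class TestScanConsensusStart:
    def test_seven_of_ten_in_one_window(self):
        ncol = 30
        rows = [("q", "-" * 13 + "M" * (ncol - 13))]
        for i in range(7):
            rows.append((f"c{i}", "-" * 13 + "M" * (ncol - 13)))
        for i, col in enumerate((2, 20, 26)):
            rows.append((f"d{i}", "-" * col + "M" * (ncol - col)))
        cs = scan_consensus_start(_family(rows))
        assert cs.support == 7
        assert cs.consensus_column == 13
        assert 13 in cs.window_columns

    def test_support_four_returns_none(self):
        ncol = 30
        rows = [("q", "-" * 13 + "M" * 17)]
        for i in range(4):
            rows.append((f"c{i}", "-" * 13 + "M" * 17))
        for i, col in enumerate((0, 4, 8, 20, 24, 28)):
            rows.append((f"d{i}", "-" * col + "M" * (ncol - col) if col < 29
                         else "-" * 28 + "MM"))
        assert scan_consensus_start(_family(rows)) is None

    def test_proximity_to_query_start_breaks_window_ties(self):
        # qualifying windows near columns 3-5 and 30-32; query starts at 31
        ncol = 40
        rows = [("q", "-" * 31 + "M" * 9)]
        for i in range(5):
            rows.append((f"a{i}", "-" * 4 + "M" * 36))
        for i in range(5):
            rows.append((f"b{i}", "-" * 31 + "M" * 9))
        cs = scan_consensus_start(_family(rows))
        assert cs.consensus_column == 31

    def test_query_row_not_counted_as_support(self):
        rows = [("q", "-" * 10 + "M" * 10)]
        for i in range(4):
            rows.append((f"c{i}", "-" * 10 + "M" * 10))
        # 4 homolog votes + the query itself must NOT reach support 5
        assert scan_consensus_start(_family(rows)) is None


class TestRemapStart:
    def _gene_genome(self, upstream_codons, annotated_codons):
        """Plus-strand gene; returns (genome, gene). ``upstream_codons`` sit
        5' of the annotated start (nearest last)."""
        flank = "C" * 30
        up = "".join(upstream_codons)
        body = "ATG" + "GCC" * max(annotated_codons - 2, 1) + "TGA"
        seq = flank + up + body + "C" * 30
        s = len(flank) + len(up)
        gene = GeneRecord("q", "CDS", s, s + len(body), "+")
        return Genome(id="t", sequence=seq, genes=[gene]), gene

    def _consensus(self, gene_start_col, consensus_col, row):
        return ConsensusStart("q", (0, 1, 2), 7, consensus_col,
                              gene_start_col, row)

    def test_upstream_choice_minimizes_extension(self):
        # consensus 6 codons upstream; in-frame ATG at -6 and GTG at -3:
        # the start closest to the annotation (-3) wins
        genome, gene = self._gene_genome(
            ["ATG", "CCC", "CCC", "GTG", "CCC", "CCC"], 10)
        cs = self._consensus(gene_start_col=6, consensus_col=0,
                             row="-" * 6 + "M" * 11)
        new5 = remap_start(genome, gene, cs)
        assert new5 == gene.start - 9  # the GTG three codons up

    def test_downstream_choice_minimizes_loss(self):
        # consensus 5 codons downstream; in-frame ATG at +2 and +5
        flank = "C" * 30
        body = ("ATG" + "CCC" + "ATG" + "CCC" + "CCC" + "ATG"
                + "GCC" * 6 + "TGA")
        seq = flank + body + "C" * 30
        gene = GeneRecord("q", "CDS", 30, 30 + len(body), "+")
        genome = Genome(id="t", sequence=seq, genes=[gene])
        cs = self._consensus(gene_start_col=0, consensus_col=5,
                             row="M" * 13)
        assert remap_start(genome, gene, cs) == gene.start + 6

    def test_consensus_at_annotation_is_unchanged(self):
        genome, gene = self._gene_genome([], 10)
        cs = self._consensus(5, 5, "-" * 5 + "M" * 10)
        assert remap_start(genome, gene, cs) is None

    def test_no_start_codon_in_interval_is_unchanged(self):
        genome, gene = self._gene_genome(["CCC", "CCC"], 10)
        cs = self._consensus(2, 0, "-" * 2 + "M" * 10)
        assert remap_start(genome, gene, cs) is None

    def test_codon_offset_counts_query_residues_downstream(self):
        # a gap inside the query row must not count as a codon
        cs = self._consensus(0, 6, "MM-MMM" + "M" * 10)
        assert consensus_codon_offset(cs) == 5


class TestPipelineRecovery:
    def test_planted_true_start_recovered(self):
        fam, truth = generate_homolog_family(concordant=8, perturbation_nt=6,
                                             seed=77)
        cs = scan_consensus_start(fam)
        gene = truth.genome.gene("query")
        assert remap_start(truth.genome, gene, cs) == truth.true_five_prime

    def test_reannotation_is_idempotent(self):
        fam, truth = generate_homolog_family(concordant=8, perturbation_nt=-6,
                                             seed=78)
        gene = truth.genome.gene("query")
        cs = scan_consensus_start(fam)
        new5 = remap_start(truth.genome, gene, cs)
        assert new5 == truth.true_five_prime
        # second pass: the realigned query starts at the consensus column
        fam.start_column["query"] = truth.true_start_column
        cs2 = scan_consensus_start(fam)
        assert cs2.consensus_column == truth.true_start_column
        assert consensus_codon_offset(cs2) == 0

    def test_reannotated_gene_keeps_stop_and_frame(self):
        fam, truth = generate_homolog_family(concordant=9, perturbation_nt=9,
                                             seed=79)
        gene = truth.genome.gene("query")
        cs = scan_consensus_start(fam)
        new5 = remap_start(truth.genome, gene, cs)
        from retescan.annotation_io import apply_reannotation
        updated = apply_reannotation(truth.genome, [("query", new5)])
        moved = updated.gene("query")
        assert moved.end == gene.end
        assert (moved.end - moved.start) % 3 == 0

    def test_report_records_direction(self):
        fam, truth = generate_homolog_family(concordant=8, perturbation_nt=6,
                                             seed=80)
        report = reannotate_genome(truth.genome, {"query": fam})
        (rec,) = report
        assert rec["direction"] == "upstream"
        assert rec["new_start"] == truth.true_five_prime
        assert rec["support"] == 8
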