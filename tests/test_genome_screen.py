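"""Seed-and-extend alignment, cluster screening, synteny, fragmentation,
ANI and the phenotype rules, checked against planted ground truth."""

import itertools
import math

import numpy as np
import pytest

from ticksay.datasets import (
    AFLATOXIN_B1_MG_KG,
    AFLATOXIN_B2_MG_KG,
    AFLF_ACTIVE_SITE_POSITION,
    AFLF_FRAGMENT_SPANS,
    AFLF_GENE_LENGTH_BP,
    SCLEROTIUM_DIAMETER_UM,
)
from ticksay.genome_screen import (
    AlignParams,
    FragmentationReport,
    Sequence,
    ani_fragment,
    chemotype_inference,
    classify_morphotype,
    cluster_screen,
    fold_difference,
    fragmentation_report,
    gene_report,
    local_align_hits,
    synteny_concordance,
)
from ticksay.synthetic_data import (
    AFLATOXIN_CLUSTER_GENES,
    ClusterPlantSpec,
    generate_cluster_genome,
    generate_genome_pair,
)


class TestSequence:
    def test_uppercases_and_validates(self):
        s = Sequence("x", "acgtn")
        assert s.residues == "ACGTN"
        with pytest.raises(ValueError):
            Sequence("x", "ACGU")
        with pytest.raises(ValueError):
            Sequence("x", "")

    def test_reverse_complement(self):
        assert Sequence("x", "AACGT").reverse_complement().residues == "ACGTT"


class TestLocalAlign:
    def test_self_substring_full_identity(self):
        pair = generate_genome_pair(4000, 0.0, seed=1)
        query = Sequence("q", pair.a.residues[1000:1500])
        hits = local_align_hits(query, pair.a)
        top = hits[0]
        assert top.pct_identity == 100.0
        assert top.align_length == 500
        assert (top.q_start, top.q_end) == (1, 500)
        assert (top.s_start, top.s_end) == (1001, 1500)

    @pytest.mark.parametrize("mu", [0.01, 0.05, 0.10])
    def test_planted_substitution_identity_recovery(self, mu):
        # identity of the top hit tracks the planted substitution rate
        pair = generate_genome_pair(20000, mu, seed=3)
        hits = local_align_hits(pair.a, pair.b)
        assert hits[0].pct_identity == pytest.approx(100 * (1 - mu), abs=0.5)

    def test_reverse_complement_hit_coordinates(self):
        pair = generate_genome_pair(4000, 0.0, seed=4)
        query = Sequence("q", pair.a.residues[2000:2600])
        hits = local_align_hits(query, pair.a.reverse_complement())
        top = hits[0]
        assert top.minus_strand
        assert top.s_start > top.s_end
        assert top.pct_identity == 100.0
        # the minus-strand span maps back to the planted location
        assert (top.s_end, top.s_start) == (1401, 2000)

    def test_query_shorter_than_word_size(self):
        pair = generate_genome_pair(2000, 0.0, seed=5)
        assert local_align_hits(Sequence("q", "ACGTACG"), pair.a) == []

    def test_unrelated_sequences_no_hits(self):
        a = generate_genome_pair(3000, 0.0, seed=6).a
        b = generate_genome_pair(3000, 0.0, seed=7).a
        query = Sequence("q", b.residues[:1000])
        assert all(h.align_length < 100 for h in local_align_hits(query, a))


class TestGeneReport:
    def test_gene_present_verbatim(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(gene_names=("aflC", "aflR"), mu=0.0, seed=8)
        )
        rep = gene_report(pc.genes[0], pc.genome)
        assert rep.coverage_pct == 100.0
        assert rep.identity_pct == pytest.approx(100.0)
        assert rep.complete

    def test_half_deleted_gene_incomplete(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                gene_names=("aflF", "aflR"),
                gene_lengths=(1000, 1500),
                mu=0.0,
                seed=9,
                deletions={"aflF": ((1, 500),)},
            )
        )
        rep = gene_report(pc.genes[0], pc.genome)
        assert rep.coverage_pct == pytest.approx(50.0, abs=2.0)
        assert not rep.complete

    def test_absent_gene_zero_coverage(self):
        genome = generate_genome_pair(5000, 0.0, seed=10).a
        gene = generate_genome_pair(5000, 0.0, seed=11).a
        rep = gene_report(Sequence("g", gene.residues[:1200]), genome)
        assert rep.coverage_pct < 10.0
        assert not rep.complete

    def test_coverage_monotone_in_deletion_size(self):
        coverages = []
        for cut in (0, 250, 500, 750):
            deletions = {"aflF": ((1, cut),)} if cut else {}
            pc = generate_cluster_genome(
                ClusterPlantSpec(
                    gene_names=("aflF", "aflR"),
                    gene_lengths=(1000, 1500),
                    mu=0.0,
                    seed=12,
                    deletions=deletions,
                )
            )
            coverages.append(gene_report(pc.genes[0], pc.genome).coverage_pct)
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))


class TestClusterScreen:
    def test_intact_cluster_complete_and_colinear(self):
        pc = generate_cluster_genome(ClusterPlantSpec(mu=0.0, seed=13))
        rep = cluster_screen(pc.genes, pc.genome, cluster_name="aflatoxin")
        assert all(g.complete for g in rep.gene_reports)
        assert rep.mean_identity_pct == pytest.approx(100.0)
        assert rep.colinear and rep.synteny_tau == pytest.approx(1.0)

    def test_mutated_cluster_recovers_planted_identity(self):
        pc = generate_cluster_genome(ClusterPlantSpec(mu=0.04, seed=14))
        rep = cluster_screen(pc.genes, pc.genome)
        assert rep.mean_identity_pct == pytest.approx(
            pc.truth.realized_identity.mean(), abs=0.5
        )
        assert rep.mean_identity_pct == pytest.approx(96.0, abs=1.0)

    def test_two_half_deleted_genes_flagged(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                mu=0.02,
                seed=15,
                gene_lengths=tuple([1200] * 29),
                deletions={
                    "aflF": ((1, 600),),
                    "aflU": ((1, 170),),
                },
            )
        )
        rep = cluster_screen(pc.genes, pc.genome)
        incomplete = {g.gene for g in rep.gene_reports if not g.complete}
        assert incomplete == {"aflF", "aflU"}

    def test_reversed_gene_order_anti_colinear(self):
        names = AFLATOXIN_CLUSTER_GENES[:6]
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                gene_names=names, mu=0.0, seed=16, order=tuple(range(5, -1, -1))
            )
        )
        rep = cluster_screen(pc.genes, pc.genome)
        assert rep.synteny_tau == pytest.approx(-1.0)
        assert rep.colinear

    def test_rejects_single_gene(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(gene_names=("aflC", "aflR"), mu=0.0, seed=17)
        )
        with pytest.raises(ValueError):
            cluster_screen(pc.genes[:1], pc.genome)


class TestSynteny:
    @staticmethod
    def _brute_force_tau(order):
        n = len(order)
        concordant = discordant = 0
        for (i, a), (j, b) in itertools.combinations(enumerate(order), 2):
            if (a - b) * (i - j) > 0:
                concordant += 1
            else:
                discordant += 1
        return (concordant - discordant) / (n * (n - 1) / 2)

    @pytest.mark.parametrize(
        "order",
        [
            (0, 1, 2, 3, 4),
            (1, 0, 2, 3, 4),
            (4, 3, 2, 1, 0),
            (2, 0, 3, 1, 4),
            (0, 2, 1, 4, 3, 5, 6, 7),
        ],
    )
    def test_tau_matches_brute_force(self, order):
        names = AFLATOXIN_CLUSTER_GENES[: len(order)]
        pc = generate_cluster_genome(
            ClusterPlantSpec(gene_names=names, mu=0.0, seed=18, order=tuple(order))
        )
        rep = cluster_screen(pc.genes, pc.genome)
        # planted order maps reference index -> genomic slot
        slot_of = {gi: slot for slot, gi in enumerate(order)}
        expected = self._brute_force_tau([slot_of[i] for i in range(len(order))])
        assert rep.synteny_tau == pytest.approx(expected)

    def test_adjacent_swap_among_five(self):
        # one adjacent swap among 5 genes: tau = 1 - 2/10
        assert self._brute_force_tau([1, 0, 2, 3, 4]) == pytest.approx(0.8)

    def test_needs_two_placed_genes(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(gene_names=("aflC", "aflR"), mu=0.0, seed=19)
        )
        rep = gene_report(pc.genes[0], pc.genome)
        with pytest.raises(ValueError, match="synteny undefined"):
            synteny_concordance([rep])


class TestFragmentation:
    def test_single_full_length_hit(self):
        report = FragmentationReport.from_spans("aflF", 1149, [(1, 1149)])
        assert report.lengths == (1149,)
        assert report.missing_prefix == 0
        assert report.missing_suffix == 0

    def test_published_aflf_fragment_bookkeeping(self):
        report = FragmentationReport.from_spans(
            "aflF", AFLF_GENE_LENGTH_BP, AFLF_FRAGMENT_SPANS
        )
        assert report.lengths == (364, 221)
        assert report.overlaps == (9,)
        assert report.missing_prefix == 574
        assert not report.covers_position(AFLF_ACTIVE_SITE_POSITION)

    def test_disjoint_fragments(self):
        report = FragmentationReport.from_spans("g", 400, [(1, 100), (201, 300)])
        assert report.overlaps == (0,)
        assert report.missing_prefix == 0
        assert report.missing_suffix == 100

    def test_length_conservation_on_full_tilings(self, rng):
        # missing_prefix + sum(lengths) - sum(overlaps) + missing_suffix = L
        for _ in range(50):
            length = int(rng.integers(200, 3000))
            cuts = sorted(
                set(rng.integers(2, length, size=int(rng.integers(0, 4))))
            )
            spans, start = [], 1
            for cut in cuts:
                overlap = int(rng.integers(0, 20))
                spans.append((start, min(length, cut + overlap)))
                start = cut + 1
            spans.append((start, length))
            report = FragmentationReport.from_spans("g", length, spans)
            assert (
                report.missing_prefix
                + sum(report.lengths)
                - sum(report.overlaps)
                + report.missing_suffix
                == length
            )

    def test_fragmented_gene_hits_project_back(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                gene_names=("aflF", "aflR"),
                gene_lengths=(1149, 1500),
                mu=0.0,
                seed=20,
                deletions={"aflF": ((1, 574),)},
            )
        )
        rep = gene_report(pc.genes[0], pc.genome)
        frag = fragmentation_report(pc.genes[0], rep.hits)
        assert frag.missing_prefix >= 570  # 5' deletion projected back
        assert not frag.covers_position(207)

    def test_unhit_gene_rejected(self):
        with pytest.raises(ValueError, match="unhit"):
            fragmentation_report(1149, [])


class TestANI:
    def test_self_ani_is_exactly_100(self):
        genome = generate_genome_pair(20000, 0.0, seed=21).a
        result = ani_fragment(genome, genome)
        assert result.ani_pct == 100.0
        assert result.fragments_mapped == result.fragments_total

    def test_monotone_decrease_with_divergence(self):
        anis = []
        for mu in (0.0, 0.02, 0.05, 0.10):
            pair = generate_genome_pair(60000, mu, seed=22)
            anis.append(ani_fragment(pair.a, pair.b).ani_pct)
        assert all(a > b for a, b in zip(anis, anis[1:]))

    def test_close_strain_regime(self):
        pair = generate_genome_pair(60000, 0.008, seed=23)
        result = ani_fragment(pair.a, pair.b)
        assert result.ani_pct == pytest.approx(99.2, abs=0.2)

    def test_unrelated_genomes_undefined(self):
        a = generate_genome_pair(10000, 0.0, seed=24).a
        b = generate_genome_pair(10000, 0.0, seed=25).a
        result = ani_fragment(a, b)
        assert result.fragments_mapped == 0
        assert math.isnan(result.ani_pct)
        assert not result.defined

    def test_query_must_exceed_fragment_length(self):
        genome = generate_genome_pair(2000, 0.0, seed=26).a
        with pytest.raises(ValueError):
            ani_fragment(genome, genome, fragment_len=3000)


class TestPhenotypeRules:
    def test_isolate_diameter_is_morphotype_L(self):
        assert classify_morphotype(SCLEROTIUM_DIAMETER_UM) == "L"

    @pytest.mark.parametrize("d,expected", [(399.0, "S"), (400.0, "S"), (400.1, "L")])
    def test_boundary(self, d, expected):
        assert classify_morphotype(d) == expected

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            classify_morphotype(0)

    @pytest.fixture()
    def degraded_cluster(self):
        # aflF half deleted and aflU partially deleted: the G-type genes
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                mu=0.02,
                seed=27,
                gene_lengths=tuple([1200] * 29),
                deletions={"aflF": ((1, 600),), "aflU": ((1, 170),)},
            )
        )
        return cluster_screen(pc.genes, pc.genome)

    def test_intact_cluster_is_b_plus_g(self):
        pc = generate_cluster_genome(ClusterPlantSpec(mu=0.0, seed=28))
        rep = cluster_screen(pc.genes, pc.genome)
        assert chemotype_inference(rep) == "B+G"

    def test_degraded_g_genes_give_b_only(self, degraded_cluster):
        assert chemotype_inference(degraded_cluster) == "B-only"

    def test_missing_regulator_gives_none(self):
        pc = generate_cluster_genome(
            ClusterPlantSpec(
                mu=0.0,
                seed=29,
                gene_lengths=tuple([1200] * 29),
                deletions={"aflR": ((1, 800),)},
            )
        )
        rep = cluster_screen(pc.genes, pc.genome)
        assert chemotype_inference(rep) == "none"

    def test_unknown_gene_names_rejected(self, degraded_cluster):
        with pytest.raises(ValueError, match="absent"):
            chemotype_inference(degraded_cluster, g_type_genes=("nope",))

    def test_fold_difference(self):
        assert fold_difference(AFLATOXIN_B1_MG_KG, AFLATOXIN_B2_MG_KG) == (
            pytest.approx(58.92, abs=0.005)
        )
        assert fold_difference(7.0, 7.0) == 1.0
        assert fold_difference(0.0, 7.2) == 0.0
        with pytest.raises(ValueError):
            fold_difference(1.0, 0.0)
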