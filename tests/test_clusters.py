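import numpy as np
import pytest

from nlrscan.clusters import (ClusterCriteria, call_clusters, cluster_summary,
                              exon_statistics)
from nlrscan.core_io import GeneLocus
from nlrscan.grammar import NbsGeneRecord


def _gene(gid, start, end, is_nbs, chrom="chr1", exons=1):
    return GeneLocus(gene_id=gid, chrom=chrom, start=start, end=end,
                     strand="+", is_nbs=is_nbs, exon_count=exons)


def random_toy_genome(rng, max_genes=50):
    """Random gene layout over 1-2 chromosomes with ~40% NLR genes."""
    loci = []
    gid = 0
    for chrom in ["c1", "c2"][: rng.integers(1, 3)]:
        pos = int(rng.integers(1, 10_000))
        for _ in range(rng.integers(2, max_genes // 2 + 1)):
            length = int(rng.integers(500, 8_000))
            loci.append(_gene(f"g{gid}", pos, pos + length - 1,
                              bool(rng.random() < 0.4), chrom))
            gid += 1
            pos += length + int(rng.integers(0, 300_000))
    return loci


def brute_force_clusters(loci, criteria):
    """Oracle: test every consecutive NLR pair-linkage explicitly, then chain."""
    out = []
    chroms = sorted({g.chrom for g in loci})
    for chrom in chroms:
        genes = sorted([g for g in loci if g.chrom == chrom], key=lambda g: g.start)
        nbs = [g for g in genes if g.is_nbs]
        linked = []
        for a, b in zip(nbs, nbs[1:]):
            gap = max(0, b.start - a.end)
            between = len([g for g in genes
                           if not g.is_nbs and g.start > a.start and g.start < b.start])
            linked.append(gap < criteria.max_gap_bp
                          and between <= criteria.max_intervening)
        run = [nbs[0]] if nbs else []
        for ok, g in zip(linked, nbs[1:]):
            if ok:
                run.append(g)
            else:
                if len(run) >= 2:
                    out.append(tuple(x.gene_id for x in run))
                run = [g]
        if len(run) >= 2:
            out.append(tuple(x.gene_id for x in run))
    return sorted(out)


class TestCallClusters:
    def test_pair_within_both_criteria_forms_cluster(self):
        loci = [_gene("a", 1000, 2000, True)]
        for i in range(3):
            loci.append(_gene(f"x{i}", 10_000 + 30_000 * i, 12_000 + 30_000 * i, False))
        loci.append(_gene("b", 152_000, 155_000, True))  # gap 150,000
        (cluster,) = call_clusters(loci)
        assert cluster.members == ["a", "b"]

    def test_gap_criterion_fails(self):
        loci = [_gene("a", 1000, 2000, True), _gene("b", 252_000, 255_000, True)]
        assert call_clusters(loci) == []  # gap 250,000

    def test_intervening_criterion_fails(self):
        loci = [_gene("a", 1000, 2000, True)]
        for i in range(9):
            loci.append(_gene(f"x{i}", 2_100 + 800 * i, 2_600 + 800 * i, False))
        loci.append(_gene("b", 12_000, 15_000, True))  # gap 10,000 but 9 between
        assert call_clusters(loci) == []

    @pytest.mark.parametrize("gap,expected_clusters", [(199_999, 1), (200_000, 0)])
    def test_gap_boundary_is_strict(self, gap, expected_clusters):
        loci = [_gene("a", 1000, 2000, True),
                _gene("b", 2000 + gap, 5000 + gap, True)]
        assert len(call_clusters(loci)) == expected_clusters

    @pytest.mark.parametrize("between,expected_clusters", [(8, 1), (9, 0)])
    def test_intervening_boundary_is_inclusive(self, between, expected_clusters):
        loci = [_gene("a", 1000, 2000, True)]
        for i in range(between):
            loci.append(_gene(f"x{i}", 3_000 + 1_000 * i, 3_500 + 1_000 * i, False))
        loci.append(_gene("b", 50_000, 55_000, True))
        assert len(call_clusters(loci)) == expected_clusters

    def test_matches_brute_force_oracle_on_random_genomes(self):
        criteria = ClusterCriteria()
        rng = np.random.default_rng(1234)
        for _ in range(60):
            loci = random_toy_genome(rng)
            called = sorted(tuple(c.members) for c in call_clusters(loci, criteria))
            assert called == brute_force_clusters(loci, criteria)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        loci = random_toy_genome(rng)
        shifted = [_gene(g.gene_id, g.start + 10_000_000, g.end + 10_000_000,
                         g.is_nbs, g.chrom) for g in loci]
        a = [tuple(c.members) for c in call_clusters(loci)]
        b = [tuple(c.members) for c in call_clusters(shifted)]
        assert a == b

    def test_tightening_criteria_never_adds_clustered_genes(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            loci = random_toy_genome(rng)
            loose = ClusterCriteria(200_000, 8)
            for tight in (ClusterCriteria(100_000, 8), ClusterCriteria(200_000, 4),
                          ClusterCriteria(50_000, 2)):
                n_loose = sum(len(c.members) for c in call_clusters(loci, loose))
                n_tight = sum(len(c.members) for c in call_clusters(loci, tight))
                assert n_tight <= n_loose

    def test_membership_is_a_partition(self):
        rng = np.random.default_rng(5)
        loci = random_toy_genome(rng)
        members = [m for c in call_clusters(loci) for m in c.members]
        assert len(members) == len(set(members))

    def test_duplicate_gene_ids_rejected(self):
        loci = [_gene("a", 1, 10, True), _gene("a", 100, 200, True)]
        with pytest.raises(ValueError, match="duplicate"):
            call_clusters(loci)


class TestClusterSummary:
    def test_study_scale_arithmetic(self):
        """200 clustered of 352 in 75 clusters over 17 chromosomes."""
        clusters = [type("C", (), {"members": ["x"] * n, "chrom": "c"})()
                    for n in [3] * 50 + [2] * 25]
        loci = [_gene(f"g{i}", 1 + i * 10, 5 + i * 10, True) for i in range(352)]
        s = cluster_summary(clusters, loci, n_chromosomes=17)
        assert round(s["genes_per_cluster"], 1) == 2.7
        assert round(s["clusters_per_chromosome"], 1) == 4.4
        assert round(s["pct_clustered"]) == 57

    def test_no_clusters_yields_flagged_zeros(self):
        loci = [_gene("a", 1, 10, True)]
        s = cluster_summary([], loci)
        assert s["degenerate"] and s["genes_per_cluster"] == 0.0


class TestExonStatistics:
    def test_per_group_mean(self):
        loci = [_gene("a", 1, 10, True, exons=1), _gene("b", 20, 30, True, exons=4)]
        recs = [NbsGeneRecord("a", "CNL", "CNL"), NbsGeneRecord("b", "CNL", "CNL")]
        df = exon_statistics(loci, recs)
        row = df[df.group == "CNL"].iloc[0]
        assert (row.min_exons, row.max_exons, row.mean_exons) == (1, 4, 2.5)

    def test_empty_input_empty_table(self):
        assert exon_statistics([], []).empty
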