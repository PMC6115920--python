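"""Physical NLR gene-cluster calling and exon-structure statistics.

A cluster is a chromosomal run of two or more NLR genes in which every
adjacent pair is linked, and a pair is linked iff (a) the intergenic gap is
strictly below ``max_gap_bp`` and (b) at most ``max_intervening`` annotated
non-NLR genes lie strictly between them. The defaults (200 kb, 8) are the
criteria used throughout the R-gene clustering literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core_io import GeneLocus


@dataclass(frozen=True)
class ClusterCriteria:
    max_gap_bp: int = 200_000
    max_intervening: int = 8

    def __post_init__(self) -> None:
        if self.max_gap_bp < 0 or self.max_intervening < 0:
            raise ValueError("cluster criteria must be nonnegative")


@dataclass
class GeneCluster:
    chrom: str
    members: list[str]  # gene ids sorted by start, >= 2
    span: tuple[int, int]


def pair_linked(prev: GeneLocus, nxt: GeneLocus, between: int,
                criteria: ClusterCriteria, anchor: str = "gap") -> bool:
    """Linkage test for two consecutive NLR genes on one chromosome.

    ``between`` is the count of annotated non-NLR genes strictly between
    them. ``anchor`` selects the distance convention: "gap" (end-to-start,
    negatives clamped to 0) or "start" (start-to-start).
    """
    if anchor == "gap":
        dist = max(0, nxt.start - prev.end)
    elif anchor == "start":
        dist = abs(nxt.start - prev.start)
    else:
        raise ValueError(f"unknown distance anchor {anchor!r}")
    return dist < criteria.max_gap_bp and between <= criteria.max_intervening


def call_clusters(loci: Iterable[GeneLocus],
                  criteria: ClusterCriteria = ClusterCriteria(),
                  anchor: str = "gap") -> list[GeneCluster]:
    """Cluster calls per chromosome; singletons never form clusters."""
    loci = sorted(loci, key=lambda g: (g.chrom, g.start, g.gene_id))
    ids = [g.gene_id for g in loci]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")

    clusters: list[GeneCluster] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        nbs_idx = [i for i, g in enumerate(genes) if g.is_nbs]
        run: list[GeneLocus] = []
        for k, i in enumerate(nbs_idx):
            if not run:
                run = [genes[i]]
                continue
            j = nbs_idx[k - 1]
            between = sum(1 for g in genes[j + 1:i] if not g.is_nbs)
            if pair_linked(genes[j], genes[i], between, criteria, anchor):
                run.append(genes[i])
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(chrom, run))
                run = [genes[i]]
        if len(run) >= 2:
            clusters.append(_make_cluster(chrom, run))
    return clusters


def _make_cluster(chrom: str, run: list[GeneLocus]) -> GeneCluster:
    return GeneCluster(
        chrom=chrom,
        members=[g.gene_id for g in run],
        span=(run[0].start, run[-1].end),
    )


def cluster_summary(clusters: list[GeneCluster], loci: Iterable[GeneLocus],
                    n_chromosomes: int = 17,
                    chromosome_filter=None) -> dict:
    """Summary statistics of a cluster call.

    ``clusters_per_chromosome`` divides by ``n_chromosomes``; genes on
    unplaced scaffolds still count toward totals (pass ``chromosome_filter``,
    a predicate on chromosome names, to restrict per-chromosome rows).
    Ratios are 0 (with ``degenerate=True``) when there are no clusters.
    Rounding is left to presentation; values here are exact.
    """
    loci = list(loci)
    total_nbs = sum(1 for g in loci if g.is_nbs)
    n_clusters = len(clusters)
    n_clustered = sum(len(c.members) for c in clusters)
    per_chrom: dict[str, dict] = {}
    for c in clusters:
        if chromosome_filter is not None and not chromosome_filter(c.chrom):
            continue
        row = per_chrom.setdefault(c.chrom, {"n_clusters": 0, "n_genes": 0})
        row["n_clusters"] += 1
        row["n_genes"] += c.members.__len__()
    return {
        "n_clusters": n_clusters,
        "n_clustered_genes": n_clustered,
        "total_nbs_genes": total_nbs,
        "genes_per_cluster": n_clustered / n_clusters if n_clusters else 0.0,
        "clusters_per_chromosome": n_clusters / n_chromosomes if n_chromosomes else 0.0,
        "pct_clustered": 100.0 * n_clustered / total_nbs if total_nbs else 0.0,
        "per_chromosome": per_chrom,
        "degenerate": n_clusters == 0,
    }


def exon_statistics(loci: Iterable[GeneLocus], records) -> pd.DataFrame:
    """Per-group min/max/mean exon counts for classified NLR genes.

    ``records`` supplies the protein->group mapping (NbsGeneRecord objects);
    gene and protein identifiers are assumed to coincide. Groups with no
    members are simply absent.
    """
    group_of = {r.protein_id: r.group for r in records}
    rows: dict[str, list[int]] = {}
    for g in loci:
        grp = group_of.get(g.gene_id)
        if grp is not None:
            rows.setdefault(grp, []).append(g.exon_count)
    out = pd.DataFrame(
        [
            {
                "group": grp,
                "n_genes": len(v),
                "min_exons": min(v),
                "max_exons": max(v),
                "mean_exons": sum(v) / len(v),
            }
            for grp, v in sorted(rows.items())
        ]
    )
    return out
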