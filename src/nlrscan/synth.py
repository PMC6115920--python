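"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates a compact multi-chromosome plant genome carrying a
full NLR complement: proteins are concatenations of unit blocks (an ideal
heptad coiled-coil, TIR/RPW8 placeholder blocks with matching domain-table
rows, an NB-ARC block embedding the P-loop / Kinase-2 / RNBS-B / GLPL /
MHDL motifs with planted signature residues, and LxxLxxLxx repeat blocks
with exact planted unit counts) joined by linkers drawn from an alphabet
that excludes L, D, W and the strongly hydrophobic residues, so no block
can fake another block's evidence. Genes are laid out on chromosomes so
that planted clusters satisfy both clustering criteria with margin and
everything else violates at least one.

The default blueprint mirrors a sunflower-scale NLR complement:
352 NLR genes across the 18 subgroup codes, 75 planted clusters
holding 200 genes (25 clusters / 73 genes on chromosome 13), 17 chromosomes
plus a handful of genes on an unplaced scaffold, group exon-count means
2.7/6.1/6.2/2.9, and a nominal proteome of 52,243 for percentage
denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import Alphabet, DomainHit, GeneLocus, SequenceRecord
from .kaks import CODON_TABLE, NUCLEOTIDES, STOP_CODONS, CodonAlignment, count_sites

#: Subgroup complement of the emulated genome (letter code -> gene count).
DEFAULT_SUBGROUP_COUNTS = {
    "CNL": 90, "CN": 5, "CNNL": 4, "CNN": 1,
    "RNL": 10, "RN": 1, "RCNL": 2,
    "TNL": 52, "TN": 21, "TNNL": 0, "TTNL": 1, "TNLTNL": 1, "CTNL": 1, "CTN": 1,
    "N": 29, "NL": 125, "NN": 2, "NNL": 6,
}

#: Kinase-2 signature mix per group (proportions assigned by largest remainder).
KINASE2_MIX = {
    "CNL": (("DDVW", 81), ("DDIW", 7), ("DDMW", 6), ("DDLW", 6)),
    "TNL": (("DDVD", 50), ("DDVW", 27)),
    "RNL": (("DDVW", 12), ("DDVR", 1)),
    "NL": (("DDVW", 83), ("DDVD", 18), ("DDIW", 31), ("DDMW", 30)),
}

#: RNBS-B signature per group.
RNBSB_SIG = {"CNL": "TSR", "TNL": "TTRD", "RNL": "TSR", "NL": "TSR"}

#: How many genes per group carry a planted NLS stretch.
NLS_COUNTS = {"CNL": 13, "TNL": 7, "RNL": 1, "NL": 8}

#: LxxLxxLxx unit count ranges per group for LRR-bearing architectures.
LRR_RANGES = {"CNL": (2, 22), "TNL": (2, 26), "RNL": (1, 8), "NL": (2, 30)}

DEFAULT_EXON_MEANS = {"CNL": 2.7, "TNL": 6.1, "RNL": 6.2, "NL": 2.9}

#: Linker alphabet: no L (LRR signature), no D/W (Kinase-2 dyad and W),
#: no I/V/M/F (coiled-coil core positions), no K/R (NLS basic stretches).
LINKER_ALPHABET = np.array(list("AEGHNPQSTY"))

CC_BLOCK = "LEALEGK" * 5
NLS_BLOCK = "KKKKRRRKKK"
PLOOP = "GMGGLGKTT"
GLPL = "GLPLA"
MHDL = "MHDL"

SUBGROUP_ORDER = tuple(DEFAULT_SUBGROUP_COUNTS)


def group_of_code(code: str) -> str:
    if "T" in code:
        return "TNL"
    if "R" in code:
        return "RNL"
    if "C" in code:
        return "CNL"
    return "NL"


@dataclass
class GenomeBlueprint:
    """Everything the generator needs; all randomness flows from ``seed``."""

    n_chromosomes: int = 17
    subgroup_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_COUNTS))
    #: planted clusters as (chromosome index 1-based, member count); None
    #: derives the default 75-cluster / 200-gene layout
    planted_clusters: list[tuple[int, int]] | None = None
    intra_gap: tuple[int, int] = (20_000, 150_000)       # within-cluster NBS gaps
    between_gap: tuple[int, int] = (250_000, 400_000)    # separation outside clusters
    intervening: tuple[int, int] = (0, 3)                # non-NBS genes inside gaps
    exon_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EXON_MEANS))
    n_unplaced: int = 4
    proteome_size: int = 52_243
    seed: int = 0

    def clusters(self) -> list[tuple[int, int]]:
        if self.planted_clusters is not None:
            return list(self.planted_clusters)
        # 25 clusters / 73 genes on chromosome 13, 50 clusters / 127 elsewhere:
        # 75 clusters, 200 clustered genes in total
        plan = [(13, 3)] * 23 + [(13, 2)] * 2
        other = [c for c in range(1, self.n_chromosomes + 1) if c not in (5, 12, 13)]
        sizes = [3] * 27 + [2] * 23
        plan += [(other[i % len(other)], s) for i, s in enumerate(sizes)]
        return plan


@dataclass
class PlantedGene:
    gene_id: str
    subgroup: str
    group: str
    kinase2: str
    rnbsb: str
    lrr_count: int
    has_nls: bool
    has_kelch: bool
    cluster_id: str | None
    chrom: str
    exon_count: int


@dataclass
class PlantedTruth:
    genes: dict[str, PlantedGene]
    clusters: dict[str, list[str]]

    def to_json(self, path=None) -> str:
        payload = {
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "clusters": self.clusters,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    """Integer apportionment of ``total`` by proportional weights."""
    raw = [w * total / sum(weights) for w in weights]
    out = [int(x) for x in raw]
    for i in sorted(range(len(raw)), key=lambda i: raw[i] - out[i], reverse=True):
        if sum(out) == total:
            break
        out[i] += 1
    return out


def _chrom_name(index: int) -> str:
    return f"Chr{index:02d}"


def plan_genes(bp: GenomeBlueprint) -> tuple[list[PlantedGene], dict[str, list[str]]]:
    """The deterministic gene plan shared by the proteome and genome emitters."""
    rng = np.random.default_rng(bp.seed)
    # 1. one entry per gene, grouped by subgroup code in canonical order
    entries: list[dict] = []
    for code in sorted(bp.subgroup_counts, key=lambda c: SUBGROUP_ORDER.index(c)
                       if c in SUBGROUP_ORDER else len(SUBGROUP_ORDER)):
        for _ in range(bp.subgroup_counts[code]):
            entries.append({"subgroup": code, "group": group_of_code(code)})
    # 2. Kinase-2 and RNBS-B signatures apportioned exactly within each group
    for grp, mix in KINASE2_MIX.items():
        idx = [i for i, e in enumerate(entries) if e["group"] == grp]
        counts = _largest_remainder([w for _sig, w in mix], len(idx))
        flat = [sig for (sig, _w), c in zip(mix, counts) for _ in range(c)]
        for i, sig in zip(idx, flat):
            entries[i]["kinase2"] = sig
            entries[i]["rnbsb"] = RNBSB_SIG[grp]
    # 3. LRR unit counts for L-bearing codes, NLS flags, the lone Kelch gene
    for e in entries:
        lo, hi = LRR_RANGES[e["group"]]
        e["lrr_count"] = int(rng.integers(lo, hi + 1)) if "L" in e["subgroup"] else 0
        e["has_nls"] = False
        e["has_kelch"] = False
    for grp, n in NLS_COUNTS.items():
        idx = [i for i, e in enumerate(entries) if e["group"] == grp]
        for i in idx[:n]:
            entries[i]["has_nls"] = True
    tnl_idx = [i for i, e in enumerate(entries) if e["subgroup"] == "TNL"]
    if tnl_idx:
        entries[tnl_idx[0]]["has_kelch"] = True
    # 4. placement: clustered genes first (shuffled), then singletons
    order = rng.permutation(len(entries))
    cluster_plan = bp.clusters()
    n_clustered = sum(size for _c, size in cluster_plan)
    if n_clustered > len(entries):
        raise ValueError("cluster plan asks for more genes than the blueprint has")
    per_chrom: dict[str, list[dict]] = {}
    clusters: dict[str, list[int]] = {}
    pos = 0
    for ci, (chrom_idx, size) in enumerate(cluster_plan):
        chrom = _chrom_name(chrom_idx)
        cid = f"{chrom}_cl{ci:03d}"
        members = []
        for _ in range(size):
            e = entries[order[pos]]
            pos += 1
            e["cluster_id"] = cid
            e["chrom"] = chrom
            per_chrom.setdefault(chrom, []).append(e)
            members.append(e)
        clusters[cid] = members  # resolved to ids below
    singles = [entries[i] for i in order[pos:]]
    for j, e in enumerate(singles):
        if j < bp.n_unplaced:
            e["chrom"] = "Chr00c0001"
        else:
            e["chrom"] = _chrom_name(1 + (j - bp.n_unplaced) % bp.n_chromosomes)
        e["cluster_id"] = None
        per_chrom.setdefault(e["chrom"], []).append(e)
    # 5. ids per chromosome, exon counts
    genes: list[PlantedGene] = []
    for chrom in sorted(per_chrom):
        for k, e in enumerate(per_chrom[chrom], 1):
            e["gene_id"] = f"Syn{chrom}g{k:04d}"
    for e in entries:
        mean = bp.exon_means[e["group"]]
        e["exon_count"] = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
        genes.append(
            PlantedGene(
                gene_id=e["gene_id"], subgroup=e["subgroup"], group=e["group"],
                kinase2=e["kinase2"], rnbsb=e["rnbsb"], lrr_count=e["lrr_count"],
                has_nls=e["has_nls"], has_kelch=e["has_kelch"],
                cluster_id=e["cluster_id"], chrom=e["chrom"],
                exon_count=e["exon_count"],
            )
        )
    cluster_ids = {cid: [m["gene_id"] for m in members] for cid, members in clusters.items()}
    return genes, cluster_ids


# ---------------------------------------------------------------------------
# Proteome


def _linker(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(LINKER_ALPHABET, size=n))


def _nbs_block(rng: np.random.Generator, kinase2: str, rnbsb: str) -> str:
    return "".join([
        _linker(rng, 8), PLOOP,
        _linker(rng, 9), "LL" + kinase2,
        _linker(rng, 9), "GSRIII" + rnbsb,
        _linker(rng, 9), GLPL,
        _linker(rng, 8), MHDL,
        _linker(rng, 8),
    ])


def build_protein(gene: PlantedGene,
                  rng: np.random.Generator) -> tuple[SequenceRecord, list[DomainHit]]:
    """One protein assembled block-by-block from its subgroup letter code.

    Every planted L block carries an equal share of the planted LxxLxxLxx
    units (remainder to the last block); domain-table rows are emitted for
    each C/T/R/N/L block at its realised coordinates.
    """
    code = gene.subgroup
    n_lblocks = code.count("L")
    shares = []
    if n_lblocks:
        base = gene.lrr_count // n_lblocks
        shares = [base] * n_lblocks
        shares[-1] += gene.lrr_count - base * n_lblocks
    parts: list[str] = [_linker(rng, 10)]
    hits: list[DomainHit] = []
    li = 0
    for letter in code:
        if letter == "C":
            block, kind, acc = CC_BLOCK, "CC", "CC"
        elif letter == "T":
            block, kind, acc = _linker(rng, 60), "TIR", "PF01582"
        elif letter == "R":
            block, kind, acc = _linker(rng, 50), "RPW8", "PF05659"
        elif letter == "N":
            block, kind, acc = _nbs_block(rng, gene.kinase2, gene.rnbsb), "NBS", "PF00931"
        else:  # L
            block, kind, acc = "LAALAALAA" * max(shares[li], 1), "LRR", "LRR"
            if shares[li] == 0:
                block = ""
            li += 1
        if not block:
            continue
        start = sum(len(p) for p in parts) + 1
        parts.append(block)
        hits.append(DomainHit(protein_id=gene.gene_id, kind=kind, start=start,
                              end=start + len(block) - 1, score=100.0,
                              source_accession=acc if acc.startswith("PF") else ""))
        parts.append(_linker(rng, 10))
    if gene.has_kelch:
        start = sum(len(p) for p in parts) + 1
        block = _linker(rng, 40)
        parts.append(block)
        hits.append(DomainHit(protein_id=gene.gene_id, kind="KELCH", start=start,
                              end=start + len(block) - 1, score=100.0,
                              source_accession="PF01344"))
        parts.append(_linker(rng, 6))
    if gene.has_nls:
        parts.append(NLS_BLOCK)
        parts.append(_linker(rng, 8))
    seq = SequenceRecord(id=gene.gene_id, residues="".join(parts),
                         alphabet=Alphabet.protein)
    return seq, hits


def gen_proteome(bp: GenomeBlueprint) -> tuple[list[SequenceRecord], list[DomainHit], PlantedTruth]:
    """Synthetic proteome: sequences, matching domain-table rows, ground truth."""
    genes, cluster_ids = plan_genes(bp)
    rng = np.random.default_rng(bp.seed + 1)
    seqs: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        s, h = build_protein(g, rng)
        seqs.append(s)
        hits.extend(h)
    truth = PlantedTruth(genes={g.gene_id: g for g in genes}, clusters=cluster_ids)
    return seqs, hits, truth


# ---------------------------------------------------------------------------
# Genome


def gen_genome(bp: GenomeBlueprint) -> tuple[list[GeneLocus], PlantedTruth]:
    """Gene models laid out so planted clusters (and only they) pass the criteria."""
    genes, cluster_ids = plan_genes(bp)
    rng = np.random.default_rng(bp.seed + 2)
    by_chrom: dict[str, list[PlantedGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    loci: list[GeneLocus] = []
    filler = 0
    for chrom in sorted(by_chrom):
        # ids encode the placement order: cluster members are consecutive
        members = sorted(by_chrom[chrom], key=lambda g: g.gene_id)
        cursor = int(rng.integers(10_000, 50_000))
        prev: PlantedGene | None = None
        for g in members:
            if prev is not None:
                same_cluster = (g.cluster_id is not None
                                and g.cluster_id == prev.cluster_id)
                lo, hi = bp.intra_gap if same_cluster else bp.between_gap
                gap = int(rng.integers(lo, hi + 1))
                k = int(rng.integers(bp.intervening[0], bp.intervening[1] + 1))
                for j in range(k):
                    s = cursor + ((gap - 2001) * (j + 1)) // (k + 1)
                    filler += 1
                    loci.append(GeneLocus(
                        gene_id=f"Syn{chrom}nb{filler:05d}", chrom=chrom,
                        start=s, end=s + 1999, strand="+", is_nbs=False,
                        exon_count=int(rng.integers(1, 9)),
                    ))
                # cursor sits one base past the previous gene's end, so the
                # realised end-to-start gap is exactly the drawn value
                cursor += gap - 1
            length = int(rng.integers(3_000, 8_000))
            loci.append(GeneLocus(
                gene_id=g.gene_id, chrom=chrom, start=cursor,
                end=cursor + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                is_nbs=True, exon_count=g.exon_count,
            ))
            cursor += length
            prev = g
    loci.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    truth = PlantedTruth(genes={g.gene_id: g for g in genes}, clusters=cluster_ids)
    return loci, truth


# ---------------------------------------------------------------------------
# Codon pairs with controlled divergence


def _proportion(distance: float) -> float:
    """Invert the Jukes-Cantor correction: expected raw proportion at a distance."""
    return 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    sense = sorted(set(CODON_TABLE) - STOP_CODONS)
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def _neighbors(codon: str, synonymous: bool) -> list[str]:
    out = []
    aa = CODON_TABLE[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            m = codon[:pos] + nt + codon[pos + 1:]
            if m in STOP_CODONS:
                continue
            if (CODON_TABLE[m] == aa) == synonymous:
                out.append(m)
    return out


def gen_codon_pairs(n_pairs: int, n_codons: int = 300, omega: float = 0.3,
                    ks_target: float = 0.2, seed: int = 0
                    ) -> tuple[list[CodonAlignment], list[dict]]:
    """Pairs of coding sequences with controlled synonymous/nonsynonymous divergence.

    Each pair shares a random sense-codon ancestor; the derived copy receives
    Poisson numbers of single-nucleotide synonymous and nonsynonymous codon
    changes whose expectations hit the Jukes-Cantor-implied proportions of
    ``ks_target`` and ``omega * ks_target``. No codon is mutated twice and no
    stop codons are ever created, so the realised difference counts recorded
    in the truth are exact.
    """
    rng = np.random.default_rng(seed)
    pairs: list[CodonAlignment] = []
    truth: list[dict] = []
    for i in range(n_pairs):
        anc = _random_sense_codons(rng, n_codons)
        N = S = 0.0
        for c in anc:
            n_c, s_c = count_sites(c)
            N += n_c
            S += s_c
        n_syn = int(rng.poisson(_proportion(ks_target) * S))
        n_non = int(rng.poisson(_proportion(omega * ks_target) * N))
        der = list(anc)
        available = list(rng.permutation(n_codons))
        applied_syn = applied_non = 0
        for want_syn, want_n in ((True, n_syn), (False, n_non)):
            done = 0
            rest = []
            while available and done < want_n:
                j = available.pop()
                nb = _neighbors(der[j], synonymous=want_syn)
                if not nb:
                    rest.append(j)
                    continue
                der[j] = nb[rng.integers(len(nb))]
                done += 1
            available.extend(rest)
            if want_syn:
                applied_syn = done
            else:
                applied_non = done
        pairs.append(CodonAlignment(
            id_a=f"pair{i:03d}_a", id_b=f"pair{i:03d}_b",
            seq_a="".join(anc), seq_b="".join(der),
        ))
        truth.append({"pair": i, "n_syn": applied_syn, "n_non": applied_non,
                      "N_sites": N, "S_sites": S})
    return pairs, truth


# ---------------------------------------------------------------------------
# Expression


DEFAULT_TISSUES = ("bract", "corolla", "leaves", "ligule", "ovary",
                   "pollen", "seed", "stamen", "stem")


def gen_expression(n_genes: int = 71, tissues: tuple[str, ...] = DEFAULT_TISSUES,
                   class_means: tuple[float, ...] = (20.0, 0.3, 6.0),
                   class_sizes: tuple[int, ...] = (13, 43, 15),
                   noise_sigma: float = 0.2, seed: int = 0
                   ) -> tuple["np.ndarray", list[str], list[int], bool]:
    """(values, gene_ids, planted class per gene, degenerate flag).

    Three planted expression-level classes with log-normal multiplicative
    noise; class i has mean level ``class_means[i]`` in every tissue. The
    default sizes mirror a moderate / basal-to-none / minimal three-way
    split. ``degenerate`` is True when the class means are not distinct.
    """
    if len(class_means) != len(class_sizes):
        raise ValueError("class_means and class_sizes lengths differ")
    if sum(class_sizes) != n_genes:
        raise ValueError("class sizes must sum to n_genes")
    rng = np.random.default_rng(seed)
    labels: list[int] = []
    for ci, size in enumerate(class_sizes):
        labels.extend([ci] * size)
    means = np.array([class_means[c] for c in labels])[:, None]
    values = means * rng.lognormal(mean=0.0, sigma=noise_sigma,
                                   size=(n_genes, len(tissues)))
    gene_ids = [f"expr_g{i:03d}" for i in range(n_genes)]
    degenerate = len(set(class_means)) != len(class_means)
    return values, gene_ids, labels, degenerate
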