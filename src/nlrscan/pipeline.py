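"""File-level orchestration of the NLR survey stages.

Stages run in a fixed order — identify -> classify -> cluster -> kaks
(optional) -> express (optional) -> report — and each one reads and writes
only its declared files, so running the stages individually through the CLI
gives byte-identical results to :func:`run_pipeline`. A manifest records
the seed and a digest of every input consumed.

Gene and protein identifiers are assumed to coincide (one primary protein
per gene model), which is how the synthetic genome is emitted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (DomainHit, check_hit_coordinates, read_domain_table,
                      read_fasta, read_gff3, write_domain_table, write_fasta,
                      write_gff3)
from .clusters import ClusterCriteria, call_clusters, cluster_summary, exon_statistics
from .expression import (ExpressionMatrix, classify_expression_levels,
                         kmeans_cluster, normalize)
from .grammar import classify_proteins, count_lrr_signatures
from .kaks import CodonAlignment, clade_average, pairwise_kaks
from .motifs import extract_signatures, scan_known_motifs
from .report import filter_homology_hits, summarize
from .signals import TwoStateHMM, call_cc, nls_decode
from .synth import GenomeBlueprint, gen_codon_pairs, gen_expression, gen_proteome, gen_genome


@dataclass
class PipelineConfig:
    out_dir: str = "nlrscan_out"
    proteins_fasta: str | None = None
    domain_table: str | None = None
    gff3: str | None = None
    cds_pairs_fasta: str | None = None
    clade_map: str | None = None          # TSV: pair_id <tab> clade
    expression_tsv: str | None = None
    homology_tsv: str | None = None
    proteome_size: int = 52_243
    n_chromosomes: int = 17
    cc_threshold: float = 0.4
    cc_scanner: str = "auto"              # auto | always | never
    nls_cutoff: float = 0.5
    nls_mode: str = "posterior"
    cluster_max_gap: int = 200_000
    cluster_max_intervening: int = 8
    homology_max_evalue: float = 0.01
    homology_min_identity: float = 50.0
    kmeans_k: int = 3
    kmeans_max_iter: int = 1000
    kmeans_n_init: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for prob in (self.cc_threshold, self.nls_cutoff):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilistic thresholds must lie in [0, 1]")
        for name in ("proteins_fasta", "domain_table", "gff3", "cds_pairs_fasta",
                     "expression_tsv", "homology_tsv", "clade_map"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config error: {name} path {p} does not exist")
        if self.cc_scanner not in ("auto", "always", "never"):
            raise ValueError(f"cc_scanner must be auto/always/never")

    def derived_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Stages


def stage_synth(cfg: PipelineConfig,
                blueprint: GenomeBlueprint | None = None) -> dict[str, str]:
    """Emit the synthetic dataset into out_dir/synth and point the config's
    input paths at it. The default blueprint is the full survey-scale one."""
    out = Path(cfg.out_dir) / "synth"
    out.mkdir(parents=True, exist_ok=True)
    bp = blueprint or GenomeBlueprint(seed=cfg.derived_seed("synth"),
                                      proteome_size=cfg.proteome_size,
                                      n_chromosomes=cfg.n_chromosomes)
    cfg.proteome_size = bp.proteome_size
    cfg.n_chromosomes = bp.n_chromosomes
    seqs, hits, truth = gen_proteome(bp)
    loci, _ = gen_genome(bp)
    write_fasta(seqs, out / "proteins.fasta")
    write_domain_table(hits, out / "domains.tsv")
    write_gff3(loci, out / "genes.gff3")
    truth.to_json(out / "truth.json")
    pairs, pair_truth = gen_codon_pairs(
        n_pairs=10, n_codons=300, omega=0.3, ks_target=0.2,
        seed=cfg.derived_seed("synth_codons"))
    with open(out / "cds_pairs.fasta", "w") as fh:
        for p in pairs:
            fh.write(f">{p.id_a}\n{p.seq_a}\n>{p.id_b}\n{p.seq_b}\n")
    values, gene_ids, labels, _deg = gen_expression(seed=cfg.derived_seed("synth_expr"))
    from .synth import DEFAULT_TISSUES
    pd.DataFrame(values, index=gene_ids, columns=list(DEFAULT_TISSUES)).to_csv(
        out / "expression.tsv", sep="\t")
    cfg.proteins_fasta = str(out / "proteins.fasta")
    cfg.domain_table = str(out / "domains.tsv")
    cfg.gff3 = str(out / "genes.gff3")
    cfg.cds_pairs_fasta = str(out / "cds_pairs.fasta")
    cfg.expression_tsv = str(out / "expression.tsv")
    return {"truth": str(out / "truth.json")}


def stage_identify(cfg: PipelineConfig) -> pd.DataFrame:
    """Per-protein evidence: domains, LRR count, signatures, CC and NLS calls.

    Writes identified.tsv and hits.tsv under out_dir. A coiled-coil call
    contributes CC domain evidence only when its segment starts before the
    first NBS hit (N-terminal placement).
    """
    if cfg.proteins_fasta is None or cfg.domain_table is None:
        raise StageError("identify", "proteins_fasta and domain_table are required")
    seqs = read_fasta(cfg.proteins_fasta)
    hits = read_domain_table(cfg.domain_table)
    check_hit_coordinates(hits, seqs)
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    hmm = TwoStateHMM.default_nls()
    rows = []
    for seq in seqs:
        own = by_protein.setdefault(seq.id, [])
        has_cc_row = any(h.kind == "CC" for h in own)
        nbs_starts = [h.start for h in own if h.kind == "NBS"]
        cc_start = cc_end = None
        if cfg.cc_scanner == "always" or (cfg.cc_scanner == "auto" and not has_cc_row):
            call = call_cc(seq, threshold=cfg.cc_threshold)
            if call is not None and (not nbs_starts or call.start < min(nbs_starts)):
                own.append(DomainHit(protein_id=seq.id, kind="CC",
                                     start=call.start, end=call.end,
                                     score=call.support))
                cc_start, cc_end = call.start, call.end
        elif has_cc_row:
            first = min((h for h in own if h.kind == "CC"), key=lambda h: h.start)
            cc_start, cc_end = first.start, first.end
        motif_hits = scan_known_motifs(seq)
        sig = extract_signatures(seq, motif_hits)
        nls = nls_decode(seq, hmm, mode=cfg.nls_mode, cutoff=cfg.nls_cutoff)
        rows.append({
            "protein_id": seq.id,
            "lrr_count": count_lrr_signatures(seq),
            "kinase2": sig.kinase2 or "",
            "rnbsb": sig.rnbsb or "",
            "has_nls": int(bool(nls)),
            "cc_start": cc_start if cc_start is not None else "",
            "cc_end": cc_end if cc_end is not None else "",
        })
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(out / "identified.tsv", sep="\t", index=False)
    write_domain_table([h for hs in by_protein.values() for h in hs], out / "hits.tsv")
    return df


def stage_classify(cfg: PipelineConfig) -> pd.DataFrame:
    """Architecture building and taxonomy assignment; writes classified.tsv."""
    out = Path(cfg.out_dir)
    ident = pd.read_csv(out / "identified.tsv", sep="\t", dtype={"kinase2": str})
    hits = read_domain_table(out / "hits.tsv")
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    # proteins with no hit rows at all still enter (and are excluded with reason)
    for pid in ident["protein_id"]:
        by_protein.setdefault(pid, [])
    lrr = dict(zip(ident["protein_id"], ident["lrr_count"]))
    k2 = {r.protein_id: (r.kinase2 if isinstance(r.kinase2, str) and r.kinase2 else None)
          for r in ident.itertuples()}
    nls = dict(zip(ident["protein_id"], ident["has_nls"].astype(bool)))
    records, excluded = classify_proteins(by_protein, lrr, kinase2=k2, nls_flags=nls)
    df = pd.DataFrame([
        {
            "protein_id": r.protein_id, "group": r.group, "subgroup": r.subgroup,
            "lrr_count": r.lrr_count, "kinase2": r.kinase2 or "",
            "nl_subtype": r.nl_subtype, "has_nls": int(r.has_nls),
            "has_kelch": int(r.has_kelch),
        }
        for r in records
    ])
    df.to_csv(out / "classified.tsv", sep="\t", index=False)
    pd.DataFrame({"protein_id": excluded, "reason": "no NBS domain"}).to_csv(
        out / "excluded.tsv", sep="\t", index=False)
    return df


def stage_cluster(cfg: PipelineConfig) -> dict:
    """Physical clustering from the GFF3; writes clusters.tsv and cluster_summary.json."""
    if cfg.gff3 is None:
        raise StageError("cluster", "gff3 input is required")
    out = Path(cfg.out_dir)
    loci = read_gff3(cfg.gff3)
    classified = pd.read_csv(out / "classified.tsv", sep="\t")
    nbs_ids = set(classified["protein_id"])
    for g in loci:
        g.is_nbs = g.is_nbs or g.gene_id in nbs_ids
    criteria = ClusterCriteria(cfg.cluster_max_gap, cfg.cluster_max_intervening)
    clusters = call_clusters(loci, criteria)
    placed = lambda chrom: "c" not in chrom.split("Chr")[-1]
    summary = cluster_summary(clusters, loci, n_chromosomes=cfg.n_chromosomes,
                              chromosome_filter=placed)
    rows = [
        {"chrom": c.chrom, "start0": c.span[0] - 1, "end": c.span[1],
         "n_members": len(c.members), "members": ",".join(c.members)}
        for c in clusters
    ]
    pd.DataFrame(rows, columns=["chrom", "start0", "end", "n_members", "members"]).to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    exon_stats = exon_statistics(loci, list(classified.itertuples(index=False)))
    exon_stats.to_csv(out / "exon_stats.tsv", sep="\t", index=False)
    with open(out / "cluster_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def stage_kaks(cfg: PipelineConfig) -> pd.DataFrame:
    """Pairwise Ka/Ks on consecutive FASTA record pairs; writes kaks.tsv.

    Clade averages are appended to kaks_clades.tsv when a clade map is given.
    """
    if cfg.cds_pairs_fasta is None:
        raise StageError("kaks", "cds_pairs_fasta input is required")
    out = Path(cfg.out_dir)
    from .core_io import Alphabet
    recs = read_fasta(cfg.cds_pairs_fasta, alphabet=Alphabet.nucleotide)
    if len(recs) % 2 != 0:
        raise StageError("kaks", "pair FASTA must hold an even number of records")
    rows = []
    results = {}
    for a, b in zip(recs[::2], recs[1::2]):
        res = pairwise_kaks(CodonAlignment(a.id, b.id, a.residues, b.residues))
        results[(a.id, b.id)] = res
        rows.append({
            "id_a": a.id, "id_b": b.id, "N_sites": res.N_sites, "S_sites": res.S_sites,
            "Nd": res.Nd, "Sd": res.Sd, "pN": res.pN, "pS": res.pS,
            "Ka": res.Ka if res.Ka is not None else "NA",
            "Ks": res.Ks if res.Ks is not None else "NA",
            "ratio": res.ratio if res.ratio is not None else "NA",
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "kaks.tsv", sep="\t", index=False)
    if cfg.clade_map is not None:
        clades = pd.read_csv(cfg.clade_map, sep="\t")
        crows = []
        for clade, sub in clades.groupby("clade"):
            keys = {tuple(x) for x in sub[["id_a", "id_b"]].itertuples(index=False)}
            subset = [results[k] for k in results if k in keys]
            mean, excluded = clade_average(subset)
            crows.append({"clade": clade, "mean_ratio": mean,
                          "n_pairs": len(subset), "n_excluded": excluded})
        pd.DataFrame(crows).to_csv(out / "kaks_clades.tsv", sep="\t", index=False)
    return df


def stage_express(cfg: PipelineConfig) -> pd.DataFrame:
    """Median-of-ratios normalisation + K-means expression classes."""
    if cfg.expression_tsv is None:
        raise StageError("express", "expression_tsv input is required")
    out = Path(cfg.out_dir)
    matrix = ExpressionMatrix.from_tsv(cfg.expression_tsv)
    normed = normalize(matrix)
    normed.to_frame().to_csv(out / "expression_normalized.tsv", sep="\t")
    km = kmeans_cluster(normed, k=cfg.kmeans_k, max_iter=cfg.kmeans_max_iter,
                        seed=cfg.derived_seed("kmeans"), n_init=cfg.kmeans_n_init)
    labels = classify_expression_levels(km) if cfg.kmeans_k == 3 else {}
    df = pd.DataFrame({
        "gene_id": km.gene_ids,
        "cluster": km.assignments,
        "level": [labels.get(c, str(c)) for c in km.assignments],
    })
    df.to_csv(out / "expression_clusters.tsv", sep="\t", index=False)
    return df


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble the survey summary; writes report.json and subgroup_counts.tsv."""
    out = Path(cfg.out_dir)
    classified = pd.read_csv(out / "classified.tsv", sep="\t")
    from .grammar import NbsGeneRecord
    records = [
        NbsGeneRecord(
            protein_id=r.protein_id, group=r.group, subgroup=r.subgroup,
            lrr_count=int(r.lrr_count),
            kinase2=r.kinase2 if isinstance(r.kinase2, str) and r.kinase2 else None,
            nl_subtype=r.nl_subtype, has_nls=bool(r.has_nls),
        )
        for r in classified.itertuples(index=False)
    ]
    summary_path = out / "cluster_summary.json"
    csum = json.loads(summary_path.read_text()) if summary_path.exists() else None
    exon_path = out / "exon_stats.tsv"
    exon = pd.read_csv(exon_path, sep="\t") if exon_path.exists() else None
    rep = summarize(records, proteome_size=cfg.proteome_size,
                    cluster_summary=csum, exon_stats=exon)
    rep.to_json(out / "report.json")
    rep.subgroup_table().to_csv(out / "subgroup_counts.tsv", sep="\t", index=False)
    if cfg.homology_tsv is not None:
        hom = pd.read_csv(cfg.homology_tsv, sep="\t")
        filt = filter_homology_hits(hom, cfg.homology_max_evalue,
                                    cfg.homology_min_identity)
        filt.to_csv(out / "homology_filtered.tsv", sep="\t", index=False)
    return json.loads(rep.to_json())


STAGES = ("identify", "classify", "cluster", "kaks", "express", "report")


def run_pipeline(cfg: PipelineConfig, synth_first: bool = False,
                 blueprint: GenomeBlueprint | None = None) -> dict:
    """Run every applicable stage in order and write a manifest.

    Optional stages (kaks, express) run only when their inputs are
    configured. Any stage failure is re-raised as :class:`StageError`
    naming the stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if synth_first:
        stage_synth(cfg, blueprint=blueprint)
    inputs = {
        name: getattr(cfg, name)
        for name in ("proteins_fasta", "domain_table", "gff3", "cds_pairs_fasta",
                     "expression_tsv", "homology_tsv")
        if getattr(cfg, name) is not None
    }
    report = None
    for stage in STAGES:
        if stage == "kaks" and cfg.cds_pairs_fasta is None:
            continue
        if stage == "express" and cfg.expression_tsv is None:
            continue
        fn = globals()[f"stage_{stage}"]
        try:
            result = fn(cfg)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        if stage == "report":
            report = result
    manifest = {
        "tool": "nlrscan",
        "version": __version__,
        "seed": cfg.seed,
        "derived_seeds": {s: cfg.derived_seed(s) for s in
                          ("synth", "synth_codons", "synth_expr", "kmeans")},
        "inputs": {k: {"path": v, "sha256": _digest(v)} for k, v in inputs.items()},
        "config": asdict(cfg),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
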