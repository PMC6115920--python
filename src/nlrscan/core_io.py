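"""Shared data model and readers/writers for FASTA, GFF3 and domain tables.

Coordinate conventions follow the source formats throughout: GFF3 base
positions and domain-table residue positions are 1-based inclusive in every
in-memory object. Any half-open arithmetic is local to the operation that
needs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")

#: Pfam-style accession -> domain kind used by the identification stage.
ACCESSION_KINDS = {
    "PF01582": "TIR",
    "PF00931": "NBS",
    "PF05659": "RPW8",
    "PF01344": "KELCH",
}

DOMAIN_KINDS = ("TIR", "NBS", "RPW8", "CC", "LRR", "KELCH")


class Alphabet(str, Enum):
    protein = "protein"
    nucleotide = "nucleotide"


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over the protein (20 letters + X) or DNA (ACGTN) alphabet."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.protein

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = (
            PROTEIN_ALPHABET if self.alphabet == Alphabet.protein else NUCLEOTIDE_ALPHABET
        )
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet.value} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneLocus:
    """A gene model from GFF3: 1-based inclusive span plus NLR status and exon count."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    is_nbs: bool = False
    exon_count: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass
class DomainHit:
    """One located domain or signal on a protein, 1-based inclusive residue span."""

    protein_id: str
    kind: str
    start: int
    end: int
    score: float = 0.0
    source_accession: str = ""

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}/{self.kind}: start {self.start} > end {self.end}"
            )
        if self.source_accession and self.source_accession in ACCESSION_KINDS:
            expected = ACCESSION_KINDS[self.source_accession]
            if expected != self.kind:
                raise ValueError(
                    f"{self.protein_id}: accession {self.source_accession} maps to "
                    f"{expected}, not {self.kind}"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.protein) -> list[SequenceRecord]:
    """Read a multi-record FASTA; order preserved, residues upper-cased.

    Raises ValueError on duplicate ids; an empty file yields an empty list
    with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneLocus]:
    """Read gene models from GFF3 and return loci sorted by (chrom, start).

    ``exon_count`` is taken from the primary transcript, defined as the mRNA
    child with the most exons (ties broken by file order). A gene with no
    mRNA child gets exon_count 1. An exon whose Parent cannot be resolved is
    an error naming the feature.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise ValueError(
                f"exon without resolvable mRNA Parent: {str(exon).strip()}"
            )

    loci: list[GeneLocus] = []
    for gene in db.features_of_type("gene"):
        exon_count = 0
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            n = sum(1 for _ in db.children(mrna, featuretype="exon"))
            if n > exon_count:
                exon_count = n
        loci.append(
            GeneLocus(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else ".",
                is_nbs=gene.attributes.get("is_nbs", ["0"])[0] in ("1", "true", "True"),
                exon_count=max(exon_count, 1),
            )
        )
    loci.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return loci


def write_gff3(loci: Iterable[GeneLocus], path: str | Path,
               exon_spans: dict[str, list[tuple[int, int]]] | None = None) -> None:
    """Write gene/mRNA/exon features for each locus.

    ``exon_spans`` maps gene_id to explicit exon coordinates; absent entries
    get ``exon_count`` evenly spaced exons synthesised inside the gene span.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(loci, key=lambda x: (x.chrom, x.start, x.gene_id)):
            attrs = f"ID={g.gene_id};is_nbs={int(g.is_nbs)}"
            fh.write(
                f"{g.chrom}\tnlrscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tnlrscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            spans = (exon_spans or {}).get(g.gene_id)
            if spans is None:
                spans = _even_exons(g.start, g.end, g.exon_count)
            for i, (s, e) in enumerate(spans, 1):
                fh.write(
                    f"{g.chrom}\tnlrscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


def _even_exons(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """n disjoint exon spans covering [start, end] with unit gaps where possible."""
    length = end - start + 1
    if n <= 1 or length < 2 * n - 1:
        return [(start, end)]
    # alternate exon/intron blocks of roughly equal size
    block = length // (2 * n - 1)
    spans = []
    pos = start
    for i in range(n):
        s = pos
        e = min(end, s + block - 1) if i < n - 1 else end
        spans.append((s, e))
        pos = e + block + 1
    return spans


# ---------------------------------------------------------------------------
# Domain table


def read_domain_table(path: str | Path, unknown: str = "reject",
                      extra_kinds: dict[str, str] | None = None) -> list[DomainHit]:
    """Read a TSV of domain evidence (protein_id, accession, start, end, score).

    Accessions are mapped to kinds via the fixed Pfam table; bare kind names
    (TIR/NBS/RPW8/CC/LRR/KELCH) are accepted as their own accession.
    ``unknown`` is "reject" (error on unmapped accession) or "skip".
    ``extra_kinds`` extends the accession->kind map.
    """
    mapping = dict(ACCESSION_KINDS)
    if extra_kinds:
        mapping.update(extra_kinds)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "accession", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table {path} missing columns {sorted(missing)}")
    hits: list[DomainHit] = []
    for row in df.itertuples(index=False):
        acc = row.accession
        if acc in mapping:
            kind = mapping[acc]
        elif acc in DOMAIN_KINDS:
            kind = acc
        elif unknown == "skip":
            continue
        else:
            raise ValueError(f"unknown accession {acc!r} for protein {row.protein_id}")
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(
                f"domain row for {row.protein_id}/{acc}: start {start} > end {end}"
            )
        hits.append(
            DomainHit(
                protein_id=row.protein_id,
                kind=kind,
                start=start,
                end=end,
                score=float(row.score),
                source_accession=acc if acc in mapping else "",
            )
        )
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "accession": h.source_accession or h.kind,
            "start": h.start,
            "end": h.end,
            "score": h.score,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["protein_id", "accession", "start", "end", "score"]).to_csv(
        path, sep="\t", index=False
    )


def check_hit_coordinates(hits: Iterable[DomainHit],
                          sequences: Iterable[SequenceRecord]) -> None:
    """Assert every hit lies within its protein when sequences are supplied."""
    lengths = {s.id: len(s) for s in sequences}
    for h in hits:
        n = lengths.get(h.protein_id)
        if n is not None and h.end > n:
            raise ValueError(
                f"hit {h.protein_id}/{h.kind} end {h.end} exceeds protein length {n}"
            )
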