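"""Ordered domain architectures and the 4-group / 18-subgroup NLR taxonomy.

Each protein with an NB-ARC (NBS) domain gets an ordered letter string over
{C, T, R, N} from its domain hits; LRR evidence (LxxLxxLxx signature count,
or explicit LRR hit positions for repeated-unit architectures) contributes
the trailing 'L' of the subgroup code. Group membership follows domain
dominance T > R > C: any TIR makes the protein a TNL (covering the mixed
CTNL/CTN codes), otherwise any RPW8 makes it an RNL (covering RCNL),
otherwise any coiled-coil makes it a CNL, and bare architectures are NLs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core_io import DomainHit, SequenceRecord

LRR_PATTERN = re.compile(r"L..L..L..")

KIND_LETTER = {"CC": "C", "TIR": "T", "RPW8": "R", "NBS": "N"}

#: The recognised subgroup letter codes.
SUBGROUPS = (
    "CNL", "CN", "CNNL", "CNN",
    "RNL", "RN", "RCNL",
    "TNL", "TN", "TNNL", "TTNL", "TNLTNL", "CTNL", "CTN",
    "N", "NL", "NN", "NNL",
)

GROUPS = ("CNL", "TNL", "RNL", "NL")

UNCLASSIFIED = "unclassified_architecture"


class NoNbsDomain(ValueError):
    """Raised when a protein has no NBS hit and cannot enter classification."""

    def __init__(self, protein_id: str):
        super().__init__(f"{protein_id}: no NBS domain")
        self.protein_id = protein_id


@dataclass
class Architecture:
    """Ordered domain letters plus LRR and Kelch evidence for one protein."""

    protein_id: str
    letters: str  # over C/T/R/N, sorted by domain start
    has_lrr: bool = False
    lrr_count: int = 0
    has_kelch: bool = False
    #: merged LRR hit spans (1-based inclusive), used to place 'L' between
    #: repeated units (e.g. TNLTNL); empty when only a count is known
    lrr_segments: list[tuple[int, int]] = field(default_factory=list)
    #: start positions aligned with ``letters`` for unit interleaving
    letter_starts: list[int] = field(default_factory=list)


@dataclass
class NbsGeneRecord:
    """A classified NLR gene."""

    protein_id: str
    group: str
    subgroup: str
    lrr_count: int = 0
    kinase2: str | None = None
    nl_subtype: str = "unassigned"  # N_CC / N_TIR / unassigned
    has_nls: bool = False
    has_cc_rx_like: bool = False  # supplied metadata, never computed here
    has_kelch: bool = False
    exon_count: int | None = None
    clade: str | None = None


def merge_intervals(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, sorted."""
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_lrr_signatures(seq: SequenceRecord | str) -> int:
    """Greedy left-to-right non-overlapping count of the LxxLxxLxx signature."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    count = 0
    pos = 0
    while True:
        m = LRR_PATTERN.search(residues, pos)
        if m is None:
            return count
        count += 1
        pos = m.end()


def build_architecture(protein_id: str, hits: list[DomainHit],
                       lrr_count: int = 0) -> Architecture:
    """Ordered architecture from domain hits; overlapping same-kind hits merge.

    Raises :class:`NoNbsDomain` when no NBS hit is present — such proteins
    are excluded from classification (the TX class is out of scope).
    """
    own = [h for h in hits if h.protein_id == protein_id]
    by_kind: dict[str, list[tuple[int, int]]] = {}
    for h in own:
        by_kind.setdefault(h.kind, []).append((h.start, h.end))
    if "NBS" not in by_kind:
        raise NoNbsDomain(protein_id)
    lettered: list[tuple[int, str]] = []
    for kind, letter in KIND_LETTER.items():
        for s, _e in merge_intervals(by_kind.get(kind, [])):
            lettered.append((s, letter))
    lettered.sort()
    lrr_segments = merge_intervals(by_kind.get("LRR", []))
    return Architecture(
        protein_id=protein_id,
        letters="".join(l for _s, l in lettered),
        has_lrr=lrr_count >= 1 or bool(lrr_segments),
        lrr_count=lrr_count,
        has_kelch="KELCH" in by_kind,
        lrr_segments=lrr_segments,
        letter_starts=[s for s, _l in lettered],
    )


def _interleaved_code(arch: Architecture) -> str:
    """Letter code with 'L' placed by LRR hit position; consecutive L collapse."""
    events = [(s, l) for s, l in zip(arch.letter_starts, arch.letters)]
    events += [(s, "L") for s, _e in arch.lrr_segments]
    events.sort()
    code = ""
    for _s, l in events:
        if l == "L" and code.endswith("L"):
            continue
        code += l
    return code


def classify(arch: Architecture) -> tuple[str, str]:
    """(group, subgroup) for an architecture containing at least one N.

    Subgroup = the letter code with a trailing 'L' when LRR signatures are
    present; architectures with positional LRR evidence (hit spans) have 'L'
    interleaved at its observed position instead, which is what separates
    TNLTNL from TTNNL-style strings. Codes outside the recognised table are
    reported as ``unclassified_architecture``.
    """
    if "N" not in arch.letters:
        raise NoNbsDomain(arch.protein_id)
    if "T" in arch.letters:
        group = "TNL"
    elif "R" in arch.letters:
        group = "RNL"
    elif "C" in arch.letters:
        group = "CNL"
    else:
        group = "NL"
    if arch.lrr_segments:
        code = _interleaved_code(arch)
    else:
        code = arch.letters + ("L" if arch.has_lrr else "")
    if code not in SUBGROUPS:
        # positional interleaving may produce e.g. "CLN" for an N-terminal
        # LRR; fall back to the presence rule before giving up
        fallback = arch.letters + ("L" if arch.has_lrr else "")
        code = fallback if fallback in SUBGROUPS else UNCLASSIFIED
    return group, code


def subtype_nl(record: NbsGeneRecord) -> str:
    """N_CC / N_TIR subtype of an NL-group gene from its Kinase-2 signature.

    DDVW marks the CC lineage (N_CC), DDVD the TIR lineage (N_TIR);
    anything else is unassigned. Calling this on a non-NL record is an error.
    """
    if record.group != "NL":
        raise ValueError(f"{record.protein_id}: nl subtype applies to NL group only")
    if record.kinase2 == "DDVW":
        return "N_CC"
    if record.kinase2 == "DDVD":
        return "N_TIR"
    return "unassigned"


def classify_proteins(
    hits_by_protein: dict[str, list[DomainHit]],
    lrr_counts: dict[str, int],
    kinase2: dict[str, str | None] | None = None,
    nls_flags: dict[str, bool] | None = None,
    rx_flags: dict[str, bool] | None = None,
) -> tuple[list[NbsGeneRecord], list[str]]:
    """Classify every protein with an NBS hit; returns (records, excluded ids)."""
    records: list[NbsGeneRecord] = []
    excluded: list[str] = []
    for pid in sorted(hits_by_protein):
        try:
            arch = build_architecture(pid, hits_by_protein[pid], lrr_counts.get(pid, 0))
            group, subgroup = classify(arch)
        except NoNbsDomain:
            excluded.append(pid)
            continue
        rec = NbsGeneRecord(
            protein_id=pid,
            group=group,
            subgroup=subgroup,
            lrr_count=arch.lrr_count,
            kinase2=(kinase2 or {}).get(pid),
            has_nls=(nls_flags or {}).get(pid, False),
            has_cc_rx_like=(rx_flags or {}).get(pid, False),
            has_kelch=arch.has_kelch,
        )
        if rec.group == "NL":
            rec.nl_subtype = subtype_nl(rec)
        records.append(rec)
    return records, excluded
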