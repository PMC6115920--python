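"""Summary statistics of an NLR classification run and the homology-hit filter.

``summarize`` assembles the headline numbers of a genome-wide NLR survey:
subgroup and group counts, the fraction of the proteome that is
NBS-encoding, the CNL:TNL ratio, Kinase-2 signature tallies, and the
clustering and exon-structure statistics computed upstream.

Two percentage-presentation conventions coexist in this literature:
truncation toward zero and half-up rounding. Both are provided and every
formatted report notes which one it used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import pandas as pd

from .grammar import GROUPS, NbsGeneRecord


def truncate_pct(x: float) -> int:
    """Truncate a percentage to its integer part (67.5 -> 67)."""
    return math.floor(x) if x >= 0 else math.ceil(x)


def half_up_pct(x: float) -> int:
    """Round half away from zero (36.5 -> 37)."""
    return math.floor(x + 0.5)


@dataclass
class SummaryReport:
    subgroup_counts: dict[str, int]
    group_counts: dict[str, int]
    total_nbs: int
    proteome_size: int
    pct_of_proteome: float
    cnl_tnl_ratio: float | None
    kinase2_tally: dict[str, dict[str, int]]
    nl_subtype_counts: dict[str, int]
    lrr_positive: dict[str, int]
    cluster_summary: dict | None = None
    exon_stats: list[dict] | None = None
    notes: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def subgroup_table(self) -> pd.DataFrame:
        """Subgroup x count table in letter-code layout."""
        return pd.DataFrame(
            [{"subgroup": k, "n": v} for k, v in self.subgroup_counts.items()]
        )


def summarize(records: Iterable[NbsGeneRecord], proteome_size: int,
              cluster_summary: dict | None = None,
              exon_stats: pd.DataFrame | None = None) -> SummaryReport:
    """Assemble the survey summary from classified records.

    pct_of_proteome = total / proteome_size x 100; cnl_tnl_ratio is the CNL
    group count over the TNL group count (None when no TNLs). Tallies are
    exact; rounding is presentation-only.
    """
    if proteome_size <= 0:
        raise ValueError("proteome_size must be positive")
    records = list(records)
    subgroup_counts: dict[str, int] = {}
    group_counts = {g: 0 for g in GROUPS}
    kinase2_tally: dict[str, dict[str, int]] = {g: {} for g in GROUPS}
    nl_subtypes: dict[str, int] = {}
    lrr_positive = {g: 0 for g in GROUPS}
    for r in records:
        subgroup_counts[r.subgroup] = subgroup_counts.get(r.subgroup, 0) + 1
        group_counts[r.group] = group_counts.get(r.group, 0) + 1
        if r.kinase2:
            tally = kinase2_tally.setdefault(r.group, {})
            tally[r.kinase2] = tally.get(r.kinase2, 0) + 1
        if r.group == "NL":
            nl_subtypes[r.nl_subtype] = nl_subtypes.get(r.nl_subtype, 0) + 1
        if r.lrr_count >= 1:
            lrr_positive[r.group] = lrr_positive.get(r.group, 0) + 1
    total = len(records)
    cnl, tnl = group_counts.get("CNL", 0), group_counts.get("TNL", 0)
    return SummaryReport(
        subgroup_counts=dict(sorted(subgroup_counts.items())),
        group_counts=group_counts,
        total_nbs=total,
        proteome_size=proteome_size,
        pct_of_proteome=100.0 * total / proteome_size,
        cnl_tnl_ratio=(cnl / tnl) if tnl else None,
        kinase2_tally=kinase2_tally,
        nl_subtype_counts=dict(sorted(nl_subtypes.items())),
        lrr_positive=lrr_positive,
        cluster_summary=cluster_summary,
        exon_stats=exon_stats.to_dict("records") if exon_stats is not None else None,
    )


def filter_homology_hits(hits: pd.DataFrame, max_evalue: float = 0.01,
                         min_identity: float = 50.0) -> pd.DataFrame:
    """Keep rows with evalue < max_evalue AND pct_identity > min_identity.

    Both inequalities are strict. The per-query best hit (highest identity,
    ties by lowest E-value) is flagged in a ``best_hit`` column. Malformed
    rows (non-numeric identity or E-value) are dropped; their count is in
    ``df.attrs["n_malformed"]``.
    """
    required = {"query", "subject", "pct_identity", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"homology table missing columns {sorted(missing)}")
    df = hits.copy()
    df["pct_identity"] = pd.to_numeric(df["pct_identity"], errors="coerce")
    df["evalue"] = pd.to_numeric(df["evalue"], errors="coerce")
    malformed = df["pct_identity"].isna() | df["evalue"].isna()
    df = df[~malformed]
    kept = df[(df["evalue"] < max_evalue) & (df["pct_identity"] > min_identity)].copy()
    kept["best_hit"] = False
    if len(kept):
        best_idx = (
            kept.sort_values(["pct_identity", "evalue"], ascending=[False, True])
            .groupby("query", sort=False)
            .head(1)
            .index
        )
        kept.loc[best_idx, "best_hit"] = True
    kept = kept.reset_index(drop=True)
    kept.attrs["n_malformed"] = int(malformed.sum())
    return kept
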