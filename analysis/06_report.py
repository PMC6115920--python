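#!/usr/bin/env python
"""Assemble the survey summary report from the upstream stage tables.

Writes report.json and subgroup_counts.tsv under results/pipeline/ and
prints the headline numbers (total NLR count, proteome share, CNL:TNL
ratio, clustering summary).
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nlrscan.pipeline import PipelineConfig, stage_report

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=root / "results" / "pipeline")
ap.add_argument("--proteome-size", type=int, default=52_243)
args = ap.parse_args()

cfg = PipelineConfig(out_dir=str(args.out), proteome_size=args.proteome_size,
                     seed=args.seed)
rep = stage_report(cfg)
print(f"total NBS-encoding genes: {rep['total_nbs']} "
      f"({rep['pct_of_proteome']:.2f}% of the proteome)")
print(f"group counts: {rep['group_counts']}")
if rep["cnl_tnl_ratio"] is not None:
    print(f"CNL:TNL ratio: {rep['cnl_tnl_ratio']:.1f}:1")
if rep.get("cluster_summary"):
    cs = rep["cluster_summary"]
    print(f"clusters: {cs['n_clusters']} holding {cs['n_clustered_genes']} genes")
print(f"report at {args.out / 'report.json'}")
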