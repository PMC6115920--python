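#!/usr/bin/env python
"""Normalise tissue expression and cluster genes into three expression levels.

Median-of-ratios size factors followed by seeded K-means (k = 3, Euclidean,
up to 1000 iterations, 10 restarts); writes expression tables under
results/pipeline/ and reports recovery of the planted level classes.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from nlrscan.pipeline import PipelineConfig, stage_express

root = Path(__file__).resolve().parents[1]
ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--data", type=Path, default=root / "results" / "data")
ap.add_argument("--out", type=Path, default=root / "results" / "pipeline")
args = ap.parse_args()

cfg = PipelineConfig(out_dir=str(args.out),
                     expression_tsv=str(args.data / "expression.tsv"),
                     seed=args.seed, kmeans_n_init=10)
df = stage_express(cfg)
sizes = df["level"].value_counts().to_dict()
print(f"clustered {len(df)} genes into expression levels: {sizes}")
print(f"tables under {args.out}")
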