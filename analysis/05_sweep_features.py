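#!/usr/bin/env python
"""Sweep the number of RFE-selected features.

Repeats the LOOCV pipeline for k = 1..10 retained features on the baseline
table and reports the pooled-AUC curve and the AUC-optimal k.
"""

import argparse
from pathlib import Path

import pandas as pd

from vttml.containers import FeatureTable
from vttml.predictor import PipelineConfig, sweep_n_features
from vttml.preprocess import preprocess_table
from vttml.response import labels_series


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/k_sweep.csv"))
    ap.add_argument("--kmax", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    features = FeatureTable(
        pd.read_csv(args.cohort / "features.csv", index_col=0),
        pd.read_csv(args.cohort / "features_meta.csv", index_col=0))
    y = labels_series(pd.read_csv(args.labels, index_col=0))
    pruned, _, _ = preprocess_table(features, seed=args.seed)

    best_k, curve = sweep_n_features(pruned, y, PipelineConfig(seed=args.seed),
                                     range(1, args.kmax + 1))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    curve.to_csv(args.out)
    print(curve.round(3))
    print(f"\nAUC-optimal number of RFE features: k = {best_k} -> {args.out}")


if __name__ == "__main__":
    main()
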