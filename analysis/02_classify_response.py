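#!/usr/bin/env python
"""Classify responders from VTT segment lengths.

Reads results/cohort/vtt.csv (three MRI-measured thrombus segments per
patient per scan week), computes total length, the week-9 percent change
versus baseline, and the binary responder call (shrinkage of more than 30%).
"""

import argparse
from pathlib import Path

import pandas as pd

from vttml.response import classify_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--vtt", type=Path, default=Path("results/cohort/vtt.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/labels.csv"))
    args = ap.parse_args()

    labels = classify_cohort(pd.read_csv(args.vtt))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    labels.to_csv(args.out)
    print(labels.round(1))
    print(f"\n{int(labels['responder'].sum())}/{len(labels)} responders "
          f"-> {args.out}")


if __name__ == "__main__":
    main()
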