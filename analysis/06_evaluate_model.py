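#!/usr/bin/env python
"""Bootstrap evaluation of the trained model on the held-out test regions.

Reads results/test_predictions.csv (from 05_train_model.py), resamples the
test regions 1000 times, and writes results/report.json plus a printed
metric table: balanced accuracy, ROC AUC, PR AUC, sensitivity and
specificity with 95% percentile CIs, and the one-sided exceedance p-value
of the balanced-accuracy delta over the 0.5 all-negative baseline.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cribromics.metrics import bootstrap_metrics


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--preds", type=Path, default=Path("results/test_predictions.csv"))
    ap.add_argument("--n-boot", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    preds = pd.read_csv(args.preds)
    report = bootstrap_metrics(preds["target"].to_numpy(),
                               preds["probability"].to_numpy(),
                               n_boot=args.n_boot, seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    print(f"test set: {len(preds)} regions, {int(preds['target'].sum())} cribriform")
    print(report.to_text())
    print(f"wrote {args.out / 'report.json'}")


if __name__ == "__main__":
    main()
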