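#!/usr/bin/env python
"""Split the feature table, rank by mRMR, choose the feature count by CV,
and fit the class-weighted logistic model.

Reads results/features.csv (from 04_extract_features.py), writes
results/model.json and results/cv_trace.csv, and prints the selected
features and coefficients.  For a single-ADC-feature model the printed
decision boundary -w0/w1 is the ADC cutoff (in 1e-3 mm^2/s) at which the
predicted cribriform probability crosses 0.5.
"""

import argparse
from pathlib import Path

import pandas as pd

from cribromics.model import decision_boundary_1d
from cribromics.pipeline import PipelineConfig, train_and_evaluate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    features = pd.read_csv(args.features)
    cfg = PipelineConfig(seed=args.seed)
    res = train_and_evaluate(features, cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "model.json").write_text(res.model.to_json())
    pd.DataFrame({"k": range(1, len(res.cv_trace) + 1),
                  "cv_balanced_accuracy": res.cv_trace}).to_csv(
        args.out / "cv_trace.csv", index=False)
    res.test_probabilities.to_csv(args.out / "test_predictions.csv", index=False)

    print("split sizes:", res.features["split"].value_counts().to_dict())
    print(f"mRMR top 5: {res.ranking.features[:5]}")
    print(f"selected k = {res.n_features}: {list(res.model.coefficients)}")
    print(f"w0 = {res.model.intercept:.3f}, coefficients = "
          f"{ {k: round(v, 3) for k, v in res.model.coefficients.items()} }")
    if res.n_features == 1:
        print(f"decision boundary (P=0.5): {decision_boundary_1d(res.model):.3f}")
    print(f"wrote {args.out / 'model.json'} and test predictions")


if __name__ == "__main__":
    main()
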