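#!/usr/bin/env python
"""Fit segmented-IVIM ADC/fBV maps on phantom cases and score them against truth.

For each case the multi-b DWI stack is fitted voxelwise (log-linear over
the 200-800 s/mm^2 window) and compared to the generative ADC/fBV fields
inside the prostate.  Writes results/ivim_accuracy.csv and prints the
per-label mean fitted vs true ADC, which should reproduce the encoded
ordering (cribriform lowest).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cribromics.ivim import DwiStack, fit_segmented_ivim
from cribromics.phantom import PhantomSpec, generate_phantom_case


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-cases", type=int, default=30)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    spec = PhantomSpec(n_cases=args.n_cases, seed=args.seed)
    rows = []
    for i in range(spec.n_cases):
        case = generate_phantom_case(spec, i)
        maps = fit_segmented_ivim(DwiStack(volumes=case.dwi, mask=case.prostate_mask))
        for reg in case.regions:
            rows.append({
                "case_id": case.case_id,
                "region_id": reg.region_id,
                "label": reg.label,
                "n_voxels": reg.n_voxels,
                "true_adc_mean": float(case.truth_adc.data[reg.voxels].mean()),
                "fitted_adc_mean": float(maps.adc.data[reg.voxels].mean()),
                "true_fbv_mean": float(case.truth_fbv.data[reg.voxels].mean()),
                "fitted_fbv_mean": float(maps.fbv.data[reg.voxels].mean()),
            })
    df = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "ivim_accuracy.csv", index=False)

    df["adc_err"] = np.abs(df["fitted_adc_mean"] - df["true_adc_mean"])
    print(f"{len(df)} regions over {spec.n_cases} cases")
    print("median |fitted - true| region-mean ADC: "
          f"{df['adc_err'].median():.2e} mm^2/s")
    by_label = df.groupby("label")[["true_adc_mean", "fitted_adc_mean"]].mean()
    print((1e3 * by_label).round(3).rename(
        columns=lambda c: c + "_1e-3"))
    print(f"wrote {args.out / 'ivim_accuracy.csv'}")


if __name__ == "__main__":
    main()
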