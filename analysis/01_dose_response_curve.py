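#!/usr/bin/env python
"""Steady-state dose-response of the T-cell subsets and the Treg:TEM ratio.

Evaluates the fitted indirect-response models on a dense fortnightly-dose
grid, locates the ratio-maximizing dose, and writes the curve to
results/dose_response_curve.csv.

Finding: the Treg:TEM ratio is non-monotonic in dose — it rises from the
baseline ratio (~0.73) to a maximum near 3 mg/kg q2w, where occupancy of the
cellular receptor is already near-maximal, then declines as the higher doses
begin to suppress Treg as well (ED50 ~7 mg/kg/2wk, ~20x the TEM ED50).
"""

import pathlib

import numpy as np
import pandas as pd

from il7r_pkpd.doseresponse import argmax_dose, ratio_curve, steady_state
from il7r_pkpd.params import default_dr_pair

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    pair = default_dr_pair()
    # 0.05 steps keep the stored table compact; argmax_dose refines on its
    # own 0.01 grid plus golden-section search
    grid = np.round(np.arange(0.0, 16.0 + 1e-9, 0.05), 10)
    curve = pd.DataFrame({
        "dose_mgkg_2wk": grid,
        "tem_cells_ul": steady_state(grid, pair.tem),
        "treg_cells_ul": steady_state(grid, pair.treg),
        "treg_tem_ratio": ratio_curve(grid, pair),
    })
    OUT.mkdir(exist_ok=True)
    curve.to_csv(OUT / "dose_response_curve.csv", index=False)

    d_star = argmax_dose(pair)
    print(f"baseline Treg:TEM ratio: {ratio_curve(0.0, pair):.3f}")
    print(f"ratio-maximizing dose:   {d_star:.2f} mg/kg q2w "
          f"(ratio {ratio_curve(d_star, pair):.3f})")
    print(f"high-dose asymptote:     {ratio_curve(1e9, pair):.3f}")
    print(f"wrote {OUT / 'dose_response_curve.csv'}")


if __name__ == "__main__":
    main()
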