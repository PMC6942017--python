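#!/usr/bin/env python
"""Typical-subject TMDD simulations for the studied regimens.

Simulates total antibody, total soluble receptor, and free receptor
occupancy for a 70 kg subject under each regimen and writes the profiles to
results/typical_profiles.csv with a per-regimen occupancy summary.

Findings at the published typical parameters: a single 1 mg/kg dose gives
near-complete occupancy that is lost over the second week (Free RO back to
~70% by day 14), because at this dose the free antibody falls below the
cellular-receptor pool within ~10 days and elimination is dominated by the
target-mediated pathway.  At 3 mg/kg q2w, occupancy stays high across the
whole course (trough RO ~94-96%), with the first interval being the worst.
"""

import pathlib

import numpy as np
import pandas as pd

from il7r_pkpd.params import REFERENCE_WEIGHT_KG, default_tmdd
from il7r_pkpd.tmdd import (
    DoseEvent,
    observe_free_ro,
    observe_total_mab,
    observe_total_sr,
    simulate_profile,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"

REGIMENS = {
    "1 mg/kg single": [(0.0, 1.0)],
    "1 mg/kg q2w x6": [(14.0 * k, 1.0) for k in range(6)],
    "3 mg/kg q2w x6": [(14.0 * k, 3.0) for k in range(6)],
    "6 mg/kg q2w x6": [(14.0 * k, 6.0) for k in range(6)],
    "8 mg/kg q2w x6": [(14.0 * k, 8.0) for k in range(6)],
}


def main():
    p = default_tmdd()
    wt = REFERENCE_WEIGHT_KG
    times = np.arange(0.0, 126.001, 0.25)
    frames = []
    print(f"{'regimen':18s} {'min RO %':>9s} {'FreeRO d14 %':>13s}")
    for name, sched in REGIMENS.items():
        doses = [DoseEvent(t, d * wt) for t, d in sched]
        traj = simulate_profile(p, doses, wt, times)
        ro = observe_free_ro(traj)
        keep = np.isclose(times % 1.0, 0.0)  # store daily, simulate finer
        frames.append(pd.DataFrame({
            "regimen": name, "time_day": times[keep],
            "total_mab_ngml": observe_total_mab(traj)[keep],
            "total_sil7r_ngml": observe_total_sr(traj)[keep],
            "free_ro_pct": ro[keep],
        }))
        last_dose = max(t for t, _ in sched)
        in_intervals = (times > 0) & (times <= last_dose + 14.0)
        min_ro = 100.0 - ro[in_intervals].max()
        ro14 = ro[np.argmin(np.abs(times - 14.0))]
        print(f"{name:18s} {min_ro:9.2f} {ro14:13.2f}")
    OUT.mkdir(exist_ok=True)
    pd.concat(frames).to_csv(OUT / "typical_profiles.csv", index=False)
    print(f"wrote {OUT / 'typical_profiles.csv'}")


if __name__ == "__main__":
    main()
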