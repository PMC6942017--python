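#!/usr/bin/env python
"""Prediction-corrected visual predictive checks of the simulation model.

Treats one virtual trial as "observed" data, overlays its prediction-
corrected 10th/50th/90th percentiles on bands from replicate simulations,
and writes one table per stream to results/vpc_<stream>.csv.

Because the observed trial is simulated from the same model, the observed
percentiles should sit inside the bands — this is the self-consistency
diagnostic, not a validation against real data.
"""

import argparse
import pathlib

from il7r_pkpd.datasets import GeneratorConfig, generate_study
from il7r_pkpd.params import default_dr_pair, default_tmdd
from il7r_pkpd.population import default_design, pcvpc, population_predictions

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def stream_frame(seed, stream, tmdd_p, dr, design):
    cfg = GeneratorConfig(seed=seed, streams=(stream,))
    df, _ = generate_study(cfg)
    df = population_predictions(df, tmdd_p, dr, design)
    return df[(df["EVID"] == 0) & (df["CMT"] == stream) & (df["BLQ"] == 0)]


def main(seed: int = 2020, n_sim: int = 50, streams=("TEM", "TREG")):
    tmdd_p, dr, design = default_tmdd(), default_dr_pair(), default_design()
    OUT.mkdir(exist_ok=True)
    for stream in streams:
        obs = stream_frame(seed, stream, tmdd_p, dr, design)
        table = pcvpc(
            obs,
            lambda rep: stream_frame(seed + 1 + rep, stream, tmdd_p, dr,
                                     design),
            n_sim=n_sim, band=(2.5, 97.5))
        table.to_csv(OUT / f"vpc_{stream.lower()}.csv", index=False)
        inside = sum(
            row[f"sim_{t}_lo"] <= row[f"obs_{t}"] <= row[f"sim_{t}_hi"]
            for _, row in table.iterrows() for t in ("p10", "p50", "p90"))
        total = 3 * len(table)
        print(f"{stream}: {inside}/{total} percentile points inside the "
              f"95% bands -> results/vpc_{stream.lower()}.csv")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2020)
    ap.add_argument("--n-sim", type=int, default=50)
    ap.add_argument("--streams", nargs="+", default=["TEM", "TREG"],
                    choices=["PK", "SIL7R", "FREERO", "TEM", "TREG"])
    a = ap.parse_args()
    main(seed=a.seed, n_sim=a.n_sim, streams=tuple(a.streams))
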