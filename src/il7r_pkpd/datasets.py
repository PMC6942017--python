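"""Virtual study datasets: generation, reading, and writing.

A generated study is a NONMEM-style long-format table (one row per dosing or
observation event) plus a "truth" sidecar recording every subject's
generative parameters, so estimation code can be validated by parameter
recovery without any external data.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import pandas as pd

from .params import (
    MW_MAB_KDA,
    MW_SR_KDA,
    DRPair,
    TMDDParams,
    default_dr_pair,
    default_tmdd,
)
from .population import (
    STREAMS,
    IIVSpec,
    ResidualSpec,
    TrialDesign,
    default_design,
    default_iiv,
    default_residual,
    simulate_trial,
)

__all__ = ["GeneratorConfig", "generate_study", "read_dataset",
           "write_dataset", "write_truth", "read_truth"]

_REQUIRED_COLUMNS = ["ID", "ARM", "TIME", "EVID", "CMT", "AMT", "DOSE", "WT",
                     "DV", "MDV", "BLQ"]
_VALID_CMT = set(STREAMS) | {"DOSE"}


@dataclass
class GeneratorConfig:
    """Everything that determines a virtual study; same config => same bytes."""

    seed: int = 0
    design: TrialDesign = field(default_factory=default_design)
    tmdd: TMDDParams = field(default_factory=default_tmdd)
    dr: DRPair = field(default_factory=default_dr_pair)
    iiv: IIVSpec = field(default_factory=default_iiv)
    residual: ResidualSpec = field(default_factory=default_residual)
    mw_mab_kda: float = MW_MAB_KDA
    mw_sr_kda: float = MW_SR_KDA
    streams: tuple[str, ...] = STREAMS
    #: scale each arm's baseline T-cell counts to the study's observed
    #: between-arm imbalance (off by default: arms share one typical baseline)
    arm_baseline_imbalance: bool = False


def generate_study(config: GeneratorConfig):
    """Simulate a complete virtual study.

    Returns ``(dataset, truth)``: the long-format observation table and a
    list of per-subject dicts with the generative individual parameters.
    """
    factors = None
    if config.arm_baseline_imbalance:
        from .params import TABLE_BASELINES

        factors = {
            arm: {"tem_r0": TABLE_BASELINES["tem_by_arm"][arm] / config.dr.tem.r0,
                  "treg_r0": TABLE_BASELINES["treg_by_arm"][arm] / config.dr.treg.r0}
            for arm in TABLE_BASELINES["tem_by_arm"]
        }
    return simulate_trial(
        design=config.design,
        tmdd_params=config.tmdd,
        dr_pair=config.dr,
        iiv=config.iiv,
        residual=config.residual,
        seed=config.seed,
        streams=config.streams,
        mw_mab_kda=config.mw_mab_kda,
        mw_sr_kda=config.mw_sr_kda,
        arm_baseline_factors=factors,
        return_truth=True,
    )


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write the long-format table as CSV (lossless round trip)."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    records.to_csv(path, index=False, float_format="%.12g")


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV, validating structure row by row.

    Tolerates column reordering; raises with a line number on malformed rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    bad_cmt = ~df["CMT"].isin(_VALID_CMT)
    if bad_cmt.any():
        i = int(df.index[bad_cmt][0])
        raise ValueError(
            f"line {i + 2}: unknown stream label {df.loc[i, 'CMT']!r} "
            f"(expected one of {sorted(_VALID_CMT)})")
    bad_evid = ~df["EVID"].isin([0, 1])
    if bad_evid.any():
        i = int(df.index[bad_evid][0])
        raise ValueError(f"line {i + 2}: EVID must be 0 or 1")
    obs = df["EVID"] == 0
    if df.loc[obs, "DV"].isna().any():
        i = int(df.index[obs & df["DV"].isna()][0])
        raise ValueError(f"line {i + 2}: observation row without a DV value")
    return df[_REQUIRED_COLUMNS + [c for c in df.columns
                                   if c not in _REQUIRED_COLUMNS]]


def dataset_checksum(records: pd.DataFrame) -> str:
    """Stable content hash of a dataset (for determinism checks)."""
    import hashlib

    buf = io.StringIO()
    records.to_csv(buf, index=False, float_format="%.12g")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def write_truth(truth: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)
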