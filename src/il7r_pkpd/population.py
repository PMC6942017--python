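"""Statistical layer: inter-individual variability, residual error,
virtual-trial simulation, and prediction-corrected VPCs.

Individual parameters are log-normal around the typicals,
``P_i = P_hat * exp(eta_i)`` with ``eta_i ~ N(0, Omega)``.  Residual error is
additive, proportional, or combined: ``C_ij = Chat_ij (1 + eps_p) + eps_a``.

The default :class:`TrialDesign` reproduces the multiple-ascending-dose
study: three q2w cohorts (1, 3, 8 mg/kg SC on days 1, 15, 29, 43, 57, 71),
one q1w cohort (6 mg/kg SC weekly, days 1-78), pooled placebo subjects, and
the protocol's PK/biomarker sampling days.  Five observation streams are
produced: total antibody (PK, ng/mL), total soluble receptor (SIL7R, ng/mL),
free receptor occupancy (FREERO, % of baseline), and TEM/TREG absolute
counts (cells/uL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tmdd as tm
from .doseresponse import dose_metric_q2w, response_t
from .params import (
    IIV_CV,
    LLOQ_PK_NGML,
    LLOQ_SR_NGML,
    SIGMA_PK_PROP,
    SIGMA_RO_ADD,
    SIGMA_SR_PROP,
    SIGMA_TEM_PROP,
    SIGMA_TREG_PROP,
    ULOQ_PK_NGML,
    ULOQ_SR_NGML,
    DRPair,
    TMDDParams,
)

__all__ = [
    "IIVSpec",
    "ResidualSpec",
    "Cohort",
    "TrialDesign",
    "default_design",
    "default_iiv",
    "default_residual",
    "draw_subject",
    "apply_residual",
    "simulate_trial",
    "population_predictions",
    "pcvpc",
    "STREAMS",
]

STREAMS = ("PK", "SIL7R", "FREERO", "TEM", "TREG")

_HOUR = 1.0 / 24.0

# Protocol sampling days (fractional days for the 1 h / 4 h / 48 h draws).
PK_DAYS_Q2W = (1.0, 1.0 + _HOUR, 1.0 + 4 * _HOUR, 3.0, 8.0, 15.0, 29.0, 43.0,
               57.0, 71.0, 71.0 + _HOUR, 71.0 + 4 * _HOUR, 73.0, 78.0, 85.0,
               92.0, 99.0, 113.0, 127.0)
PK_DAYS_Q1W = (1.0, 1.0 + _HOUR, 1.0 + 4 * _HOUR, 3.0, 8.0, 15.0, 29.0, 43.0,
               57.0, 71.0, 78.0, 78.0 + _HOUR, 78.0 + 4 * _HOUR, 80.0, 85.0,
               92.0, 99.0, 113.0, 127.0)
SR_DAYS_Q2W = (1.0, 1.0 + _HOUR, 3.0, 8.0, 15.0, 29.0, 43.0, 57.0, 71.0,
               73.0, 85.0, 113.0, 127.0)
SR_DAYS_Q1W = (1.0, 1.0 + _HOUR, 3.0, 8.0, 15.0, 29.0, 43.0, 57.0, 71.0,
               78.0, 80.0, 85.0, 113.0, 127.0)
RO_DAYS_Q2W = (1.0, 3.0, 8.0, 15.0, 29.0, 43.0, 57.0, 71.0, 73.0, 85.0,
               113.0, 127.0)
RO_DAYS_Q1W = (1.0, 3.0, 8.0, 15.0, 29.0, 43.0, 57.0, 71.0, 78.0, 80.0, 85.0,
               113.0, 127.0)
TCELL_DAYS = (1.0, 8.0, 15.0, 29.0, 43.0, 57.0, 71.0, 85.0, 99.0, 113.0, 127.0)

DOSING_DAYS_Q2W = (1.0, 15.0, 29.0, 43.0, 57.0, 71.0)
DOSING_DAYS_Q1W = tuple(float(d) for d in range(1, 79, 7))


@dataclass
class IIVSpec:
    """Log-normal inter-individual variability.

    ``omega2`` maps parameter names to log-scale variances; an optional
    correlation matrix (in ``names`` order) induces a full covariance block.
    """

    omega2: dict[str, float]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for k, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega2[{k!r}] must be non-negative")

    @property
    def names(self) -> list[str]:
        return list(self.omega2)

    @classmethod
    def from_cv_percent(cls, cv: dict[str, float],
                        correlation: np.ndarray | None = None) -> "IIVSpec":
        """CV% of a log-normal maps to omega^2 = ln(1 + CV^2)."""
        return cls({k: float(np.log1p((v / 100.0) ** 2)) for k, v in cv.items()},
                   correlation)

    def covariance(self) -> np.ndarray:
        sd = np.sqrt([self.omega2[k] for k in self.names])
        if self.correlation is None:
            cov = np.diag(sd ** 2)
        else:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (len(sd), len(sd)):
                raise ValueError("correlation matrix shape mismatch")
            cov = corr * np.outer(sd, sd)
        # PSD check (allowing tiny numerical negatives)
        eig = np.linalg.eigvalsh(cov) if cov.size else np.array([0.0])
        if cov.size and eig.min() < -1e-12 * max(eig.max(), 1.0):
            raise ValueError("IIV covariance matrix is not positive semi-definite")
        return cov


def default_iiv() -> IIVSpec:
    """Published CVs on CL_A, V_C, k_a, BL_SR and the T-cell R0/Emax;
    diagonal Omega (off-diagonal correlations were not reported)."""
    return IIVSpec.from_cv_percent(dict(IIV_CV))


def draw_subject(typicals: dict[str, float], iiv: IIVSpec,
                 rng: np.random.Generator) -> dict[str, float]:
    """One individual parameter set, P_i = P_hat * exp(eta_i)."""
    cov = iiv.covariance()
    names = iiv.names
    eta = rng.multivariate_normal(np.zeros(len(names)), cov) if names else []
    out = dict(typicals)
    for name, e in zip(names, eta):
        if name in out:
            out[name] = out[name] * float(np.exp(e))
    return out


@dataclass(frozen=True)
class ResidualModel:
    """sigma_prop is a fractional SD; sigma_add is in the DV's units."""

    sigma_prop: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be non-negative")


@dataclass
class ResidualSpec:
    """Per-stream residual error models."""

    models: dict[str, ResidualModel]

    def for_stream(self, stream: str) -> ResidualModel:
        return self.models.get(stream, ResidualModel())


def default_residual() -> ResidualSpec:
    return ResidualSpec({
        "PK": ResidualModel(sigma_prop=SIGMA_PK_PROP),
        "SIL7R": ResidualModel(sigma_prop=SIGMA_SR_PROP),
        "FREERO": ResidualModel(sigma_add=SIGMA_RO_ADD),
        "TEM": ResidualModel(sigma_prop=SIGMA_TEM_PROP),
        "TREG": ResidualModel(sigma_prop=SIGMA_TREG_PROP),
    })


def apply_residual(pred: float, model: ResidualModel,
                   rng: np.random.Generator,
                   clamp_at_zero: bool = True) -> tuple[float, bool]:
    """Observed value under the combined error model; returns (value, clamped)."""
    if not np.isfinite(pred):
        raise ValueError("prediction must be finite")
    eps_p = rng.normal(0.0, model.sigma_prop) if model.sigma_prop > 0 else 0.0
    eps_a = rng.normal(0.0, model.sigma_add) if model.sigma_add > 0 else 0.0
    val = pred * (1.0 + eps_p) + eps_a
    if clamp_at_zero and val < 0.0:
        return 0.0, True
    return float(val), False


@dataclass(frozen=True)
class Cohort:
    name: str
    dose_mgkg: float
    interval: str            # "q1w" | "q2w"
    n_active: int            # subjects in the T-lymphocyte analysis
    n_pk: int                # subset contributing PK/sIL7R/RO streams
    dosing_days: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.dose_mgkg <= 0 or self.n_active <= 0:
            raise ValueError("dose and n_active must be positive")
        if not 0 <= self.n_pk <= self.n_active:
            raise ValueError("n_pk must be within [0, n_active]")
        if self.interval not in ("q1w", "q2w"):
            raise ValueError("interval must be 'q1w' or 'q2w'")


@dataclass
class TrialDesign:
    """Cohorts, dosing and sampling schedules, weights, and assay limits."""

    cohorts: list[Cohort]
    n_placebo: int = 7
    pk_days: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "q2w": PK_DAYS_Q2W, "q1w": PK_DAYS_Q1W})
    sr_days: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "q2w": SR_DAYS_Q2W, "q1w": SR_DAYS_Q1W})
    ro_days: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "q2w": RO_DAYS_Q2W, "q1w": RO_DAYS_Q1W})
    tcell_days: tuple[float, ...] = TCELL_DAYS
    weight_range: tuple[float, float] = (50.0, 100.0)
    lloq_pk: float = LLOQ_PK_NGML
    uloq_pk: float = ULOQ_PK_NGML
    lloq_sr: float = LLOQ_SR_NGML
    uloq_sr: float = ULOQ_SR_NGML


def default_design() -> TrialDesign:
    """The MAD study design: arm sizes follow the analysis populations."""
    return TrialDesign(cohorts=[
        Cohort("1 mg/kg q2w", 1.0, "q2w", n_active=8, n_pk=5,
               dosing_days=DOSING_DAYS_Q2W),
        Cohort("3 mg/kg q2w", 3.0, "q2w", n_active=8, n_pk=8,
               dosing_days=DOSING_DAYS_Q2W),
        Cohort("8 mg/kg q2w", 8.0, "q2w", n_active=8, n_pk=8,
               dosing_days=DOSING_DAYS_Q2W),
        Cohort("6 mg/kg q1w", 6.0, "q1w", n_active=5, n_pk=5,
               dosing_days=DOSING_DAYS_Q1W),
    ])


_COLUMNS = ["ID", "ARM", "TIME", "EVID", "CMT", "AMT", "DOSE", "WT", "DV",
            "MDV", "BLQ"]


def _tmdd_typicals(p: TMDDParams) -> dict[str, float]:
    return {"cl_a": p.cl_a, "v_c": p.v_c, "k_a": p.k_a, "bl_sr": p.bl_sr}


def _dr_typicals(pair: DRPair) -> dict[str, float]:
    return {"tem_r0": pair.tem.r0, "tem_e_max": pair.tem.e_max,
            "treg_r0": pair.treg.r0, "treg_e_max": pair.treg.e_max}


def _clamp_emax(e: float) -> float:
    # log-normal draws can exceed 1; the structural model requires Emax < 1
    return min(e, 0.999)


def simulate_trial(
    design: TrialDesign,
    tmdd_params: TMDDParams,
    dr_pair: DRPair,
    iiv: IIVSpec,
    residual: ResidualSpec,
    seed: int,
    streams: tuple[str, ...] = STREAMS,
    mw_mab_kda: float = tm.MW_MAB_KDA,
    mw_sr_kda: float = tm.MW_SR_KDA,
    arm_baseline_factors: dict[str, dict[str, float]] | None = None,
    return_truth: bool = False,
):
    """Simulate one virtual trial as a NONMEM-style long-format table.

    Dose rows have EVID=1 and carry AMT (mg); observation rows have EVID=0
    and one of the five stream labels in CMT.  PK values below the LLOQ are
    flagged BLQ=1.  Fixed ``seed`` gives a bit-identical table.
    """
    rng = np.random.default_rng(seed)
    typicals = {**_tmdd_typicals(tmdd_params), **_dr_typicals(dr_pair)}

    def draw_for_arm(arm):
        indiv = draw_subject(typicals, iiv, rng)
        for key, mult in (arm_baseline_factors or {}).get(arm, {}).items():
            indiv[key] = indiv[key] * mult
        return indiv

    want_pk = any(s in streams for s in ("PK", "SIL7R", "FREERO"))
    rows: list[tuple] = []
    truth: list[dict] = []
    sid = 0

    def tcell_rows(sid, arm, dose_mgkg, dose2w, wt, indiv, rng):
        for stream, r0_key, emax_key, p0 in (
                ("TEM", "tem_r0", "tem_e_max", dr_pair.tem),
                ("TREG", "treg_r0", "treg_e_max", dr_pair.treg)):
            if stream not in streams:
                continue
            from dataclasses import replace as _replace
            p_i = _replace(p0, r0=indiv[r0_key],
                           e_max=_clamp_emax(indiv[emax_key]))
            model = residual.for_stream(stream)
            for day in design.tcell_days:
                pred = float(response_t(max(day - 1.0, 0.0), dose2w, p_i))
                dv, _ = apply_residual(pred, model, rng)
                rows.append((sid, arm, day, 0, stream, 0.0, dose_mgkg, wt,
                             dv, 0, 0))

    # placebo subjects: T-cell streams only, no drug effect
    for _ in range(design.n_placebo):
        sid += 1
        wt = rng.uniform(*design.weight_range)
        indiv = draw_for_arm("placebo")
        truth.append({"ID": sid, "ARM": "placebo", "DOSE_MGKG": 0.0,
                      "DOSE_2W": 0.0, "WT": wt, **indiv})
        tcell_rows(sid, "placebo", 0.0, 0.0, wt, indiv, rng)

    for cohort in design.cohorts:
        dose2w = dose_metric_q2w(cohort.dose_mgkg, cohort.interval)
        for j in range(cohort.n_active):
            sid += 1
            wt = rng.uniform(*design.weight_range)
            indiv = draw_for_arm(cohort.name)
            truth.append({"ID": sid, "ARM": cohort.name,
                          "DOSE_MGKG": cohort.dose_mgkg, "DOSE_2W": dose2w,
                          "WT": wt, **indiv})
            dose_mg = cohort.dose_mgkg * wt
            for day in cohort.dosing_days:
                rows.append((sid, cohort.name, day, 1, "DOSE", dose_mg,
                             cohort.dose_mgkg, wt, np.nan, 1, 0))
            in_pk_subset = j < cohort.n_pk
            if want_pk and in_pk_subset:
                p_i = tmdd_params.with_updates(
                    cl_a=indiv["cl_a"], v_c=indiv["v_c"], k_a=indiv["k_a"],
                    bl_sr=indiv["bl_sr"])
                pk_days = design.pk_days[cohort.interval]
                sr_days = design.sr_days[cohort.interval]
                ro_days = design.ro_days[cohort.interval]
                all_days = np.unique(np.concatenate([pk_days, sr_days, ro_days]))
                doses = [tm.DoseEvent(d, dose_mg) for d in cohort.dosing_days]
                traj = tm.simulate_profile(p_i, doses, wt, all_days,
                                           mw_mab_kda=mw_mab_kda,
                                           mw_sr_kda=mw_sr_kda)
                obs = {
                    "PK": dict(zip(all_days, tm.observe_total_mab(traj))),
                    "SIL7R": dict(zip(all_days, tm.observe_total_sr(traj))),
                    "FREERO": dict(zip(all_days, tm.observe_free_ro(traj))),
                }
                for stream, days in (("PK", pk_days), ("SIL7R", sr_days),
                                     ("FREERO", ro_days)):
                    if stream not in streams:
                        continue
                    model = residual.for_stream(stream)
                    for day in days:
                        dv, _ = apply_residual(obs[stream][day], model, rng)
                        blq = 0
                        if stream == "PK" and dv < design.lloq_pk:
                            blq = 1
                        elif stream == "SIL7R" and dv < design.lloq_sr:
                            blq = 1
                        rows.append((sid, cohort.name, day, 0, stream, 0.0,
                                     cohort.dose_mgkg, wt, dv, 0, blq))
            tcell_rows(sid, cohort.name, cohort.dose_mgkg, dose2w, wt, indiv, rng)

    df = pd.DataFrame(rows, columns=_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID", "CMT"],
                        kind="mergesort").reset_index(drop=True)
    if return_truth:
        return df, truth
    return df


def population_predictions(
    df: pd.DataFrame,
    tmdd_params: TMDDParams,
    dr_pair: DRPair,
    design: TrialDesign,
    mw_mab_kda: float = tm.MW_MAB_KDA,
    mw_sr_kda: float = tm.MW_SR_KDA,
) -> pd.DataFrame:
    """Attach a PRED column: predictions at typical parameters.

    PK-type predictions depend on the subject's weight through the absolute
    dose; T-cell predictions depend only on the dose metric.
    """
    df = df.copy()
    df["PRED"] = np.nan
    arm_by_name = {c.name: c for c in design.cohorts}
    obs = df["EVID"] == 0

    # T-cell streams: closed form at typicals
    for stream, p in (("TEM", dr_pair.tem), ("TREG", dr_pair.treg)):
        m = obs & (df["CMT"] == stream)
        if not m.any():
            continue
        dose2w = np.array([
            dose_metric_q2w(arm_by_name[a].dose_mgkg, arm_by_name[a].interval)
            if a in arm_by_name else 0.0
            for a in df.loc[m, "ARM"]])
        t = np.maximum(df.loc[m, "TIME"].to_numpy(dtype=float) - 1.0, 0.0)
        df.loc[m, "PRED"] = p.r0 * (np.exp(-p.k_out * t)
                                    + (1 - p.e_max * dose2w / (p.ed50 + dose2w))
                                    * (1 - np.exp(-p.k_out * t)))

    pk_like = obs & df["CMT"].isin(["PK", "SIL7R", "FREERO"])
    if pk_like.any():
        for (arm, wt), grp in df[pk_like].groupby(["ARM", "WT"]):
            cohort = arm_by_name[arm]
            days = np.unique(grp["TIME"].to_numpy(dtype=float))
            doses = [tm.DoseEvent(d, cohort.dose_mgkg * wt)
                     for d in cohort.dosing_days]
            traj = tm.simulate_profile(tmdd_params, doses, wt, days,
                                       mw_mab_kda=mw_mab_kda,
                                       mw_sr_kda=mw_sr_kda)
            lookup = {
                "PK": dict(zip(days, tm.observe_total_mab(traj))),
                "SIL7R": dict(zip(days, tm.observe_total_sr(traj))),
                "FREERO": dict(zip(days, tm.observe_free_ro(traj))),
            }
            for idx, row in grp.iterrows():
                df.loc[idx, "PRED"] = lookup[row["CMT"]][row["TIME"]]
    return df


def pcvpc(
    dataset: pd.DataFrame,
    simulate_fn,
    n_sim: int,
    bins: np.ndarray | None = None,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
    band: tuple[float, float] = (10.0, 90.0),
) -> pd.DataFrame:
    """Prediction-corrected visual predictive check for one stream.

    ``dataset`` must hold observation rows of a single stream with TIME, DV
    and PRED columns.  Each record is prediction-corrected,
    ``pcY = Y * median(PRED in bin) / PRED``, binned by nominal time (or a
    supplied bin edge array), and the observed 10/50/90th percentiles are
    compared with prediction intervals of the same percentiles across
    ``n_sim`` replicates from ``simulate_fn(replicate_index)``, which must
    return a table with the same structure.
    """
    if "PRED" not in dataset.columns:
        raise ValueError("dataset must carry population predictions (PRED)")

    def _bin_of(times):
        if bins is None:
            return np.asarray(times, dtype=float)
        idx = np.digitize(times, bins)
        return idx.astype(float)

    def _pc_percentiles(df):
        df = df[df["PRED"] > 0].copy()
        df["_BIN"] = _bin_of(df["TIME"].to_numpy(dtype=float))
        out = {}
        for b, grp in df.groupby("_BIN"):
            med = float(np.median(grp["PRED"]))
            pcy = grp["DV"].to_numpy(dtype=float) * med / grp["PRED"].to_numpy(dtype=float)
            out[b] = (len(pcy), np.percentile(pcy, percentiles))
        return out

    obs_stats = _pc_percentiles(dataset)
    if not obs_stats:
        raise ValueError("no usable observation records")

    sim_stats: dict[float, list[np.ndarray]] = {b: [] for b in obs_stats}
    for rep in range(n_sim):
        rep_stats = _pc_percentiles(simulate_fn(rep))
        for b in sim_stats:
            if b in rep_stats:
                sim_stats[b].append(rep_stats[b][1])

    rows = []
    for b in sorted(obs_stats):
        n, opcts = obs_stats[b]
        sims = np.array(sim_stats[b])
        if sims.size == 0:
            warnings.warn(f"bin {b} empty in all simulations; dropped",
                          stacklevel=2)
            continue
        row = {"bin": b, "n_obs": n}
        for k, p in enumerate(percentiles):
            tag = f"p{int(p)}"
            row[f"obs_{tag}"] = opcts[k]
            row[f"sim_{tag}_lo"] = np.percentile(sims[:, k], band[0])
            row[f"sim_{tag}_med"] = np.percentile(sims[:, k], 50.0)
            row[f"sim_{tag}_hi"] = np.percentile(sims[:, k], band[1])
        rows.append(row)
    return pd.DataFrame(rows)
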