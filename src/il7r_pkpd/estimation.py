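"""Estimation: population dose-response fits, per-subject TMDD fits,
and nonparametric bootstrap uncertainty.

The population dose-response fit maximizes a Laplace-type approximate
marginal likelihood: log-normal random effects on R0 and Emax, proportional
residual error, the inner random-effect modes found by vectorized
Gauss-Newton with analytic derivatives, and the marginal contribution of
each subject approximated with the Gauss-Newton Hessian.  Structural
parameters are optimized on transformed scales (log for positive
parameters, logit for Emax) with multi-start Nelder-Mead.

The per-subject TMDD fit is penalized least squares on log residuals with
log-normal shrinkage toward the population typical values, the published
inter-individual variances serving as penalty weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit, logit

from . import tmdd as tm
from .doseresponse import response_t
from .params import IIV_CV, DRPair, DRParams, TMDDParams

__all__ = [
    "FitResult",
    "BootstrapSet",
    "IdentifiabilityError",
    "default_dr_init",
    "fit_dr_population",
    "fit_dr_pair",
    "fit_subject_tmdd",
    "bootstrap_dr",
    "dr_uncertainty_bands",
]

_FLOOR = 1e-4          # lower bound for sigma and omega (SD scales)
_EMAX_CAP = 0.999      # individual Emax cap (structural model needs Emax < 1)


class IdentifiabilityError(ValueError):
    """Raised when the design cannot identify the requested parameters."""


@dataclass
class FitResult:
    population: str
    estimates: dict[str, float]
    iiv_cv: dict[str, float]            # % CV of the log-normal random effects
    sigma: float
    objective: float
    converged: bool
    n_subjects: int
    eta_modes: dict[int, dict[str, float]] = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)
    message: str = ""

    @property
    def dr_params(self) -> DRParams:
        return DRParams(r0=self.estimates["r0"], k_out=self.estimates["k_out"],
                        e_max=self.estimates["e_max"], ed50=self.estimates["ed50"])

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "estimates": self.estimates,
            "iiv_cv": self.iiv_cv,
            "sigma": self.sigma,
            "objective": self.objective,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "message": self.message,
        }


def _dose2w_of(df: pd.DataFrame) -> pd.Series:
    """Fortnightly dose metric per row from DOSE (mg/kg) and the arm label."""
    mult = df["ARM"].astype(str).str.contains("q1w").map({True: 2.0, False: 1.0})
    return df["DOSE"].astype(float) * mult


@dataclass
class _SubjectGroup:
    """Subjects sharing one observation-time grid, stacked for vector math."""

    ids: list[int]
    t: np.ndarray       # (T,) days since first dose
    y: np.ndarray       # (S, T)
    dose: np.ndarray    # (S,)


def _build_groups(df: pd.DataFrame, stream: str) -> list[_SubjectGroup]:
    obs = df[(df["EVID"] == 0) & (df["CMT"] == stream)].copy()
    if obs.empty:
        raise ValueError(f"dataset has no {stream} observations")
    obs["DOSE2W"] = _dose2w_of(obs)
    obs["T"] = np.maximum(obs["TIME"].astype(float) - 1.0, 0.0)
    groups: dict[tuple, list] = {}
    for sid, sub in obs.groupby("ID"):
        sub = sub.sort_values("T")
        key = tuple(np.round(sub["T"].to_numpy(dtype=float), 9))
        groups.setdefault(key, []).append(
            (int(sid), sub["DV"].to_numpy(dtype=float),
             float(sub["DOSE2W"].iloc[0])))
    out = []
    for key, members in groups.items():
        out.append(_SubjectGroup(
            ids=[m[0] for m in members],
            t=np.array(key, dtype=float),
            y=np.vstack([m[1] for m in members]),
            dose=np.array([m[2] for m in members]),
        ))
    return out


def _model_f(eta, t, dose, r0, kout, emax, ed50, idx):
    """Individual predictions f (S, T) and pieces needed for derivatives."""
    S = dose.shape[0]
    r0i = np.full(S, r0)
    emaxi = np.full(S, emax)
    if "r0" in idx:
        r0i = r0 * np.exp(np.clip(eta[:, idx["r0"]], -40.0, 40.0))
    if "e_max" in idx:
        emaxi = emax * np.exp(np.clip(eta[:, idx["e_max"]], -40.0, 40.0))
    clamped = emaxi > _EMAX_CAP
    emaxi = np.minimum(emaxi, _EMAX_CAP)
    inh = emaxi * dose / (ed50 + dose)            # (S,)
    e = np.exp(-kout * t)                          # (T,)
    f = r0i[:, None] * (e[None, :] + (1.0 - inh)[:, None] * (1.0 - e)[None, :])
    return f, r0i, emaxi, inh, clamped, e


def _inner_modes(group: _SubjectGroup, r0, kout, emax, ed50, sigma, om2, idx,
                 max_iter=50, tol=1e-6):
    """Vectorized Gauss-Newton for the random-effect modes of one group.

    Always starts from eta = 0 so the marginal objective is a deterministic
    function of the structural parameters.  Subjects whose Gauss-Newton step
    fails the backtracking line search retry along the (Omega-preconditioned)
    steepest-descent direction.  Returns (eta_hat, f_hat, JtJ) with JtJ the
    (S, d, d) Gauss-Newton information of the weighted residuals at the mode.
    """
    S = group.dose.shape[0]
    d = len(idx)
    eta = np.zeros((S, d))
    if d == 0:
        f, *_ = _model_f(eta, group.t, group.dose, r0, kout, emax, ed50, idx)
        return eta, f, np.zeros((S, 0, 0))
    y = group.y
    inv_om2 = 1.0 / om2                            # (d,)

    def q_of(eta_):
        f, *_ = _model_f(eta_, group.t, group.dose, r0, kout, emax, ed50, idx)
        r = (y - f) / (sigma * f)
        return np.sum(r * r, axis=1) + np.sum(eta_ * eta_ * inv_om2, axis=1), f

    def grad_and_dir(eta_):
        f, r0i, emaxi, inh, clamped, e = _model_f(
            eta_, group.t, group.dose, r0, kout, emax, ed50, idx)
        r = (y - f) / (sigma * f)
        # dr/deta_k = -df/deta_k * y / (sigma f^2)
        w = y / (sigma * f * f)                    # (S, T)
        Jcols = []
        for name in idx:
            if name == "r0":
                dfde = f
            else:  # e_max
                dinh = np.where(clamped, 0.0, inh)
                dfde = -(r0i * dinh)[:, None] * (1.0 - e)[None, :]
            Jcols.append(-dfde * w)
        J = np.stack(Jcols, axis=2)                # (S, T, d)
        g = np.einsum("stk,st->sk", J, r) + eta_ * inv_om2
        JtJ = np.einsum("stk,stl->skl", J, J)
        A = JtJ + np.diag(inv_om2)[None, :, :]
        try:
            delta = -np.linalg.solve(A, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            delta = -g * om2
        return g, delta, JtJ

    def line_search(eta_, q, direction, active):
        step = np.ones(S)
        accepted = np.zeros(S, dtype=bool)
        out = eta_.copy()
        for _half in range(8):
            todo = active & ~accepted
            if not todo.any():
                break
            cand = np.where(todo[:, None], eta_ + step[:, None] * direction,
                            out)
            q_new, _ = q_of(cand)
            better = (q_new < q - 1e-14 * np.abs(q)) & todo
            out = np.where(better[:, None], cand, out)
            accepted |= better
            step[todo] *= 0.5
        return out, accepted

    q, f = q_of(eta)
    frozen = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        g, delta, _ = grad_and_dir(eta)
        active = (np.max(np.abs(delta), axis=1) > tol) & ~frozen
        if not active.any():
            break
        eta_new, accepted = line_search(eta, q, delta, active)
        failed = active & ~accepted
        if failed.any():
            # Omega-preconditioned steepest descent for the stragglers;
            # subjects that still fail are at the line-search floor
            eta_sd, acc_sd = line_search(eta, q, -g * om2, failed)
            eta_new = np.where((failed & acc_sd)[:, None], eta_sd, eta_new)
            frozen |= failed & ~acc_sd
        eta = eta_new
        q, f = q_of(eta)
    # final Gauss-Newton information at the mode
    f, r0i, emaxi, inh, clamped, e = _model_f(
        eta, group.t, group.dose, r0, kout, emax, ed50, idx)
    w = y / (sigma * f * f)
    Jcols = []
    for name, k in idx.items():
        if name == "r0":
            dfde = f
        else:
            dinh = np.where(clamped, 0.0, inh)
            dfde = -(r0i * dinh)[:, None] * (1.0 - e)[None, :]
        Jcols.append(-dfde * w)
    J = np.stack(Jcols, axis=2)
    JtJ = np.einsum("stk,stl->skl", J, J)
    return eta, f, JtJ


_X_BOUNDS = {
    "r0": (math.log(1e-2), math.log(1e4)),
    "k_out": (math.log(1e-4), math.log(2.0)),
    "e_max": (-8.0, 8.0),          # logit scale
    "ed50": (math.log(1e-3), math.log(1e3)),
    "omega": (math.log(_FLOOR), math.log(3.0)),
    "sigma": (math.log(_FLOOR), math.log(3.0)),
}


def _x_bounds(idx):
    return ([_X_BOUNDS["r0"], _X_BOUNDS["k_out"], _X_BOUNDS["e_max"],
             _X_BOUNDS["ed50"]] + [_X_BOUNDS["omega"]] * len(idx)
            + [_X_BOUNDS["sigma"]])


def _theta_unpack(x, idx):
    x = np.clip(x, -60.0, 60.0)
    r0 = math.exp(x[0])
    kout = math.exp(x[1])
    emax = float(expit(x[2]))
    ed50 = math.exp(x[3])
    om = np.maximum(np.exp(x[4:4 + len(idx)]), _FLOOR)
    sigma = max(math.exp(x[4 + len(idx)]), _FLOOR)
    return r0, kout, emax, ed50, om ** 2, sigma


def _neg2ll(x, groups, idx):
    r0, kout, emax, ed50, om2, sigma = _theta_unpack(x, idx)
    total = 0.0
    for group in groups:
        eta, f, JtJ = _inner_modes(group, r0, kout, emax, ed50, sigma, om2, idx)
        y = group.y
        r = (y - f) / (sigma * f)
        total += float(np.sum(np.log(2.0 * np.pi * sigma * sigma * f * f) + r * r))
        if idx:
            total += float(np.sum(eta * eta / om2))
            # Laplace correction: log det(I + Omega * JtJ) per subject
            M = np.eye(len(idx))[None, :, :] + om2[None, :, None] * JtJ
            sign, logdet = np.linalg.slogdet(M)
            total += float(np.sum(logdet))
    return total


def default_dr_init(dataset: pd.DataFrame, population: str = "TEM") -> DRParams:
    """Data-derived starting values (no reference to generative truth).

    Baseline from day-1 samples across all subjects; Emax from the terminal
    suppression in the highest-dose arm; ED50 at a quarter of the median
    positive dose; turnover half-life started at two weeks.
    """
    obs = dataset[(dataset["EVID"] == 0) & (dataset["CMT"] == population)].copy()
    if obs.empty:
        raise ValueError(f"no {population} observations")
    obs["DOSE2W"] = _dose2w_of(obs)
    r0 = float(obs.loc[obs["TIME"] <= 1.0, "DV"].mean())
    if not np.isfinite(r0) or r0 <= 0:
        r0 = float(obs["DV"].mean())
    pos = obs[obs["DOSE2W"] > 0]
    if pos.empty:
        raise IdentifiabilityError(
            f"{population}: all subjects are unexposed (placebo-only dataset); "
            "Emax and ED50 are not identifiable")
    top = pos[pos["DOSE2W"] == pos["DOSE2W"].max()]
    terminal = float(top.loc[top["TIME"] >= 85.0, "DV"].mean())
    if not np.isfinite(terminal) or terminal <= 0:
        terminal = float(top["DV"].min())
    e_max = float(np.clip(1.0 - terminal / r0, 0.10, 0.90))
    ed50 = float(np.median(pos["DOSE2W"].unique()) / 4.0)
    return DRParams(r0=r0, k_out=math.log(2.0) / 14.0, e_max=e_max, ed50=ed50)


def fit_dr_population(
    dataset: pd.DataFrame,
    init: DRParams | None = None,
    population: str = "TEM",
    iiv_on: tuple[str, ...] = ("r0", "e_max"),
    sigma_init: float = 0.15,
    omega_init: float = 0.3,
    n_starts: int = 3,
    seed: int = 0,
    maxfev: int = 6000,
    ftol: float = 1e-10,
) -> FitResult:
    """Fit the indirect-response dose-response model to one T-cell stream.

    Requires exposed subjects (placebo alone cannot identify Emax/ED50).
    Each of the ``n_starts`` jittered starts runs a quasi-Newton pass
    (L-BFGS-B on the transformed parameters with finite-difference
    gradients); the best start is polished with Powell line searches.
    """
    groups = _build_groups(dataset, population)
    if all((g.dose == 0).all() for g in groups):
        raise IdentifiabilityError(
            f"{population}: all subjects are unexposed (placebo-only dataset); "
            "Emax and ED50 are not identifiable")
    if init is None:
        init = default_dr_init(dataset, population)
    idx = {name: k for k, name in enumerate(iiv_on)}

    x0 = np.array([math.log(init.r0), math.log(init.k_out),
                   float(logit(init.e_max)), math.log(init.ed50)]
                  + [math.log(omega_init)] * len(idx)
                  + [math.log(sigma_init)])

    rng = np.random.default_rng(seed)
    trace: list[float] = []

    def fun(x):
        val = _neg2ll(x, groups, idx)
        if not np.isfinite(val):
            return 1e12
        trace.append(val if not trace else min(trace[-1], val))
        return val

    bounds = _x_bounds(idx)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    for s in range(n_starts):
        # the primary start gets the full budget; jittered restarts probe
        # for alternative basins on a smaller one
        x_start = x0 if s == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
        x_start = np.clip(x_start, lo, hi)
        res = minimize(fun, x_start, method="L-BFGS-B", bounds=bounds,
                       options={"eps": 1e-6,
                                "maxfun": maxfev // 2 if s == 0 else 400})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    polish = minimize(fun, best.x, method="Powell", bounds=bounds,
                      options={"ftol": ftol, "xtol": 1e-8, "maxfev": maxfev})
    # the polish stage settles convergence even when it cannot improve on
    # the quasi-Newton iterate (noisy finite-difference gradients make
    # L-BFGS-B end with a line-search failure at the optimum)
    converged = bool(polish.success or best.success)
    if polish.fun <= best.fun:
        best = polish

    r0, kout, emax, ed50, om2, sigma = _theta_unpack(best.x, idx)
    eta_modes: dict[int, dict[str, float]] = {}
    for gi, group in enumerate(groups):
        eta, _, _ = _inner_modes(group, r0, kout, emax, ed50, sigma, om2, idx)
        for si, sid in enumerate(group.ids):
            mode = {}
            if "r0" in idx:
                mode["r0"] = r0 * math.exp(eta[si, idx["r0"]])
            if "e_max" in idx:
                mode["e_max"] = min(emax * math.exp(eta[si, idx["e_max"]]),
                                    _EMAX_CAP)
            eta_modes[sid] = mode

    iiv_cv = {name: 100.0 * math.sqrt(math.expm1(om2[k]))
              for name, k in idx.items()}
    return FitResult(
        population=population,
        estimates={"r0": r0, "k_out": kout, "e_max": emax, "ed50": ed50},
        iiv_cv=iiv_cv,
        sigma=sigma,
        objective=float(best.fun),
        converged=converged,
        n_subjects=sum(len(g.ids) for g in groups),
        eta_modes=eta_modes,
        objective_trace=trace,
        message=str(best.message),
    )


def fit_dr_pair(dataset: pd.DataFrame, seed: int = 0, **kwargs) -> dict[str, FitResult]:
    """Fit TEM and TREG models independently to the same trial."""
    return {pop: fit_dr_population(dataset, population=pop, seed=seed, **kwargs)
            for pop in ("TEM", "TREG")}


# ---------------------------------------------------------------------------
# per-subject TMDD fit


def fit_subject_tmdd(
    records: pd.DataFrame,
    typicals: TMDDParams,
    free: tuple[str, ...] = ("cl_a", "v_c", "k_a", "bl_sr"),
    omega_cv: dict[str, float] | None = None,
    sigma_pk: float = 0.434,
    sigma_sr: float = 0.150,
    sigma_ro: float = 18.2,
    use_ro: bool = True,
    mw_mab_kda: float = tm.MW_MAB_KDA,
    mw_sr_kda: float = tm.MW_SR_KDA,
) -> dict[str, float]:
    """Penalized least squares for one subject's PK/target-engagement data.

    Log residuals for the PK and soluble-receptor streams (proportional
    error), optional additive residuals for Free RO, and a log-normal
    shrinkage penalty toward the typical values weighted by the published
    inter-individual variances.  All other parameters stay at typicals.
    """
    if omega_cv is None:
        omega_cv = {k: IIV_CV[k] for k in free}
    omega = {k: math.sqrt(math.log1p((omega_cv[k] / 100.0) ** 2)) for k in free}

    doses_df = records[records["EVID"] == 1]
    if doses_df.empty:
        raise ValueError("subject has no dose records")
    wt = float(records["WT"].iloc[0])
    doses = [tm.DoseEvent(float(r.TIME), float(r.AMT))
             for r in doses_df.itertuples()]

    def stream_obs(name, drop_blq=True):
        m = (records["EVID"] == 0) & (records["CMT"] == name)
        if drop_blq:
            m &= records["BLQ"] == 0
        sub = records[m]
        return sub["TIME"].to_numpy(dtype=float), sub["DV"].to_numpy(dtype=float)

    t_pk, y_pk = stream_obs("PK")
    if t_pk.size < 4:
        raise ValueError(
            f"only {t_pk.size} quantifiable PK observations; at least 4 are "
            "required for a per-subject TMDD fit")
    t_sr, y_sr = stream_obs("SIL7R")
    t_ro, y_ro = stream_obs("FREERO") if use_ro else (np.array([]), np.array([]))

    all_times = np.unique(np.concatenate([t_pk, t_sr, t_ro]))
    log_typ = np.array([math.log(getattr(typicals, k)) for k in free])
    om = np.array([omega[k] for k in free])

    def residuals(x):
        p = typicals.with_updates(**{k: math.exp(v) for k, v in zip(free, x)})
        traj = tm.simulate_profile(p, doses, wt, all_times,
                                   mw_mab_kda=mw_mab_kda, mw_sr_kda=mw_sr_kda)
        pk = dict(zip(all_times, tm.observe_total_mab(traj)))
        sr = dict(zip(all_times, tm.observe_total_sr(traj)))
        ro = dict(zip(all_times, tm.observe_free_ro(traj)))
        res = []
        for t, y in zip(t_pk, y_pk):
            res.append((math.log(max(y, 1e-9)) - math.log(max(pk[t], 1e-12)))
                       / sigma_pk)
        for t, y in zip(t_sr, y_sr):
            res.append((math.log(max(y, 1e-9)) - math.log(max(sr[t], 1e-12)))
                       / sigma_sr)
        for t, y in zip(t_ro, y_ro):
            res.append((y - ro[t]) / sigma_ro)
        res.extend((x - log_typ) / om)
        return np.array(res)

    sol = least_squares(residuals, log_typ, method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    return {k: math.exp(v) for k, v in zip(free, sol.x)}


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapSet:
    """Replicate dose-response parameter sets from subject-level resampling."""

    replicates: list[dict[str, DRParams]]
    seed: int
    n_requested: int
    n_converged: int
    populations: tuple[str, ...]


def _subject_blocks(dataset: pd.DataFrame, populations) -> dict[str, list[int]]:
    obs = dataset[(dataset["EVID"] == 0) & dataset["CMT"].isin(populations)]
    by_arm: dict[str, list[int]] = {}
    for (arm, sid), _ in obs.groupby(["ARM", "ID"]):
        by_arm.setdefault(arm, []).append(int(sid))
    return by_arm


def bootstrap_dr(
    dataset: pd.DataFrame,
    n_boot: int,
    seed: int,
    base_fits: dict[str, FitResult] | None = None,
    populations: tuple[str, ...] = ("TEM", "TREG"),
    resampler=None,
    **fit_kwargs,
) -> BootstrapSet:
    """Nonparametric bootstrap of the dose-response fits.

    Subjects are resampled with replacement within each arm (preserving the
    dose design); each replicate is refit from the base estimates with a
    single start.  ``resampler(rng, ids_by_arm) -> list[int]`` may override
    the resampling (e.g. the identity for testing).  Non-converging
    replicates are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    if base_fits is None:
        base_fits = {p: fit_dr_population(dataset, population=p, seed=seed,
                                          **fit_kwargs)
                     for p in populations}
    by_arm = _subject_blocks(dataset, populations)
    blocks = {int(sid): grp for sid, grp in dataset.groupby("ID")}

    replicates = []
    n_converged = 0
    for _b in range(n_boot):
        if resampler is not None:
            ids = list(resampler(rng, by_arm))
        else:
            ids = []
            for arm in sorted(by_arm):
                pool = by_arm[arm]
                ids.extend(rng.choice(pool, size=len(pool), replace=True))
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            blk = blocks[int(sid)].copy()
            blk["ID"] = new_id
            parts.append(blk)
        boot_df = pd.concat(parts, ignore_index=True)
        rep: dict[str, DRParams] = {}
        ok = True
        for pop in populations:
            try:
                fit = fit_dr_population(
                    boot_df, init=base_fits[pop].dr_params, population=pop,
                    n_starts=1, seed=int(rng.integers(2 ** 31 - 1)),
                    sigma_init=max(base_fits[pop].sigma, 0.01),
                    **fit_kwargs)
            except (IdentifiabilityError, ValueError):
                ok = False
                break
            if not fit.converged:
                ok = False
                break
            rep[pop] = fit.dr_params
        if ok:
            replicates.append(rep)
            n_converged += 1
    return BootstrapSet(replicates=replicates, seed=seed, n_requested=n_boot,
                        n_converged=n_converged, populations=populations)


def dr_uncertainty_bands(
    bset: BootstrapSet,
    dose_grid,
    band: tuple[float, float] = (5.0, 95.0),
) -> pd.DataFrame:
    """Percentile bands of the steady-state dose-response across replicates.

    Columns per endpoint (tem, treg, ratio when both populations are
    present): lower band, median, upper band at each grid dose.
    """
    from .doseresponse import steady_state

    if not bset.replicates:
        raise ValueError("bootstrap produced no converged replicates")
    dose_grid = np.asarray(dose_grid, dtype=float)
    out = {"dose": dose_grid}
    curves: dict[str, np.ndarray] = {}
    for pop in bset.populations:
        curves[pop] = np.vstack([steady_state(dose_grid, rep[pop])
                                 for rep in bset.replicates])
    if {"TEM", "TREG"} <= set(bset.populations):
        curves["RATIO"] = curves["TREG"] / curves["TEM"]
    for name, arr in curves.items():
        tag = name.lower()
        out[f"{tag}_lo"] = np.percentile(arr, band[0], axis=0)
        out[f"{tag}_med"] = np.percentile(arr, 50.0, axis=0)
        out[f"{tag}_hi"] = np.percentile(arr, band[1], axis=0)
    return pd.DataFrame(out)
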