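"""Two-compartment quasi-equilibrium TMDD model with two IL-7Ralpha targets.

Five states, all amounts in nmol:

    A1  total antibody in the central compartment (free + both complexes)
    A2  free antibody in the peripheral compartment
    A3  total soluble receptor in the central compartment
    A4  total cellular receptor in the central compartment
    A5  antibody in the SC depot

At every right-hand-side evaluation the algebraic QE system is solved for
the complex and free amounts (see :mod:`il7r_pkpd.binding`); elimination
then acts on the free/complex species separately:

    dA1/dt = ka*A5 + Q*(A2/Vp - FAB/Vc) - CLA/Vc*FAB - CLC1/Vc*CPX1 - CLC2/Vc*CPX2
    dA2/dt = Q*(FAB/Vc - A2/Vp)
    dA3/dt = ksyn1 - CLSR/Vc*FSR - CLC1/Vc*CPX1
    dA4/dt = ksyn2 - CLCR/Vc*FCR - CLC2/Vc*CPX2
    dA5/dt = -ka*A5

Receptor synthesis rates are tied to baseline (``ksyn = CL*BL``) so the
drug-free system is at steady state.  SC doses enter the depot as
``F * dose`` (in nmol) with integration restarted at each dose event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .binding import BindingInputs, ComplexSolution, solve_complex_pair
from .params import MW_MAB_KDA, MW_SR_KDA, TMDDParams

__all__ = [
    "DoseEvent",
    "Trajectory",
    "rhs",
    "simulate_profile",
    "observe_total_mab",
    "observe_total_sr",
    "observe_free_ro",
    "mgkg_to_nmol",
    "mg_to_nmol",
    "nM_to_ngml",
    "ngml_to_nM",
]


@dataclass(frozen=True)
class DoseEvent:
    """A subcutaneous dose: absolute amount in mg at a given day."""

    time: float
    amount_mg: float

    def __post_init__(self) -> None:
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")


def mg_to_nmol(amount_mg: float, mw_kda: float) -> float:
    """Convert mg of protein to nmol given molecular weight in kDa."""
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return amount_mg / mw_kda * 1e3


def mgkg_to_nmol(dose_mgkg: float, weight_kg: float, mw_kda: float) -> float:
    """Convert a weight-based dose (mg/kg) to nmol."""
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return mg_to_nmol(dose_mgkg * weight_kg, mw_kda)


def nM_to_ngml(conc_nM: float, mw_kda: float) -> float:
    """nmol/L -> ng/mL; numerically conc * MW(kDa)."""
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return conc_nM * mw_kda


def ngml_to_nM(conc_ngml: float, mw_kda: float) -> float:
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return conc_ngml / mw_kda


def rhs(state, params: TMDDParams):
    """Time derivative of the five amount states."""
    a1 = max(state[0], 0.0)
    a2 = max(state[1], 0.0)
    a3 = max(state[2], 0.0)
    a4 = max(state[3], 0.0)
    a5 = max(state[4], 0.0)
    sol = solve_complex_pair(BindingInputs(a1, a3, a4, params.kd1, params.kd2, params.v_c))
    vc = params.v_c
    da1 = (params.k_a * a5
           + params.q * (a2 / params.v_p - sol.FAB / vc)
           - params.cl_a / vc * sol.FAB
           - params.cl_c1 / vc * sol.CPX1
           - params.cl_c2 / vc * sol.CPX2)
    da2 = params.q * (sol.FAB / vc - a2 / params.v_p)
    da3 = params.k_syn1 - params.cl_sr / vc * sol.FSR - params.cl_c1 / vc * sol.CPX1
    da4 = params.k_syn2 - params.cl_cr / vc * sol.FCR - params.cl_c2 / vc * sol.CPX2
    da5 = -params.k_a * a5
    return (da1, da2, da3, da4, da5)


@dataclass
class Trajectory:
    """Simulated state and QE species on an output time grid.

    Observation times that coincide with a dose are pre-dose values.
    """

    times: np.ndarray          # (n,) days
    states: np.ndarray         # (n, 5) amounts, nmol
    complexes: list            # n ComplexSolution entries
    params: TMDDParams
    mw_mab_kda: float = MW_MAB_KDA
    mw_sr_kda: float = MW_SR_KDA

    def to_frame(self):
        """Tidy export: one row per (time, state), columns time_day/state/value/unit."""
        import pandas as pd

        rows = []
        names = ["A1", "A2", "A3", "A4", "A5"]
        for i, t in enumerate(self.times):
            for j, name in enumerate(names):
                rows.append((t, name, self.states[i, j], "nmol"))
            c = self.complexes[i]
            for name, val in (("CPX1", c.CPX1), ("CPX2", c.CPX2),
                              ("FAB", c.FAB), ("FSR", c.FSR), ("FCR", c.FCR)):
                rows.append((t, name, val, "nmol"))
        return pd.DataFrame(rows, columns=["time_day", "state", "value", "unit"])


def _initial_state(params: TMDDParams) -> np.ndarray:
    # drug-free steady state: receptors at baseline amount, antibody absent
    return np.array([0.0, 0.0, params.bl_sr * params.v_c, params.bl_cr * params.v_c, 0.0])


def simulate_profile(
    params: TMDDParams,
    doses: list[DoseEvent],
    weight_kg: float,
    times,
    mw_mab_kda: float = MW_MAB_KDA,
    mw_sr_kda: float = MW_SR_KDA,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the TMDD system over ``times`` with SC dose restarts.

    ``times`` must be sorted; ``weight_kg`` is accepted for interface symmetry
    with weight-based dosing but doses are absolute mg (convert upstream).
    An output time equal to a dose time is evaluated pre-dose.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("output times must be sorted")
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")

    dose_list = sorted(doses, key=lambda d: d.time)
    t0 = min([times[0] if times.size else 0.0] + [d.time for d in dose_list])

    state = _initial_state(params)
    out_states = np.empty((times.size, 5))
    filled = np.zeros(times.size, dtype=bool)

    # record any output times at/before the very start
    def _record(mask, values):
        out_states[mask] = values
        filled[mask] = True

    t_end = times[-1] if times.size else t0
    t_cur = t0

    # apply any dose at t0 after recording pre-dose outputs
    pre_mask = times <= t_cur
    _record(pre_mask, state)

    pending = list(dose_list)

    def _apply_doses_at(t):
        nonlocal pending, state
        while pending and abs(pending[0].time - t) < 1e-12:
            d = pending.pop(0)
            state = state.copy()
            state[4] += mg_to_nmol(d.amount_mg, mw_mab_kda) * params.f

    _apply_doses_at(t_cur)

    while t_cur < t_end:
        t_next = min([d.time for d in pending if d.time > t_cur + 1e-12] + [t_end])
        mask = (times > t_cur) & (times <= t_next) & ~filled
        t_out = np.unique(times[mask])
        t_eval = np.unique(np.append(t_out, t_next))
        sol = solve_ivp(
            lambda t, y: rhs(y, params),
            (t_cur, t_next),
            state,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{t_cur}, {t_next}]: {sol.message}; params={params}"
            )
        for tv in t_out:
            sub = mask & (times == tv)
            out_states[sub] = sol.y[:, np.searchsorted(t_eval, tv)]
            filled[sub] = True
        state = np.maximum(sol.y[:, -1], 0.0)
        t_cur = t_next
        _apply_doses_at(t_cur)

    complexes = [
        solve_complex_pair(BindingInputs(
            max(s[0], 0.0), max(s[2], 0.0), max(s[3], 0.0),
            params.kd1, params.kd2, params.v_c))
        for s in out_states
    ]
    return Trajectory(times=times, states=out_states, complexes=complexes,
                      params=params, mw_mab_kda=mw_mab_kda, mw_sr_kda=mw_sr_kda)


def observe_total_mab(traj: Trajectory) -> np.ndarray:
    """Total (free + bound) serum antibody, ng/mL."""
    return np.array([nM_to_ngml(a1 / traj.params.v_c, traj.mw_mab_kda)
                     for a1 in traj.states[:, 0]])


def observe_total_sr(traj: Trajectory) -> np.ndarray:
    """Total (free + bound) soluble receptor, ng/mL."""
    return np.array([nM_to_ngml(a3 / traj.params.v_c, traj.mw_sr_kda)
                     for a3 in traj.states[:, 2]])


def observe_free_ro(traj: Trajectory, baseline_normalized: bool = True) -> np.ndarray:
    """Free receptor occupancy on T cells, percent.

    By default relative to the pre-dose baseline total cellular receptor
    (matching the assay's percent-of-baseline readout); with
    ``baseline_normalized=False`` relative to the instantaneous total.
    """
    fcr = np.array([c.FCR for c in traj.complexes])
    if baseline_normalized:
        ref = traj.params.bl_cr * traj.params.v_c
        return 100.0 * fcr / ref
    total = traj.states[:, 3]
    return 100.0 * fcr / np.maximum(total, 1e-300)
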