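"""Quasi-equilibrium solution of one antibody binding two targets.

At each instant the amounts of the two drug-target complexes (mAb bound to
soluble IL-7Ralpha, ``CPX1``, and to cellular IL-7Ralpha, ``CPX2``) satisfy a
pair of coupled quadratic mass-action relations in the total amounts
``A1`` (antibody), ``A3`` (soluble receptor) and ``A4`` (cellular receptor):

    CPX1 = 1/2 [ (KD1*Vc + A1 + A3 - CPX2)
                 - sqrt((KD1*Vc + A1 + A3 - CPX2)^2 - 4 (A1 - CPX2) A3) ]

and symmetrically for ``CPX2`` with ``KD2``, ``A4`` and ``CPX1`` swapped in.
Free species follow by mass balance: ``FAB = A1 - CPX1 - CPX2``,
``FSR = A3 - CPX1``, ``FCR = A4 - CPX2``.

All state is carried as amounts (nmol); the ``KD*Vc`` terms then balance
dimensionally.  Two solvers are provided: a damped Gauss-Seidel fixed-point
iteration on the coupled quadratics, and an independent scalar-root oracle on
the free-antibody concentration, which brackets the unique root of the
antibody mass balance and therefore cannot miss.  The fixed-point solver
falls back to the oracle if it stalls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BindingInputs",
    "ComplexSolution",
    "BindingConvergenceError",
    "solve_complex_pair",
    "free_ligand_oracle",
]

#: radicands more negative than -RADICAND_SLACK * scale indicate bad inputs
RADICAND_SLACK = 1e-9


class BindingConvergenceError(RuntimeError):
    """Raised when the fixed-point iteration fails and no fallback is allowed."""


@dataclass(frozen=True)
class BindingInputs:
    """Total amounts and binding constants entering the QE solve.

    A1_total, A3_total, A4_total in nmol; KD1, KD2 in nM; Vc in L.
    """

    A1_total: float
    A3_total: float
    A4_total: float
    KD1: float
    KD2: float
    Vc: float

    def __post_init__(self) -> None:
        if min(self.A1_total, self.A3_total, self.A4_total) < 0:
            raise ValueError("total amounts must be non-negative")
        if self.KD1 <= 0 or self.KD2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.Vc <= 0:
            raise ValueError("central volume must be positive")


@dataclass(frozen=True)
class ComplexSolution:
    """Amounts (nmol) of complexes and free species at one time point."""

    CPX1: float
    CPX2: float
    FAB: float
    FSR: float
    FCR: float


def _quad_root(kd_vc: float, ligand_avail: float, target: float) -> float:
    """Smaller root of the single-target binding quadratic, in amounts.

    ``ligand_avail`` is the antibody amount not sequestered by the other
    target; the root is the complex amount and always lies in
    [0, min(ligand_avail, target)].
    """
    if ligand_avail <= 0.0 or target <= 0.0:
        return 0.0
    b = kd_vc + ligand_avail + target
    rad = b * b - 4.0 * ligand_avail * target
    if rad < 0.0:
        if rad < -RADICAND_SLACK * b * b:
            raise ValueError(
                f"negative radicand {rad:.3e} in QE quadratic "
                f"(b={b:.6e}, ligand={ligand_avail:.6e}, target={target:.6e})"
            )
        rad = 0.0
    # citardauq form of the smaller root: no cancellation when the
    # complex is far from saturation
    return 2.0 * ligand_avail * target / (b + math.sqrt(rad))


def _mass_balance(sol_cpx1: float, sol_cpx2: float, inp: BindingInputs) -> ComplexSolution:
    fab = inp.A1_total - sol_cpx1 - sol_cpx2
    fsr = inp.A3_total - sol_cpx1
    fcr = inp.A4_total - sol_cpx2
    # tiny negatives are floating noise from the quadratic roots
    return ComplexSolution(
        CPX1=max(sol_cpx1, 0.0),
        CPX2=max(sol_cpx2, 0.0),
        FAB=max(fab, 0.0),
        FSR=max(fsr, 0.0),
        FCR=max(fcr, 0.0),
    )


def free_ligand_oracle(inputs: BindingInputs) -> ComplexSolution:
    """Solve the QE system via the scalar free-antibody mass balance.

    The free antibody concentration ``c`` (nM) satisfies

        A1/Vc = c + c*(A3/Vc)/(KD1 + c) + c*(A4/Vc)/(KD2 + c)

    whose left side is strictly increasing in ``c`` on [0, A1/Vc], so the
    root is unique and bracketed.  Complexes follow from the Langmuir
    isotherms ``CPX1 = A3*c/(KD1+c)``, ``CPX2 = A4*c/(KD2+c)``.
    """
    a1c = inputs.A1_total / inputs.Vc
    if a1c == 0.0:
        return ComplexSolution(0.0, 0.0, 0.0, inputs.A3_total, inputs.A4_total)
    a3c = inputs.A3_total / inputs.Vc
    a4c = inputs.A4_total / inputs.Vc
    kd1, kd2 = inputs.KD1, inputs.KD2

    def g(c: float) -> float:
        return c * (1.0 + a3c / (kd1 + c) + a4c / (kd2 + c)) - a1c

    if a3c == 0.0 and a4c == 0.0:
        c = a1c
    else:
        # g(0) = -a1c < 0, g(a1c) >= 0: bracketed
        c = brentq(g, 0.0, a1c, xtol=1e-18 * (1.0 + a1c), rtol=8.9e-16,
                   maxiter=200)
    cpx1 = inputs.A3_total * c / (kd1 + c)
    cpx2 = inputs.A4_total * c / (kd2 + c)
    return _mass_balance(cpx1, cpx2, inputs)


def solve_complex_pair(
    inputs: BindingInputs,
    tol: float = 1e-12,
    max_iter: int = 200,
    fallback: bool = True,
) -> ComplexSolution:
    """Solve the coupled QE quadratics for both complex amounts.

    Damped Gauss-Seidel fixed-point iteration from ``CPX1 = CPX2 = 0``:
    each sweep solves the CPX1 quadratic given CPX2, then the CPX2 quadratic
    given the fresh CPX1.  The first half of the budget runs undamped (the
    map is strongly contractive away from exact double saturation); if it
    has not converged, the second half retries with damping 0.5; on failure
    the bracketing oracle is used (or a diagnostic raised if ``fallback``
    is disabled).

    Converged output satisfies both quadratics to relative residual ``tol``
    and agrees with :func:`free_ligand_oracle` to well under 1e-8 relative.
    """
    a1, a3, a4 = inputs.A1_total, inputs.A3_total, inputs.A4_total
    if a1 == 0.0 or (a3 == 0.0 and a4 == 0.0):
        return ComplexSolution(0.0, 0.0, a1, a3, a4)
    kd1vc = inputs.KD1 * inputs.Vc
    kd2vc = inputs.KD2 * inputs.Vc
    scale = max(a1, a3, a4)

    for damp in (1.0, 0.5):
        cpx1 = 0.0
        cpx2 = 0.0
        for _ in range(max_iter // 2):
            prev1, prev2 = cpx1, cpx2
            new1 = _quad_root(kd1vc, max(a1 - cpx2, 0.0), a3)
            cpx1 = prev1 + damp * (new1 - prev1)
            new2 = _quad_root(kd2vc, max(a1 - cpx1, 0.0), a4)
            cpx2 = prev2 + damp * (new2 - prev2)
            if (abs(cpx1 - prev1) <= tol * (abs(cpx1) + tol * scale)
                    and abs(cpx2 - prev2) <= tol * (abs(cpx2) + tol * scale)):
                # confirm both quadratics hold simultaneously
                r1 = _quad_root(kd1vc, max(a1 - cpx2, 0.0), a3) - cpx1
                r2 = _quad_root(kd2vc, max(a1 - cpx1, 0.0), a4) - cpx2
                if abs(r1) <= 10.0 * tol * scale and abs(r2) <= 10.0 * tol * scale:
                    return _mass_balance(cpx1, cpx2, inputs)
    if fallback:
        return free_ligand_oracle(inputs)
    raise BindingConvergenceError(
        f"QE fixed point stalled after {max_iter} sweeps at "
        f"CPX1={cpx1:.6e}, CPX2={cpx2:.6e} (inputs: {inputs})"
    )
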