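"""Default parameter sets for the anti-IL-7Ralpha mAb PK/PD models.

The typical values are the published population estimates from the
multiple-ascending-dose study in adults with type 1 diabetes: a
quasi-equilibrium TMDD model for the antibody binding its soluble and
cellular (T-cell surface) IL-7Ralpha targets, and indirect-response
dose-response models for effector-memory (TEM) and regulatory (Treg)
CD4+ T-cell counts.

Units follow the source estimates: clearances in L/day, volumes in L,
rate constants in 1/day, dissociation constants and baseline receptor
concentrations in nM, cell counts in cells/uL, doses in mg/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


# -- molecular weights (kDa) -------------------------------------------------
# The mAb is an IgG1; 150 kDa is the conventional IgG molecular weight.
# The soluble-receptor MW is back-derived from the published baseline pair
# (0.45 nM <-> ~14 ng/mL), giving 14/0.45 ~= 31.1 kDa.
MW_MAB_KDA = 150.0
MW_SR_KDA = 14.0 / 0.45

#: reference body weight (kg) for typical-subject simulations
REFERENCE_WEIGHT_KG = 70.0

# -- assay quantification limits (ng/mL) -------------------------------------
LLOQ_PK_NGML = 75.0
ULOQ_PK_NGML = 1500.0
LLOQ_SR_NGML = 0.7
ULOQ_SR_NGML = 241.0


@dataclass
class TMDDParams:
    """Structural parameters of the two-target quasi-equilibrium TMDD model.

    ``k_syn1``/``k_syn2`` (receptor synthesis rates, nmol/day) are not
    independent estimates: they are forced by the drug-free steady state,
    ``k_syn = CL * BL``, which also makes the initial conditions
    self-consistent.  They may be overridden explicitly.
    """

    cl_a: float = 0.999    # free antibody clearance (L/day)
    v_c: float = 1.10      # central volume (L)
    v_p: float = 5.28      # peripheral volume (L)
    q: float = 1.1         # intercompartmental clearance (L/day), fixed
    f: float = 0.5         # SC bioavailability, fixed
    k_a: float = 0.211     # first-order absorption rate (1/day)
    cl_sr: float = 2.24    # free soluble receptor clearance (L/day)
    cl_c1: float = 0.196   # mAb:sIL7Ra complex clearance (L/day)
    kd1: float = 0.779     # KD mAb:sIL7Ra (nM)
    bl_sr: float = 0.45    # baseline soluble receptor (nM)
    cl_cr: float = 10.4    # free cellular receptor clearance (L/day)
    cl_c2: float | None = None   # mAb:cIL7Ra complex clearance; ties to cl_cr
    kd2: float = 0.450     # KD mAb:cIL7Ra (nM)
    bl_cr: float = 1.37    # baseline cellular receptor (nM)
    k_syn1_override: float | None = None
    k_syn2_override: float | None = None

    def __post_init__(self) -> None:
        if self.cl_c2 is None:
            self.cl_c2 = self.cl_cr  # published tie: complex-2 clearance = CL_CR
        for name in ("cl_a", "v_c", "v_p", "q", "k_a", "cl_sr", "cl_c1",
                     "kd1", "bl_sr", "cl_cr", "cl_c2", "kd2", "bl_cr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f <= 1:
            raise ValueError("bioavailability f must be in (0, 1]")

    @property
    def k_syn1(self) -> float:
        """Soluble-receptor synthesis rate (nmol/day)."""
        if self.k_syn1_override is not None:
            return self.k_syn1_override
        return self.cl_sr * self.bl_sr

    @property
    def k_syn2(self) -> float:
        """Cellular-receptor synthesis rate (nmol/day)."""
        if self.k_syn2_override is not None:
            return self.k_syn2_override
        return self.cl_cr * self.bl_cr

    @property
    def v_ss(self) -> float:
        """Steady-state volume of distribution (L)."""
        return self.v_c + self.v_p

    def with_updates(self, **kwargs) -> "TMDDParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DRParams:
    """Indirect-response dose-response parameters for one T-cell population.

    The drug inhibits the zero-order input rate through an Emax function of
    the fortnightly dose; ``k_in = R0 * k_out`` so the untreated population
    sits at its baseline.
    """

    r0: float       # baseline cell count (cells/uL)
    k_out: float    # first-order disappearance rate (1/day)
    e_max: float    # maximum fractional inhibition (0-1)
    ed50: float     # dose at half-maximum effect (mg/kg per 2 weeks)

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.k_out <= 0 or self.ed50 <= 0:
            raise ValueError("r0, k_out, ed50 must be positive")
        if not 0 < self.e_max < 1:
            raise ValueError("e_max must lie strictly in (0, 1)")

    @property
    def k_in(self) -> float:
        """Zero-order input rate (cells/uL/day)."""
        return self.r0 * self.k_out

    @property
    def half_life(self) -> float:
        """Cell turnover half-life, ln2/k_out (days)."""
        import math
        return math.log(2.0) / self.k_out


@dataclass(frozen=True)
class DRPair:
    """TEM and Treg dose-response models fitted to the same trial."""

    tem: DRParams
    treg: DRParams


def default_tmdd() -> TMDDParams:
    """Published typical TMDD parameter estimates."""
    return TMDDParams()


def default_dr_pair() -> DRPair:
    """Published typical dose-response estimates for TEM and Treg."""
    return DRPair(
        tem=DRParams(r0=63.1, k_out=0.0665, e_max=0.715, ed50=0.353),
        treg=DRParams(r0=46.2, k_out=0.0308, e_max=0.700, ed50=7.06),
    )


# Residual-error magnitudes (population estimates). Proportional sigmas are
# fractional SDs; the receptor-occupancy sigma is additive in percentage
# points of Free RO.
SIGMA_PK_PROP = 0.434
SIGMA_RO_ADD = 18.2
SIGMA_SR_PROP = 0.150
SIGMA_TEM_PROP = 0.11
SIGMA_TREG_PROP = 0.061

# Observed baseline cell counts (cells/uL) by dose group from the study
# summary, used as emulation targets by the synthetic-data generator
# (optional between-arm imbalance) and for the observed baseline ratio.
TABLE_BASELINES = {
    "tem_by_arm": {"placebo": 78.8, "1 mg/kg q2w": 61.6, "3 mg/kg q2w": 46.7,
                   "8 mg/kg q2w": 98.3, "6 mg/kg q1w": 104.0},
    "treg_by_arm": {"placebo": 44.3, "1 mg/kg q2w": 45.7, "3 mg/kg q2w": 46.5,
                    "8 mg/kg q2w": 63.3, "6 mg/kg q1w": 50.6},
    "tem_grand_mean": 76.4,
    "treg_grand_mean": 50.3,
    "sil7r_grand_mean_ngml": 14.0,
}

# Inter-individual variability, % coefficient of variation (log-normal).
IIV_CV = {
    "cl_a": 42.5,
    "v_c": 7.3,
    "k_a": 31.3,
    "bl_sr": 35.1,
    "tem_r0": 41.0,
    "tem_e_max": 21.0,
    "treg_r0": 33.0,
    "treg_e_max": 27.0,
}
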