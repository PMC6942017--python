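"""Estimation: dose-response population fit, per-subject TMDD fit, and
bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest

from il7r_pkpd.datasets import GeneratorConfig, generate_study
from il7r_pkpd.estimation import (
    IdentifiabilityError,
    bootstrap_dr,
    default_dr_init,
    dr_uncertainty_bands,
    fit_dr_population,
    fit_subject_tmdd,
)
from il7r_pkpd.params import default_dr_pair, default_tmdd
from il7r_pkpd.population import IIVSpec, ResidualSpec, default_design


def _noise_free_tem_trial(seed=0):
    cfg = GeneratorConfig(seed=seed, iiv=IIVSpec({}), residual=ResidualSpec({}),
                          streams=("TEM",))
    return generate_study(cfg)[0]


class TestFitDRPopulation:
    def test_noise_free_recovery(self):
        """Zero noise, zero IIV: the generating structural parameters are
        recovered to 0.1% (sigma and omegas collapse to their floors)."""
        df = _noise_free_tem_trial()
        truth = default_dr_pair().tem
        fit = fit_dr_population(df, population="TEM", n_starts=1, seed=0,
                                iiv_on=())
        assert fit.estimates["r0"] == pytest.approx(truth.r0, rel=1e-3)
        assert fit.estimates["k_out"] == pytest.approx(truth.k_out, rel=1e-3)
        assert fit.estimates["e_max"] == pytest.approx(truth.e_max, rel=1e-3)
        assert fit.estimates["ed50"] == pytest.approx(truth.ed50, rel=1e-3)

    def test_placebo_only_dataset_unidentifiable(self, tcell_trial):
        _, df, _ = tcell_trial
        placebo = df[df["ARM"] == "placebo"]
        with pytest.raises(IdentifiabilityError):
            fit_dr_population(placebo, population="TEM")

    def test_objective_trace_non_increasing(self, tem_fit):
        trace = np.array(tem_fit.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_fit_estimates_in_plausible_range(self, tem_fit):
        # single-trial estimates land near the generating values
        assert tem_fit.estimates["e_max"] == pytest.approx(0.715, rel=0.2)
        assert 0.03 <= tem_fit.estimates["k_out"] <= 0.15
        assert tem_fit.n_subjects == 36
        assert len(tem_fit.eta_modes) == 36

    def test_data_derived_init_is_reasonable(self, tcell_trial):
        _, df, _ = tcell_trial
        init = default_dr_init(df, "TEM")
        assert 40.0 < init.r0 < 110.0
        assert 0.1 <= init.e_max <= 0.9


class TestEstimatorConsistency:
    def test_emax_bias_shrinks_with_arm_size(self):
        """The Emax estimate concentrates around the truth as per-arm n
        grows (8 -> 32 -> 128 subjects per arm)."""
        from dataclasses import replace

        truth = default_dr_pair().tem.e_max
        bias = {}
        for n, seeds in ((8, (1, 2)), (32, (3, 4)), (128, (5,))):
            errs = []
            for seed in seeds:
                design = default_design()
                design.cohorts = [replace(c, n_active=n, n_pk=0)
                                  for c in design.cohorts]
                design.n_placebo = n
                cfg = GeneratorConfig(seed=seed, design=design,
                                      streams=("TEM",))
                df, _ = generate_study(cfg)
                fit = fit_dr_population(df, population="TEM", n_starts=1,
                                        seed=seed)
                errs.append(abs(fit.estimates["e_max"] - truth) / truth)
            bias[n] = np.mean(errs)
        assert bias[128] < bias[8] + 0.02
        assert bias[128] < 0.10


class TestFitSubjectTMDD:
    @staticmethod
    def _subject_records(eta_cl=0.0, noise=False, seed=0):
        """One 3 mg/kg q2w subject simulated directly from the TMDD model."""
        from il7r_pkpd import tmdd as tm
        from il7r_pkpd.population import (
            PK_DAYS_Q2W, RO_DAYS_Q2W, SR_DAYS_Q2W, default_residual,
        )

        p = default_tmdd()
        p_i = p.with_updates(cl_a=p.cl_a * np.exp(eta_cl))
        wt = 70.0
        doses = [tm.DoseEvent(d, 3.0 * wt) for d in
                 (1.0, 15.0, 29.0, 43.0, 57.0, 71.0)]
        days = np.unique(np.concatenate([PK_DAYS_Q2W, SR_DAYS_Q2W,
                                         RO_DAYS_Q2W]))
        traj = tm.simulate_profile(p_i, doses, wt, days)
        obs = {"PK": dict(zip(days, tm.observe_total_mab(traj))),
               "SIL7R": dict(zip(days, tm.observe_total_sr(traj))),
               "FREERO": dict(zip(days, tm.observe_free_ro(traj)))}
        rng = np.random.default_rng(seed)
        residual = default_residual()
        rows = [(1, "3 mg/kg q2w", d.time, 1, "DOSE", d.amount_mg, 3.0, wt,
                 np.nan, 1, 0) for d in doses]
        for stream, sched in (("PK", PK_DAYS_Q2W), ("SIL7R", SR_DAYS_Q2W),
                              ("FREERO", RO_DAYS_Q2W)):
            for day in sched:
                dv = obs[stream][day]
                if noise:
                    from il7r_pkpd.population import apply_residual
                    dv, _ = apply_residual(dv, residual.for_stream(stream), rng)
                blq = 1 if stream == "PK" and dv < 75.0 else 0
                rows.append((1, "3 mg/kg q2w", day, 0, stream, 0.0, 3.0, wt,
                             dv, 0, blq))
        return pd.DataFrame(rows, columns=["ID", "ARM", "TIME", "EVID", "CMT",
                                           "AMT", "DOSE", "WT", "DV", "MDV",
                                           "BLQ"]), p_i

    def test_noise_free_recovery_at_typicals(self):
        records, _ = self._subject_records()
        est = fit_subject_tmdd(records, default_tmdd())
        typ = default_tmdd()
        for k, v in est.items():
            assert v == pytest.approx(getattr(typ, k), rel=0.01), k

    def test_shrinkage_pulls_estimate_toward_typical(self):
        """Data generated at +1 SD on CL_A: the penalized estimate lies
        between the typical and the generating value."""
        omega_cl = np.sqrt(np.log1p(0.425 ** 2))
        records, p_i = self._subject_records(eta_cl=omega_cl, noise=True,
                                             seed=3)
        est = fit_subject_tmdd(records, default_tmdd())
        typ = default_tmdd().cl_a
        assert typ < est["cl_a"] < p_i.cl_a * 1.02

    def test_too_few_pk_points_refused(self):
        records, _ = self._subject_records()
        records.loc[records["CMT"] == "PK", "BLQ"] = 1
        with pytest.raises(ValueError, match="quantifiable PK"):
            fit_subject_tmdd(records, default_tmdd())


class TestBootstrap:
    def test_identity_resample_collapses_to_point(self, tcell_trial, tem_fit):
        _, df, _ = tcell_trial

        def identity(rng, by_arm):
            return [sid for arm in sorted(by_arm) for sid in by_arm[arm]]

        bset = bootstrap_dr(df, n_boot=1, seed=0,
                            base_fits={"TEM": tem_fit},
                            populations=("TEM",), resampler=identity)
        assert bset.n_converged == 1
        bands = dr_uncertainty_bands(bset, [0.0, 3.0, 8.0])
        np.testing.assert_allclose(bands["tem_lo"], bands["tem_hi"])
        # the replicate refit of the identical data stays at the base fit
        rep = bset.replicates[0]["TEM"]
        assert rep.e_max == pytest.approx(tem_fit.estimates["e_max"], rel=0.05)

    def test_band_covers_generating_emax(self, tcell_trial, tem_fit):
        """90% bootstrap band for Emax covers the generating value in this
        trial (small replicate count keeps the check affordable)."""
        _, df, _ = tcell_trial
        bset = bootstrap_dr(df, n_boot=12, seed=1,
                            base_fits={"TEM": tem_fit}, populations=("TEM",))
        assert bset.n_converged >= 8
        emaxes = np.array([r["TEM"].e_max for r in bset.replicates])
        lo, hi = np.percentile(emaxes, [5, 95])
        assert lo <= 0.715 <= hi

    def test_reproducible_with_same_seed(self, tcell_trial, tem_fit):
        _, df, _ = tcell_trial
        a = bootstrap_dr(df, n_boot=2, seed=7, base_fits={"TEM": tem_fit},
                         populations=("TEM",))
        b = bootstrap_dr(df, n_boot=2, seed=7, base_fits={"TEM": tem_fit},
                         populations=("TEM",))
        for ra, rb in zip(a.replicates, b.replicates):
            assert ra["TEM"] == rb["TEM"]

    def test_empty_bootstrap_bands_rejected(self):
        from il7r_pkpd.estimation import BootstrapSet

        empty = BootstrapSet(replicates=[], seed=0, n_requested=0,
                             n_converged=0, populations=("TEM",))
        with pytest.raises(ValueError):
            dr_uncertainty_bands(empty, [0.0, 1.0])
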