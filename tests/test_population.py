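"""Statistical layer: random-effect draws, residual models, virtual-trial
structure, and the prediction-corrected VPC."""

import numpy as np
import pandas as pd
import pytest

from il7r_pkpd.datasets import GeneratorConfig, generate_study
from il7r_pkpd.params import default_dr_pair, default_tmdd
from il7r_pkpd.population import (
    IIVSpec,
    ResidualModel,
    apply_residual,
    default_design,
    default_iiv,
    default_residual,
    draw_subject,
    pcvpc,
    population_predictions,
    simulate_trial,
)


class TestDrawSubject:
    def test_zero_variance_returns_typicals(self, rng):
        iiv = IIVSpec({"cl_a": 0.0, "v_c": 0.0})
        out = draw_subject({"cl_a": 1.0, "v_c": 1.1}, iiv, rng)
        assert out == {"cl_a": 1.0, "v_c": 1.1}

    def test_lognormal_cv_recovered_by_monte_carlo(self):
        """10^5 draws with 42.5% CV: the empirical CV of the draws matches
        sqrt(exp(omega^2) - 1) within 2%."""
        rng = np.random.default_rng(5)
        iiv = IIVSpec.from_cv_percent({"cl_a": 42.5})
        draws = np.array([draw_subject({"cl_a": 0.999}, iiv, rng)["cl_a"]
                          for _ in range(100_000)])
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(0.425, rel=0.02)
        # log-normal median sits at the typical value
        assert np.median(draws) == pytest.approx(0.999, rel=0.01)

    def test_non_psd_covariance_rejected(self, rng):
        iiv = IIVSpec({"a": 0.1, "b": 0.1},
                      correlation=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            draw_subject({"a": 1.0, "b": 1.0}, iiv, rng)

    def test_correlated_draws(self):
        rng = np.random.default_rng(9)
        iiv = IIVSpec({"a": 0.2, "b": 0.2},
                      correlation=np.array([[1.0, 0.8], [0.8, 1.0]]))
        samples = [draw_subject({"a": 1.0, "b": 1.0}, iiv, rng)
                   for _ in range(20_000)]
        draws = np.array([[s["a"], s["b"]] for s in samples])
        r = np.corrcoef(np.log(draws).T)[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)


class TestResiduals:
    def test_zero_sigma_is_identity(self, rng):
        val, clamped = apply_residual(123.4, ResidualModel(), rng)
        assert val == 123.4 and not clamped

    def test_proportional_sd_by_monte_carlo(self):
        rng = np.random.default_rng(6)
        model = ResidualModel(sigma_prop=0.434)
        reps = np.array([apply_residual(1000.0, model, rng,
                                        clamp_at_zero=False)[0]
                         for _ in range(20_000)])
        assert reps.std() == pytest.approx(434.0, rel=0.05)

    def test_additive_error_clamped_at_zero(self, rng):
        model = ResidualModel(sigma_add=50.0)
        clamped_any = False
        for _ in range(200):
            val, clamped = apply_residual(1.0, model, rng)
            assert val >= 0.0
            clamped_any |= clamped
        assert clamped_any

    def test_nonfinite_prediction_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_residual(np.inf, ResidualModel(), rng)


class TestSimulateTrial:
    def test_fixed_seed_is_bit_identical(self):
        cfg = dict(design=default_design(), tmdd_params=default_tmdd(),
                   dr_pair=default_dr_pair(), iiv=default_iiv(),
                   residual=default_residual(), streams=("TEM", "TREG"))
        a = simulate_trial(seed=42, **cfg)
        b = simulate_trial(seed=42, **cfg)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_trial(seed=43, **cfg)
        assert not a["DV"].equals(c["DV"])

    def test_placebo_subjects_have_no_pk_rows(self, full_trial):
        _, df, _ = full_trial
        placebo = df[df["ARM"] == "placebo"]
        assert set(placebo["CMT"]) == {"TEM", "TREG"}
        assert (placebo["EVID"] == 0).all()
        # T-cell rows fluctuate about baseline
        tem = placebo[placebo["CMT"] == "TEM"]["DV"]
        assert 40.0 < tem.mean() < 110.0

    def test_pk_observation_counts_match_study(self, full_trial):
        """Collected PK samples per active arm reproduce the study's
        reported totals (91, 150, 149, 84) within +-20%.  BLQ samples are
        flagged, not removed: the study totals correspond to collected
        samples (~19 per subject), which would be impossible after
        censoring the late follow-up visits."""
        _, df, _ = full_trial
        pk = df[(df["CMT"] == "PK") & (df["EVID"] == 0)]
        counts = pk.groupby("ARM").size()
        expected = {"1 mg/kg q2w": 91, "3 mg/kg q2w": 150,
                    "8 mg/kg q2w": 149, "6 mg/kg q1w": 84}
        for arm, n in expected.items():
            assert 0.8 * n <= counts[arm] <= 1.2 * n, (arm, counts[arm])
        # censoring exists (pre-dose and late follow-up) but spares most data
        blq_frac = (pk["BLQ"] == 1).mean()
        assert 0.0 < blq_frac < 0.35

    def test_baseline_soluble_receptor_level_and_spread(self, full_trial):
        """Day-1 pre-dose sIL7R: mean near 14 ng/mL, between-subject spread
        near the published 35-39% CV."""
        _, df, _ = full_trial
        base = df[(df["CMT"] == "SIL7R") & (df["TIME"] == 1.0)]["DV"]
        assert base.mean() == pytest.approx(14.0, rel=0.15)
        cv = base.std() / base.mean()
        assert 0.22 <= cv <= 0.55   # n = 26 subjects: wide sampling band

    def test_tcell_baselines_bracket_reported_group_means(self, full_trial):
        _, df, _ = full_trial
        tem = df[(df["CMT"] == "TEM") & (df["TIME"] == 1.0)]["DV"]
        assert 46.7 <= tem.mean() <= 104.0

    def test_dose_rows_carry_amount(self, full_trial):
        _, df, _ = full_trial
        doses = df[df["EVID"] == 1]
        assert (doses["AMT"] > 0).all()
        assert (doses["MDV"] == 1).all()
        q2w = doses[doses["ARM"] == "3 mg/kg q2w"]
        assert sorted(q2w["TIME"].unique()) == [1, 15, 29, 43, 57, 71]
        q1w = doses[doses["ARM"] == "6 mg/kg q1w"]
        assert len(q1w["TIME"].unique()) == 12


class TestPcVPC:
    @staticmethod
    def _tem_frame(seed):
        cfg = GeneratorConfig(seed=seed, streams=("TEM",))
        df, _ = generate_study(cfg)
        df = population_predictions(df, default_tmdd(), default_dr_pair(),
                                    default_design())
        return df[(df["EVID"] == 0) & (df["CMT"] == "TEM")]

    def test_identity_correction_when_pred_constant(self):
        obs = pd.DataFrame({"TIME": [1.0] * 4, "DV": [1.0, 2.0, 3.0, 4.0],
                            "PRED": [2.0] * 4})
        out = pcvpc(obs, lambda rep: obs, n_sim=2)
        assert out.loc[0, "obs_p50"] == pytest.approx(2.5)

    def test_single_replicate_band_degenerates(self):
        obs = pd.DataFrame({"TIME": [1.0] * 5, "DV": np.arange(5.0) + 1,
                            "PRED": [1.0] * 5})
        out = pcvpc(obs, lambda rep: obs, n_sim=1)
        assert out.loc[0, "sim_p50_lo"] == out.loc[0, "sim_p50_hi"]

    def test_self_consistency_band_coverage(self):
        """Data simulated from the model fall inside their own simulated
        95% prediction bands for each percentile in at least 80% of bins."""
        obs = self._tem_frame(21)
        out = pcvpc(obs, lambda rep: self._tem_frame(100 + rep), n_sim=40,
                    band=(2.5, 97.5))
        inside = 0
        total = 0
        for _, row in out.iterrows():
            for tag in ("p10", "p50", "p90"):
                total += 1
                if row[f"sim_{tag}_lo"] <= row[f"obs_{tag}"] <= row[f"sim_{tag}_hi"]:
                    inside += 1
        assert inside / total >= 0.8

    def test_missing_pred_rejected(self):
        with pytest.raises(ValueError):
            pcvpc(pd.DataFrame({"TIME": [1.0], "DV": [1.0]}),
                  lambda rep: None, n_sim=1)
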