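"""Chained-equations PMM imputation, Rubin pooling, MI-aware CEACs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialcea.cea import WTPGrid, specs_for_outcome, bootstrap_incrementals, ceac
from trialcea.config import default_config
from trialcea.estimate import AdjustmentSpec, adjusted_difference
from trialcea.impute import (
    ImputationConfig,
    ceac_under_mi,
    mice_impute,
    pool_rubin,
    pooled_adjusted_difference,
)
from trialcea.outcomes import add_qaly_columns
from trialcea.simulate import apply_missingness, generate_trial

SDQ_SPEC = AdjustmentSpec(
    outcome="sdq_12", baseline_covariates=["cost_baseline_3m", "sdq_0"], estimator="ols"
)


class TestPoolRubin:
    def test_hand_computed_two_imputations(self):
        pe = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert pe.q_bar == 2.0
        assert pe.w_bar == 1.0
        assert pe.b_var == 2.0
        assert pe.total_var == 4.0  # 1 + (1 + 1/2) * 2
        assert pe.df == pytest.approx((2 - 1) * (1 + 1.0 / 3.0) ** 2)

    def test_all_estimates_equal_degenerate(self):
        pe = pool_rubin([2.5] * 5, [0.4] * 5)
        assert pe.b_var == 0.0
        assert pe.total_var == pe.w_bar
        assert np.isinf(pe.df)

    def test_identical_fits_pool_to_single_fit(self, masked_frame):
        fit = adjusted_difference(masked_frame, SDQ_SPEC)
        pe = pool_rubin([fit.estimate] * 7, [fit.se**2] * 7)
        assert pe.q_bar == pytest.approx(fit.estimate)
        assert pe.total_var == pytest.approx(fit.se**2)

    @given(
        q=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        w=st.lists(st.floats(0.01, 10), min_size=12, max_size=12),
    )
    def test_rubin_identity(self, q, w):
        m = len(q)
        pe = pool_rubin(q, w[:m])
        assert pe.total_var - pe.w_bar == pytest.approx((1 + 1 / m) * pe.b_var, rel=1e-12)
        assert pe.total_var >= pe.w_bar
        assert pe.b_var >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pool_rubin([1.0, 2.0], [1.0])

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            pool_rubin([1.0], [1.0])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pool_rubin([1.0, 2.0], [1.0, 0.0])


class TestMiceImpute:
    def test_no_missing_values_noop(self, study_frame):
        cfg = ImputationConfig(m_imputations=3, seed=0)
        completed = mice_impute(study_frame, cfg)
        assert len(completed) == 3
        for d in completed:
            pd.testing.assert_series_equal(d["sdq_12"], study_frame["sdq_12"])

    def test_pmm_support_exact_membership(self, masked_frame):
        cfg = ImputationConfig(m_imputations=4, iterations=3, seed=5)
        completed = mice_impute(masked_frame, cfg)
        for col in ("sdq_12", "sdq_6", "cost_m0_6", "qaly_cyp"):
            observed = set(masked_frame.loc[masked_frame[col].notna(), col])
            for d in completed:
                assert d[col].notna().all()
                assert set(d[col]) <= observed, col

    def test_imputed_sdq_stays_integer_valued(self, masked_frame):
        completed = mice_impute(masked_frame, ImputationConfig(m_imputations=2, iterations=2, seed=1))
        for d in completed:
            assert (d["sdq_12"] == d["sdq_12"].round()).all()

    def test_derived_columns_recomputed(self, masked_frame):
        d = mice_impute(masked_frame, ImputationConfig(m_imputations=2, iterations=2, seed=2))[0]
        assert np.allclose(d["cost_followup_excl"], d["cost_m0_6"] + d["cost_m6_12"])
        assert np.allclose(d["cost_total"], d["cost_followup_excl"] + d["cost_intervention"])
        assert np.allclose(d["qaly_combined"], d["qaly_cyp"] + d["qaly_caregiver"])

    def test_seed_determinism(self, masked_frame):
        cfg = ImputationConfig(m_imputations=2, iterations=2, seed=7)
        a = mice_impute(masked_frame, cfg)
        b = mice_impute(masked_frame, cfg)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da, db)

    def test_single_donor_nearest_prediction(self):
        # noise-free linear relation: predictions are exact, so the k=1
        # donor is the unique nearest-prediction observed value
        n = 12
        x = np.arange(n, dtype=float)
        df = pd.DataFrame(
            {
                "arm": ["intervention", "control"] * (n // 2),
                "site_id": 1,
                "disorder": "anxiety",
                "age_group": "<11",
                "asd": 0,
                "intellectual_disability": 0,
                "cost_baseline_3m": x,
                "sdq_0": 20,
                "utility_cyp_0": 0.7,
                "utility_caregiver_0": 0.7,
                "y": 2.0 * x,
            }
        )
        df.loc[5, "y"] = np.nan  # true prediction 10; nearest donors y=8 or 12
        cfg = ImputationConfig(
            m_imputations=2, donors_k=1, iterations=1, columns=("y",), seed=3
        )
        completed = mice_impute(df, cfg)
        for d in completed:
            assert d.loc[5, "y"] in (8.0, 12.0)

    def test_too_few_donors_rejected(self):
        df = pd.DataFrame(
            {
                "arm": ["intervention", "control"] * 3,
                "site_id": 1,
                "disorder": "anxiety",
                "age_group": "<11",
                "asd": 0,
                "intellectual_disability": 0,
                "cost_baseline_3m": 1.0,
                "sdq_0": 20,
                "utility_cyp_0": 0.7,
                "utility_caregiver_0": 0.7,
                "y": [1.0, 2.0] + [np.nan] * 4,
            }
        )
        with pytest.raises(ValueError, match="donors_k"):
            mice_impute(df, ImputationConfig(m_imputations=2, donors_k=5, columns=("y",), seed=0))

    def test_missing_predictor_rejected(self, masked_frame):
        df = masked_frame.copy()
        df.loc[0, "sdq_0"] = np.nan
        with pytest.raises(ValueError, match="fully observed"):
            mice_impute(df, ImputationConfig(m_imputations=2, seed=0))


class TestMonteCarloCalibration:
    """Pooled MI inference recovers the configured truth.

    One replicate = generate a calibrated trial, mask follow-up data,
    impute m=31 times, pool the adjusted SDQ fit by Rubin's rules.
    Unbiasedness is checked under MAR (the mechanism MI assumes) and
    interval coverage under MCAR.
    """

    REPS = 200

    def _run(self, mechanism):
        cfg = default_config(seed=0, missingness_mechanism=mechanism)
        icfg_kwargs = dict(m_imputations=31, iterations=3, donors_k=5)
        seeds = np.random.default_rng({"MAR": 11, "MCAR": 22}[mechanism]).integers(
            0, 2**31 - 1, size=self.REPS
        )
        pooled = []
        for s in seeds:
            ds = generate_trial(cfg.replace(seed=int(s)), include_service_use=False)
            df = add_qaly_columns(apply_missingness(ds).participants)
            completed = mice_impute(df, ImputationConfig(seed=int(s) % 2**31, **icfg_kwargs))
            pooled.append(pooled_adjusted_difference(completed, SDQ_SPEC))
        return cfg.effect_sdq_12m, pooled

    @pytest.fixture(scope="class")
    def mar_pooled(self):
        return self._run("MAR")

    @pytest.fixture(scope="class")
    def mcar_pooled(self):
        return self._run("MCAR")

    def test_pooled_estimate_unbiased_under_mar(self, mar_pooled):
        truth, pooled = mar_pooled
        ests = np.array([p.q_bar for p in pooled])
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) <= 3 * mc_se

    def test_nominal_coverage_under_mcar(self, mcar_pooled):
        truth, pooled = mcar_pooled
        cover = np.mean([p.ci_low <= truth <= p.ci_high for p in pooled])
        assert 0.90 <= cover <= 0.99


class TestCEACUnderMI:
    def test_degenerate_identical_datasets_match_single_dataset_ceac(self, study_frame):
        # m copies of a complete dataset: nested-bootstrap CEAC should
        # match the single-dataset CEAC within Monte-Carlo error
        grid = WTPGrid(np.arange(0.0, 50_000.0, 2500.0))
        m, B = 4, 160
        imputed = [study_frame.copy() for _ in range(m)]
        curve_mi = ceac_under_mi(
            imputed, "qaly_cyp", grid=grid, B=B, seed=3, estimator="ols"
        )
        cost_spec, effect_spec, sign, label = specs_for_outcome("qaly_cyp", "ols")
        dist = bootstrap_incrementals(
            study_frame, cost_spec, effect_spec, B=B, seed=3,
            effect_sign=sign, effect_label=label,
        )
        curve_single = ceac(dist, grid)
        se = np.sqrt(0.25 / B)
        assert np.max(np.abs(curve_mi.probability - curve_single.probability)) <= 4 * se + 1e-9

    def test_bootstrap_budget_below_m_rejected(self, study_frame):
        imputed = [study_frame.copy() for _ in range(5)]
        with pytest.raises(ValueError, match="at least"):
            ceac_under_mi(imputed, "qaly_cyp", B=3, seed=0, estimator="ols")

    def test_rubin_nmb_variant_probabilities_valid(self, masked_frame):
        completed = mice_impute(
            masked_frame, ImputationConfig(m_imputations=5, iterations=2, seed=4)
        )
        grid = WTPGrid(np.arange(0.0, 50_000.0, 5000.0))
        curve = ceac_under_mi(
            completed, "qaly_combined", grid=grid, B=100, seed=5,
            method="rubin_nmb", estimator="ols",
        )
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()
        assert len(curve.probability) == len(grid.values)

    def test_unknown_method_rejected(self, study_frame):
        with pytest.raises(ValueError, match="unknown method"):
            ceac_under_mi([study_frame] * 2, "qaly_cyp", B=10, seed=0, method="jackknife")
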