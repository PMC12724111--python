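"""ICERs, net monetary benefit, bootstrap incrementals and CEACs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trialcea.cea import (
    IncrementalDistribution,
    Scenario,
    WTPGrid,
    bootstrap_incrementals,
    ceac,
    icer,
    net_monetary_benefit,
    run_scenarios,
    specs_for_outcome,
)
from trialcea.estimate import AdjustmentSpec, adjusted_difference


def make_dist(dc, de, di=None):
    dc = np.asarray(dc, dtype=float)
    if di is None:
        di = np.zeros_like(dc)
    return IncrementalDistribution(
        delta_cost_excl=dc - np.asarray(di, dtype=float),
        delta_intervention=np.asarray(di, dtype=float),
        delta_effect=np.asarray(de, dtype=float),
        effect_label="QALY",
    )


class TestICER:
    @pytest.mark.parametrize(
        "dc, de, ratio, quadrant",
        [
            (100.0, 0.05, 2000.0, "trade-off NE"),
            (-100.0, 0.05, -2000.0, "dominant SE"),
            (100.0, -0.05, -2000.0, "dominated NW"),
            (-100.0, -0.05, 2000.0, "trade-off SW"),
        ],
    )
    def test_quadrants(self, dc, de, ratio, quadrant):
        out = icer(dc, de)
        assert out["ratio"] == pytest.approx(ratio)
        assert out["quadrant"] == quadrant

    def test_zero_effect_undefined_marker(self):
        out = icer(50.0, 0.0)
        assert np.isnan(out["ratio"])
        assert out["quadrant"] == "undefined"
        assert out["delta_cost_sign"] == 1


class TestNMB:
    def test_arithmetic(self):
        assert net_monetary_benefit(0.7, 5000.0, 20_000.0) == pytest.approx(9000.0)

    def test_zero_wtp_is_negative_cost(self):
        assert net_monetary_benefit(0.9, 1234.0, 0.0) == pytest.approx(-1234.0)

    def test_zero_effect_zero_cost(self):
        assert net_monetary_benefit(0.0, 0.0, 10_000.0) == 0.0


class TestCEAC:
    def test_brute_force_four_replicates(self):
        # NMB at lambda=25: {15, 5, -55, -15} -> probability 0.5
        dist = make_dist([10, 20, 30, 40], [1, 1, -1, 1])
        curve = ceac(dist, WTPGrid([25.0]))
        assert curve.probability[0] == pytest.approx(0.5)

    def test_tie_counts_half(self):
        dist = make_dist([25.0, 10.0], [1.0, 1.0])
        curve = ceac(dist, WTPGrid([25.0]))
        assert curve.probability[0] == pytest.approx(0.75)  # one win, one tie

    def test_lambda_zero_is_fraction_cost_saving(self):
        dist = make_dist([-5, 3, -1, 7], [1, 1, 1, 1])
        curve = ceac(dist, WTPGrid([0.0, 10.0]))
        assert curve.probability[0] == pytest.approx(0.5)

    def test_dominance_probability_one_everywhere(self):
        dist = make_dist([-10, -20], [0.5, 0.7])
        curve = ceac(dist, WTPGrid(np.arange(0.0, 1000.0, 100.0)))
        assert (curve.probability == 1.0).all()
        assert curve.crossing_lambda == 0.0

    def test_monotone_when_all_effects_positive(self):
        rng = np.random.default_rng(1)
        dist = make_dist(rng.normal(500, 300, 400), rng.uniform(0.01, 0.2, 400))
        curve = ceac(dist, WTPGrid(np.arange(0.0, 50_000.0, 500.0)))
        assert (np.diff(curve.probability) >= 0).all()

    def test_nonincreasing_when_all_effects_negative(self):
        rng = np.random.default_rng(2)
        dist = make_dist(rng.normal(0, 300, 400), -rng.uniform(0.01, 0.2, 400))
        curve = ceac(dist, WTPGrid(np.arange(0.0, 50_000.0, 500.0)))
        assert (np.diff(curve.probability) <= 0).all()

    def test_crossing_lambda_first_grid_point_at_half(self):
        dist = make_dist([100.0] * 3 + [-100.0], [1.0] * 4)
        curve = ceac(dist, WTPGrid([0.0, 50.0, 101.0, 150.0]))
        # NMB>0 for 3 of 4 replicates once lambda > 100
        assert curve.probability[1] == pytest.approx(0.25)
        assert curve.crossing_lambda == 101.0

    def test_never_crossing_is_none(self):
        dist = make_dist([100.0], [-1.0])
        curve = ceac(dist, WTPGrid([0.0, 10.0]))
        assert curve.crossing_lambda is None

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            WTPGrid(np.array([]))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            WTPGrid([10.0, 5.0])


class TestScaling:
    def test_scaling_never_lowers_probability(self):
        rng = np.random.default_rng(3)
        dist = make_dist(
            rng.normal(800, 400, 300), rng.normal(0.02, 0.05, 300),
            di=rng.normal(1466, 100, 300),
        )
        grid = WTPGrid(np.arange(0.0, 50_000.0, 500.0))
        p_full = ceac(dist, grid).probability
        p_75 = ceac(dist.scaled(0.75), grid).probability
        assert (p_75 >= p_full).all()

    def test_scaled_one_is_identity(self):
        dist = make_dist([10.0, 20.0], [0.1, 0.2], di=[5.0, 5.0])
        assert np.array_equal(dist.scaled(1.0).delta_cost, dist.delta_cost)

    def test_bad_factor_rejected(self):
        dist = make_dist([1.0], [1.0])
        with pytest.raises(ValueError):
            dist.scaled(0.0)


def _toy_specs():
    cost_spec = AdjustmentSpec(outcome="cost", baseline_covariates=[],
                               minimisation_factors=(), estimator="ols")
    effect_spec = AdjustmentSpec(outcome="effect", baseline_covariates=[],
                                 minimisation_factors=(), estimator="ols")
    return cost_spec, effect_spec


def toy_dataset():
    return pd.DataFrame(
        {
            "arm": ["intervention", "intervention", "control", "control"],
            "site_id": [1, 1, 1, 1],
            "cost": [100.0, 300.0, 50.0, 150.0],
            "effect": [0.8, 0.6, 0.5, 0.3],
            "cost_intervention": [80.0, 120.0, 0.0, 0.0],
        }
    )


class TestBootstrap:
    def test_identity_resample_reproduces_point_estimates(self):
        cost_spec, effect_spec = _toy_specs()
        df = toy_dataset()

        def identity(rng, arm_idx):
            return np.concatenate(list(arm_idx.values()))

        dist = bootstrap_incrementals(
            df, cost_spec, effect_spec, B=1, seed=0, resampler=identity,
            intervention_spec=AdjustmentSpec(outcome="cost_intervention",
                                             baseline_covariates=[],
                                             minimisation_factors=(), estimator="ols"),
        )
        assert dist.delta_cost[0] == pytest.approx(dist.point["delta_cost_excl"]
                                                   + dist.point["delta_intervention"])
        assert dist.delta_effect[0] == pytest.approx(dist.point["delta_effect"])
        assert dist.point["delta_effect"] == pytest.approx(0.3)  # 0.7 - 0.4

    def test_matches_exhaustive_enumeration_on_toy_data(self):
        # with 2 participants per arm, the stratified bootstrap has 4x4
        # equally likely (ordered) resamples; enumerate the exact
        # distribution of the effect difference and compare frequencies
        df = toy_dataset()
        eff = {"intervention": [0.8, 0.6], "control": [0.5, 0.3]}
        exact = {}
        for ii in itertools.product([0, 1], repeat=2):
            for cc in itertools.product([0, 1], repeat=2):
                de = np.mean([eff["intervention"][i] for i in ii]) - np.mean(
                    [eff["control"][c] for c in cc]
                )
                exact[round(de, 10)] = exact.get(round(de, 10), 0) + 1 / 16
        cost_spec, effect_spec = _toy_specs()
        B = 3000
        dist = bootstrap_incrementals(
            df, cost_spec, effect_spec, B=B, seed=42,
            intervention_spec=AdjustmentSpec(outcome="cost_intervention",
                                             baseline_covariates=[],
                                             minimisation_factors=(), estimator="ols"),
        )
        observed = pd.Series(np.round(dist.delta_effect, 10)).value_counts(normalize=True)
        assert set(observed.index) <= set(exact)
        for value, p in exact.items():
            se = np.sqrt(p * (1 - p) / B)
            assert abs(observed.get(value, 0.0) - p) <= 3 * se + 1e-12, value

    def test_seed_determinism(self, small_frame):
        cost_spec, effect_spec, sign, label = specs_for_outcome("qaly_cyp", "ols")
        kwargs = dict(B=20, seed=9, effect_sign=sign, effect_label=label)
        d1 = bootstrap_incrementals(small_frame, cost_spec, effect_spec, **kwargs)
        d2 = bootstrap_incrementals(small_frame, cost_spec, effect_spec, **kwargs)
        assert np.array_equal(d1.delta_effect, d2.delta_effect)
        assert np.array_equal(d1.delta_cost, d2.delta_cost)

    def test_bootstrap_mean_near_point_estimate(self, small_frame):
        cost_spec, effect_spec, sign, label = specs_for_outcome("qaly_cyp", "ols")
        dist = bootstrap_incrementals(
            small_frame, cost_spec, effect_spec, B=200, seed=4,
            effect_sign=sign, effect_label=label,
        )
        se = dist.delta_effect.std(ddof=1) / np.sqrt(dist.B)
        assert abs(dist.delta_effect.mean() - dist.point["delta_effect"]) <= 4 * se

    def test_degenerate_dataset_raises_after_redraws(self):
        # a binary covariate on 2-per-arm data is constant in ~half of
        # resamples, so redraws exceed the 10% budget
        df = toy_dataset()
        df["z"] = [0.0, 1.0, 0.5, 0.5]
        cost_spec = AdjustmentSpec(outcome="cost", baseline_covariates=["z"],
                                   minimisation_factors=(), estimator="ols")
        effect_spec = AdjustmentSpec(outcome="effect", baseline_covariates=["z"],
                                     minimisation_factors=(), estimator="ols")
        with pytest.raises(RuntimeError, match="degenerate"):
            bootstrap_incrementals(df, cost_spec, effect_spec, B=100, seed=0)


class TestScenarios:
    def test_unknown_scenario_token_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario outcome"):
            Scenario("eq5d_vas")

    def test_single_scenario_one_row(self, small_frame):
        table, curves = run_scenarios(
            small_frame, [Scenario("qaly_cyp")], B=30, seed=11, estimator="ols"
        )
        assert len(table) == 1
        assert set(curves) == {"qaly_cyp_complete_case"}
        assert ((curves["qaly_cyp_complete_case"].probability >= 0)
                & (curves["qaly_cyp_complete_case"].probability <= 1)).all()

    def test_cost_scaling_scenarios_share_replicates(self, small_frame):
        table, curves = run_scenarios(
            small_frame,
            [Scenario("sdq_12m"), Scenario("sdq_12m", intervention_scaling=0.75)],
            B=60,
            seed=13,
            estimator="ols",
        )
        full = curves["sdq_12m_complete_case"]
        scaled = curves["sdq_12m_complete_case_cost75"]
        assert (scaled.probability >= full.probability).all()
        if full.crossing_lambda is not None and scaled.crossing_lambda is not None:
            assert scaled.crossing_lambda <= full.crossing_lambda
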