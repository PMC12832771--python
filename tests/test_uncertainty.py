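"""Sensitivity machinery: tornado, two-way grids, PSA distributions,
acceptability curves, price thresholds and the scenario runner."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from psmcea.economics import ARM_CONTROL, ARM_TREAT
from psmcea.errors import ConfigurationError
from psmcea.outcomes import StrategyResult, icer
from psmcea.pipeline import (
    default_psa_params,
    make_model_fn,
    run_scenario,
)
from psmcea.psm import PSMConfig
from psmcea.uncertainty import (
    ParamRange,
    PSAParam,
    PSASpec,
    beta_moments,
    ceac,
    gamma_moments,
    one_way_sa,
    pct20,
    price_threshold,
    psa,
    two_way_sa,
    validate_scenario,
)


def toy_model(int_price_base=100.0, units=10.0, other_cost=500.0, d_eff=0.5,
              wtp=150_000.0):
    """Linear toy: intervention cost = units * price + other; comparator
    fixed; effect gap constant.  Overrides: 'price.x' (intervention only)
    and 'shared' (added to both arms, cancels in the increment)."""

    def model_fn(overrides):
        price = overrides.get("price.x", int_price_base)
        shared = overrides.get("shared", 0.0)
        a = StrategyResult("A", units * price + other_cost + shared, 10.0, 1.0 + d_eff)
        b = StrategyResult("B", other_cost + shared, 10.0, 1.0)
        return icer(a, b, wtp)

    return model_fn


class TestOneWay:
    def test_shared_parameter_has_zero_spread(self):
        table = one_way_sa(toy_model(), [
            pct20("price.x", 100.0),
            ParamRange("shared", 0.0, 0.0, 1000.0, source="custom"),
        ])
        shared_row = table[table.param == "shared"].iloc[0]
        assert shared_row.spread == pytest.approx(0.0, abs=1e-9)
        assert table.iloc[0]["param"] == "price.x"  # sorted by spread

    def test_intervention_price_moves_icer_monotonically(self):
        table = one_way_sa(toy_model(), [pct20("price.x", 100.0)])
        row = table.iloc[0]
        assert row.icer_low < row.icer_high

    def test_failures_flagged_not_dropped(self):
        def fragile(overrides):
            if overrides.get("bad", 0) > 0:
                raise ValueError("boom")
            return toy_model()(overrides)

        table = one_way_sa(fragile, [ParamRange("bad", 0.0, 0.0, 1.0, "custom")])
        assert len(table) == 1 and bool(table.iloc[0].failed)

    def test_default_ranges_produce_ranked_tornado(self, us_model_fn, us_econ):
        from psmcea.pipeline import default_ranges

        table = one_way_sa(us_model_fn, default_ranges(us_econ))
        spreads = table["spread"].to_numpy()
        assert np.all(np.diff(spreads[~np.isnan(spreads)]) <= 1e-9)  # sorted
        discount = table[table.param == "discount_rate"].iloc[0]
        assert discount.spread > 0  # horizon-long discounting moves the ICER


class TestTwoWay:
    def test_base_cell_matches_base_icer(self, us_model_fn, us_econ):
        base = us_model_fn({}).icer
        ra = pct20("price.nivolumab", us_econ.drug_prices["nivolumab"])
        rb = pct20("price.ipilimumab", us_econ.drug_prices["ipilimumab"])
        grid = two_way_sa(us_model_fn, ra, rb, grid_size=3)
        mid = grid[np.isclose(grid["price.nivolumab"], ra.base)
                   & np.isclose(grid["price.ipilimumab"], rb.base)]
        assert mid.iloc[0].icer == pytest.approx(base, rel=1e-12)

    def test_corner_monotonicity(self):
        grid = two_way_sa(toy_model(), pct20("price.x", 100.0),
                          ParamRange("shared", 0.0, 0.0, 10.0, "custom"), grid_size=3)
        low = grid.icer.min()
        high = grid.icer.max()
        assert low <= high


class TestPSADistributions:
    def test_gamma_method_of_moments(self):
        assert gamma_moments(100.0, 20.0) == (pytest.approx(25.0), pytest.approx(4.0))

    def test_beta_method_of_moments(self):
        alpha, beta = beta_moments(0.84, 0.05)
        assert alpha == pytest.approx(44.32, abs=0.01)
        assert beta == pytest.approx(8.44, abs=0.01)

    def test_beta_infeasible_moments_rejected(self):
        with pytest.raises(ConfigurationError, match="infeasible"):
            beta_moments(0.5, 0.6)

    def test_degenerate_sd_reproduces_base_icer(self, us_model_fn, us_econ):
        params = [dataclasses.replace(p, sd=0.0) for p in default_psa_params(us_econ)]
        draws = psa(us_model_fn, PSASpec(params, n_draws=5, seed=3))
        base = us_model_fn({}).icer
        assert np.allclose(draws["icer"], base)

    def test_seed_reproducibility(self, us_model_fn, us_econ):
        spec = PSASpec(default_psa_params(us_econ), n_draws=20, seed=11)
        a = psa(us_model_fn, spec)
        b = psa(us_model_fn, spec)
        pd.testing.assert_frame_equal(a, b)
        c = psa(us_model_fn, PSASpec(default_psa_params(us_econ), n_draws=20, seed=12))
        assert not a["dcost"].equals(c["dcost"])


class TestCEAC:
    def test_single_point_cloud_switches_at_icer(self):
        draws = pd.DataFrame({"dcost": [86_403.43] * 8, "dqaly": [0.68] * 8})
        table = ceac(draws, [100_000.0, 150_000.0])
        assert table.probability.tolist() == [0.0, 1.0]

    def test_wtp_zero_counts_cost_saving_draws(self):
        draws = pd.DataFrame({"dcost": [-5.0, 10.0, -1.0, 3.0], "dqaly": [0.1] * 4})
        table = ceac(draws, [0.0])
        assert table.probability.iloc[0] == 0.5

    def test_probabilities_are_exact_fractions(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({"dcost": rng.normal(1000, 300, 40),
                              "dqaly": rng.normal(0.5, 0.1, 40)})
        table = ceac(draws, [2000.0])
        count = int((2000.0 * draws.dqaly - draws.dcost > 0).sum())
        assert table.probability.iloc[0] == count / 40


class TestPriceThreshold:
    def test_linear_toy_matches_analytic_multiplier(self):
        # other_cost enters both arms and cancels: WTP * dE = units * p0 * m
        units, p0, other, d_eff, wtp = 10.0, 100.0, 500.0, 0.5, 20_000.0
        model = toy_model(p0, units, other, d_eff, wtp)
        analytic = wtp * d_eff / (units * p0)
        res = price_threshold(model, ["price.x"], wtp, bounds=(0.01, 20.0),
                              base_prices={"price.x": p0})
        assert res.status == "solved"
        assert res.multiplier == pytest.approx(analytic, rel=1e-4)
        assert abs(res.achieved_icer - wtp) / wtp < 1e-4

    def test_direction_when_wtp_above_current_icer(self):
        model = toy_model(wtp=150_000.0)  # base ICER = (10*100+500)/0.5 = 3,000
        res = price_threshold(model, ["price.x"], 10_000.0, bounds=(0.01, 10.0),
                              base_prices={"price.x": 100.0})
        assert res.multiplier > 1.0

    def test_joint_threshold_not_above_single(self, us_model_fn, us_econ):
        base_prices = {
            "price.nivolumab": us_econ.drug_prices["nivolumab"],
            "price.ipilimumab": us_econ.drug_prices["ipilimumab"],
        }
        wtp = 100_000.0
        singles = [
            price_threshold(us_model_fn, [p], wtp, base_prices=base_prices)
            for p in base_prices
        ]
        joint = price_threshold(us_model_fn, list(base_prices), wtp,
                                base_prices=base_prices)
        assert joint.status == "solved"
        for single in singles:
            if single.status == "solved":
                assert joint.multiplier >= single.multiplier - 1e-6

    def test_no_crossing_reported(self):
        model = toy_model(wtp=1e9)
        res = price_threshold(model, ["price.x"], 1e9, bounds=(0.5, 1.5),
                              base_prices={"price.x": 100.0})
        assert res.status == "always"
        assert res.multiplier is None


class TestScenarios:
    def _grids(self, benefit_after=24, n=240):
        """Comparator survival equal to intervention until ``benefit_after``
        months, faster decline afterwards; PFS identical in both arms."""
        t = np.arange(n + 1, dtype=float)
        s_treat = np.exp(-0.02 * t)
        extra = np.where(t > benefit_after, 0.06 * (t - benefit_after), 0.0)
        s_ctrl = s_treat * np.exp(-extra)
        pfs = np.exp(-0.08 * t)
        return {
            ARM_TREAT: {"OS": s_treat, "PFS": np.minimum(pfs, s_treat)},
            ARM_CONTROL: {"OS": s_ctrl, "PFS": np.minimum(pfs, s_ctrl)},
        }

    def test_short_horizon_inflates_icer_when_benefit_is_late(self, us_econ):
        grids = {"ITT": self._grids()}
        cfg = PSMConfig()
        *_, ce20 = run_scenario(grids, us_econ, cfg, {"horizon_years": 20})
        *_, ce4 = run_scenario(grids, us_econ, cfg, {"horizon_years": 4})
        assert ce4.icer > ce20.icer

    def test_excluding_absent_ae_disutilities_is_noop(self, itt_stage, us_econ):
        econ = dataclasses.replace(
            us_econ,
            adverse_events=[dataclasses.replace(ae, disutility=0.0)
                            for ae in us_econ.adverse_events],
        )
        grids = {"ITT": itt_stage.grids}
        cfg = PSMConfig()
        *_, base = run_scenario(grids, econ, cfg, {})
        *_, excl = run_scenario(grids, econ, cfg, {"exclude_ae_disutility": True})
        assert excl.delta_cost == pytest.approx(base.delta_cost)
        assert excl.delta_effect == pytest.approx(base.delta_effect)

    def test_pfs_only_accrual_noop_when_pfs_equals_os(self, us_econ):
        t = np.arange(241, dtype=float)
        s = np.exp(-0.03 * t)
        grids = {"ITT": {arm: {"OS": s, "PFS": s} for arm in (ARM_TREAT, ARM_CONTROL)}}
        cfg = PSMConfig()
        treat_a, _, base = run_scenario(grids, us_econ, cfg, {})
        treat_b, _, only = run_scenario(grids, us_econ, cfg, {"pfs_only_accrual": True})
        assert treat_b.cost == pytest.approx(treat_a.cost)
        assert only.delta_effect == pytest.approx(base.delta_effect)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown scenario"):
            validate_scenario({"horizon_months": 48})

    def test_comparator_switch_changes_control_costs(self, itt_stage, us_econ):
        grids = {"ITT": itt_stage.grids}
        cfg = PSMConfig()
        _, ctrl_len, _ = run_scenario(grids, us_econ, cfg, {"comparator": "lenvatinib"})
        _, ctrl_sor, _ = run_scenario(grids, us_econ, cfg, {"comparator": "sorafenib"})
        assert ctrl_len.cost != pytest.approx(ctrl_sor.cost)
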