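"""Decision-tree cost-effectiveness: rollback, ICER/NMB, sensitivity analyses."""

import numpy as np
import pytest

from lipidrisk.cea import (
    CeaInputs,
    DEFAULT_EFFICACY,
    Node,
    StrategySpec,
    build_default_strategies,
    build_tree,
    evaluate_strategies,
    icer_nmb,
    one_way_microsim,
    rollback,
    tornado,
)

RISK_DISTS = {
    "fpg": {"HR": 0.25, "LR": 0.75},
    "lrs": {"HR": 1 / 3, "LR": 2 / 3},
    "fpg_lrs": {"HR": 0.15, "MR": 0.25, "LR": 0.60},
    "rf_lrs": {"HR": 0.20, "MR": 0.20, "LR": 0.60},
}


@pytest.fixture(scope="module")
def strategies():
    return build_default_strategies(RISK_DISTS)


@pytest.fixture(scope="module")
def inputs():
    return CeaInputs()


def enumerate_paths(node, prob=1.0):
    """Brute-force path enumeration oracle for rollback."""
    if node.kind == "leaf":
        return [(prob, node.payoff)]
    out = []
    for p, child in node.branches:
        out.extend(enumerate_paths(child, prob * p))
    return out


def random_tree(rng, depth=0, max_depth=3):
    if depth >= max_depth or rng.random() < 0.3:
        return Node("leaf", payoff={"cost": float(rng.uniform(0, 100)), "qaly": float(rng.uniform(0, 5))})
    k = int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(k))
    return Node(
        "chance",
        branches=[(float(p), random_tree(rng, depth + 1, max_depth)) for p in probs],
    )


class TestCostConstants:
    def test_lrs_strategy_screening_cost_components(self, strategies):
        lrs_metformin = strategies[2]
        # 11 per assay + 29 sample prep + 50 primary-care visit, once
        assert lrs_metformin.screening_cost == pytest.approx(11 + 29 + 50)

    def test_combined_strategy_charges_shared_costs_once(self, strategies):
        combined = strategies[5]  # FPG + LRS
        assert combined.screening_cost == pytest.approx(9 + 11 + 29 + 50)
        assert combined.shared_costs == pytest.approx(79)

    def test_efficacy_constants(self):
        assert DEFAULT_EFFICACY["lifestyle"] == 0.58
        assert DEFAULT_EFFICACY["metformin"] == 0.31

    def test_seven_strategies(self, strategies):
        assert len(strategies) == 7


class TestRollback:
    def test_toy_two_branch_expected_value(self):
        toy = Node(
            "chance",
            branches=[
                (0.2, Node("leaf", payoff={"qaly": 4.0})),
                (0.8, Node("leaf", payoff={"qaly": 5.0})),
            ],
        )
        assert rollback(toy)["qaly"] == pytest.approx(4.8)

    def test_deterministic_tree_returns_single_path(self):
        tree = Node(
            "chance",
            branches=[
                (1.0, Node("leaf", payoff={"cost": 7.0, "qaly": 2.0})),
                (0.0, Node("leaf", payoff={"cost": 99.0, "qaly": 0.0})),
            ],
        )
        assert rollback(tree) == {"cost": 7.0, "qaly": 2.0}

    def test_unnormalized_chance_node_rejected(self):
        bad = Node("chance", branches=[(0.5, Node("leaf", payoff={"qaly": 1.0}))])
        with pytest.raises(ValueError, match="unnormalized"):
            rollback(bad)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_path_enumeration_oracle(self, seed):
        tree = random_tree(np.random.default_rng(seed))
        ev = rollback(tree)
        paths = enumerate_paths(tree)
        assert sum(p for p, _ in paths) == pytest.approx(1.0)
        for key in ("cost", "qaly"):
            oracle = sum(p * payoff[key] for p, payoff in paths)
            assert ev[key] == pytest.approx(oracle, abs=1e-10)

    def test_zero_efficacy_gives_zero_risk_reduction(self, strategies):
        inp = CeaInputs(efficacy={"lifestyle": 0.0, "metformin": 0.0, "none": 0.0})
        res = evaluate_strategies(strategies, inp)
        assert np.allclose(res["risk_reduction"], 0.0, atol=1e-12)

    def test_treated_group_probability_scaling(self, inputs):
        s = StrategySpec(
            name="t", tests=[], shared_costs=0.0,
            risk_groups={"HR": 1.0}, interventions={"HR": "lifestyle"},
        )
        ev = rollback(build_tree(s, inputs))
        expected = inputs.p_t2d_5y["HR"] * (1 - inputs.efficacy["lifestyle"])
        assert ev["t2d"] == pytest.approx(expected)


class TestIcerNmb:
    def test_icer_arithmetic(self, inputs):
        import pandas as pd

        res = pd.DataFrame(
            {"cost": [1000.0, 2000.0], "qaly": [1.0, 1.5]},
            index=["ref", "alt"],
        )
        out = icer_nmb(res, reference="ref", wtp=4450.12)
        assert out.loc["alt", "icer"] == pytest.approx(1000 / 0.5)
        assert not out.loc["ref", "icer_defined"]

    def test_nmb_ordering_invariant_to_constant_cost(self, strategies, inputs):
        res = evaluate_strategies(strategies, inputs)
        out1 = icer_nmb(res, strategies[2].name, inputs.wtp)
        shifted = res.copy()
        shifted["cost"] += 500.0
        out2 = icer_nmb(shifted, strategies[2].name, inputs.wtp)
        assert (out1["nmb"].rank() == out2["nmb"].rank()).all()

    def test_nmb_sign_flips_across_icer(self, strategies, inputs):
        res = evaluate_strategies(strategies, inputs)
        out = icer_nmb(res, strategies[0].name, inputs.wtp)
        candidates = out[
            out["icer_defined"] & np.isfinite(out["icer"]) & (out["delta_cost"] > 0)
        ]
        name = candidates.index[0]
        icer = out.loc[name, "icer"]
        for factor, sign in ((0.5, -1), (2.0, +1)):
            wtp = icer * factor
            nmb_diff = (wtp * out.loc[name, "qaly"] - out.loc[name, "cost"]) - (
                wtp * out.loc[strategies[0].name, "qaly"] - out.loc[strategies[0].name, "cost"]
            )
            assert np.sign(nmb_diff) == sign

    def test_dominated_flagging(self):
        import pandas as pd

        res = pd.DataFrame(
            {"cost": [100.0, 200.0], "qaly": [2.0, 2.0]}, index=["ref", "worse"]
        )
        out = icer_nmb(res, "ref", wtp=1000.0)
        assert bool(out.loc["worse", "dominated"])


class TestSensitivity:
    def test_zero_width_range_zero_swing(self, strategies, inputs):
        base = inputs.get_parameter("p_t2d_5y.HR")
        tor = tornado(strategies, inputs, {"p_t2d_5y.HR": (base, base)})
        assert tor["swing"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_high_risk_probability_has_widest_swing(self, strategies, inputs):
        ranges = {
            "p_t2d_5y.HR": (0.20, 0.50),
            "efficacy.metformin": (0.21, 0.41),
            "intervention_cost_5y.metformin": (170.0, 370.0),
        }
        tor = tornado(strategies, inputs, ranges)
        assert tor.loc[0, "parameter"] == "p_t2d_5y.HR"

    def test_swing_monotone_in_range_width(self, strategies, inputs):
        narrow = tornado(strategies, inputs, {"p_t2d_5y.HR": (0.3, 0.5)})
        wide = tornado(strategies, inputs, {"p_t2d_5y.HR": (0.2, 0.6)})
        assert wide["swing"].iloc[0] >= narrow["swing"].iloc[0] - 1e-12

    def test_range_must_bracket_base(self, strategies, inputs):
        with pytest.raises(ValueError, match="bracket"):
            tornado(strategies, inputs, {"p_t2d_5y.HR": (0.6, 0.9)})


class TestMicrosim:
    def test_reproducible_under_fixed_seed(self, strategies, inputs):
        a = one_way_microsim(strategies, inputs, "p_t2d_5y.HR", (0.2, 0.5), n_runs=40, seed=9)
        b = one_way_microsim(strategies, inputs, "p_t2d_5y.HR", (0.2, 0.5), n_runs=40, seed=9)
        name = strategies[2].name
        assert np.allclose(a[name]["ev"], b[name]["ev"])
        assert np.allclose(a[name]["poly"], b[name]["poly"])

    def test_constant_payoff_flat_polynomial(self, strategies, inputs):
        # strategy 1 treats nobody in the HR group, so varying the MR
        # probability leaves its payoffs untouched
        out = one_way_microsim(
            [strategies[0]], inputs, "p_t2d_5y.MR", (0.10, 0.20), n_runs=30, seed=1
        )
        rec = out[strategies[0].name]
        assert np.ptp(rec["ev"]) < 1e-9
        assert np.ptp(rec["fitted"]) < 1e-6  # flat fitted polynomial

    def test_linear_truth_reproduced(self, strategies, inputs):
        # expected cost is linear in the diabetes medical cost while QALYs
        # are unaffected, so EV = cost/qaly is linear in the parameter
        out = one_way_microsim(
            [strategies[2]], inputs, "medical_cost_5y.True", (10000.0, 16000.0),
            n_runs=60, seed=2,
        )
        rec = out[strategies[2].name]
        resid = rec["ev"] - rec["fitted"]
        ss_res = np.sum(resid**2)
        ss_tot = np.sum((rec["ev"] - rec["ev"].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_too_few_runs_rejected(self, strategies, inputs):
        with pytest.raises(ValueError):
            one_way_microsim(strategies, inputs, "p_t2d_5y.HR", (0.2, 0.5), n_runs=5)


class TestSpecValidation:
    def test_unnormalized_risk_groups_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            StrategySpec(name="bad", risk_groups={"HR": 0.5, "LR": 0.4},
                         interventions={"HR": "none", "LR": "none"})

    def test_missing_intervention_rejected(self):
        with pytest.raises(ValueError, match="intervention"):
            StrategySpec(name="bad", risk_groups={"HR": 1.0}, interventions={})

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            CeaInputs(p_t2d_5y={"HR": 1.4, "MR": 0.1, "LR": 0.05, "ALL": 0.1})
        with pytest.raises(ValueError):
            CeaInputs(efficacy={"lifestyle": -0.2, "metformin": 0.3, "none": 0.0})
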