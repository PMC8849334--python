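"""Normalized Hill activation, gate algebra, and protocol integration."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fibronet as fn
from fibronet.engine import (
    PerturbationSpec,
    SolverConfig,
    StageSpec,
    compile_model,
    hill_ceiling,
    node_drive,
    normalized_hill,
    or_fold,
    reaction_activation,
    run_protocol,
    steady_state,
    steady_state_delta,
)
from fibronet.fixtures import chain_steady_state, euler_oracle
from fibronet.model import ReactionDef, Term


class TestNormalizedHill:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_anchor_points(self, x, expected):
        assert normalized_hill(x, 0.5, 1.4) == pytest.approx(expected, abs=1e-12)

    def test_quarter_dose_matches_direct_evaluation(self):
        # oracle: evaluate B and K^n from their defining formulas directly
        ec50, n = 0.5, 1.4
        b = (ec50**n - 1) / (2 * ec50**n - 1)
        k_n = b - 1
        expected = b * 0.25**n / (k_n + 0.25**n)
        assert normalized_hill(0.25, ec50, n) == pytest.approx(expected, rel=1e-12)

    @given(
        ec50=st.floats(0.05, 0.95),
        n=st.floats(0.2, 6.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_anchors_and_monotonicity_hold_generally(self, ec50, n):
        if abs(2 * ec50**n - 1) < 1e-4:
            return  # singular neighborhood excluded
        xs = np.linspace(0, 1, 50)
        ys = normalized_hill(xs, ec50, n)
        assert ys[0] == pytest.approx(0, abs=1e-12)
        assert ys[-1] == pytest.approx(1, rel=1e-7)
        assert normalized_hill(ec50, ec50, n) == pytest.approx(0.5, rel=1e-7)
        assert np.all(np.diff(ys) >= -1e-12)

    def test_saturates_at_ceiling_above_one(self):
        b = hill_ceiling(0.5, 1.4)
        assert normalized_hill(50.0, 0.5, 1.4) == pytest.approx(b, rel=1e-2)
        assert normalized_hill(1.5, 0.5, 1.4) > 1.0

    def test_singular_parameters_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            normalized_hill(0.3, 0.5, 1.0)  # 2*0.5^1 == 1


class TestGateAlgebra:
    def test_input_reaction_constant_drive(self):
        r = ReactionDef(target="X", weight=0.1)
        assert reaction_activation(r, {}) == 0.1

    def test_single_activator(self):
        r = ReactionDef(target="X", terms=(Term("A"),), weight=1.0)
        assert reaction_activation(r, {"A": 0.5}) == pytest.approx(0.5)

    def test_and_product_with_inhibitor(self):
        # f(A)=0.5 at A=EC50; inhibitor contributes 1-f(B)
        r = ReactionDef(
            target="X",
            terms=(Term("A"), Term("B", "inhibitor")),
            weight=0.8,
        )
        b_act = normalized_hill(0.7, 0.5, 1.4)
        expected = 0.8 * 0.5 * (1 - b_act)
        assert reaction_activation(r, {"A": 0.5, "B": 0.7}) == pytest.approx(expected)

    def test_missing_source_raises(self):
        r = ReactionDef(target="X", terms=(Term("A"),))
        with pytest.raises(KeyError):
            reaction_activation(r, {})

    @pytest.mark.parametrize(
        "drives,expected",
        [((0.5, 0.5), 0.75), ((1.0, 0.3), 1.0), ((0.2, 0.3, 0.4), 0.664)],
    )
    def test_or_fold_values(self, drives, expected):
        assert or_fold(drives) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_or_fold_permutation_invariant(self, drives):
        results = {or_fold(p) for p in itertools.permutations(drives)}
        assert max(results) - min(results) < 1e-12
        assert 0 <= or_fold(drives) <= 1 + 1e-12

    def test_node_drive_or_combines_reactions(self):
        rxns = [
            ReactionDef(target="X", terms=(Term("A"),)),
            ReactionDef(target="X", terms=(Term("B"),)),
            ReactionDef(target="Y", terms=(Term("A"),)),
        ]
        acts = {"A": 0.5, "B": 0.5}
        assert node_drive("X", rxns, acts) == pytest.approx(0.75)
        assert node_drive("Y", rxns, acts) == pytest.approx(0.5)


class TestProtocols:
    def test_single_input_fixed_point(self):
        m = fn.make_fixture(fn.FixtureSpec("chain", n_nodes=1, n_inputs=1))
        res = steady_state(m, {"IN1": 0.4}, duration=240.0)
        assert res.final_activities["IN1"] == pytest.approx(0.4, abs=1e-6)
        assert res.converged

    def test_chain_matches_closed_form(self, chain3):
        res = steady_state(chain3, {"IN1": 0.8}, duration=400.0)
        closed = chain_steady_state(chain3, 0.8)
        for k, v in closed.items():
            assert res.final_activities[k] == pytest.approx(v, abs=1e-6)

    def test_knockdown_bounds_activity(self, chain3):
        res = steady_state(
            chain3,
            {"IN1": 0.8},
            perturbations=[PerturbationSpec("N1", "set_ymax", 0.1)],
            duration=400.0,
        )
        assert res.final_activities["N1"] <= 0.1 + 1e-9

    def test_trajectory_bounded_by_ymax(self, random_cyclic7):
        cfg = SolverConfig(n_trajectory_points=80)
        res = run_protocol(
            random_cyclic7,
            [StageSpec(input_weights={"IN1": 0.9}, duration=100.0)],
            config=cfg,
        )
        ymax = np.array([s.y_max for s in random_cyclic7.species])
        assert np.all(res.trajectory_y >= -1e-8)
        assert np.all(res.trajectory_y <= ymax[:, None] + 1e-6)

    def test_steady_state_independent_of_tau(self, random_cyclic7):
        scaled = fn.NetworkModel(
            species=[
                dataclasses.replace(s, tau=s.tau * 10) for s in random_cyclic7.species
            ],
            reactions=list(random_cyclic7.reactions),
        )
        w = {"IN1": 0.7, "IN2": 0.3}
        a = steady_state(random_cyclic7, w, duration=5000.0).final_activities
        b = steady_state(scaled, w, duration=5000.0).final_activities
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-6)

    def test_adaptive_matches_euler_oracle(self, random_cyclic7):
        stages = [StageSpec(input_weights={"IN1": 0.8, "IN2": 0.2}, duration=40.0)]
        oracle = euler_oracle(random_cyclic7, stages, dt=1e-3)
        res = run_protocol(random_cyclic7, stages)
        for k in oracle:
            assert res.final_activities[k] == pytest.approx(oracle[k], abs=1e-4)

    def test_monotone_response_along_chain(self):
        m = fn.make_fixture(fn.FixtureSpec("chain", n_nodes=4, n_inputs=1))
        finals = [
            steady_state(m, {"IN1": w}, duration=400.0).final_activities
            for w in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        for node in ("N1", "N2", "N3"):
            vals = [f[node] for f in finals]
            assert np.all(np.diff(vals) >= -1e-9)

    def test_unknown_perturbation_node_raises(self, chain3):
        with pytest.raises(KeyError):
            steady_state(
                chain3, {}, perturbations=[PerturbationSpec("nope", "set_ymax", 0.1)]
            )

    def test_perturbation_driving_ymax_nonpositive_raises(self, chain3):
        with pytest.raises(ValueError, match="Ymax"):
            steady_state(
                chain3, {}, perturbations=[PerturbationSpec("N1", "subtract_ymax", 1.5)]
            )

    def test_empty_protocol_rejected(self, chain3):
        with pytest.raises(ValueError):
            run_protocol(chain3, [])


class TestSteadyStateDelta:
    def test_identical_stages_give_zero(self, chain3):
        stage = StageSpec(input_weights={"IN1": 0.1}, duration=200.0)
        d = steady_state_delta(chain3, stage, stage)
        assert all(abs(v) < 1e-6 for v in d.values())

    def test_isolated_input_weight_step(self):
        m = fn.make_fixture(fn.FixtureSpec("chain", n_nodes=1, n_inputs=1))
        d = steady_state_delta(
            m,
            StageSpec(input_weights={"IN1": 0.1}, duration=200.0),
            StageSpec(input_weights={"IN1": 0.8}, duration=200.0),
        )
        assert d["IN1"] == pytest.approx(0.7, abs=1e-6)

    def test_inhibitor_knockdown_sign_matches_oracle(self):
        # Input -> A, A -| B, B activated by its own input drive:
        # knocking down A should raise B; verify sign against the Euler oracle.
        m = fn.NetworkModel(
            species=[
                fn.SpeciesDef(id="IN1", category="input", tau=0.1),
                fn.SpeciesDef(id="A", tau=0.1),
                fn.SpeciesDef(id="B", tau=0.1),
            ],
            reactions=[
                ReactionDef(target="IN1"),
                ReactionDef(target="A", terms=(Term("IN1"),)),
                ReactionDef(target="B", terms=(Term("A", "inhibitor"),), weight=0.9),
            ],
        )
        base = StageSpec(input_weights={"IN1": 0.8}, duration=50.0)
        kd = StageSpec(
            input_weights={"IN1": 0.8},
            perturbations=(PerturbationSpec("A", "set_ymax", 0.1),),
            duration=50.0,
        )
        d = steady_state_delta(m, base, kd)
        o_base = euler_oracle(m, [base], dt=1e-3)
        o_kd = euler_oracle(m, [base, kd], dt=1e-3)
        assert d["B"] > 0
        assert np.sign(d["B"]) == np.sign(o_kd["B"] - o_base["B"])
        assert d["B"] == pytest.approx(o_kd["B"] - o_base["B"], abs=1e-4)
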