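"""Perturbation enumeration, MCC scoring, and mechano-adaptive ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import fibronet as fn
from fibronet.engine import PerturbationSpec, StageSpec, run_protocol
from fibronet.screen import (
    DEFAULT_OUTPUT_GROUPS,
    KD,
    OE,
    OutputGroups,
    ScreenPerturbation,
    adaptive_rank,
    enumerate_perturbations,
    matrix_content_change,
    run_screen,
)


def brute_force_doubles(nodes):
    """Independent enumeration of all distinct two-node mode assignments."""
    out = set()
    for a, b in itertools.permutations(nodes, 2):
        for ma, mb in itertools.product((KD, OE), repeat=2):
            out.add(frozenset([(a, ma), (b, mb)]))
    return out


class TestEnumeration:
    def test_counts_at_network_scale(self):
        nodes = [f"n{i}" for i in range(109)]
        singles = enumerate_perturbations(nodes, include_double=False)
        doubles = enumerate_perturbations(nodes, include_single=False)
        assert len(singles) == 218
        assert len(doubles) == 23544
        assert len(doubles) == 4 * math.comb(109, 2)

    @pytest.mark.parametrize("n", range(2, 21))
    def test_formula_matches_brute_force(self, n):
        nodes = [f"n{i}" for i in range(n)]
        singles = enumerate_perturbations(nodes, include_double=False)
        doubles = enumerate_perturbations(nodes, include_single=False)
        assert len(singles) == 2 * n
        assert {(p.nodes[0], p.modes[0]) for p in singles} == {
            (x, m) for x in nodes for m in (KD, OE)
        }
        expected = brute_force_doubles(nodes)
        got = {frozenset(zip(p.nodes, p.modes)) for p in doubles}
        assert got == expected
        assert len(doubles) == len(got)  # no duplicates emitted

    def test_deterministic_order(self):
        a = enumerate_perturbations(list("abc"))
        b = enumerate_perturbations(list("abc"))
        assert [p.label for p in a] == [p.label for p in b]

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError):
            enumerate_perturbations(["a", "a"])
        with pytest.raises(ValueError):
            ScreenPerturbation(("a", "a"), (KD, KD))


class TestMCC:
    def test_zero_delta(self):
        delta = {n: 0.0 for n in DEFAULT_OUTPUT_GROUPS.all_nodes}
        assert matrix_content_change(delta) == 0.0

    def test_group_membership_signs(self):
        delta = {n: 0.0 for n in DEFAULT_OUTPUT_GROUPS.all_nodes}
        delta["proCI"] = 0.1
        assert matrix_content_change(delta) == pytest.approx(0.1)
        delta["proCI"] = 0.0
        delta["proMMP1"] = 0.1
        delta["TIMP1"] = 0.1
        assert matrix_content_change(delta) == pytest.approx(0.0)

    def test_missing_output_named(self):
        delta = {n: 0.0 for n in DEFAULT_OUTPUT_GROUPS.all_nodes if n != "PAI1"}
        with pytest.raises(KeyError, match="PAI1"):
            matrix_content_change(delta)

    def test_linearity_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        delta = {n: rng.normal() for n in DEFAULT_OUTPUT_GROUPS.all_nodes}
        m1 = matrix_content_change(delta)
        scaled = {k: 2.5 * v for k, v in delta.items()}
        assert matrix_content_change(scaled) == pytest.approx(2.5 * m1)
        shuffled = dict(reversed(list(delta.items())))
        assert matrix_content_change(shuffled) == pytest.approx(m1)


@pytest.fixture(scope="module")
def tiny_groups():
    return OutputGroups(matrix=("N1",), mmp=("N2",), inhibitor=())


@pytest.fixture(scope="module")
def tiny_screen_model():
    """IN1 -> N1 and IN1 -> N2 -> N3: two competing 'outputs' plus a tail."""
    m = fn.make_fixture(fn.FixtureSpec("star", n_nodes=5, n_inputs=1, seed=0))
    return m


class TestRunScreen:
    def test_empty_perturbation_is_identity(self, tiny_screen_model, tiny_groups):
        records = run_screen(
            tiny_screen_model,
            [ScreenPerturbation((), ())],
            tensions=(0.1, 0.6),
            groups=tiny_groups,
            tension_input="none",
            basal_duration=40.0,
            perturb_duration=60.0,
        )
        assert np.allclose(records["mcc"], 0.0, atol=1e-6)
        assert np.allclose(records[["delta_N1", "delta_N2"]], 0.0, atol=1e-6)

    def test_mcc_matches_brute_force_simulation(self, tiny_screen_model, tiny_groups):
        perts = enumerate_perturbations(["N1", "N2", "N3"], include_double=True)
        records = run_screen(
            tiny_screen_model,
            perts,
            tensions=(0.4,),
            groups=tiny_groups,
            tension_input="none",
            basal_duration=40.0,
            perturb_duration=60.0,
        )
        # independent loop: simulate each perturbation from scratch, no caching
        weights = {"IN1": 0.1}
        base = run_protocol(
            tiny_screen_model,
            [
                StageSpec(input_weights=weights, duration=40.0),
                StageSpec(input_weights=weights, duration=60.0),
            ],
        ).final_activities
        for _, row in records.iterrows():
            pert = next(p for p in perts if p.label == row["perturbation"])
            res = run_protocol(
                tiny_screen_model,
                [
                    StageSpec(input_weights=weights, duration=40.0),
                    StageSpec(
                        input_weights=weights,
                        perturbations=pert.to_perturbation_specs(),
                        duration=60.0,
                    ),
                ],
            ).final_activities
            expected = (res["N1"] - base["N1"]) - (res["N2"] - base["N2"])
            assert row["mcc"] == pytest.approx(expected, abs=1e-6)

    def test_cache_resume_skips_completed_rows(self, tmp_path, tiny_screen_model,
                                               tiny_groups):
        perts = enumerate_perturbations(["N1", "N2"], include_double=False)
        cache = tmp_path / "cache.tsv"
        first = run_screen(
            tiny_screen_model, perts[:2], tensions=(0.4,), groups=tiny_groups,
            tension_input="none", basal_duration=40.0, perturb_duration=60.0,
            cache_path=cache,
        )
        assert len(first) == 2
        full = run_screen(
            tiny_screen_model, perts, tensions=(0.4,), groups=tiny_groups,
            tension_input="none", basal_duration=40.0, perturb_duration=60.0,
            cache_path=cache,
        )
        assert len(full) == len(perts)
        # cached rows were reused verbatim
        merged = full.set_index("perturbation")
        for _, row in first.iterrows():
            assert merged.loc[row["perturbation"], "mcc"] == pytest.approx(row["mcc"])

    def test_screen_is_deterministic(self, tiny_screen_model, tiny_groups):
        perts = enumerate_perturbations(["N1", "N2"], include_double=False)
        kw = dict(tensions=(0.1, 0.6), groups=tiny_groups, tension_input="none",
                  basal_duration=40.0, perturb_duration=60.0)
        a = run_screen(tiny_screen_model, perts, **kw)
        b = run_screen(tiny_screen_model, perts, **kw)
        pd.testing.assert_frame_equal(a, b)


def _records(mcc_low: dict, mcc_high: dict) -> pd.DataFrame:
    rows = []
    for p, v in mcc_low.items():
        rows.append({"perturbation": p, "tension": 0.1, "mcc": v})
    for p, v in mcc_high.items():
        rows.append({"perturbation": p, "tension": 0.6, "mcc": v})
    return pd.DataFrame(rows)


class TestAdaptiveRank:
    def test_no_record_satisfies_sign_filter(self):
        df = _records({"a": 0.2, "b": 0.1}, {"a": 0.3, "b": -0.2})
        assert adaptive_rank(df).empty

    def test_three_record_hand_ranking(self):
        # hand-ranked oracle: most negative low-MCC and most positive
        # high-MCC both belong to record a -> rank 1 + rank 1
        df = _records(
            {"a": -0.3, "b": -0.2, "c": -0.1},
            {"a": 0.3, "b": 0.2, "c": 0.1},
        )
        out = adaptive_rank(df)
        assert out.loc["a", "rank_low"] == 1 and out.loc["a", "rank_high"] == 1
        assert out.loc["c", "rank_low"] == 3 and out.loc["c", "rank_high"] == 3
        # quoted formula: N - 2*(r_low + r_high)
        assert out.loc["a", "adaptive_score"] == 3 - 2 * 2
        assert out.loc["c", "adaptive_score"] == 3 - 2 * 6
        assert out.index[0] == "a"

    def test_extremal_record_attains_maximum(self):
        rng = np.random.default_rng(6)
        low = {f"p{i}": -rng.uniform(0.01, 1) for i in range(20)}
        high = {f"p{i}": rng.uniform(0.01, 1) for i in range(20)}
        low["best"] = -2.0
        high["best"] = 2.0
        out = adaptive_rank(_records(low, high))
        assert out["adaptive_score"].idxmax() == "best"
        assert out.index[0] == "best"

    def test_invariant_to_record_order(self):
        df = _records({"a": -0.3, "b": -0.2}, {"a": 0.1, "b": 0.4})
        out1 = adaptive_rank(df)
        out2 = adaptive_rank(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_score_conventions(self):
        df = _records(
            {"a": -0.3, "b": -0.2, "c": -0.1},
            {"a": 0.3, "b": 0.2, "c": 0.1},
        )
        quoted = adaptive_rank(df, convention="quoted")
        zero = adaptive_rank(df, convention="zero_based")
        clamped = adaptive_rank(df, convention="clamped")
        assert (zero["adaptive_score"] == quoted["adaptive_score"] + 4).all()
        assert (clamped["adaptive_score"] >= 0).all()
        # ordering is identical under all conventions
        assert list(quoted.index) == list(zero.index) == list(clamped.index)

    def test_mixed_sign_ties_share_minimum_rank(self):
        df = _records({"a": -0.2, "b": -0.2, "c": -0.1},
                      {"a": 0.2, "b": 0.2, "c": 0.3})
        out = adaptive_rank(df)
        assert out.loc["a", "rank_low"] == out.loc["b", "rank_low"] == 1
        assert out.loc["c", "rank_low"] == 3
        assert out.loc["c", "rank_high"] == 1
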