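"""Quantification: summaries, Mann-Whitney, dynamic range, trapping."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qibc import quantify, staging
from qibc.quantify import compare_conditions, gate_mask
from qibc.simulate import DrugEffects, SimulationParams, simulate_features


def mann_whitney_enumeration(a, b):
    """Exhaustive-enumeration oracle: exact two-sided Mann-Whitney p.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the first
    group and counts assignments at least as extreme (U distance from its
    null mean) as observed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_stat(a, b)
    center = n1 * n2 / 2.0
    extreme = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        sel = set(comb)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(n1 + n2) if i not in sel]
        if abs(u_stat(ga, gb) - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
        total += 1
    return u_obs, extreme / total


class TestCompareConditions:
    def test_textbook_separated_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 0.1 (2 of the
        20 assignments are as extreme)."""
        res = compare_conditions([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.effect_size == pytest.approx(1.0)

    def test_identical_groups_symmetric(self, rng):
        vals = rng.normal(10, 2, size=50)
        res = compare_conditions(vals, vals)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided > 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_conditions([], [1.0])

    @given(
        n1=st.integers(min_value=1, max_value=6),
        n2=st.integers(min_value=1, max_value=6),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle_small_samples(self, n1, n2, data):
        """For all n1+n2 <= 12 (tie-free), the implementation equals the
        exhaustive enumeration oracle exactly."""
        vals = data.draw(
            st.lists(
                st.floats(min_value=-100, max_value=100,
                          allow_nan=False, allow_infinity=False),
                min_size=n1 + n2, max_size=n1 + n2, unique=True,
            )
        )
        a, b = vals[:n1], vals[n1:]
        u_oracle, p_oracle = mann_whitney_enumeration(a, b)
        res = compare_conditions(a, b)
        assert res.u == pytest.approx(u_oracle)
        assert res.p_two_sided == pytest.approx(p_oracle, rel=1e-9)

    def test_u_bounds_and_cohort_size(self, rng):
        """At the working cohort size (400 vs 400) a genuine shift is
        detected and U stays within [0, n1*n2]."""
        a = rng.lognormal(math.log(120), 0.4, 400)
        b = rng.lognormal(math.log(220), 0.4, 400)
        res = compare_conditions(a, b)
        assert 0 <= res.u <= 400 * 400
        assert res.p_two_sided < 1e-6
        assert res.effect_size > 0.2  # first group smaller

    def test_power_monotone_in_effect_size(self):
        """Detection rate at fixed n is non-decreasing in the S-phase
        gamma-H2AX fold."""
        rng = np.random.default_rng(17)
        rates = []
        for fold in (1.2, 2.0, 4.0):
            hits = 0
            for _ in range(40):
                a = rng.lognormal(math.log(120), 0.4, 100)
                b = rng.lognormal(math.log(120 * fold), 0.4, 100)
                if compare_conditions(a, b).p_two_sided < 0.05:
                    hits += 1
            rates.append(hits / 40)
        assert rates == sorted(rates)


class TestSummaries:
    def test_hand_oracle(self):
        df = pd.DataFrame(
            {"stage": ["S"] * 3, "mean_gh2ax": [10.0, 20.0, 30.0],
             "condition": "x"}
        )
        out = quantify.summarize_by_stage(df, "gh2ax", gates=("S",))
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["mean"] == pytest.approx(20.0)
        assert row["median"] == pytest.approx(20.0)
        assert row["sd"] == pytest.approx(10.0)

    def test_whole_population_is_weighted_union_of_stages(self, staged_default):
        """The whole-population mean equals the cell-count-weighted mean of
        the disjoint per-stage gates exactly (conservation)."""
        df = staged_default.assign(condition="c")
        gates = ("G1", "S", "G2", "M_pro_meta", "M_ana_telo")
        out = quantify.summarize_by_stage(df, "gh2ax", gates=("all",) + gates)
        whole = out[out["gate"] == "all"].iloc[0]
        parts = out[out["gate"] != "all"]
        weighted = (parts["mean"] * parts["n"]).sum() / parts["n"].sum()
        assert parts["n"].sum() == whole["n"]
        assert weighted == pytest.approx(whole["mean"], rel=1e-12)

    def test_empty_gate_flagged(self):
        df = pd.DataFrame({"stage": ["G1"], "mean_gh2ax": [1.0],
                           "condition": "x"})
        out = quantify.summarize_by_stage(df, "gh2ax", gates=("mid_S",))
        assert out.iloc[0]["n"] == 0
        assert out.iloc[0]["flag"] == "empty_gate"

    def test_unknown_gate_rejected(self, staged_default):
        with pytest.raises(KeyError, match="unknown gate"):
            gate_mask(staged_default, "prophase")


class TestDynamicRange:
    @staticmethod
    def _two_conditions(fold, seed=51, n=6000):
        base = SimulationParams(n_cells=n, markers=("gh2ax", "edu"), seed=seed)
        treated = dataclasses.replace(
            base, drug_effects=DrugEffects(s_phase_gh2ax_fold=fold),
            seed=seed + 1,
        )
        both = pd.concat(
            [
                simulate_features(base, meta={"condition": "untreated"}),
                simulate_features(treated, meta={"condition": "treated"}),
            ],
            ignore_index=True,
        )
        staged = staging.stage_cells(both, available_markers=("dapi", "edu"))
        return staging.bin_s_phase(staged)

    def test_identity_when_treated_equals_reference(self, staged_default):
        df = staged_default.assign(condition="c")
        out = quantify.dynamic_range(df, "c", "c", "gh2ax")
        assert np.allclose(out["fold_change"], 1.0)

    def test_matches_mixture_oracle_and_gate_ordering(self):
        """With an S-only fold f and S fraction w, the whole-population fold
        is 1 + w(f-1) (closed-form mixture oracle) while mid-S reads ~f;
        gates order mid-S >= S > whole for any S-restricted effect."""
        fold = 4.0
        staged = self._two_conditions(fold)
        out = quantify.dynamic_range(
            staged, "treated", "untreated", "gh2ax", gates=("all", "S", "mid_S")
        ).set_index("gate")["fold_change"]
        w = 0.35  # default S fraction
        assert out["all"] == pytest.approx(1 + w * (fold - 1), rel=0.06)
        assert out["mid_S"] == pytest.approx(fold, rel=0.08)
        assert out["mid_S"] > out["all"]
        assert out["S"] > out["all"]

    def test_undefined_reference_flagged(self):
        df = pd.DataFrame(
            {"stage": ["G1", "G1"], "mean_gh2ax": [0.0, 1.0],
             "condition": ["ref", "treat"]}
        )
        out = quantify.dynamic_range(df, "treat", "ref", "gh2ax", gates=("all",))
        assert out.iloc[0]["flag"] == "undefined_reference"
        assert np.isnan(out.iloc[0]["fold_change"])


class TestTrappingProfile:
    @staticmethod
    def _staged(trapping_fold, pre_extraction=True, seed=61):
        params = SimulationParams(
            n_cells=6000, markers=("gh2ax", "edu", "parp1"),
            drug_effects=DrugEffects(trapping_fold=trapping_fold,
                                     s_phase_gh2ax_fold=5.0),
            pre_extraction=pre_extraction, seed=seed,
        )
        feats = simulate_features(params)
        return staging.stage_cells(feats, available_markers=("dapi", "edu"))

    def test_uniform_trapping_flat_while_damage_s_restricted(self):
        staged = self._staged(trapping_fold=3.0)
        profile = quantify.trapping_profile(staged)
        assert profile.max_pairwise_fold <= 1.2
        assert profile.kruskal_p > 0.01
        dmg = profile.damage_per_stage.set_index("gate")["mean"]
        assert dmg["S"] / dmg["G1"] >= 2.0

    def test_no_drug_equals_baseline(self):
        staged = self._staged(trapping_fold=1.0)
        profile = quantify.trapping_profile(staged)
        # lognormal(median 250, sigma .35) mean, small measurement inflation
        expected = 250 * math.exp(0.35**2 / 2)
        for _, row in profile.per_stage.iterrows():
            assert row["mean"] == pytest.approx(expected, rel=0.05)

    def test_rejects_non_preextracted_input(self):
        staged = self._staged(trapping_fold=3.0, pre_extraction=False)
        with pytest.raises(ValueError, match="pre-extract"):
            quantify.trapping_profile(staged)


class TestCondensationMetrics:
    def test_stronger_condensation_orders_mean_dapi_and_area(self):
        frames = []
        for name, cf in (("combo", 0.4), ("single", 0.6)):
            params = SimulationParams(n_cells=4000, condensation_factor=cf,
                                      seed=71)
            feats = simulate_features(params, meta={"condition": name})
            frames.append(staging.stage_cells(feats))
        staged = pd.concat(frames, ignore_index=True)
        out = quantify.condensation_metrics(staged).set_index("condition")
        assert out.loc["combo", "mean_dapi_mean"] > out.loc["single", "mean_dapi_mean"]
        assert out.loc["combo", "area_mean"] < out.loc["single", "area_mean"]

    def test_identical_conditions_not_significant(self):
        params = SimulationParams(n_cells=4000, seed=72)
        a = staging.stage_cells(simulate_features(params, meta={"condition": "a"}))
        b = staging.stage_cells(
            simulate_features(params, meta={"condition": "b"}, seed=73)
        )
        mit_a = a[gate_mask(a, "mitotic")]["mean_dapi"]
        mit_b = b[gate_mask(b, "mitotic")]["mean_dapi"]
        assert compare_conditions(mit_a, mit_b).p_two_sided > 0.05

    def test_no_mitotic_cells_flagged(self):
        df = pd.DataFrame({"stage": ["G1"], "mean_dapi": [300.0],
                           "area": [250], "condition": "x"})
        out = quantify.condensation_metrics(df)
        assert out.iloc[0]["flag"] == "no_mitotic_cells"


class TestHelpers:
    def test_bh_adjustment_monotone(self):
        p = [0.001, 0.01, 0.02, 0.8]
        q = quantify.adjust_pvalues(p)
        assert (q >= p).all()
        assert q[-1] <= 1.0

    def test_jitter_only_for_plotting(self):
        vals = np.array([0, 1, 1, 2, 5])
        out = quantify.jittered_column(vals, amount=0.25, seed=1)
        assert np.abs(out - vals).max() <= 0.25
        assert not np.array_equal(out, vals)
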