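"""Core competitive-equilibrium solver and its derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raswiring import (
    EffectorDef,
    GtpScenario,
    OdeOracleConfig,
    TissueProfile,
    active_ras_total,
    aggregate_by_class,
    competition_check,
    complex_percentages,
    isoform_split,
    ode_equilibrium,
    rank_changes,
    rank_entities,
    solve_equilibrium,
    solve_tissue,
)

from conftest import random_panel, single_ligand_complex


def _eff(name="E", kd_um=1.0, class_id=1):
    return EffectorDef(name, class_id, kd_um)


class TestActiveRas:
    def test_uniform_load_is_linear(self):
        p = TissueProfile("t", {}, {"HRAS": 100, "KRAS": 300, "NRAS": 100})
        assert active_ras_total(p, GtpScenario.uniform(0.2)) == pytest.approx(100.0)

    def test_mutant_scenario_arithmetic(self):
        p = TissueProfile("t", {}, {"HRAS": 100, "KRAS": 300, "NRAS": 100})
        sc = GtpScenario({"HRAS": 0.2, "KRAS": 1.0, "NRAS": 0.2})
        assert active_ras_total(p, sc) == pytest.approx(340.0)

    def test_zero_ras(self):
        p = TissueProfile("t", {}, {"HRAS": 0, "KRAS": 0, "NRAS": 0})
        assert active_ras_total(p, GtpScenario.uniform(0.9)) == 0.0

    def test_missing_isoform_named_in_error(self):
        p = TissueProfile("t", {}, {"HRAS": 100, "KRAS": 300})
        with pytest.raises(KeyError, match="NRAS"):
            active_ras_total(p, GtpScenario.baseline())


class TestSolveEquilibrium:
    def test_single_ligand_matches_quadratic_closed_form(self):
        state = solve_equilibrium(100.0, [(_eff(kd_um=0.1), 100.0)])
        expected = single_ligand_complex(100.0, 100.0, 100.0)
        assert state.complexes_nm["E"] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(38.19660112501051, rel=1e-10)

    def test_empty_panel(self):
        state = solve_equilibrium(100.0, [])
        assert state.free_ras == 100.0
        assert state.total_complexes == 0.0

    def test_two_effector_competition(self):
        # E1 high affinity (50 nM), E2 low (5000 nM), both 200 nM
        state = solve_equilibrium(
            100.0, [(_eff("E1", 0.05), 200.0), (_eff("E2", 5.0), 200.0)])
        oracle = ode_equilibrium(
            100.0, [(_eff("E1", 0.05), 200.0), (_eff("E2", 5.0), 200.0)])
        for name in ("E1", "E2"):
            assert state.complexes_nm[name] == pytest.approx(oracle[name], rel=1e-6)
        assert state.free_ras == pytest.approx(27.7, abs=0.1)
        assert state.complexes_nm["E1"] == pytest.approx(71.2, abs=0.2)
        assert state.complexes_nm["E2"] == pytest.approx(1.1, abs=0.1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_ode_oracle_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        active, effs = random_panel(rng)
        state = solve_equilibrium(active, effs)
        oracle = ode_equilibrium(active, effs, OdeOracleConfig(k_on=1.0))
        for (e, _), _ in zip(effs, range(len(effs))):
            assert state.complexes_nm[e.name] == pytest.approx(
                oracle[e.name], rel=1e-6, abs=1e-9)

    def test_oracle_kon_invariance(self):
        rng = np.random.default_rng(7)
        active, effs = random_panel(rng, n_max=4)
        for k_on in (0.01, 10.0):
            oracle = ode_equilibrium(active, effs, OdeOracleConfig(k_on=k_on))
            state = solve_equilibrium(active, effs)
            for e, _ in effs:
                assert state.complexes_nm[e.name] == pytest.approx(
                    oracle[e.name], rel=1e-6, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_positivity(self, seed):
        rng = np.random.default_rng(seed)
        active, effs = random_panel(rng)
        state = solve_equilibrium(active, effs)
        scale = max(active, 1.0)
        assert abs(state.free_ras + state.total_complexes - active) <= 1e-9 * scale
        for e, tot in effs:
            assert state.free_effectors[e.name] >= 0
            assert state.complexes_nm[e.name] >= 0
            assert (abs(state.free_effectors[e.name] + state.complexes_nm[e.name] - tot)
                    <= 1e-9 * max(tot, 1.0))
        if state.total_complexes > 0:
            assert sum(state.complexes_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_active_ras_gives_all_zero_state(self):
        state = solve_equilibrium(0.0, [(_eff(), 100.0)])
        assert state.free_ras == 0.0
        assert state.complexes_nm["E"] == 0.0

    def test_zero_abundance_effector_retained_with_zero_complex(self):
        state = solve_equilibrium(100.0, [(_eff("A", 1.0), 100.0), (_eff("B", 1.0), 0.0)])
        assert state.complexes_nm["B"] == 0.0
        assert state.free_effectors["B"] == 0.0

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_equilibrium(math.nan, [])
        with pytest.raises(ValueError):
            solve_equilibrium(100.0, [(_eff(), math.inf)])

    def test_competition_leaves_every_effector_partially_free(self):
        # sum of effectors exceeds active Ras -> nobody saturates
        effs = [(_eff(f"E{i}", 0.05 * (i + 1)), 100.0) for i in range(5)]
        state = solve_equilibrium(100.0, effs)
        for e, _ in effs:
            assert state.free_effectors[e.name] > 0

    def test_monotone_in_kd_and_abundance(self):
        base = [(_eff("A", 1.0), 100.0), (_eff("B", 2.0), 100.0)]
        s0 = solve_equilibrium(100.0, base)
        s_hi_kd = solve_equilibrium(100.0, [(_eff("A", 2.0), 100.0), base[1]])
        assert s_hi_kd.complexes_nm["A"] < s0.complexes_nm["A"]
        assert s_hi_kd.complexes_nm["B"] > s0.complexes_nm["B"]
        s_hi_ab = solve_equilibrium(100.0, [(_eff("A", 1.0), 200.0), base[1]])
        assert s_hi_ab.complexes_nm["A"] > s0.complexes_nm["A"]

    def test_saturation_at_high_ras(self):
        effs = [(_eff("big", 0.1), 500.0), (_eff("small", 5.0), 10.0)]
        low = solve_equilibrium(100.0, effs)
        high = solve_equilibrium(1e7, effs)
        assert high.complexes_nm["big"] == pytest.approx(500.0, rel=1e-3)
        assert high.complexes_nm["small"] == pytest.approx(10.0, rel=1e-3)
        # the dominant complex loses share as competition relaxes
        assert high.complexes_pct["big"] < low.complexes_pct["big"]
        assert high.complexes_pct["small"] > low.complexes_pct["small"]


class TestDerivedQuantities:
    def test_percentage_normalization(self):
        assert complex_percentages({"A": 30.0, "B": 70.0}) == pytest.approx(
            {"A": 30.0, "B": 70.0})
        assert complex_percentages({"A": 5.0}) == {"A": 100.0}
        assert complex_percentages({"A": 0.0, "B": 0.0}) == {}

    def test_isoform_split_proportions(self):
        p = TissueProfile("t", {}, {"HRAS": 100, "KRAS": 300, "NRAS": 100})
        split = isoform_split(p, GtpScenario.baseline())
        assert split == pytest.approx({"HRAS": 0.2, "KRAS": 0.6, "NRAS": 0.2})

    def test_isoform_split_single_isoform(self):
        p = TissueProfile("t", {}, {"HRAS": 0, "KRAS": 300, "NRAS": 0})
        split = isoform_split(p, GtpScenario.baseline())
        assert split["KRAS"] == 1.0

    def test_isoform_split_pancreas_like_equal_thirds(self):
        p = TissueProfile("pancreas", {}, {"HRAS": 150, "KRAS": 150, "NRAS": 150})
        split = isoform_split(p, GtpScenario.baseline())
        for iso in split:
            assert split[iso] == pytest.approx(1 / 3)

    def test_isoform_split_zero_active_errors(self):
        p = TissueProfile("t", {}, {"HRAS": 0, "KRAS": 0, "NRAS": 0})
        with pytest.raises(ValueError):
            isoform_split(p, GtpScenario.baseline())

    def test_aggregate_by_class(self):
        panel = [_eff("ARAF", 0.07, 1), _eff("BRAF", 0.2, 1), _eff("MLLT4", 3.0, 4)]
        out = aggregate_by_class({"ARAF": 10.0, "BRAF": 5.0, "MLLT4": 2.0}, panel)
        assert out == {1: 15.0, 4: 2.0}
        assert aggregate_by_class({}, panel) == {}
        with pytest.raises(KeyError):
            aggregate_by_class({"XXX": 1.0}, panel)

    def test_aggregate_matches_brute_force_on_solved_tissue(self, panel, profile, baseline):
        state = solve_tissue(profile, baseline, panel)
        agg = aggregate_by_class(state.complexes_pct, panel)
        for class_id in range(1, 13):
            brute = sum(state.complexes_pct[e.name] for e in panel
                        if e.class_id == class_id)
            assert agg.get(class_id, 0.0) == pytest.approx(brute)
        assert sum(agg.values()) == pytest.approx(sum(state.complexes_pct.values()))

    def test_ranking_and_ties(self):
        assert rank_entities({"A": 50, "B": 30, "C": 20}) == [
            ("A", 50, 1), ("B", 30, 2), ("C", 20, 3)]
        assert rank_entities({"B": 40, "A": 40}) == [("A", 40, 1), ("B", 40, 2)]

    def test_rank_change_from_peer_movement(self):
        # C's value is unchanged but B overtakes it -> C down-ranks
        ref = {"A": 50.0, "B": 20.0, "C": 30.0}
        new = {"A": 50.0, "B": 35.0, "C": 30.0}
        changes = rank_changes(ref, new)
        # brute-force pairwise check
        def brute_rank(d, x):
            return 1 + sum(1 for k, v in d.items()
                           if v > d[x] or (v == d[x] and k < x))
        for name in ref:
            assert changes[name] == brute_rank(ref, name) - brute_rank(new, name)
        assert changes["C"] == -1
        assert changes["B"] == 1

    def test_competition_check(self):
        p = TissueProfile("t", {"E1": 300.0, "E2": 200.0},
                          {"HRAS": 100, "KRAS": 300, "NRAS": 100})
        chk = competition_check(p, GtpScenario.baseline())
        assert chk.competitive and chk.sum_effectors_nm == 500.0
        p_small = TissueProfile("t", {"E1": 60.0, "E2": 40.0}, p.ras_totals)
        chk_hi = competition_check(
            p_small, GtpScenario({"HRAS": 0.2, "KRAS": 1.0, "NRAS": 0.2}))
        assert not chk_hi.competitive and chk_hi.active_ras_nm == pytest.approx(340.0)
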