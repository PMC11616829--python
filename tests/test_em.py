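import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trioemvs.em import (
    build_penalty,
    em_iteration,
    estep_common,
    estep_rare,
    estep_region,
    estep_region_scalar,
    final_selection,
    observed_objective,
    run_daem,
    update_pis,
)
from trioemvs.likelihood import build_contrasts
from trioemvs.priors import AnnealingSchedule, ConvergenceSpec, PriorSpec
from trioemvs.variants import build_layout

from .conftest import random_families, toy_panel
from .oracles import (
    enumerate_common,
    enumerate_region,
    numeric_pi1,
    numeric_pi3,
    observed_log_posterior,
)


def prior(**kw):
    return PriorSpec(**kw).resolve_hypers(3, 2, 5)


class TestEStepCommon:
    def test_equal_spike_slab_collapses_to_tempered_mixing_weight(self):
        p = PriorSpec(v0=0.399999, v1=0.4)  # effectively equal variances
        for t in (0.3, 1.0):
            got = estep_common(np.array([0.7]), 0.2, p, t)
            want = 0.2**t / (0.2**t + 0.8**t)
            assert got[0] == pytest.approx(want, rel=1e-4)

    def test_symmetric_evidence_gives_half_at_any_temperature(self):
        # choose beta so that the two weighted densities coincide exactly
        p = prior(v0=0.01, v1=0.4)
        # solve pi N(b;v1) = (1-pi) N(b;v0) for pi given b
        b = 0.25
        from .oracles import norm_pdf

        pi1 = norm_pdf(b, 0.01) / (norm_pdf(b, 0.01) + norm_pdf(b, 0.4))
        for t in (0.1, 0.5, 1.0):
            assert estep_common(np.array([b]), pi1, p, t)[0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scalar_bayes_oracle(self):
        p = prior(v0=0.01, v1=0.4)
        got = estep_common(np.array([0.3]), 0.1, p, 1.0)[0]
        assert got == pytest.approx(enumerate_common(0.3, 0.1, 0.01, 0.4), rel=1e-12)

    def test_huge_coefficients_do_not_underflow(self):
        p = prior(v0=1e-4, v1=0.4)
        got = estep_common(np.array([50.0, -50.0, 0.0]), 0.5, p, 1.0)
        assert np.all(np.isfinite(got))
        # at beta = 0 the spike dominates but not absolutely: the posterior
        # odds are the density ratio sqrt(v1/v0) ~ 63, i.e. p ~ 0.016
        assert got[0] == 1.0 and got[1] == 1.0 and got[2] == pytest.approx(
            1 / (1 + np.sqrt(0.4 / 1e-4)), rel=1e-6
        )

    def test_annealing_sharpens_toward_the_favored_state(self):
        p = prior(v0=0.01, v1=0.4)
        ts = [0.1, 0.3, 0.6, 1.0]
        ps = [estep_common(np.array([0.5]), 0.3, p, t)[0] for t in ts]
        assert all(b > a for a, b in zip(ps, ps[1:]))  # slab favored: increases with t
        qs = [estep_common(np.array([0.0]), 0.3, p, t)[0] for t in ts]
        assert all(b < a for a, b in zip(qs, qs[1:]))  # spike favored: decreases


class TestEStepRare:
    def test_equal_variances_give_pi3(self):
        p = PriorSpec(v2=0.499999, v3=0.5)
        assert estep_rare(np.array([0.3]), 0.05, p, 1.0)[0] == pytest.approx(0.05, rel=1e-4)

    def test_large_effects_always_enter_the_slab(self):
        p = prior(v2=0.01, v3=0.5)
        assert estep_rare(np.array([8.0]), 0.05, p, 1.0)[0] == pytest.approx(1.0)

    def test_matches_scalar_bayes_oracle(self):
        p = prior(v2=0.01, v3=0.5)
        got = estep_rare(np.array([0.2]), 0.05, p, 1.0)[0]
        _, q = enumerate_region(np.array([0.2]), 0.5, 0.05, 0.01, 0.5)
        assert got == pytest.approx(q[0], rel=1e-12)


class TestEStepRegion:
    def test_equal_variances_collapse_to_pi2(self):
        p = PriorSpec(v2=0.499999, v3=0.5)
        variants, layout = toy_panel(1, [3])
        g = estep_region(np.array([0.1, -0.4, 0.2]), layout, 0.3, 0.05, p, 1.0)
        assert g[0] == pytest.approx(0.3, rel=1e-4)

    def test_null_coefficients_favor_exclusion(self):
        p = prior(v2=0.01, v3=0.5)
        variants, layout = toy_panel(1, [3])
        g = estep_region(np.zeros(3), layout, 0.3, 0.05, p, 1.0)
        assert g[0] < 0.3

    def test_matches_enumeration_oracle_two_members(self):
        p = prior(v2=0.01, v3=0.5)
        got = estep_region_scalar(np.array([0.4, 0.0]), 0.1, 0.1, p, 1.0)
        g, _ = enumerate_region(np.array([0.4, 0.0]), 0.1, 0.1, 0.01, 0.5)
        assert got == pytest.approx(g, rel=1e-12)

    def test_vectorized_regions_agree_with_scalar(self, rng):
        p = prior(v2=0.005, v3=0.5)
        variants, layout = toy_panel(2, [2, 3])
        alpha = rng.normal(scale=0.4, size=5)
        g = estep_region(alpha, layout, 0.2, 0.1, p, 0.7)
        assert g[0] == pytest.approx(estep_region_scalar(alpha[:2], 0.2, 0.1, p, 0.7))
        assert g[1] == pytest.approx(estep_region_scalar(alpha[2:], 0.2, 0.1, p, 0.7))


class TestPenaltyAndPiUpdates:
    def test_penalty_interpolates_between_spike_and_slab(self):
        p = prior(v0=0.01, v1=0.4, v2=0.02, v3=0.5)
        d = build_penalty(np.array([0.0, 1.0, 0.5]), np.array([0.25]), p)
        assert d[0] == pytest.approx(1 / 0.01)
        assert d[1] == pytest.approx(1 / 0.4)
        assert d[2] == pytest.approx(0.5 / 0.01 + 0.5 / 0.4)
        assert d[3] == pytest.approx(0.75 / 0.02 + 0.25 / 0.5)
        assert np.all(d >= 1 / 0.5)

    def test_printed_update_formulas_at_default_hyperparameters(self):
        variants, layout = toy_panel(3, [2])
        p = PriorSpec().resolve_hypers(layout.S, layout.R, layout.L)
        # one region with g = 1, members q = (1, 0): pi3 = 1/3
        pi1, pi2, pi3 = update_pis(
            np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0]), np.array([1.0]), layout, p, (0.5,) * 3
        )
        assert pi1 == pytest.approx(2 / 5)  # sum p / (2S - 1), S = 3
        assert pi2 == pytest.approx(1.0)  # single region, g = 1: sum g / (2R - 1) = 1
        assert pi3 == pytest.approx(1 / 3)  # (1*1) / (L + 1*2 - 1), L = 2

    def test_two_region_mixing_weight(self):
        variants, layout = toy_panel(2, [1, 1])
        p = PriorSpec().resolve_hypers(layout.S, layout.R, layout.L)
        _, pi2, _ = update_pis(
            np.zeros(2), np.array([0.5, 0.5]), np.array([0.5, 0.5]), layout, p, (0.5,) * 3
        )
        assert pi2 == pytest.approx(1 / 3)  # (0.5 + 0.5) / (2*2 - 1)

    def test_generalized_updates_match_numeric_maximization(self, rng):
        variants, layout = toy_panel(4, [2, 3])
        for a1, b1 in [(1.0, 4.0), (2.0, 7.0)]:
            p = PriorSpec(a=(a1, 1.0, a1), b=(b1, None, b1)).resolve_hypers(4, 2, 5)
            p_s = rng.random(4)
            q = rng.random(5)
            g = rng.random(2)
            pi1, _, pi3 = update_pis(p_s, q, g, layout, p, (0.5,) * 3)
            assert pi1 == pytest.approx(numeric_pi1(p_s, 4, a1, b1), abs=1e-8)
            assert pi3 == pytest.approx(
                numeric_pi3([q[:2], q[2:]], g, 5, a1, p.b[2]), abs=1e-8
            )

    def test_empty_classes_hold_weights_fixed(self):
        variants, layout = toy_panel(2, [])
        p = PriorSpec().resolve_hypers(2, 0, 0)
        pi1, pi2, pi3 = update_pis(np.array([1.0, 0.0]), np.array([]), np.array([]), layout, p, (0.5, 0.4, 0.3))
        assert pi2 == 0.4 and pi3 == 0.3
        assert pi1 == pytest.approx(1 / 3)


class TestObservedObjectiveAndEM:
    def test_identical_states_have_zero_difference(self, small_instance, rng):
        contrasts, layout, variants = small_instance
        p = PriorSpec().resolve_hypers(layout.S, layout.R, layout.L)
        w = rng.normal(scale=0.3, size=layout.p)
        a = observed_objective(contrasts, layout, w, (0.2, 0.2, 0.1), p)
        b = observed_objective(contrasts, layout, w.copy(), (0.2, 0.2, 0.1), p)
        assert a == b

    def test_matches_direct_marginalization_oracle(self, rng):
        variants, layout = toy_panel(1, [2])
        fams = random_families(rng, 20, layout.p)
        contrasts = build_contrasts(fams).reorder_columns(layout.column_order)
        p = PriorSpec(v0=0.01, v2=0.02).resolve_hypers(layout.S, layout.R, layout.L)
        hyper = tuple((a, b) for a, b in zip(p.a, p.b))
        states = [
            (rng.normal(scale=0.4, size=3), (0.3, 0.2, 0.15)),
            (rng.normal(scale=0.4, size=3), (0.5, 0.4, 0.3)),
        ]
        vals, oracles = [], []
        for w, pis in states:
            vals.append(observed_objective(contrasts, layout, w, pis, p))
            oracles.append(
                observed_log_posterior(
                    contrasts.X.astype(float), 1, [[0, 1]], w, pis, (p.v0, p.v1, p.v2, p.v3), hyper
                )
            )
        # equal up to one additive constant: differences must agree
        assert vals[0] - vals[1] == pytest.approx(oracles[0] - oracles[1], abs=1e-9)

    def test_em_never_decreases_objective_at_unit_temperature(self, rng):
        for rep in range(5):
            variants, layout = toy_panel(2, [2, 2])
            fams = random_families(rng, 30, layout.p)
            contrasts = build_contrasts(fams).reorder_columns(layout.column_order)
            p = PriorSpec(v0=0.01, v2=0.01).resolve_hypers(layout.S, layout.R, layout.L)
            w = np.full(layout.p, 0.5)
            pis = p.pi_means
            prev = observed_objective(contrasts, layout, w, pis, p)
            for _ in range(15):
                w, pis, *_ = em_iteration(contrasts, layout, w, pis, p, 1.0)
                cur = observed_objective(contrasts, layout, w, pis, p)
                assert cur >= prev - 1e-9
                prev = cur


class TestRunDaem:
    def test_uninformative_data_selects_nothing(self, rng):
        variants, layout = toy_panel(2, [2])
        z = np.zeros(layout.p, np.int8)
        from trioemvs.likelihood import TrioFamily

        fams = [TrioFamily(f"F{i}", z, np.stack([z, z, z])) for i in range(10)]
        contrasts = build_contrasts(fams).reorder_columns(layout.column_order)
        state = run_daem(contrasts, layout, PriorSpec(), keep_trace=False)
        assert state.converged
        assert np.all(np.abs(state.omega) < 1e-6)
        sel = final_selection(state, layout, variants)
        assert not sel.selected_variants

    def test_duplicating_every_family_preserves_selection(self, rng):
        variants, layout = toy_panel(2, [2])
        fams = random_families(rng, 60, layout.p)
        C1 = build_contrasts(fams).reorder_columns(layout.column_order)
        C2 = build_contrasts(fams + fams).reorder_columns(layout.column_order)
        p = PriorSpec()
        s1 = run_daem(C1, layout, p, keep_trace=False)
        s2 = run_daem(C2, layout, p, keep_trace=False)
        sel1 = final_selection(s1, layout, variants).selected_variants
        sel2 = final_selection(s2, layout, variants).selected_variants
        assert sel1 == sel2

    def test_trace_records_iterations_and_temperatures(self, small_instance):
        contrasts, layout, variants = small_instance
        state = run_daem(contrasts, layout, PriorSpec(), keep_trace=True)
        assert list(state.trace.columns) == ["k", "t", "objective", "pi1", "pi2", "pi3"]
        assert (state.trace["t"].iloc[:10].to_numpy() == np.arange(1, 11) / 10).all()
        assert state.trace["k"].is_monotonic_increasing

    def test_iteration_cap_returns_unconverged_state(self, small_instance):
        contrasts, layout, variants = small_instance
        state = run_daem(
            contrasts, layout, PriorSpec(), conv=ConvergenceSpec(epsilon=1e-300, max_iter=3),
            keep_trace=False,
        )
        assert not state.converged and state.k == 13  # 10 anneal sweeps + 3 capped

    def test_selection_equivariant_under_within_region_permutation(self, rng):
        variants, layout = toy_panel(1, [3])
        fams = random_families(rng, 80, layout.p)
        C = build_contrasts(fams).reorder_columns(layout.column_order)
        s = run_daem(C, layout, PriorSpec(), keep_trace=False)
        # permute the three rare variants of the single region
        perm = np.array([0, 3, 1, 2])  # common col 0 fixed; rare rotated
        Cp = C.reorder_columns(perm)
        sp = run_daem(Cp, layout, PriorSpec(), keep_trace=False)
        assert sp.alpha == pytest.approx(s.alpha[[2, 0, 1]], abs=1e-6)
        assert sp.q_rj == pytest.approx(s.q_rj[[2, 0, 1]], abs=1e-6)
        assert sp.g_r == pytest.approx(s.g_r, abs=1e-8)


class TestFinalSelection:
    def _state(self, layout, p_s, q_rj, g_r):
        from trioemvs.em import ModelState

        return ModelState(
            beta=np.full(layout.S, 0.5),
            alpha=np.full(layout.L, 0.2),
            pis=(0.1, 0.1, 0.1),
            p_s=np.asarray(p_s, float),
            q_rj=np.asarray(q_rj, float),
            g_r=np.asarray(g_r, float),
            t=1.0,
            k=1,
            converged=True,
            objective=0.0,
        )

    def test_common_thresholding(self):
        variants, layout = toy_panel(2, [1])
        state = self._state(layout, [0.9, 0.1], [1.0], [0.4])
        sel = final_selection(state, layout, variants, threshold=0.5)
        assert sel.selected_variants == {"C0"}

    def test_excluded_region_suppresses_members(self):
        variants, layout = toy_panel(0, [1])
        state = self._state(layout, [], [1.0], [0.4])
        sel = final_selection(state, layout, variants, threshold=0.5)
        assert not sel.selected_variants  # joint 0.4 * 1.0 < 0.5
        assert not sel.selected_regions

    def test_threshold_extremes_are_monotone(self):
        variants, layout = toy_panel(2, [2])
        state = self._state(layout, [0.9, 0.1], [0.7, 1.0], [1.0])
        all_sel = final_selection(state, layout, variants, threshold=0.0).selected_variants
        assert all_sel == {v.id for v in variants}
        only_sure = final_selection(state, layout, variants, threshold=1.0).selected_variants
        assert only_sure == {"R1_1"}  # joint probability exactly 1.0

    def test_region_selected_when_member_selected(self):
        variants, layout = toy_panel(0, [1, 1])
        state = self._state(layout, [], [1.0, 0.1], [0.6, 0.1])
        sel = final_selection(state, layout, variants, threshold=0.5)
        assert sel.selected_regions == {1}
        regions = sel.regions.set_index("region_id")
        assert bool(regions.loc[1, "selected"]) and not bool(regions.loc[2, "selected"])
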