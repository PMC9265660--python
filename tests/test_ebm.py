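import numpy as np
import pandas as pd
import pytest

from ebmdea import (
    TechnologySpec,
    affinity_epsilon_weights,
    decompose_efficiency,
    score_panel,
    solve_ebm,
)

from oracles import multiplier_radial_score


def _radial_spec(**kw):
    return TechnologySpec(epsilon_x=0.0, **kw)


class TestAffinityWeights:
    def test_proportional_columns_give_radial_limit(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [5.0, 10.0]])
        eps, w = affinity_epsilon_weights(X)
        assert eps == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_single_input_degenerate(self):
        eps, w = affinity_epsilon_weights(np.array([[1.0], [2.0], [3.0]]))
        assert eps == 0.0 and w.tolist() == [1.0]

    def test_matches_eigen_oracle_on_4x2_matrix(self):
        X = np.array([[1.0, 3.0], [2.0, 1.0], [4.0, 5.0], [3.0, 2.0]])
        # hand-built affinity matrix and eigen decomposition
        c = np.log(X[:, 0] / X[:, 1])
        div = np.mean(np.abs(c - c.mean())) / (c.max() - c.min())
        S = np.array([[1.0, 1 - 2 * div], [1 - 2 * div, 1.0]])
        lam, vec = np.linalg.eigh(S)
        eps_expect = (2 - lam[-1]) / (2 - 1)
        w_expect = np.abs(vec[:, -1]) / np.abs(vec[:, -1]).sum()
        eps, w = affinity_epsilon_weights(X)
        assert eps == pytest.approx(eps_expect, abs=1e-12)
        np.testing.assert_allclose(w, w_expect, atol=1e-12)

    def test_epsilon_in_unit_interval_weights_simplex(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            X = rng.uniform(0.5, 9.0, size=(7, 4))
            eps, w = affinity_epsilon_weights(X)
            assert 0.0 <= eps <= 1.0
            assert np.all(w >= 0) and w.sum() == pytest.approx(1.0)


class TestSolveEbm:
    # two units: A(x=2,y=4) on the frontier, B(x=4,y=4) halfway
    X2 = np.array([[2.0], [4.0]])
    Y2 = np.array([[4.0], [4.0]])
    B0 = np.zeros((2, 0))

    def test_radial_score_of_dominated_unit(self):
        res = solve_ebm(1, self.X2, self.Y2, self.B0, _radial_spec())
        assert res.score == pytest.approx(0.5, abs=1e-9)
        assert res.status == "optimal"

    def test_super_efficiency_of_frontier_unit(self):
        res = solve_ebm(0, self.X2, self.Y2, self.B0,
                        _radial_spec(super_efficiency=True))
        # reference shrinks to B: lambda = 1 forced, theta = 4/2
        assert res.score == pytest.approx(2.0, abs=1e-9)

    def test_self_domination_scores_one(self):
        X = np.array([[3.0, 1.0], [3.0, 1.0], [5.0, 9.0]])
        Y = np.array([[2.0], [2.0], [1.0]])
        res = solve_ebm(0, X, Y, np.zeros((3, 0)), _radial_spec())
        assert res.score == pytest.approx(1.0, abs=1e-7)

    def test_score_bounded_by_theta_when_slacks_active(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 10, size=(8, 3))
        Y = rng.uniform(1, 10, size=(8, 1))
        spec = TechnologySpec(epsilon_x=0.5)
        for k in range(8):
            res = solve_ebm(k, X, Y, np.zeros((8, 0)), spec)
            assert res.score <= res.theta + 1e-9
            assert np.all(res.slacks >= 0) and np.all(res.lambdas >= 0)
            assert res.score <= 1 + 1e-7


class TestOracleEquivalence:
    """Envelopment EBM at eps=0 vs the independent multiplier-form LP."""

    @pytest.mark.parametrize("vrs", [False, True])
    @pytest.mark.parametrize("super_eff", [False, True])
    def test_radial_reduction_matches_dual_form(self, vrs, super_eff):
        rng = np.random.default_rng(42)
        spec = _radial_spec(rts="vrs" if vrs else "crs",
                            super_efficiency=super_eff)
        for trial in range(6):
            n = rng.integers(3, 9)
            m = rng.integers(1, 4)
            s = rng.integers(1, 3)
            X = rng.uniform(1, 10, size=(n, m))
            Y = rng.uniform(1, 10, size=(n, s))
            for k in range(n):
                expected = multiplier_radial_score(k, X, Y, vrs=vrs,
                                                   super_eff=super_eff)
                got = solve_ebm(k, X, Y, np.zeros((n, 0)), spec)
                if expected is None:
                    assert got.status == "infeasible"
                else:
                    assert got.score == pytest.approx(expected, abs=1e-6), \
                        f"trial {trial}, unit {k}"


class TestScorePanelProperties:
    def test_singleton_unit_scores_one(self, random_panel_factory):
        panel = random_panel_factory(J=1, T=3, seed=2)
        tab = score_panel(panel, _radial_spec(frontier="contemporaneous"))
        np.testing.assert_allclose(tab.to_numpy(), 1.0, atol=1e-9)

    def test_toy_fixture_hand_scores(self, toy_panel):
        tab = score_panel(toy_panel, _radial_spec())
        expected = np.array([1.0, 0.5, 0.25, 0.25])
        for t in toy_panel.periods:
            np.testing.assert_allclose(tab[t].to_numpy(), expected, atol=1e-9)

    def test_static_panel_frontier_invariance(self, toy_panel):
        tab = score_panel(toy_panel, TechnologySpec(epsilon_x=0.4))
        np.testing.assert_allclose(tab[2000], tab[2001], atol=1e-9)

    def test_units_invariance(self, random_panel_factory):
        panel = random_panel_factory(J=6, T=2, m=2, seed=9)
        spec = TechnologySpec(epsilon_x=0.3)
        base = score_panel(panel, spec)
        X2 = panel.X.copy()
        X2[:, :, 0] *= 37.5
        scaled = score_panel(panel.replace_inputs(X2), spec)
        np.testing.assert_allclose(base.to_numpy(), scaled.to_numpy(),
                                   atol=1e-7)

    def test_monotonicity_in_own_input(self, random_panel_factory):
        panel = random_panel_factory(J=6, T=1, m=2, seed=13)
        spec = TechnologySpec(epsilon_x=0.4)
        base = score_panel(panel, spec)
        X2 = panel.X.copy()
        X2[2, 0, :] *= 1.5
        worse = score_panel(panel.replace_inputs(X2), spec)
        assert worse.iloc[2, 0] <= base.iloc[2, 0] + 1e-9

    def test_global_leq_contemporaneous(self, random_panel_factory):
        panel = random_panel_factory(J=5, T=3, m=2, seed=21)
        for eps in (0.0, 0.5):
            spec_g = TechnologySpec(epsilon_x=eps, frontier="global")
            spec_c = TechnologySpec(epsilon_x=eps, frontier="contemporaneous")
            g = score_panel(panel, spec_g).to_numpy()
            c = score_panel(panel, spec_c).to_numpy()
            assert np.all(g <= c + 1e-7)

    def test_batching_equals_looped_single_calls(self, random_panel_factory):
        panel = random_panel_factory(J=5, T=3, m=2, seed=33)
        spec = TechnologySpec(epsilon_x=0.2)
        tab = score_panel(panel, spec)
        labels, Xo, Yo, Bo, *_ = panel.flatten()
        for kk, (j, t) in enumerate(labels):
            res = solve_ebm(kk, Xo, Yo, Bo, spec)
            assert tab.iloc[j, t] == pytest.approx(res.score, abs=1e-9)

    def test_bad_output_modes_run_and_cap_scores(self, random_panel_factory):
        panel = random_panel_factory(J=6, T=2, m=2, seed=44, with_bad=True)
        for mode in ("as-input", "weak-disposability"):
            spec = TechnologySpec(epsilon_x=0.3, bad_output_mode=mode)
            tab = score_panel(panel, spec)
            assert np.all(tab.to_numpy() <= 1 + 1e-7)
            assert np.all(tab.to_numpy() > 0)


class TestDecomposeEfficiency:
    def test_direct_ratio_and_identity(self):
        assert decompose_efficiency(0.5, 1.0) == pytest.approx(0.5)
        assert decompose_efficiency(0.73, 0.73) == pytest.approx(1.0)

    def test_rejects_nonpositive_pte(self):
        with pytest.raises(ValueError):
            decompose_efficiency(0.5, 0.0)

    def test_scale_efficiency_at_most_one_non_super(self, random_panel_factory):
        panel = random_panel_factory(J=7, T=2, m=2, seed=55)
        cte = score_panel(panel, _radial_spec(rts="crs"))
        pte = score_panel(panel, _radial_spec(rts="vrs"))
        se = decompose_efficiency(cte, pte)
        assert np.all(se.to_numpy() <= 1 + 1e-7)
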