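"""Fixed points, stability, continuation, existence windows."""

import numpy as np
import pytest

from cleaverep import (
    CatalyticParams,
    ChemostatParams,
    approx_bounds,
    continuation_in_beta,
    cooperative_fixed_point,
    existence_window,
    fixed_point_census,
    integrate,
    monomer_steady_state,
    noncooperative_fixed_points,
    random_steady_state,
    survival_condition,
)
from cleaverep.model_core import CatalyticState, symmetric_rhs_array


class TestRandomModel:
    def test_analytic_steady_state_values(self, chem):
        fp = random_steady_state(chem)
        st = fp.state
        assert fp.kind == "surviving"
        assert st.c == pytest.approx(0.25)
        assert st.M == pytest.approx(16.666666666, rel=1e-9)
        assert chem.m0 - st.M - st.M_bar == pytest.approx(monomer_steady_state(chem))
        assert monomer_steady_state(chem) == pytest.approx(66.66666666, rel=1e-8)

    def test_mean_length_consistency(self, chem):
        """<L> = M/c = delta/beta0 = r*m*/delta holds to machine precision."""
        st = random_steady_state(chem).state
        L = st.M / st.c
        assert L == pytest.approx(chem.delta / chem.beta0, rel=1e-12)
        assert L == pytest.approx(
            chem.r * monomer_steady_state(chem) / chem.delta, rel=1e-12
        )

    def test_extinct_below_feed_threshold(self):
        chem = ChemostatParams(m0=50.0)
        assert random_steady_state(chem).kind == "extinct"
        assert not survival_condition(chem)

    @pytest.mark.parametrize(
        "beta0, m0, r, delta, expected",
        [
            (0.015, 100.0, 1.0, 1.0, True),
            (0.015, 50.0, 1.0, 1.0, False),
            (0.01, 100.0, 1.0, 1.0, False),  # boundary is strict
        ],
    )
    def test_survival_condition(self, beta0, m0, r, delta, expected):
        chem = ChemostatParams(m0=m0, delta=delta, r=r, beta0=beta0)
        assert survival_condition(chem) is expected
        # algebraic agreement with m0 > m*
        assert expected == (m0 > monomer_steady_state(chem))


class TestNoncooperativePoints:
    def test_both_reduce_to_random_model(self, p10):
        pa, pb = noncooperative_fixed_points(p10)
        assert pa.kind == "pure_a" and pb.kind == "pure_b"
        for fp in (pa, pb):
            assert fp.monomer(p10) == pytest.approx(66.6666666, rel=1e-8)
            assert fp.stable

    def test_zero_rhs_exactly(self, p10):
        pa, pb = noncooperative_fixed_points(p10)
        for fp in (pa, pb):
            st = fp.state
            x = np.array([st.a, st.b, st.aL, st.aR, st.M])
            assert np.max(np.abs(symmetric_rhs_array(x, p10))) < 1e-12 * st.M

    def test_extinct_regime_flagged(self):
        p = CatalyticParams(chemostat=ChemostatParams(m0=50.0), beta=10.0)
        pa, pb = noncooperative_fixed_points(p)
        assert pa.kind == pb.kind == "extinct"


class TestCooperativePoint:
    def test_exists_only_at_intermediate_beta(self, p6, p10, p18):
        assert cooperative_fixed_point(p6) is None
        assert cooperative_fixed_point(p18) is None
        fp = cooperative_fixed_point(p10)
        assert fp is not None and fp.stable
        st = fp.state
        assert min(st.a, st.b, st.aL, st.aR) > 0
        assert st.a == pytest.approx(st.a_bar) and st.b == pytest.approx(st.b_bar)

    def test_census_regime_structure(self, census10, p6, p18):
        kinds10 = {fp.kind for fp in census10}
        assert {"extinct", "pure_a", "pure_b", "cooperative", "saddle"} <= kinds10
        for p in (p6, p18):
            kinds = {fp.kind for fp in fixed_point_census(p)}
            assert "cooperative" not in kinds
            assert {"pure_a", "pure_b"} <= kinds

    def test_ode_oracle_returns_to_fixed_point(self, p10, coop10):
        """A 1%-perturbed state relaxes back, coordinate-wise to 1e-6."""
        target = coop10.state.to_array()
        start = CatalyticState.from_array(target * 1.01)
        traj = integrate(start, p10, t_end=400.0, n_samples=2)
        end = traj.states[-1]
        assert np.max(np.abs(end - target) / np.maximum(np.abs(target), 1e-9)) < 1e-6

    def test_saddles_have_unstable_directions(self, census10, coop10):
        saddles = [fp for fp in census10 if fp.kind == "saddle"]
        assert saddles
        for s in saddles:
            assert s.eigenvalues.real.max() > 0
            assert not np.allclose(s.state.to_array(), coop10.state.to_array())

    def test_symmetry_breaking_stability_reported(self, coop10):
        assert coop10.full_eigenvalues is not None
        assert coop10.full_stable  # stable against asymmetric perturbations too


class TestContinuation:
    def test_stable_branch_monotone_and_bounded(self, p10, chem):
        df = continuation_in_beta(p10, np.linspace(7.5, 16.5, 13))
        stable = df[df.branch == "stable"].sort_values("beta")
        assert len(stable) >= 10
        ratios = stable.ratio.to_numpy()
        assert np.all(np.diff(ratios) > 0)  # monotone increasing with beta
        assert np.all(ratios < 0.5)  # cooperative monomer level below m*/2
        saddle = df[df.branch == "saddle"]
        assert len(saddle) > 0
        assert not saddle.stable.any()


class TestExistenceWindow:
    def test_window_brackets_the_three_regimes(self, p10):
        w = existence_window(p10)
        assert not w.empty
        assert 10.0 in w
        assert 6.0 not in w and 18.0 not in w

    def test_window_inside_inflated_asymptotic_bounds(self, p10):
        w = existence_window(p10)
        ab = approx_bounds(p10)
        assert ab.beta_lo / 2 < w.beta_min < ab.beta_lo * 2
        assert ab.beta_hi / 2 < w.beta_max < ab.beta_hi * 2

    def test_window_converges_to_bounds_at_small_beta0(self):
        p = CatalyticParams(
            chemostat=ChemostatParams(m0=2e4, beta0=1e-3), beta=10.0, lam=2.0
        )
        w = existence_window(p, beta_search_range=(1.0, 750.0))
        assert w.beta_min == pytest.approx(8.0, rel=0.05)
        assert w.beta_max == pytest.approx(250.0, rel=0.05)

    def test_no_window_without_elongation_asymmetry(self, chem):
        p = CatalyticParams(chemostat=chem, beta=10.0, lam=1.0)
        assert existence_window(p, beta_search_range=(1.0, 50.0)).empty

    def test_window_edges_independent_of_feed(self):
        edges = []
        for m0 in (100.0, 200.0):
            p = CatalyticParams(
                chemostat=ChemostatParams(m0=m0, beta0=0.05), beta=5.5, lam=2.0
            )
            w = existence_window(p, beta_search_range=(1.0, 50.0))
            assert not w.empty
            edges.append((w.beta_min, w.beta_max))
        assert edges[0] == pytest.approx(edges[1], rel=1e-3)


class TestApproxBounds:
    @pytest.mark.parametrize(
        "lam, beta0, expected_lo, expected_hi, empty",
        [
            (2.0, 0.015, 8.0, 16.6667, False),
            (3.0, 0.015, 12.0, 33.3333, False),
            (2.0, 0.0625, 8.0, 4.0, True),  # bounds cross
            (1.0, 0.015, 4.0, 0.0, True),  # no asymmetry, no window
        ],
    )
    def test_formula_values(self, lam, beta0, expected_lo, expected_hi, empty):
        p = CatalyticParams(
            chemostat=ChemostatParams(beta0=beta0), beta=10.0, lam=lam
        )
        ab = approx_bounds(p)
        assert ab.beta_lo == pytest.approx(expected_lo, rel=1e-4)
        assert ab.beta_hi == pytest.approx(expected_hi, abs=1e-4)
        assert ab.empty is empty
        assert ab.ratio_max == 0.5
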