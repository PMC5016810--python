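"""Pair-approximation chain dynamics, mean-field baseline and classification."""

import numpy as np
import pytest

from patchchain.epdm import (
    ChainParams,
    EPDMState,
    classify_coexistence,
    initial_state,
    integrate_to_steady_state,
    mean_field_baseline,
    rhs,
    rhs_pairs,
)

FIG2 = dict(c=1.0, e=0.05, mu=0.025)


class TestChainParams:
    def test_default_dispersal_scales_with_rank(self):
        assert ChainParams.symmetric(2).dispersal == ("neighbour", "global")
        assert ChainParams.symmetric(3).dispersal == (
            "neighbour", "cluster", "global"
        )

    @pytest.mark.parametrize("kwargs", [
        dict(n_levels=4, c=(1,) * 4, e=(0.05,) * 4, mu=(0.025,) * 3),
        dict(n_levels=2, c=(1,), e=(0.05, 0.05), mu=(0.025,)),
        dict(n_levels=2, c=(1, 1), e=(0.05, -0.05), mu=(0.025,)),
        dict(n_levels=2, c=(1, 1), e=(0.05, 0.05), mu=(0.025,),
             dispersal=("teleport", "global")),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ChainParams(**kwargs)


class TestMeanFieldBaseline:
    def test_levins_equilibrium(self):
        res = mean_field_baseline(ChainParams.symmetric(1), 1.0)
        assert res.occupancies[0] == pytest.approx(0.95, abs=1e-12)

    def test_prey_predator_closed_form(self, params2):
        # simultaneous stationarity: rho1 solves the quadratic
        # rho1^2 - 0.925 rho1 - 0.003125 = 0, and rho12 = rho1 - 0.125
        res = mean_field_baseline(params2, 1.0)
        rho1_expected = (0.925 + np.sqrt(0.925**2 + 4 * 0.003125)) / 2
        assert res.occupancies[0] == pytest.approx(rho1_expected, abs=1e-12)
        assert res.occupancies[0] - res.occupancies[1] == pytest.approx(
            0.125, abs=1e-12
        )

    def test_tritrophic_equilibrium_satisfies_stationarity(self, params3):
        res = mean_field_baseline(params3, 1.0)
        # predator stationarity gap (e1+e2+e3+mu21+mu32)/c3 = 0.2
        assert res.occupancies[1] - res.occupancies[2] == pytest.approx(
            0.2, abs=1e-10
        )
        # verify by substitution into the all-global vector field
        pg = params3.with_dispersal("global", "global", "global")
        y = np.concatenate([res.occupancies, [0.0, 0.0]])
        assert np.abs(rhs(y, pg, 1.0, 1.0)[:3]).max() < 1e-10

    def test_below_persistence_threshold(self):
        res = mean_field_baseline(ChainParams.symmetric(1), 0.04)
        assert res.coexistence == ()

    def test_predation_lowers_prey_occupancy(self, params2):
        prey_only = mean_field_baseline(ChainParams.symmetric(1), 1.0)
        both = mean_field_baseline(params2, 1.0)
        assert both.occupancies[0] < prey_only.occupancies[0]


class TestGlobalLimit:
    """All-global EPDM trajectories land on the mean-field equilibrium."""

    def test_bitrophic(self, params2):
        pg = params2.with_dispersal("global", "global")
        num = integrate_to_steady_state(pg, 1.0, 1.0, rtol=1e-12, atol=1e-13)
        ana = mean_field_baseline(params2, 1.0)
        np.testing.assert_allclose(
            num.raw_occupancies[:2], ana.raw_occupancies[:2], atol=1e-7
        )

    def test_tritrophic(self, params3):
        pg = params3.with_dispersal("global", "global", "global")
        num = integrate_to_steady_state(pg, 1.0, 1.0, rtol=1e-12, atol=1e-13)
        ana = mean_field_baseline(params3, 1.0)
        np.testing.assert_allclose(
            num.raw_occupancies, ana.raw_occupancies, atol=1e-7
        )


class TestVectorField:
    def test_predator_free_state_absorbing(self, params2):
        y = np.array([0.3, 0.0, 0.0, 0.12, 0.1])
        d = rhs(y, params2, 0.5, 0.6)
        assert d[1] == 0.0 and d[2] == 0.0
        # prey block equals the single-species pair-approximation model
        p1 = ChainParams.symmetric(1)
        d_single = rhs(y, p1, 0.5, 0.6)
        np.testing.assert_allclose(d[[0, 3, 4]], d_single[[0, 3, 4]])

    def test_pair_flux_identity_along_trajectory(self, params2):
        # singlet colonization flux c1*rho1*q_s/1 == pair flux c1*rho10
        res = integrate_to_steady_state(
            params2, 0.6, 0.7, keep_trajectory=True
        )
        t, ys = res.trajectory
        for y in ys.T[:: max(1, len(t) // 25)]:
            rho1, rho11, rho1u = y[0], y[3], y[4]
            singlet = params2.c[0] * rho1 * (1 - (rho11 + rho1u) / rho1)
            pairflux = params2.c[0] * (rho1 - rho11 - rho1u)
            assert singlet == pytest.approx(pairflux, abs=1e-8)

    def test_tritrophic_nests_bitrophic_when_top_absent(self, params3):
        y = np.array([0.4, 0.2, 0.0, 0.2, 0.1])
        d3 = rhs(y, params3, 0.6, 0.8)
        # same system with consumer colonization scaled by q_ss
        p2q = ChainParams(2, (1.0, 1.0), (0.05, 0.05), (0.025,),
                          ("neighbour", "cluster"))
        d2 = rhs(y, p2q, 0.6, 0.8)
        np.testing.assert_allclose(d3[:2], d2[:2])
        assert d3[2] == 0.0

    def test_zero_connectivity_kills_consumer(self, params3):
        res = integrate_to_steady_state(params3, 0.4, 0.0)
        assert res.coexistence in ((), (1,))
        assert res.occupancies[1] == 0.0

    def test_pure_decay_when_no_pairs_to_colonize(self):
        # rho10 = 0 and rho0u = 0: both pair derivatives are pure decay
        d11, d1u = rhs_pairs(
            rho1=0.3, rho11=0.2, rho1u=0.1, c1=1.0, m1=0.05, s=0.5, q_ss=0.8
        )
        assert d11 == pytest.approx(-2 * 0.05 * 0.2)
        assert d1u == pytest.approx(-0.05 * 0.1)


class TestIntegration:
    def test_mortality_exceeding_colonization_extinguishes(self):
        p = ChainParams.symmetric(2, c=0.04, e=0.05, mu=0.025)
        res = integrate_to_steady_state(p, 0.8, 0.8)
        assert res.coexistence == ()

    def test_fig2_corner_coexistence(self, params2):
        res = integrate_to_steady_state(params2, 0.9, 0.9)
        assert res.coexistence == (1, 2)

    def test_invariants_along_random_trajectories(self, params3, rng):
        # nesting, habitat bound and pair bookkeeping hold pointwise
        for _ in range(10):
            s = rng.uniform(0.15, 0.95)
            q_lo = max(0.0, (2 * s - 1) / s)
            q = rng.uniform(q_lo, 1.0)
            c = rng.uniform(0.5, 2.0)
            p = ChainParams.symmetric(3, c=c, e=0.05, mu=0.025)
            res = integrate_to_steady_state(p, s, q, keep_trajectory=True)
            _, ys = res.trajectory
            tol = 1e-6
            rho1, rho12, rho23, rho11, rho1u = ys
            assert (rho1 <= s + tol).all()
            assert (rho12 <= rho1 + tol).all()
            assert (rho23 <= rho12 + tol).all()
            assert (rho23 >= -tol).all()
            rho10 = rho1 - rho11 - rho1u
            rho0u = s * (1 - q) - rho1u
            assert (rho10 >= -tol).all() and (rho10 <= 1 + tol).all()
            assert (rho0u >= -tol).all() and (rho0u <= 1 + tol).all()

    def test_monotone_in_availability_and_connectivity(self, params2):
        occ = {
            (s, q): integrate_to_steady_state(params2, s, q).occupancies[0]
            for (s, q) in [(0.3, 0.6), (0.5, 0.6), (0.5, 0.9)]
        }
        assert occ[(0.5, 0.6)] >= occ[(0.3, 0.6)]
        assert occ[(0.5, 0.9)] >= occ[(0.5, 0.6)]

    def test_domain_validation(self, params2):
        with pytest.raises(ValueError):
            integrate_to_steady_state(params2, 0.0, 0.5)
        with pytest.raises(ValueError):
            integrate_to_steady_state(params2, 0.5, 1.5)


class TestInitialState:
    def test_default_seeding_nested_and_scaled(self, params3):
        st = initial_state(params3, s=0.5, q_ss=0.8)
        assert st.rho1 == pytest.approx(0.05)
        assert st.rho1 > st.rho12 > st.rho23 > 0
        assert st.rho11 == pytest.approx(0.1**2 * 0.8 * 0.5)
        assert st.rho1u == pytest.approx(0.1 * 0.5 * 0.2)

    def test_rejects_nonincreasing_densities(self, params3):
        with pytest.raises(ValueError):
            initial_state(params3, 0.5, 0.8, theta=(0.05, 0.1, 0.01))


class TestClassification:
    @pytest.mark.parametrize("occ,expected", [
        ((0.5, 0.2, 0.05), (1, 2, 3)),
        ((0.5, 0.00005, 0.0), (1,)),
        ((0.0, 0.0, 0.0), ()),
        ((0.5, 0.2, 0.00009), (1, 2)),
    ])
    def test_thresholding(self, occ, expected):
        assert classify_coexistence(occ) == expected

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            classify_coexistence((0.1, 0.3, 0.0))

    def test_conditional_density_view(self):
        st = EPDMState(rho1=0.4, rho11=0.2, rho1u=0.1)
        q11, qu1 = st.conditional_densities()
        assert (q11, qu1) == (pytest.approx(0.5), pytest.approx(0.25))
        assert q11 + qu1 <= 1.0
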