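import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_likelihood
from karyoevo.ctmc_model import (
    RateParams,
    StateSpace,
    TransitionKernel,
    build_rate_matrix,
    build_state_space,
    classify_move,
    log_likelihood,
    transition_probs,
)
from karyoevo.karyodata import Phylogeny
from karyoevo.synthetic_data import simulate_tree


class TestStateSpace:
    @pytest.mark.parametrize(
        "k_min,k_max,scs,size",
        [(4, 21, True, 36), (4, 21, False, 18), (5, 5, True, 2)],
    )
    def test_sizes(self, k_min, k_max, scs, size):
        assert build_state_space(k_min, k_max, scs).size == size

    def test_k_min_below_one_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(0, 5, True)

    def test_index_roundtrip(self):
        space = build_state_space(3, 11, True)
        for i in range(space.size):
            k, s = space.state(i)
            assert space.index(k, s) == i

    def test_tip_index_bounds_error_names_tip(self):
        space = build_state_space(4, 10, False)
        with pytest.raises(ValueError, match="Eury"):
            space.index_for_tip(3, "XY", tip="Eurysternus")

    def test_xo_maps_to_simple(self):
        space = build_state_space(1, 10, True)
        assert space.index_for_tip(5, "XO") == space.index(5, "simple")


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        space = build_state_space(1, 5, True)
        Q = build_rate_matrix(RateParams(0, 0, 0, 0), space)
        assert np.all(Q == 0)

    def test_hand_enumerated_3x3(self):
        # states k=1,2,3; fission +1 at rate 1, fusion -1 at rate 2,
        # reflecting bounds: no exit below 1 or above 3
        space = build_state_space(1, 3, False)
        Q = build_rate_matrix(RateParams(1.0, 2.0), space)
        expected = np.array(
            [[-1.0, 1.0, 0.0], [2.0, -3.0, 1.0], [0.0, 2.0, -2.0]]
        )
        np.testing.assert_allclose(Q, expected)

    def test_sa_fusion_absent_at_lower_bound(self):
        space = build_state_space(4, 8, True)
        Q = build_rate_matrix(RateParams(0.1, 0.2, 0.3, 0.4), space)
        i = space.index(4, "simple")
        # no (k_min, simple) -> (k_min - 1, neo) move exists; every
        # destination below k_min is outside the space entirely
        offdiag = {j for j in range(space.size) if Q[i, j] > 0}
        assert offdiag == {space.index(5, "simple")}

    def test_scs_moves_wired_correctly(self):
        space = build_state_space(2, 6, True)
        p = RateParams(0.11, 0.23, 0.37, 0.41)
        Q = build_rate_matrix(p, space)
        assert Q[space.index(4, "simple"), space.index(3, "neo")] == p.sa_fusion
        assert Q[space.index(4, "neo"), space.index(4, "simple")] == p.reversion
        assert Q[space.index(4, "neo"), space.index(3, "simple")] == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateParams(-0.1, 0.2)

    @given(
        rates=st.lists(
            st.floats(0, 50, allow_nan=False), min_size=4, max_size=4
        ),
        k_max=st.integers(2, 12),
    )
    @settings(max_examples=250, deadline=None)
    def test_generator_invariants(self, rates, k_max):
        space = build_state_space(1, k_max, True)
        Q = build_rate_matrix(RateParams(*rates), space)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-12


class TestClassifyMove:
    def test_all_four_moves(self):
        space = build_state_space(1, 10, True)
        assert classify_move(space, space.index(9, "simple"),
                             space.index(10, "simple")) == "fission"
        assert classify_move(space, space.index(9, "neo"),
                             space.index(8, "neo")) == "fusion"
        assert classify_move(space, space.index(9, "simple"),
                             space.index(8, "neo")) == "sa_fusion"
        assert classify_move(space, space.index(9, "neo"),
                             space.index(9, "simple")) == "reversion"

    def test_disallowed_move_raises(self):
        space = build_state_space(1, 10, True)
        with pytest.raises(ValueError, match="disallowed"):
            classify_move(space, space.index(9, "simple"),
                          space.index(7, "simple"))


class TestTransitionProbs:
    def _Q(self):
        space = build_state_space(1, 6, True)
        return build_rate_matrix(RateParams(0.5, 0.8, 0.3, 0.6), space)

    def test_t_zero_identity(self):
        Q = self._Q()
        np.testing.assert_allclose(
            transition_probs(Q, 0.0), np.eye(Q.shape[0]), atol=1e-14
        )

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(self._Q(), -0.1)

    def test_rows_sum_to_one(self):
        Q = self._Q()
        for t in (0.01, 0.5, 3.0):
            P = transition_probs(Q, t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() >= 0 and P.max() <= 1

    def test_small_t_taylor(self):
        # P = I + Qt + O(t^2); at t = 1e-4 the quadratic term bounds the error
        Q = self._Q()
        t = 1e-4
        P = transition_probs(Q, t)
        dev = np.max(np.abs(P - (np.eye(Q.shape[0]) + Q * t)))
        bound = np.max(np.abs(Q @ Q)) * t**2
        assert dev < 2 * bound

    def test_large_t_stationary(self):
        # every row converges to the left null vector of Q
        Q = self._Q()
        null = scipy.linalg.null_space(Q.T)
        pi = (null[:, 0] / null[:, 0].sum()).real
        P = transition_probs(Q, 1e4 / 0.3)
        np.testing.assert_allclose(P, np.tile(pi, (Q.shape[0], 1)), atol=1e-8)

    def test_kernel_matches_expm(self):
        Q = self._Q()
        kern = TransitionKernel(Q)
        for t in (0.05, 0.7, 2.4):
            np.testing.assert_allclose(
                kern.probs(t), scipy.linalg.expm(Q * t), atol=1e-9
            )


def _random_instance(rng, scs=None):
    n_tips = int(rng.integers(3, 6))
    tree = simulate_tree(n_tips, 1.0, 0.0, rng)
    scs_mode = bool(rng.integers(2)) if scs is None else scs
    k_max = int(rng.integers(3, 7)) if scs_mode else int(rng.integers(3, 13))
    space = build_state_space(1, k_max, scs_mode)
    params = RateParams(*rng.exponential(0.8, size=4))
    Q = build_rate_matrix(params, space)
    tip_states = {}
    for label in tree.tip_labels:
        k, system = space.state(int(rng.integers(space.size)))
        tip_states[label] = (k, {"simple": "XY", "neo": "neoXY",
                                 "none": "XY"}[system])
    return tree, space, Q, tip_states


class TestLogLikelihood:
    def test_zero_generator_same_state_flat_root(self, three_tip_tree):
        space = build_state_space(1, 6, False)
        Q = np.zeros((space.size, space.size))
        tips = {t: (3, "XY") for t in three_tip_tree.tip_labels}
        ll = log_likelihood(tips, three_tip_tree, Q, space, root_mode="flat")
        assert ll == pytest.approx(np.log(1 / space.size))

    def test_zero_generator_conflicting_tips(self, three_tip_tree):
        space = build_state_space(1, 6, False)
        Q = np.zeros((space.size, space.size))
        tips = {"A": (3, "XY"), "B": (4, "XY"), "C": (3, "XY")}
        assert log_likelihood(tips, three_tip_tree, Q, space) == -np.inf

    def test_tip_outside_bounds_names_tip(self, three_tip_tree):
        space = build_state_space(1, 6, False)
        Q = np.zeros((space.size, space.size))
        tips = {"A": (3, "XY"), "B": (9, "XY"), "C": (3, "XY")}
        with pytest.raises(ValueError, match="'B'"):
            log_likelihood(tips, three_tip_tree, Q, space)

    def test_invariant_to_tip_ordering(self, four_tip_tree, rng):
        space = build_state_space(1, 8, False)
        Q = build_rate_matrix(RateParams(0.4, 0.6), space)
        tips = {"A": (2, "XY"), "B": (5, "XY"), "C": (7, "XY"), "D": (4, "XY")}
        rev = dict(reversed(list(tips.items())))
        assert log_likelihood(tips, four_tip_tree, Q, space) == pytest.approx(
            log_likelihood(rev, four_tip_tree, Q, space)
        )

    @pytest.mark.parametrize("root_mode", ["flat", "fitzjohn", 0])
    def test_matches_brute_force_enumeration(self, root_mode, rng):
        for _ in range(12):
            tree, space, Q, tips = _random_instance(rng)
            ll = log_likelihood(tips, tree, Q, space, root_mode)
            brute = brute_force_likelihood(tips, tree, Q, space, root_mode)
            if brute == 0.0:
                assert ll == -np.inf
            else:
                assert ll == pytest.approx(np.log(brute), abs=1e-10)

    def test_time_rate_scaling_identity(self, rng):
        # doubling all rates and halving branch lengths leaves ll unchanged
        for _ in range(5):
            tree, space, Q, tips = _random_instance(rng)
            ll1 = log_likelihood(tips, tree, Q, space)
            ll2 = log_likelihood(tips, tree.scaled(0.5), 2 * Q, space)
            assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_basic_equals_scs_with_inactive_sa_moves(self, rng):
        # with sa_fusion = reversion = 0 and all tips simple, the neo block
        # is unreachable and the FitzJohn-root likelihoods coincide
        for _ in range(5):
            tree = simulate_tree(int(rng.integers(3, 7)), 1.0, 0.0, rng)
            k_max = 7
            basic = build_state_space(1, k_max, False)
            scs = build_state_space(1, k_max, True)
            d, f = rng.exponential(0.7, size=2)
            Qb = build_rate_matrix(RateParams(d, f), basic)
            Qs = build_rate_matrix(RateParams(d, f, 0.0, 0.0), scs)
            tips = {
                t: (int(rng.integers(1, k_max + 1)), "XY")
                for t in tree.tip_labels
            }
            llb = log_likelihood(tips, tree, Qb, basic, "fitzjohn")
            lls = log_likelihood(tips, tree, Qs, scs, "fitzjohn")
            assert llb == pytest.approx(lls, abs=1e-9)
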