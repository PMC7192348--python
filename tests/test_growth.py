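"""Unit and property tests for the growth process."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comgrow import (
    InvalidParameterError,
    ModelParams,
    community_pmf,
    grow,
    init_seed,
    resolve_beta,
)
from comgrow.growth import add_node

from conftest import nc_distribution


def _state_with_sizes(sizes):
    """Build a growth state whose community sizes are as given (edges
    irrelevant for PMF tests)."""
    state = init_seed(len(sizes))
    node = len(sizes)
    for i, target in enumerate(sizes):
        for _ in range(target - 1):
            state.graph.add_node(node)
            state.communities[i].append(node)
            state.node_birth[node] = node
            state.node_community[node] = i + 1
            node += 1
    return state


class TestInitSeed:
    @pytest.mark.parametrize(
        "k, n_edges", [(1, 0), (3, 3), (5, 10)]
    )
    def test_complete_seed(self, k, n_edges):
        state = init_seed(k)
        assert state.n == k
        assert state.graph.number_of_edges() == n_edges
        assert [len(c) for c in state.communities] == [1] * k
        assert [state.node_community[i] for i in range(k)] == list(range(1, k + 1))

    def test_invalid_k(self):
        with pytest.raises(InvalidParameterError):
            init_seed(0)


class TestResolveBeta:
    def test_policies_on_unequal_sizes(self):
        state = _state_with_sizes([2, 5, 11])
        assert resolve_beta("min_size", state) == 2
        assert resolve_beta("mean_size", state) == 6  # (2+5+11)/3
        assert resolve_beta("max_size", state) == 11

    def test_all_equal(self):
        state = _state_with_sizes([1, 1, 1])
        assert resolve_beta("min_size", state) == 1
        assert resolve_beta("mean_size", state) == 1

    def test_fixed_ignores_sizes(self):
        state = _state_with_sizes([3, 7])
        assert resolve_beta("fixed", state, 0.0) == 0.0
        with pytest.raises(InvalidParameterError):
            resolve_beta("fixed", state, None)


class TestCommunityPMF:
    def test_symmetric_case(self):
        # sizes [2,2], n=4, beta=2: every option gets 1/3 and the literal
        # factor product is (2/6)(2/6)(2/6)
        state = _state_with_sizes([2, 2])
        pmf = community_pmf(state, 2.0)
        np.testing.assert_allclose(pmf.probs, [1 / 3, 1 / 3, 1 / 3])
        assert pmf.p_inverse == pytest.approx(1 / 27)

    def test_beta_zero_blocks_new_communities(self):
        pmf = community_pmf(_state_with_sizes([3, 1, 4]), 0.0)
        assert pmf.p_new == 0.0
        assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_huge_beta_saturates_new(self):
        pmf = community_pmf(_state_with_sizes([1]), 1e9)
        assert pmf.p_new > 0.999

    def test_negative_beta_rejected(self):
        with pytest.raises(InvalidParameterError):
            community_pmf(_state_with_sizes([1, 1]), -0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        sizes=st.lists(st.integers(1, 30), min_size=1, max_size=12),
        beta=st.floats(0, 1e6, allow_nan=False),
        choice=st.sampled_from(["size", "age"]),
    )
    def test_pmf_normalised_and_new_iff_beta_positive(self, sizes, beta, choice):
        pmf = community_pmf(_state_with_sizes(sizes), beta, choice)
        assert np.all(pmf.probs >= 0)
        assert abs(pmf.probs.sum() - 1.0) < 1e-12
        assert (pmf.p_new == 0.0) == (beta == 0.0)

    def test_new_probability_increases_with_beta(self):
        state = _state_with_sizes([4, 2, 3])
        p_new = [community_pmf(state, b).p_new for b in (0, 0.5, 1, 2, 5, 50)]
        assert all(a < b for a, b in zip(p_new, p_new[1:]))

    def test_age_variant_favours_later_communities(self):
        pmf = community_pmf(_state_with_sizes([5, 3, 1]), 2.0, "age")
        existing = pmf.probs[:-1]
        assert all(a < b for a, b in zip(existing, existing[1:]))


class TestAddNode:
    def test_first_node_with_m_equal_k_connects_all_seeds(self):
        params = ModelParams(k=3, m=3, p=0.97, n_target=4, beta_policy="min_size")
        state = grow(params.with_seed(5))
        # only 3 existing nodes, m=3 forces complete attachment
        assert state.graph.degree(3) == 3
        assert all(state.graph.degree(i) == 3 for i in range(3))

    def test_beta_zero_freezes_community_count(self):
        params = ModelParams(
            k=4, m=2, p=0.8, n_target=40, beta_policy="fixed", beta_value=0.0, seed=11
        )
        assert grow(params).n_communities == 4

    def test_single_internal_link_when_p_one(self):
        # m=1, p=1: every joining node's link stays inside its community,
        # so each community's induced subgraph is connected
        import networkx as nx

        params = ModelParams(k=3, m=1, p=1.0, n_target=40, beta_policy="min_size", seed=2)
        state = grow(params)
        for comm in state.communities:
            assert nx.is_connected(state.graph.subgraph(comm))


class TestGrow:
    @pytest.mark.parametrize(
        "k, m, n, expect_edges",
        [(3, 1, 59, 59), (3, 3, 50, 144), (5, 2, 5, 10)],
    )
    def test_edge_count_closed_form(self, k, m, n, expect_edges):
        params = ModelParams(k=k, m=m, p=0.9, n_target=n, beta_policy="min_size", seed=3)
        state = grow(params)
        assert state.n == n
        assert state.graph.number_of_edges() == expect_edges

    def test_n_target_equal_k_returns_bare_seed(self):
        state = grow(ModelParams(k=4, m=2, p=0.5, n_target=4, beta_policy="min_size", seed=0))
        assert state.n == 4 and state.n_communities == 4

    def test_determinism(self):
        params = ModelParams(k=3, m=2, p=0.9, n_target=60, beta_policy="mean_size", seed=42)
        a, b = grow(params), grow(params)
        assert sorted(a.graph.edges()) == sorted(b.graph.edges())
        assert a.communities == b.communities

    def test_degree_floor_and_invariants(self):
        params = ModelParams(k=4, m=3, p=0.7, n_target=80, beta_policy="max_size", seed=9)
        state = grow(params)
        state.check_invariants()
        assert all(state.graph.degree(v) >= 3 for v in range(4, 80))

    def test_oldest_biased_concentrates_on_branch_roots(self):
        # with q=0.9 the community's first member should collect most of
        # its community's internal links
        params = ModelParams(
            k=3, m=1, p=1.0, n_target=59, beta_policy="min_size",
            within_choice="oldest_biased", oldest_q=0.9, seed=7,
        )
        state = grow(params)
        big = max(state.communities, key=len)
        if len(big) > 5:
            root = big[0]
            internal_deg = sum(
                1 for nb in state.graph.neighbors(root) if nb in set(big)
            )
            assert internal_deg > len(big) / 2


class TestMonteCarloMatchesEnumeration:
    def test_nc_frequencies_match_exact_distribution(self):
        """Monte-Carlo N_c frequencies agree with exhaustive trajectory
        enumeration within 3 binomial standard errors (small version; the
        full 1e5-run check lives in the acceptance suite)."""
        k, n, beta, runs = 1, 5, 2.0, 20_000
        exact = nc_distribution(k, n, beta)
        rng = np.random.default_rng(0)
        params = ModelParams(k=k, m=1, p=0.9, n_target=n, beta_policy="fixed", beta_value=beta)
        counts = {}
        for _ in range(runs):
            nc = grow(params, rng=rng).n_communities
            counts[nc] = counts.get(nc, 0) + 1
        assert abs(sum(exact.values()) - 1.0) < 1e-12
        for nc, p_exact in exact.items():
            freq = counts.get(nc, 0) / runs
            se = max(np.sqrt(p_exact * (1 - p_exact) / runs), 1e-9)
            assert abs(freq - p_exact) < 3 * se + 1e-12


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=0, m=1, p=0.5, n_target=10),
            dict(k=3, m=4, p=0.5, n_target=10),
            dict(k=3, m=1, p=1.5, n_target=10),
            dict(k=3, m=1, p=0.5, n_target=2),
            dict(k=3, m=1, p=0.5, n_target=10, beta_policy="fixed"),
            dict(k=3, m=1, p=0.5, n_target=10, beta_policy="fixed", beta_value=-1.0),
            dict(k=3, m=1, p=0.5, n_target=10, beta_policy="bogus"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ModelParams(**kwargs)
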