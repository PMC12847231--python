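import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epelearn import info
from epelearn.abc import (RejectionABC, min_cpe_select, rejection_sample,
                          standardize, summary_moments)
from epelearn.simulators import simulate_gamma_toy


class TestStandardize:
    def test_training_split_maps_to_zero_one(self, rng):
        t = rng.standard_normal((1000, 3)) * [1.0, 5.0, 0.1] + [0, -2, 7]
        moments = summary_moments(t)
        z = standardize(t, moments)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_shift_invariance(self, rng):
        t = rng.standard_normal((100, 2))
        moments = summary_moments(t)
        assert np.allclose(standardize(t + 5.0, (moments[0] + 5.0, moments[1])),
                           standardize(t, moments))

    def test_point_value(self):
        assert standardize(np.array([[4.0]]), (np.array([2.0]), np.array([2.0])))[0, 0] == 1.0

    def test_zero_variance_column_named(self, rng):
        t = np.column_stack([rng.standard_normal(50), np.ones(50)])
        with pytest.raises(ValueError, match="1"):
            summary_moments(t)


class TestRejectionSampling:
    def test_exact_match_ranked_first(self):
        table = np.array([[0.0], [1.0], [2.0], [3.0]])
        params = np.array([[10.0], [11.0], [12.0], [13.0]])
        post = rejection_sample(np.array([0.2]), table, params, accept_count=2)
        # distances after standardization preserve the ranking 0.0 < 1.0 < ...
        assert post.params[:, 0].tolist() == [10.0, 11.0]
        assert post.distances[0] < post.distances[1]

    def test_accept_all_returns_whole_table(self, rng):
        t = rng.standard_normal((50, 2))
        theta = rng.standard_normal((50, 1))
        post = rejection_sample(rng.standard_normal(2), t, theta, accept_count=50)
        assert sorted(post.indices.tolist()) == list(range(50))

    def test_ties_broken_by_row_index(self):
        # symmetric table: all four rows are exactly equidistant from 0
        t = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        theta = np.arange(4.0)[:, None]
        post = rejection_sample(np.array([0.0]), t, theta, accept_count=3)
        assert post.indices.tolist() == [0, 1, 2]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40))
    def test_matches_brute_force_oracle(self, seed, s):
        """Accepted rows are exactly the s smallest full-sort distances."""
        r = np.random.default_rng(seed)
        m = r.integers(s, 200)
        t = np.round(r.standard_normal((m, 2)), 1)  # rounding forces ties
        theta = r.standard_normal((m, 1))
        abc = RejectionABC(accept_count=s).fit(t, theta)
        obs = r.standard_normal(2)
        post = abc.sample(obs)
        z = standardize(t, abc.moments_)
        zo = standardize(obs, abc.moments_)[0]
        d = np.sqrt(np.sum((z - zo) ** 2, axis=1))
        expected = np.lexsort((np.arange(m), d))[:s]
        assert post.indices.tolist() == expected.tolist()

    def test_pipeline_deterministic(self, rng):
        t = rng.standard_normal((500, 3))
        theta = rng.standard_normal((500, 1))
        abc = RejectionABC(accept_count=20).fit(t, theta)
        obs = rng.standard_normal(3)
        assert np.array_equal(abc.sample(obs).indices, abc.sample(obs).indices)

    def test_accept_count_validated(self, rng):
        with pytest.raises(ValueError):
            RejectionABC(accept_count=100).fit(rng.standard_normal((50, 1)),
                                               rng.standard_normal(50))

    def test_sufficient_statistic_recovers_closed_form_posterior(self, session_rng):
        """With a sufficient summary and s/m -> 0, accepted draws approach
        the closed-form conjugate posterior."""
        from scipy import stats

        a, b, n = 1.5, 1.0, 4
        table = simulate_gamma_toy(a, b, n, 200_000, session_rng)
        t_obs = 0.8
        post = rejection_sample(np.array([t_obs]), table.summaries, table.params,
                                accept_count=1000)
        alpha, beta = a + n / 2, b + n * t_obs / 2
        ks = stats.kstest(post.params[:, 0], stats.gamma(a=alpha, scale=1 / beta).cdf)
        assert ks.statistic < 0.05


class TestMinCpeSelection:
    def test_unsurprising_data_discards_sufficient_statistic(self, session_rng):
        # observed t = 0.3: the posterior Gamma(3.5, 1.6) has *higher* entropy
        # than the Gamma(1.5, 1) prior, so greedy CPE selection returns nothing
        table = simulate_gamma_toy(1.5, 1.0, 4, 50_000, session_rng)
        selected = min_cpe_select(np.array([0.3]), table.summaries, table.params,
                                  accept_count=1000)
        assert selected == []

    def test_surprising_data_selects_sufficient_statistic(self, session_rng):
        # observed t = 3: posterior Gamma(3.5, 7) entropy ~ -0.003 << 1.36
        table = simulate_gamma_toy(1.5, 1.0, 4, 50_000, session_rng)
        selected = min_cpe_select(np.array([3.0]), table.summaries, table.params,
                                  accept_count=1000)
        assert selected == [0]

    def test_distractor_not_systematically_selected(self, session_rng):
        table = simulate_gamma_toy(1.5, 1.0, 4, 20_000, session_rng)
        cands = np.column_stack([table.summaries[:, 0],
                                 session_rng.random(table.m)])
        hits = 0
        for _ in range(10):
            selected = min_cpe_select(np.array([3.0, session_rng.random()]),
                                      cands, table.params, accept_count=500,
                                      candidate_names=["t", "noise"])
            if selected == ["t"]:
                hits += 1
        assert hits >= 9

    def test_requires_candidates(self, rng):
        with pytest.raises(ValueError):
            min_cpe_select(np.array([]), np.empty((10, 0)), rng.standard_normal(10))


def test_posterior_samples_hdf5_roundtrip(rng, tmp_path):
    from epelearn.abc import load_posterior_samples, save_posterior_samples

    t = rng.standard_normal((200, 2))
    theta = rng.standard_normal((200, 1))
    sampler = RejectionABC(accept_count=10).fit(t, theta)
    posts = sampler.sample(rng.standard_normal((3, 2)))
    path = tmp_path / "posts.h5"
    save_posterior_samples(posts, path)
    back = load_posterior_samples(path)
    assert len(back) == 3
    for a, b in zip(posts, back):
        assert np.array_equal(a.params, b.params)
        assert np.allclose(a.distances, b.distances)
        assert b.provenance == "abc"
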