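import numpy as np
import pytest
from scipy import integrate

from epelearn import info
from epelearn.mdn import (MDNCompressor, MixtureParams, mdn_log_prob,
                          mdn_sample, scaled_beta_log_prob)
from epelearn.simulators import simulate_benchmark


def _gaussian_mixture(logits, loc, log_scale):
    return MixtureParams("gaussian", logits=np.atleast_2d(logits),
                         loc=np.asarray(loc, dtype=float).reshape(1, -1, 1),
                         log_scale=np.asarray(log_scale, dtype=float).reshape(1, -1, 1))


class TestMixtureLogProb:
    def test_single_standard_component(self):
        mix = _gaussian_mixture([0.0], [0.0], [0.0])
        assert mdn_log_prob(mix, np.array([0.0]))[0] == pytest.approx(-0.9189385, abs=1e-6)

    def test_identical_components_collapse(self):
        single = _gaussian_mixture([0.0], [0.7], [-0.2])
        double = _gaussian_mixture([3.1, -2.2], [0.7, 0.7], [-0.2, -0.2])
        theta = np.array([0.3])
        assert mdn_log_prob(double, theta)[0] == pytest.approx(
            mdn_log_prob(single, theta)[0])

    def test_normalization_by_quadrature(self, rng):
        mix = _gaussian_mixture(rng.standard_normal(3), rng.standard_normal(3),
                                0.3 * rng.standard_normal(3))
        total, _ = integrate.quad(
            lambda th: np.exp(mdn_log_prob(mix, np.array([th]))[0]), -15, 15)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestScaledBeta:
    @pytest.mark.parametrize("shapes, bounds, theta, expected", [
        ((1.0, 1.0), (0.0, 10.0), 4.2, np.log(0.1)),   # uniform on (0, 10)
        ((2.0, 2.0), (0.0, 1.0), 0.5, np.log(1.5)),    # Beta(2,2) peak
    ])
    def test_values(self, shapes, bounds, theta, expected):
        assert scaled_beta_log_prob(shapes, bounds, theta) == pytest.approx(expected)

    def test_boundary_is_minus_infinity(self):
        assert scaled_beta_log_prob((2.0, 2.0), (0.0, 1.0), 0.0) == -np.inf
        mix = MixtureParams("scaled_beta", logits=np.zeros((1, 1)),
                            log_alpha=np.zeros((1, 1, 1)), log_beta=np.zeros((1, 1, 1)),
                            support=(0.0, 10.0))
        assert mix.log_prob(np.array([[11.0]]))[0] == -np.inf


class TestSampling:
    def test_single_gaussian_moments(self, rng):
        mix = _gaussian_mixture([0.0], [0.0], [0.0])
        draws = mdn_sample(mix, 100_000, rng)
        assert draws.mean() == pytest.approx(0.0, abs=0.02)
        assert draws.var() == pytest.approx(1.0, rel=0.02)

    def test_degenerate_logits_select_one_component(self, rng):
        mix = _gaussian_mixture([50.0, -50.0], [5.0, -5.0], [-3.0, -3.0])
        draws = mdn_sample(mix, 1000, rng)
        assert np.all(draws > 4.0)

    def test_scaled_beta_uniform_mean(self, rng):
        mix = MixtureParams("scaled_beta", logits=np.zeros((1, 1)),
                            log_alpha=np.zeros((1, 1, 1)), log_beta=np.zeros((1, 1, 1)),
                            support=(0.0, 10.0))
        draws = mix.sample(50_000, rng)
        assert draws.mean() == pytest.approx(5.0, abs=0.1)


@pytest.fixture(scope="module")
def small_fit(session_rng):
    train = simulate_benchmark(10, 8000, session_rng)
    val = simulate_benchmark(10, 1000, session_rng)
    est = MDNCompressor(compressor="set_mlp", output_dim=1, n_components=2,
                        batch_size=512, max_epochs=15, random_state=11)
    est.fit(train.payloads, train.params,
            validation_data=(val.payloads, val.params))
    return est, train, val


class TestTraining:

    def test_loss_decreases_below_prior_entropy(self, small_fit):
        est, _, _ = small_fit
        # information is extracted: validation EPE drops below 1/2 ln(2 pi e)
        assert est.best_val_loss_ < info.normal_entropy(1.0) - 0.1
        # and cannot beat the likelihood bound from the full-data posterior
        assert est.best_val_loss_ > 1.0

    def test_training_loss_equals_epe_estimate(self, small_fit):
        """The mini-batch loss is exactly the Monte Carlo EPE of the model."""
        est, train, _ = small_fit
        batch = train.payloads[:256]
        theta = train.params[:256]
        loss = float(est._loss_tensor(est._batch(batch), theta).data)
        epe = info.epe_estimate(
            lambda th, t: est.log_prob(batch, theta), theta,
            est.transform(batch), vectorized=True)
        assert loss == pytest.approx(epe.value, abs=1e-10)

    def test_summaries_deterministic_and_permutation_invariant(self, small_fit, rng):
        est, _, val = small_fit
        t1 = est.transform(val.payloads[:50])
        t2 = est.transform(val.payloads[:50])
        assert np.array_equal(t1, t2)
        permuted = val.payloads[:50][:, rng.permutation(10)]
        assert np.allclose(est.transform(permuted), t1)

    def test_learned_summary_respects_sign_flip_symmetry(self, small_fit):
        # the likelihood is invariant under z1 -> -z1; a trained summary
        # should be (nearly) invariant under the same flip
        est, _, val = small_fit
        z = val.payloads[:200].copy()
        t = est.transform(z)
        z_flipped = z.copy()
        z_flipped[:, :, 0] *= -1
        t_flip = est.transform(z_flipped)
        spread = np.std(t)
        assert np.median(np.abs(t - t_flip)) < 0.2 * spread

    def test_seeded_training_reproducible(self, session_rng):
        train = simulate_benchmark(5, 2000, np.random.default_rng(0))
        kwargs = dict(compressor="set_mlp", output_dim=1, n_components=2,
                      batch_size=256, max_epochs=3, random_state=7)
        a = MDNCompressor(**kwargs).fit(train.payloads, train.params)
        b = MDNCompressor(**kwargs).fit(train.payloads, train.params)
        assert a.loss_history_.val_loss == b.loss_history_.val_loss

    def test_pure_noise_payload_cannot_beat_prior_entropy(self, rng):
        # payloads independent of theta: best achievable validation loss is
        # the prior entropy 1/2 ln(2 pi e) (Gibbs inequality)
        theta = rng.standard_normal((4000, 1))
        noise = rng.standard_normal((4000, 5, 2))
        est = MDNCompressor(compressor="set_mlp", output_dim=1, n_components=2,
                            batch_size=512, max_epochs=10, random_state=2)
        est.fit(noise, theta)
        assert est.best_val_loss_ == pytest.approx(info.normal_entropy(1.0), abs=0.1)

    def test_empty_table_rejected(self):
        est = MDNCompressor()
        with pytest.raises(Exception):
            est.fit(np.empty((0, 3, 2)), np.empty((0, 1)))
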