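"""Model family: predictor algebra, densities, reductions, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import beta as beta_dist, lognorm, multivariate_normal, norm

from lsirt import (ItemResponseData, ModelSpec, ParameterState, PriorConfig,
                   euclidean_distance, linear_predictor, log_likelihood,
                   log_posterior, log_prior, person_item_distances,
                   reduce_model, similarity)
from lsirt.data import DimensionError
from lsirt._posterior import UnconstrainedPosterior

from conftest import random_data, random_state


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

class TestItemResponseData:
    def test_rejects_non_binary_values(self):
        with pytest.raises(ValueError, match="non-binary"):
            ItemResponseData(np.array([[0.0, 2.0], [1.0, 0.0]]), [1, 1])

    def test_rejects_factor_gaps(self):
        resp = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="at least one item"):
            ItemResponseData(resp, [1, 3])

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError):
            ItemResponseData(np.array([[0.0, 1.0]]), [1, 1])

    def test_missing_cells_are_tracked(self):
        resp = np.array([[0.0, np.nan], [1.0, 0.0], [np.nan, 1.0]])
        d = ItemResponseData(resp, [1, 1])
        assert d.mask.sum() == 4
        assert d.n_persons == 3 and d.n_items == 2

    def test_duplicate_ids_rejected(self):
        resp = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            ItemResponseData(resp, [1, 1], item_ids=["x", "x"])


class TestParameterState:
    def test_rejects_nonpositive_discrimination(self, rng):
        with pytest.raises(ValueError, match="positive"):
            random_state(rng).replace(a=np.array([1.0, -0.5, 1.0, 1.0]))

    def test_rejects_invalid_correlation(self, rng):
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError):
            random_state(rng).replace(theta_corr=bad)

    def test_dimension_mismatch_names_axis(self, rng):
        st_ = random_state(rng)
        with pytest.raises(DimensionError, match="Z rows"):
            st_.replace(Z=np.zeros((99, 2)))


class TestPriorConfig:
    def test_requires_positive_scales(self):
        with pytest.raises(ValueError, match="beta_sd"):
            PriorConfig(beta_sd=0.0)

    def test_spike_concentrates_below_slab(self):
        with pytest.raises(ValueError, match="spike_mean"):
            PriorConfig(spike_mean=1.0, slab_mean=0.5)
        with pytest.raises(ValueError, match="spike_sd"):
            PriorConfig(spike_sd=2.0, slab_sd=1.0)


# ---------------------------------------------------------------------------
# distances and similarity
# ---------------------------------------------------------------------------

class TestDistance:
    @pytest.mark.parametrize("z,w,expected", [
        ((0, 0), (0, 0), 0.0),
        ((0, 0), (3, 4), 5.0),
        ((1, 2, 2), (1, 2, 2), 0.0),
    ])
    def test_known_values(self, z, w, expected):
        assert euclidean_distance(np.array(z), np.array(w)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            euclidean_distance(np.zeros(2), np.zeros(3))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=2),
           st.lists(st.floats(-5, 5), min_size=2, max_size=2),
           st.lists(st.floats(-5, 5), min_size=2, max_size=2))
    def test_metric_axioms(self, x, y, z):
        x, y, z = map(np.array, (x, y, z))
        assert euclidean_distance(x, y) == pytest.approx(euclidean_distance(y, x))
        assert euclidean_distance(x, z) <= (euclidean_distance(x, y)
                                            + euclidean_distance(y, z) + 1e-9)


class TestSimilarity:
    def test_zero_distance_gives_one(self):
        assert similarity(0.0, 3.7) == 1.0

    def test_closed_form_and_scale_symmetry(self):
        assert similarity(1.0, 1.0) == pytest.approx(np.exp(-1), abs=1e-12)
        assert similarity(2.0, 0.5) == pytest.approx(similarity(1.0, 1.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            similarity(-1.0, 1.0)
        with pytest.raises(ValueError):
            similarity(1.0, -0.1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0, 10), st.floats(0.01, 5))
    def test_range_and_monotonicity(self, d, g):
        s = similarity(d, g)
        assert 0 < s <= 1
        assert similarity(d + 0.5, g) <= s

    def test_equals_odds_ratio_of_distance_effect(self, rng):
        """exp(-gamma d) is the odds of success relative to zero distance."""
        state = random_state(rng)
        data = random_data(rng)
        spec = ModelSpec.mls2plm(2)
        eta = linear_predictor(state, data, spec)
        eta0 = linear_predictor(state.replace(gamma=0.0), data, spec)
        p, p0 = expit(eta), expit(eta0)
        odds_ratio = (p / (1 - p)) / (p0 / (1 - p0))
        d = person_item_distances(state.Z, state.W)
        assert np.allclose(odds_ratio, similarity(d, state.gamma), atol=1e-10)


# ---------------------------------------------------------------------------
# linear predictor and likelihood
# ---------------------------------------------------------------------------

class TestLinearPredictor:
    def test_zero_case_gives_even_odds(self):
        data = ItemResponseData(np.array([[0.0, 1.0], [1.0, 0.0]]), [1, 1])
        state = ParameterState(theta=np.zeros((2, 1)), a=np.ones(2),
                               beta=np.zeros(2), Z=np.zeros((2, 2)),
                               W=np.zeros((2, 2)), gamma=0.0)
        eta = linear_predictor(state, data, ModelSpec(D=1))
        assert np.allclose(eta, 0.0)
        assert np.allclose(expit(eta), 0.5)

    def test_closed_form_without_space(self):
        data = ItemResponseData(np.array([[0.0, 1.0], [1.0, 0.0]]), [1, 1])
        state = ParameterState(theta=np.full((2, 1), 1.0), a=np.full(2, 2.0),
                               beta=np.full(2, -1.0), Z=np.zeros((2, 2)),
                               W=np.zeros((2, 2)), gamma=0.0)
        eta = linear_predictor(state, data, ModelSpec(D=1, latent_space=False))
        assert np.allclose(eta, 1.0)

    def test_distance_term_hand_value(self):
        # a=1.2, theta=0.5, beta=0.3, dist((0,0),(3,4))=5, gamma=0.2
        data = ItemResponseData(np.array([[1.0, 0.0], [0.0, 1.0]]), [1, 1])
        state = ParameterState(
            theta=np.full((2, 1), 0.5), a=np.full(2, 1.2), beta=np.full(2, 0.3),
            Z=np.zeros((2, 2)), W=np.array([[3.0, 4.0], [3.0, 4.0]]), gamma=0.2)
        eta = linear_predictor(state, data, ModelSpec(D=1))
        assert eta[0, 0] == pytest.approx(-0.1, abs=1e-12)
        assert expit(eta[0, 0]) == pytest.approx(0.47502, abs=1e-5)

    def test_dimension_mismatch_is_structured(self, rng):
        state = random_state(rng, P=5)
        data = random_data(rng, P=6)
        with pytest.raises(DimensionError, match="persons"):
            linear_predictor(state, data, ModelSpec(D=2))


class TestLogLikelihood:
    def test_all_missing_gives_zero(self):
        resp = np.full((2, 2), np.nan)
        data = ItemResponseData(resp, [1, 1])
        state = ParameterState(theta=np.zeros((2, 1)), a=np.ones(2),
                               beta=np.zeros(2), Z=np.zeros((2, 2)),
                               W=np.zeros((2, 2)), gamma=0.0)
        assert log_likelihood(state, data, ModelSpec(D=1)) == 0.0

    def test_hand_summed_even_odds(self):
        data = ItemResponseData(np.ones((2, 2)), [1, 1])
        state = ParameterState(theta=np.zeros((2, 1)), a=np.ones(2),
                               beta=np.zeros(2), Z=np.zeros((2, 2)),
                               W=np.zeros((2, 2)), gamma=0.0)
        assert log_likelihood(state, data, ModelSpec(D=1)) == pytest.approx(
            4 * np.log(0.5), abs=1e-10)

    def test_never_positive(self, rng):
        for _ in range(5):
            state = random_state(rng)
            data = random_data(rng)
            assert log_likelihood(state, data, ModelSpec(D=2)) <= 0

    def test_translation_invariance(self, rng):
        state = random_state(rng)
        data = random_data(rng)
        spec = ModelSpec(D=2)
        base = log_likelihood(state, data, spec)
        t = rng.standard_normal(2)
        shifted = state.replace(Z=state.Z + t, W=state.W + t)
        assert abs(log_likelihood(shifted, data, spec) - base) < 1e-10

    def test_rigid_motion_invariance(self, rng):
        """Rotations/reflections + translations leave the likelihood fixed."""
        state = random_state(rng)
        data = random_data(rng)
        spec = ModelSpec(D=2)
        base = log_likelihood(state, data, spec)
        for _ in range(5):
            Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
            t = rng.standard_normal(2)
            moved = state.replace(Z=state.Z @ Q + t, W=state.W @ Q + t)
            assert abs(log_likelihood(moved, data, spec) - base) < 1e-10

    def test_gamma_decreases_likelihood_of_all_ones(self, rng):
        """With every response correct, the distance term only hurts."""
        data = ItemResponseData(np.ones((4, 3)), [1, 1, 1])
        state = random_state(rng, P=4, I=3, D=1)
        spec = ModelSpec(D=1)
        vals = [log_likelihood(state.replace(gamma=g), data, spec)
                for g in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) < 0)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestLogPrior:
    def test_independent_of_data(self, rng):
        state = random_state(rng)
        spec = ModelSpec(D=2)
        assert log_prior(state, spec) == log_prior(state, spec)

    def test_standard_normal_mode_value(self):
        """A single beta at its prior mode contributes log(1/sqrt(2 pi))."""
        spec = ModelSpec(D=1, latent_space=False, discrimination_free=False,
                         prior=PriorConfig(beta_sd=1.0))
        base = ParameterState(theta=np.zeros((2, 1)), a=np.ones(2),
                              beta=np.zeros(2), Z=np.zeros((2, 2)),
                              W=np.zeros((2, 2)), gamma=0.0)
        moved = base.replace(beta=np.array([0.0, 1.0]))
        delta = log_prior(base, spec) - log_prior(moved, spec)
        # moving one coordinate off the mode costs exactly the quadratic term
        assert delta == pytest.approx(0.5, abs=1e-12)
        assert norm.logpdf(0.0) == pytest.approx(-0.91894, abs=1e-5)

    def test_density_sum_oracle(self, rng):
        """Term-by-term scipy.stats oracle for a small full state (D=1)."""
        P, I, K = 2, 2, 2
        pc = PriorConfig(gamma_prior_mode="slab_spike")
        spec = ModelSpec(D=1, K=K, prior=pc)
        state = random_state(rng, P=P, I=I, D=1, K=K, gamma=0.9, mix_w=0.6)
        expected = 0.0
        expected += multivariate_normal.logpdf(state.theta.ravel(),
                                               np.zeros(P), np.eye(P))
        expected += norm.logpdf(state.beta, pc.beta_mean, pc.beta_sd).sum()
        expected += lognorm.logpdf(state.a, s=pc.log_a_sd,
                                   scale=np.exp(pc.log_a_mean)).sum()
        expected += norm.logpdf(state.Z).sum() + norm.logpdf(state.W).sum()
        lg = np.log(state.gamma)
        mix = (state.mix_w * norm.pdf(lg, pc.slab_mean, pc.slab_sd)
               + (1 - state.mix_w) * norm.pdf(lg, pc.spike_mean, pc.spike_sd))
        expected += np.log(mix) - lg
        expected += beta_dist.logpdf(state.mix_w, pc.mix_beta_a, pc.mix_beta_b)
        assert log_prior(state, spec) == pytest.approx(expected, abs=1e-8)

    def test_lkj_shape_weighting(self, rng):
        """For D>1 the correlation term is (shape-1) * log det R."""
        state = random_state(rng, D=2)
        lp1 = log_prior(state, ModelSpec(D=2, prior=PriorConfig(lkj_shape=1.0)))
        lp3 = log_prior(state, ModelSpec(D=2, prior=PriorConfig(lkj_shape=3.0)))
        expected = 2.0 * np.linalg.slogdet(state.theta_corr)[1]
        assert lp3 - lp1 == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# posterior and gradient
# ---------------------------------------------------------------------------

class TestLogPosterior:
    def test_is_likelihood_plus_prior(self, rng):
        state = random_state(rng)
        data = random_data(rng)
        spec = ModelSpec(D=2)
        assert log_posterior(state, data, spec) == pytest.approx(
            log_likelihood(state, data, spec) + log_prior(state, spec), abs=1e-10)

    def test_missing_column_leaves_value_unchanged(self, rng):
        state = random_state(rng, I=5)
        resp = random_data(rng, I=4).responses
        d1 = ItemResponseData(np.column_stack([resp, np.full(6, np.nan)]),
                              [1, 2, 1, 2, 1])
        d2 = ItemResponseData(resp, [1, 2, 1, 2])
        spec = ModelSpec(D=2)
        state4 = state.replace(a=state.a[:4], beta=state.beta[:4], W=state.W[:4])
        ll5 = log_likelihood(state, d1, spec)
        ll4 = log_likelihood(state4, d2, spec)
        assert ll5 == pytest.approx(ll4, abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        """Exact gradients vs central differences on every parameter block."""
        cfgs = [
            ModelSpec(D=3, K=2, prior=PriorConfig(gamma_prior_mode="slab_spike",
                                                  theta_scale_mode="free")),
            ModelSpec(D=1, K=2, prior=PriorConfig()),
            ModelSpec(D=2, discrimination_free=False, latent_space=False),
        ]
        for spec in cfgs:
            data = random_data(rng, P=5, I=6, D=spec.D)
            post = UnconstrainedPosterior(data, spec)
            x = post.initial_vector(rng)
            _, g = post.value_and_grad(x)
            eps = 1e-5
            for i in range(x.size):
                xp, xm = x.copy(), x.copy()
                xp[i] += eps
                xm[i] -= eps
                fd = (post.value(xp) - post.value(xm)) / (2 * eps)
                assert abs(g[i] - fd) <= 1e-4 * max(1.0, abs(fd)), \
                    f"spec {spec.D}/{spec.latent_space}, coord {i}"

    def test_unconstrained_round_trip(self, rng):
        spec = ModelSpec(D=3, prior=PriorConfig(gamma_prior_mode="slab_spike"))
        data = random_data(rng, P=5, I=6, D=3)
        post = UnconstrainedPosterior(data, spec)
        state = random_state(rng, P=5, I=6, D=3, mix_w=0.4)
        x = post.pack(state)
        back = post.unpack(x)
        assert np.allclose(back.theta, state.theta, atol=1e-12)
        assert np.allclose(back.a, state.a, atol=1e-12)
        assert np.allclose(back.theta_corr, state.theta_corr, atol=1e-10)
        assert back.gamma == pytest.approx(state.gamma, abs=1e-12)


# ---------------------------------------------------------------------------
# nested reductions
# ---------------------------------------------------------------------------

class TestReduceModel:
    def test_taxonomy(self):
        full = ModelSpec.mls2plm(3)
        assert reduce_model(full, "fix_discrimination") == ModelSpec.mlsrm(3)
        assert reduce_model(reduce_model(full, "unidimensional"),
                            "fix_discrimination") == ModelSpec.ulsrm()
        assert reduce_model(full, "drop_space") == ModelSpec.mirm(3)

    def test_unknown_constraint(self):
        with pytest.raises(ValueError, match="unknown constraint"):
            reduce_model(ModelSpec.mls2plm(2), "probit")

    def test_drop_space_matches_gamma_zero_parent(self, rng):
        state = random_state(rng, gamma=0.0)
        data = random_data(rng)
        full = ModelSpec.mls2plm(2)
        assert abs(log_likelihood(state, data, full)
                   - log_likelihood(state, data, reduce_model(full, "drop_space"))
                   ) < 1e-12

    def test_rasch_reduction_matches_unit_discrimination(self, rng):
        """MLSRM likelihood equals MLS2PLM at a = 1, on 10 random states."""
        data = random_data(rng)
        full = ModelSpec.mls2plm(2)
        rasch = reduce_model(full, "fix_discrimination")
        for _ in range(10):
            state = random_state(rng).replace(a=np.ones(4))
            assert abs(log_likelihood(state, data, full)
                       - log_likelihood(state, data, rasch)) < 1e-12

    def test_unidimensional_reduction_matches_collapsed_factor(self, rng):
        data = random_data(rng, D=1)
        full = ModelSpec.mls2plm(2)
        state2 = random_state(rng, D=2)
        # constrain: all items load on factor 1, second factor inert
        uni = reduce_model(full, "unidimensional")
        state1 = state2.replace(theta=state2.theta[:, :1], theta_corr=np.eye(1),
                                theta_scale=np.ones(1))
        assert abs(log_likelihood(state2, data, full)
                   - log_likelihood(state1, data, uni)) < 1e-12

    def test_nesting_posterior_difference_is_prior_only(self, rng):
        """Parent minus reduced log posterior does not depend on the data."""
        full = ModelSpec.mls2plm(2)
        rasch = reduce_model(full, "fix_discrimination")
        state = random_state(rng).replace(a=np.ones(4))
        deltas = []
        for _ in range(3):
            data = random_data(rng)
            deltas.append(log_posterior(state, data, full)
                          - log_posterior(state, data, rasch))
        assert np.ptp(deltas) < 1e-10
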