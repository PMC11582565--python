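"""Discretization, stationary distributions, emissions, and forward likelihood."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from nanoak.hmm_core import (
    CurrentTrace,
    EmissionModel,
    TransitionMatrix,
    discretize,
    emission_density_vector,
    forward_loglik,
    forward_loglik_unscaled,
    joint_loglik,
    stationary_distribution,
)
from nanoak.kinetic_model import LigandConcentrations, ModelVariant, build_generator
from nanoak.reference import REFERENCE_RATES

from conftest import make_trace


def expm_series(A, terms=60):
    """Truncated power-series oracle for the matrix exponential."""
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


class TestDiscretize:
    def test_zero_generator_gives_identity(self):
        G = discretize(np.zeros((4, 4)), 0.2)
        assert np.allclose(G.gamma, np.eye(4))

    def test_two_state_closed_form_and_series_oracle(self):
        a, b = 300.0, 80.0  # s^-1
        Q = np.array([[-a, a], [b, -b]])
        dt = 0.2
        G = discretize(Q, dt)
        lam = (a + b) * dt / 1000.0
        g11 = (b + a * np.exp(-lam)) / (a + b)
        assert G.gamma[0, 0] == pytest.approx(g11, rel=1e-12)
        assert np.allclose(G.gamma, expm_series(Q * dt / 1000.0), atol=1e-10)

    def test_reference_generator_matches_series_oracle(self, ref_rates, v3):
        gen = build_generator(ref_rates, LigandConcentrations(atp_mM=1.0, amp_mM=1.0), v3)
        G = discretize(gen, 0.2)
        assert np.allclose(G.gamma, expm_series(gen.Q * 0.2 / 1000.0), atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.01, 5.0))
    def test_rows_sum_to_one_for_any_dt(self, dt):
        gen = build_generator(
            REFERENCE_RATES, LigandConcentrations(atp_mM=0.5, amp_mM=0.5), ModelVariant("V3")
        )
        G = discretize(gen, dt)
        assert np.allclose(G.gamma.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(G.gamma >= 0.0) and np.all(G.gamma <= 1.0)

    def test_first_order_limit(self, ref_rates, v3):
        gen = build_generator(ref_rates, LigandConcentrations(atp_mM=1.0), v3)
        dt = 1e-6  # ms
        G = discretize(gen, dt)
        approx = np.eye(10) + gen.Q * dt / 1000.0
        assert np.allclose(G.gamma, approx, atol=1e-8)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((2, 3)), 0.2)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((2, 2)), 0.0)


class TestStationary:
    def test_symmetric_two_state(self):
        d = stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert np.allclose(d, [0.5, 0.5])

    def test_two_state_closed_form(self):
        p12, p21 = 0.03, 0.12
        d = stationary_distribution(np.array([[1 - p12, p12], [p21, 1 - p21]]))
        assert np.allclose(d, np.array([p21, p12]) / (p12 + p21), atol=1e-12)

    def test_single_state(self):
        assert stationary_distribution(np.array([[1.0]])) == pytest.approx([1.0])

    def test_reducible_chain_rejected(self):
        # two absorbing states: stationary distribution not unique
        gamma = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="not unique"):
            stationary_distribution(gamma)

    def test_fixed_point_of_reference_chain(self, ref_rates, v3):
        gen = build_generator(ref_rates, LigandConcentrations(atp_mM=1.0, amp_mM=0.1), v3)
        G = discretize(gen, 0.2)
        d = stationary_distribution(G)
        assert np.allclose(d @ G.gamma, d, atol=1e-10)
        assert d.sum() == pytest.approx(1.0)


class TestEmissions:
    def test_density_at_group_mean(self, em, space):
        dens = emission_density_vector(em.mean("M2"), em, space)
        i, j = space.index("M2*"), space.index("M2**")
        expected = 1.0 / (em.group_sigmas["M2"] * np.sqrt(2 * np.pi))
        assert dens[i] == pytest.approx(expected, rel=1e-12)
        assert dens[j] == pytest.approx(expected, rel=1e-12)

    def test_density_one_sigma_away(self, em, space):
        y = em.mean("M") + em.group_sigmas["M"]
        dens = emission_density_vector(y, em, space)
        expected = np.exp(-0.5) / (em.group_sigmas["M"] * np.sqrt(2 * np.pi))
        assert dens[space.index("M")] == pytest.approx(expected, rel=1e-12)

    def test_grouped_states_share_density(self, em, space):
        for y in (-150.0, -200.0, -240.0):
            dens = emission_density_vector(y, em, space)
            trio = [dens[space.index(n)] for n in ("M", "M*", "M**")]
            assert trio[0] == trio[1] == trio[2]

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            EmissionModel({"A": 0.0}, {"A": 0.0}, groups=("A",))


class TestForward:
    def test_single_state_single_sample(self):
        from nanoak.kinetic_model import State, StateSpace

        sp = StateSpace((State("s", "A", "open", "open", 0),))
        em1 = EmissionModel({"A": -200.0}, {"A": 8.0}, groups=("A",))
        G = TransitionMatrix(np.array([[1.0]]), 0.2, sp)
        tr = make_trace([-195.0])
        res = forward_loglik(G, em1, tr, sp)
        assert res.loglik == pytest.approx(norm.logpdf(-195.0, -200.0, 8.0), rel=1e-12)

    @pytest.mark.parametrize("T", [1, 2, 3])
    def test_matches_path_enumeration(self, two_state, T):
        """Forward likelihood equals the exhaustive sum over hidden paths,
        with the transition matrix applied before every emission."""
        sp, emission, gamma = two_state
        G = gamma(0.1, 0.3)
        delta = stationary_distribution(G)
        y = np.array([-200.0, -215.0, -225.0])[:T]
        res = forward_loglik(G, emission, make_trace(y), sp)
        mus, sds = emission.per_state(sp)
        L = 0.0
        for s0 in range(2):
            for path in itertools.product(range(2), repeat=T):
                p = delta[s0]
                prev = s0
                for t, s in enumerate(path):
                    p *= G.gamma[prev, s] * norm.pdf(y[t], mus[s], sds[s])
                    prev = s
                L += p
        assert res.loglik == pytest.approx(np.log(L), rel=1e-12)

    def test_scaled_equals_unscaled(self, two_state):
        sp, emission, gamma = two_state
        G = gamma(0.05, 0.2)
        rng = np.random.default_rng(7)
        y = -210.0 + 10.0 * rng.standard_normal(10)
        tr = make_trace(y)
        scaled = forward_loglik(G, emission, tr, sp).loglik
        unscaled = forward_loglik_unscaled(G, emission, tr, sp)
        assert scaled == pytest.approx(unscaled, rel=1e-8)

    def test_agrees_with_hmmlearn(self, two_state):
        """Independent cross-check: hmmlearn's Gaussian HMM scorer gives the
        same value once its start distribution absorbs the leading transition."""
        from hmmlearn.hmm import GaussianHMM

        sp, emission, gamma = two_state
        G = gamma(0.1, 0.25)
        delta = stationary_distribution(G)
        rng = np.random.default_rng(3)
        y = -210.0 + 12.0 * rng.standard_normal(200)
        ours = forward_loglik(G, emission, make_trace(y), sp).loglik
        h = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        h.startprob_ = delta @ G.gamma
        h.transmat_ = G.gamma
        mus, sds = emission.per_state(sp)
        h.means_ = mus.reshape(-1, 1)
        h.covars_ = (sds**2).reshape(-1, 1)
        assert ours == pytest.approx(h.score(y.reshape(-1, 1)), rel=1e-10)

    def test_filtered_probabilities_normalized(self, two_state):
        sp, emission, gamma = two_state
        G = gamma(0.1, 0.3)
        y = np.array([-200.0, -220.0, -221.0, -199.0])
        res = forward_loglik(G, emission, make_trace(y), sp, keep_filtered=True)
        assert np.allclose(res.filtered.sum(axis=1), 1.0, atol=1e-12)

    def test_deep_tail_samples_do_not_underflow(self, em, space, ref_rates, v3):
        gen = build_generator(ref_rates, LigandConcentrations(atp_mM=1.0), v3)
        G = discretize(gen, 0.2)
        tr = make_trace(np.full(50, -433.3), atp=1.0)  # ~25 sigma from every level
        res = forward_loglik(G, em, tr, space)
        assert np.isfinite(res.loglik)

    def test_non_finite_samples_rejected(self, two_state):
        sp, emission, gamma = two_state
        with pytest.raises(ValueError):
            forward_loglik(gamma(0.1, 0.1), emission, make_trace([np.nan]), sp)


class TestJointLoglik:
    def test_single_trace_equals_forward(self, ref_rates, em, v3, space):
        rng = np.random.default_rng(0)
        tr = make_trace(-210 + 8 * rng.standard_normal(300), atp=1.0)
        joint = joint_loglik(ref_rates, em, [tr], v3)
        gen = build_generator(ref_rates, tr.conc, v3)
        single = forward_loglik(discretize(gen, tr.dt_ms), em, tr, space).loglik
        assert joint == pytest.approx(single, rel=1e-12)

    def test_two_identical_traces_double(self, ref_rates, em, v3):
        rng = np.random.default_rng(1)
        tr = make_trace(-210 + 8 * rng.standard_normal(200), atp=0.1)
        assert joint_loglik(ref_rates, em, [tr, tr], v3) == pytest.approx(
            2 * joint_loglik(ref_rates, em, [tr], v3), rel=1e-12
        )

    def test_additivity_across_conditions(self, ref_rates, em, v3):
        rng = np.random.default_rng(2)
        traces = [
            make_trace(-205 + 8 * rng.standard_normal(150), atp=a, amp=b)
            for a, b in [(0.01, 0.0), (1.0, 0.1), (1.0, 1.0)]
        ]
        total = joint_loglik(ref_rates, em, traces, v3)
        loop = sum(joint_loglik(ref_rates, em, [t], v3) for t in traces)
        assert total == pytest.approx(loop, rel=1e-12)

    def test_empty_trace_list_rejected(self, ref_rates, em, v3):
        with pytest.raises(ValueError):
            joint_loglik(ref_rates, em, [], v3)

    def test_truth_beats_perturbed_rates(self, reduced_design_traces, ref_rates, em, v3):
        """Consistency smoke test: on data simulated from the model, the
        generating parameters outscore any single rate scaled by 10."""
        from dataclasses import replace

        ll_true = joint_loglik(ref_rates, em, reduced_design_traces, v3)
        for name in ("k1", "r1", "r_m1", "b2"):
            worse = replace(ref_rates, **{name: getattr(ref_rates, name) * 10.0})
            assert ll_true > joint_loglik(worse, em, reduced_design_traces, v3)
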