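"""Stoichiometry engine: closures, drift, diffusion covariance, factorizations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rmstoch import (
    ChannelSystem,
    ModelParams,
    build_channels,
    cross_cov_ratio,
    diffusion_matrix,
    drift,
    factorize,
)

from conftest import random_interior_states


def closed_form_coupled(params, x):
    """The explicit coupled-closure covariance (e = 1) written out by hand."""
    n, p = x
    fp = params.m * n * p / (1.0 + n)
    return np.array(
        [
            [n + n * n / params.k + fp, -fp],
            [-fp, params.c * p + fp],
        ]
    ) / params.omega


class TestBuildChannels:
    def test_bernoulli_stoichiometry(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        assert cs.K == 5
        expected = np.array([[1, -1, 0, -1, -1], [0, 0, -1, 1, 0]], dtype=float)
        assert np.array_equal(cs.S, expected)
        assert cs.integer_jumps

    def test_effective_stoichiometry(self):
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=0.7)
        cs = build_channels(params, "effective")
        assert cs.K == 4
        assert np.allclose(cs.S[:, 3], [-1.0, 0.7])

    def test_split_stoichiometry(self, baseline):
        cs = build_channels(baseline, "split")
        assert cs.K == 5
        assert np.array_equal(cs.S[:, 3], [-1.0, 0.0])
        assert np.array_equal(cs.S[:, 4], [0.0, 1.0])

    def test_intensities(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        f = cs.f((1.0, 1.0))
        # f1=N, f2=N^2/k, f3=cP, f4=e*f_pred, f5=(1-e)*f_pred
        assert np.allclose(f, [1.0, 0.5, 0.4, 0.75, 0.0])

    def test_failure_channel_silent_at_full_conversion(self, baseline, rng):
        cs = build_channels(baseline, "bernoulli")
        for x in random_interior_states(rng, 10):
            assert cs.f(x)[4] == 0.0

    def test_intensities_vanish_at_origin(self, baseline):
        for closure in ("bernoulli", "effective", "split"):
            cs = build_channels(baseline, closure)
            assert np.all(cs.f((0.0, 0.0)) == 0.0)

    def test_unknown_closure_rejected(self, baseline):
        with pytest.raises(ValueError, match="closure"):
            build_channels(baseline, "diagonal")


class TestDrift:
    def test_hand_value(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        assert np.allclose(drift(cs, (1.0, 1.0)), [-0.25, 0.35], atol=1e-15)

    def test_zero_at_origin(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        assert np.array_equal(drift(cs, (0.0, 0.0)), [0.0, 0.0])

    def test_negative_state_rejected(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        with pytest.raises(ValueError):
            drift(cs, (-0.1, 1.0))

    def test_drift_identical_across_closures(self, rng):
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=0.6, omega=50.0)
        systems = [build_channels(params, c) for c in ("bernoulli", "effective", "split")]
        for x in random_interior_states(rng, 1000):
            b0 = drift(systems[0], x)
            for cs in systems[1:]:
                assert np.max(np.abs(drift(cs, x) - b0)) <= 1e-12

    def test_vanishes_at_coexistence(self, baseline):
        from rmstoch import equilibria

        cs = build_channels(baseline, "bernoulli")
        k3 = equilibria(baseline).K3
        assert np.max(np.abs(drift(cs, k3))) < 1e-14


class TestDiffusionMatrix:
    def test_hand_value(self, baseline):
        rep = diffusion_matrix(build_channels(baseline, "bernoulli"), (1.0, 1.0))
        assert np.allclose(rep.a, [[2.25, -0.75], [-0.75, 1.15]], atol=1e-14)

    def test_matches_closed_form_on_random_states(self, baseline, rng):
        cs = build_channels(baseline, "bernoulli")
        for x in random_interior_states(rng, 200):
            rep = diffusion_matrix(cs, x)
            assert np.max(np.abs(rep.a - closed_form_coupled(baseline, x))) <= 1e-12

    def test_brute_force_channel_sum_oracle(self, rng):
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=0.6, omega=37.0)
        for closure in ("bernoulli", "effective", "split"):
            cs = build_channels(params, closure)
            for x in random_interior_states(rng, 20):
                f = cs.f(x)
                brute = sum(
                    f[j] * np.outer(cs.S[:, j], cs.S[:, j]) for j in range(cs.K)
                ) / params.omega
                assert np.allclose(diffusion_matrix(cs, x).a, brute, atol=1e-15)

    def test_predation_block_shapes(self, rng):
        e = 0.6
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=e)
        blocks = {
            "bernoulli": np.array([[1.0, -e], [-e, e]]),
            "effective": np.array([[1.0, -e], [-e, e * e]]),
            "split": np.array([[1.0, 0.0], [0.0, e]]),
        }
        for closure, block in blocks.items():
            cs = build_channels(params, closure)
            for x in random_interior_states(rng, 10):
                n, p = x
                fp = params.m * n * p / (1.0 + n)
                rep = diffusion_matrix(cs, x)
                assert np.allclose(rep.a_pred, fp * block, rtol=1e-12)
                # base part is diagonal for every closure
                assert rep.a_base[0, 1] == 0.0 and rep.a_base[1, 0] == 0.0

    def test_sign_structure(self, rng):
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=0.6)
        coupled = [build_channels(params, c) for c in ("bernoulli", "effective")]
        split = build_channels(params, "split")
        for x in random_interior_states(rng, 100):
            for cs in coupled:
                assert diffusion_matrix(cs, x).a[0, 1] < 0
            assert abs(diffusion_matrix(split, x).a[0, 1]) <= 1e-14

    def test_full_conversion_makes_bernoulli_and_effective_coincide(self, baseline, rng):
        cb = build_channels(baseline, "bernoulli")
        ce = build_channels(baseline, "effective")
        for x in random_interior_states(rng, 50):
            assert np.allclose(
                diffusion_matrix(cb, x).a, diffusion_matrix(ce, x).a, atol=1e-15
            )

    def test_partial_conversion_predator_variance_ratio(self):
        params = ModelParams(m=1.5, c=0.4, k=2.0, e=0.5)
        x = (1.0, 1.0)
        fp = 1.5 * 1.0 * 1.0 / 2.0
        ab = diffusion_matrix(build_channels(params, "bernoulli"), x).a_pred
        ae = diffusion_matrix(build_channels(params, "effective"), x).a_pred
        assert ab[1, 1] == pytest.approx(0.5 * fp, rel=1e-14)
        assert ae[1, 1] == pytest.approx(0.25 * fp, rel=1e-14)
        assert ab[1, 1] / ae[1, 1] == pytest.approx(2.0, rel=1e-14)

    def test_symmetric_psd_everywhere(self, rng):
        params = ModelParams(m=2.0, c=0.3, k=5.0, e=0.4, omega=10.0)
        for closure in ("bernoulli", "effective", "split"):
            cs = build_channels(params, closure)
            for x in random_interior_states(rng, 50):
                a = diffusion_matrix(cs, x).a
                assert np.allclose(a, a.T)
                assert np.linalg.eigvalsh(a).min() >= -1e-12


class TestCrossCovRatio:
    def test_hand_value(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        expected = -0.75 / np.sqrt(2.25 * 1.15)
        assert cross_cov_ratio(cs, (1.0, 1.0)) == pytest.approx(expected, rel=1e-12)
        assert cross_cov_ratio(cs, (1.0, 1.0)) == pytest.approx(-0.4663, abs=1e-4)

    def test_split_ratio_zero(self, baseline, rng):
        cs = build_channels(baseline, "split")
        for x in random_interior_states(rng, 20):
            assert cross_cov_ratio(cs, x) == 0.0

    def test_system_size_invariance(self, rng):
        for omega in (100.0, 1e6):
            params = ModelParams(m=1.5, c=0.4, k=2.0, omega=omega)
            cs = build_channels(params, "bernoulli")
            assert cross_cov_ratio(cs, (1.0, 1.0)) == pytest.approx(
                -0.75 / np.sqrt(2.25 * 1.15), rel=1e-12
            )

    def test_bounded_by_one(self, rng):
        params = ModelParams(m=3.0, c=0.2, k=8.0)
        cs = build_channels(params, "bernoulli")
        for x in random_interior_states(rng, 100):
            assert -1.0 <= cross_cov_ratio(cs, x) <= 1.0

    def test_boundary_state_rejected(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        with pytest.raises(ValueError):
            cross_cov_ratio(cs, (0.0, 1.0))


class TestFactorize:
    def test_cholesky_hand_value(self):
        a = np.array([[2.25, -0.75], [-0.75, 1.15]])
        sigma = factorize(a, "cholesky")
        assert np.allclose(sigma, [[1.5, 0.0], [-0.5, np.sqrt(0.9)]], atol=1e-14)
        assert np.allclose(sigma @ sigma.T, a, atol=1e-14)

    def test_identity(self):
        assert np.array_equal(factorize(np.eye(2)), np.eye(2))

    def test_event_factorization_reconstructs(self, baseline):
        cs = build_channels(baseline, "bernoulli")
        x = (1.0, 1.0)
        sigma = factorize(diffusion_matrix(cs, x).a, "event", cs=cs, x=x)
        assert sigma.shape == (2, 5)
        assert np.allclose(sigma @ sigma.T, [[2.25, -0.75], [-0.75, 1.15]], atol=1e-14)

    def test_singular_boundary_matrix_handled(self, baseline):
        # on the prey axis the predator variance vanishes: Cholesky would fail
        cs = build_channels(baseline, "bernoulli")
        a = diffusion_matrix(cs, (1.0, 0.0)).a
        sigma = factorize(a, "cholesky")
        assert np.allclose(sigma @ sigma.T, a, atol=1e-14)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            factorize(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            factorize(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_event_requires_channel_context(self):
        with pytest.raises(ValueError):
            factorize(np.eye(2), "event")


class TestGenericEngine:
    """The engine accepts arbitrary (S, f) pairs, e.g. a 3-species chain."""

    @staticmethod
    def food_chain():
        # basal prey, intermediate consumer, top predator; coupled
        # predation-conversion events (-1,+1,0) and (0,-1,+1)
        S = np.array(
            [
                [1, -1, 0, 0, -1, 0],
                [0, 0, -1, 0, 1, -1],
                [0, 0, 0, -1, 0, 1],
            ],
            dtype=float,
        )

        def f(x):
            x1, x2, x3 = x
            return np.array(
                [
                    x1,
                    0.2 * x1 * x1,
                    0.3 * x2,
                    0.2 * x3,
                    1.2 * x1 * x2 / (1.0 + x1),
                    0.8 * x2 * x3 / (1.0 + x2),
                ]
            )

        return ChannelSystem.custom(S, f, name="food_chain")

    def test_trophic_covariance_banding(self):
        cs = self.food_chain()
        x = (1.0, 1.0, 1.0)
        f = cs.f(x)
        a = (cs.S * f) @ cs.S.T
        # coupled predation events induce negative covariance along the
        # chain, none between basal prey and top predator
        assert a[0, 1] < 0
        assert a[1, 2] < 0
        assert a[0, 2] == 0.0
        assert np.linalg.eigvalsh(a).min() >= -1e-12

    def test_drift_from_same_representation(self):
        cs = self.food_chain()
        b = cs.S @ cs.f((1.0, 1.0, 1.0))
        assert b.shape == (3,)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    m=st.floats(0.3, 3.0),
    c_frac=st.floats(0.05, 0.95),
    k=st.floats(0.2, 10.0),
    e=st.floats(0.05, 1.0),
    n=st.floats(0.01, 10.0),
    p=st.floats(0.01, 10.0),
)
def test_property_drift_compatible_covariance_signs(m, c_frac, k, e, n, p):
    """All closures share b(x); coupled a12 < 0, split a12 = 0, a PSD."""
    params = ModelParams(m=m, c=m * c_frac, k=k, e=e, omega=25.0)
    x = (n, p)
    systems = {cl: build_channels(params, cl) for cl in ("bernoulli", "effective", "split")}
    b_ref = drift(systems["bernoulli"], x)
    for cl, cs in systems.items():
        assert np.max(np.abs(drift(cs, x) - b_ref)) <= 1e-12
        a = diffusion_matrix(cs, x).a
        assert np.linalg.eigvalsh(a).min() >= -1e-12
        if cl == "split":
            assert abs(a[0, 1]) <= 1e-14
        else:
            assert a[0, 1] < 0
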