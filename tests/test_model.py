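"""Generative core: cluster posterior, complete-data likelihood, sampling.

Densities are checked against independent straight-line implementations
built on scipy.stats.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vada.model import (MixtureLatentParams, complete_data_loglik,
                        responsibilities, sample_generative)
from vada.networks import ArchitectureConfig, DataSpec, build_networks, apply_y_decoder

from conftest import random_params, zero_net


# --------------------------------------------------------------------------
# responsibilities h(u, Z, c; H)

def oracle_responsibilities(u, Z, p):
    """Straight-line normalized product of the three densities."""
    K, L = p.K, len(u)
    w = np.zeros(K)
    for k in range(K):
        dens = p.pi[k]
        for l in range(L):
            dens *= stats.norm.pdf(u[l], p.beta0[k] + Z[l] @ p.beta[k],
                                   np.sqrt(p.sigma2_u[k]))
            for d in range(Z.shape[1]):
                dens *= stats.norm.pdf(Z[l, d], p.mu[k, d], np.sqrt(p.sigma2[k, d]))
        w[k] = dens
    return w / w.sum()


def test_single_component_is_certain(rng):
    p = random_params(1, 3, rng)
    out = responsibilities(rng.standard_normal(2), rng.standard_normal((2, 3)), p)
    np.testing.assert_allclose(out, [1.0])


def test_identical_components_split_evenly(rng):
    base = random_params(1, 2, rng)
    p = MixtureLatentParams(pi=[0.5, 0.5],
                            mu=np.vstack([base.mu, base.mu]),
                            sigma2=np.vstack([base.sigma2, base.sigma2]),
                            beta0=np.repeat(base.beta0, 2),
                            beta=np.vstack([base.beta, base.beta]),
                            sigma2_u=np.repeat(base.sigma2_u, 2))
    out = responsibilities(rng.standard_normal(2), rng.standard_normal((2, 2)), p)
    np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_matches_brute_force_density_oracle(seed):
    rng = np.random.default_rng(seed)
    p = random_params(3, 2, rng)
    u = rng.standard_normal(2)
    Z = rng.standard_normal((2, 2))
    np.testing.assert_allclose(responsibilities(u, Z, p),
                               oracle_responsibilities(u, Z, p), atol=1e-10)


@given(seed=st.integers(0, 10_000), shift=st.floats(-500, 500))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_simplex_and_common_rescale_invariance(seed, shift):
    """Output sums to one, and rescaling all unnormalized component
    densities by a common factor (a constant shift of every log density)
    leaves the normalized posterior unchanged."""
    from vada.model import cluster_log_joint

    rng = np.random.default_rng(seed)
    p = random_params(3, 2, rng)
    u = rng.standard_normal(3)
    Z = rng.standard_normal((3, 2))
    out = responsibilities(u, Z, p)
    assert np.all(out >= 0)
    assert abs(out.sum() - 1.0) < 1e-12
    lj = cluster_log_joint(u, Z, p).value + shift
    w = np.exp(lj - lj.max())
    np.testing.assert_allclose(out, w / w.sum(), atol=1e-9)


def test_variance_underflow_reported():
    p = MixtureLatentParams(pi=[1.0], mu=[[0.0]], sigma2=[[1e-300]],
                            beta0=[0.0], beta=[[0.0]], sigma2_u=[1.0])
    with pytest.raises((FloatingPointError, ValueError)):
        responsibilities(np.array([1e300]), np.array([[1e150]]), p)


# --------------------------------------------------------------------------
# complete-data log-likelihood

def _identity_setup(L=3, P=4, D=2):
    spec = DataSpec(D=D, L=L, n_continuous=P)
    nets = build_networks(ArchitectureConfig(hidden_x=(4,), hidden_y=(4,), seed=0), spec)
    for net in (nets.x_decoder, nets.y_decoder):
        zero_net(net)
    p = MixtureLatentParams(pi=[1.0], mu=np.zeros((1, D)), sigma2=np.ones((1, D)),
                            beta0=[0.0], beta=np.zeros((1, D)), sigma2_u=[1.0])
    return nets, p, L, P, D


def test_standard_normal_at_mode_arithmetic():
    nets, p, L, P, D = _identity_setup()
    val = complete_data_loglik(np.zeros(L), np.zeros(L), np.zeros((L, P)),
                               np.zeros((L, D)), 0, p, nets)
    expected = -0.5 * (L + L * P + L + D * L) * np.log(2 * np.pi)
    np.testing.assert_allclose(val, expected, atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_matches_per_factor_oracle(seed, small_bundle):
    rng = np.random.default_rng(seed)
    nets = small_bundle
    L, P, D = nets.spec.L, nets.spec.n_continuous, nets.spec.D
    p = random_params(2, D, rng)
    y = rng.standard_normal(L)
    u = rng.standard_normal(L)
    X = rng.standard_normal((L, P))
    Z = rng.standard_normal((L, D))
    c = 1
    from vada.networks import apply_x_decoder
    dec = apply_x_decoder(nets, Z)
    ym, yv = apply_y_decoder(nets, u)
    expected = np.log(p.pi[c])
    expected += stats.norm.logpdf(Z, p.mu[c], np.sqrt(p.sigma2[c])).sum()
    expected += stats.norm.logpdf(u, p.beta0[c] + Z @ p.beta[c],
                                  np.sqrt(p.sigma2_u[c])).sum()
    expected += stats.norm.logpdf(X, dec["mean"], np.sqrt(dec["sigma2"])).sum()
    expected += stats.norm.logpdf(y, ym, np.sqrt(yv)).sum()
    np.testing.assert_allclose(complete_data_loglik(y, u, X, Z, c, p, nets),
                               expected, atol=1e-10)


def test_loglik_decreases_with_outcome_residual():
    nets, p, L, P, D = _identity_setup()
    base = np.zeros(L)
    vals = []
    for r in (0.0, 0.5, 1.0, 2.0):
        y = base.copy()
        y[0] += r
        vals.append(complete_data_loglik(y, np.zeros(L), np.zeros((L, P)),
                                         np.zeros((L, D)), 0, p, nets))
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_bad_cluster_label_rejected(small_bundle, small_params):
    L, P, D = 3, 4, 2
    with pytest.raises(ValueError, match="out of range"):
        complete_data_loglik(np.zeros(L), np.zeros(L), np.zeros((L, P)),
                             np.zeros((L, D)), 5, small_params, small_bundle)


# --------------------------------------------------------------------------
# forward sampling

def test_sampled_dataset_has_paper_dimensions():
    rng = np.random.default_rng(0)
    p = random_params(3, 10, rng)
    spec = DataSpec(D=10, L=4, n_continuous=100, K=3)
    nets = build_networks(ArchitectureConfig(seed=0), spec)
    ds = sample_generative(p, nets, 2500, seed=1)
    assert ds.X.shape == (2500, 4, 100)
    assert ds.n_subjects * ds.n_measurements == 10_000
    assert ds.c_true.shape == (2500,)


def test_seed_reproducibility(small_bundle, small_params):
    a = sample_generative(small_params, small_bundle, 20, seed=5)
    b = sample_generative(small_params, small_bundle, 20, seed=5)
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.y, b.y)
    np.testing.assert_array_equal(a.c_true, b.c_true)


def test_zero_noise_limit_is_deterministic_mean_path(rng):
    """With all variances at the floor the sample equals the mean path."""
    D, L, P = 2, 3, 4
    spec = DataSpec(D=D, L=L, n_continuous=P)
    nets = build_networks(ArchitectureConfig(hidden_x=(4,), hidden_y=(4,), seed=1), spec)
    # force decoder variance heads to ~0 via a large negative logvar bias
    for net in (nets.x_decoder, nets.y_decoder):
        b = net.head_b.value
        b[net.head_slices["logvar"]] = -60.0
    eps = 1e-12
    p = MixtureLatentParams(pi=[1.0], mu=[[0.3, -0.2]], sigma2=[[eps, eps]],
                            beta0=[0.1], beta=[[0.5, 0.5]], sigma2_u=[eps])
    ds = sample_generative(p, nets, 8, seed=3)
    np.testing.assert_allclose(ds.Z_true, np.broadcast_to(p.mu[0], (8, L, D)),
                               atol=1e-5)
    u_expected = p.beta0[0] + ds.Z_true @ p.beta[0]
    np.testing.assert_allclose(ds.u_true, u_expected, atol=1e-5)
    y_mean, _ = apply_y_decoder(nets, ds.u_true)
    # decoder variances are floored at 1e-6, so draws sit within a few 1e-3
    np.testing.assert_allclose(ds.y, y_mean, atol=1e-2)


def test_latent_moments_match_single_component():
    rng = np.random.default_rng(2)
    p = MixtureLatentParams(pi=[1.0], mu=[[1.5]], sigma2=[[0.8]],
                            beta0=[0.0], beta=[[1.0]], sigma2_u=[1.0])
    spec = DataSpec(D=1, L=1, n_continuous=2)
    nets = build_networks(ArchitectureConfig(hidden_x=(4,), hidden_y=(4,), seed=0), spec)
    ds = sample_generative(p, nets, 4000, seed=9)
    z = ds.Z_true.reshape(-1)
    se_mean = np.sqrt(0.8 / len(z))
    assert abs(z.mean() - 1.5) < 4 * se_mean
    se_var = 0.8 * np.sqrt(2.0 / (len(z) - 1))
    assert abs(z.var() - 0.8) < 4 * se_var


def test_class_frequencies_follow_pi():
    rng = np.random.default_rng(3)
    p = random_params(3, 2, rng)
    spec = DataSpec(D=2, L=2, n_continuous=2, K=3)
    nets = build_networks(ArchitectureConfig(hidden_x=(4,), hidden_y=(4,), seed=0), spec)
    ds = sample_generative(p, nets, 20_000, seed=11)
    counts = np.bincount(ds.c_true, minlength=3)
    chi2 = ((counts - 20_000 * p.pi) ** 2 / (20_000 * p.pi)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=2)


def test_empty_generation_allowed(small_bundle, small_params):
    ds = sample_generative(small_params, small_bundle, 0, seed=0)
    assert ds.n_subjects == 0


def test_dimension_mismatch_rejected(small_bundle, rng):
    p = random_params(2, 5, rng)   # D=5 but nets expect D=2
    with pytest.raises(ValueError, match="D="):
        sample_generative(p, small_bundle, 3, seed=0)
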