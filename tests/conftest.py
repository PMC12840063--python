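"""Shared fixtures: tiny parameter sets, network bundles and datasets."""

import numpy as np
import pytest

from vada.data import FeatureKind, LongitudinalDataset
from vada.model import MixtureLatentParams
from vada.networks import ArchitectureConfig, DataSpec, build_networks


def random_params(K, D, rng) -> MixtureLatentParams:
    pi = rng.dirichlet(np.ones(K))
    return MixtureLatentParams(
        pi=pi,
        mu=rng.standard_normal((K, D)),
        sigma2=rng.uniform(0.3, 2.0, (K, D)),
        beta0=rng.standard_normal(K),
        beta=rng.standard_normal((K, D)),
        sigma2_u=rng.uniform(0.3, 2.0, K),
    )


def zero_net(net):
    """Zero every weight/bias of a DenseNet (affine identity checks)."""
    net.set_weights([np.zeros_like(w) for w in net.get_weights()])
    return net


def random_dataset(n, L, P, rng, categorical=()):
    """Continuous covariates plus optional categorical features."""
    kinds = [FeatureKind(f"x{j}") for j in range(P)]
    mats = [rng.standard_normal((n, L, P))]
    for i, g in enumerate(categorical):
        codes = rng.integers(0, g, size=(n, L))
        onehot = np.zeros((n, L, g))
        onehot[np.arange(n)[:, None], np.arange(L)[None, :], codes] = 1.0
        mats.append(onehot)
        kinds.append(FeatureKind(f"c{i}", tuple(range(g))))
    X = np.concatenate(mats, axis=2)
    y = rng.standard_normal((n, L))
    return LongitudinalDataset(np.arange(1, n + 1), X, kinds, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bundle():
    """Nets for L=3, P=4 continuous, D=2, real outcome."""
    spec = DataSpec(D=2, L=3, n_continuous=4, K=2)
    return build_networks(ArchitectureConfig(hidden_x=(8,), hidden_y=(5,), seed=3), spec)


@pytest.fixture
def small_params(rng):
    return random_params(K=2, D=2, rng=rng)
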