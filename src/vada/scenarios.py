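"""Synthetic benchmark scenarios with ground-truth cluster labels.

Four generating mechanisms are provided, coded by two switches: whether
the covariates come from a nonlinear decoder of latent codes (first
digit 1) or directly from a Gaussian mixture in feature space (first
digit 0), and whether the outcomes are mixed across measurements by a
nonlinear Y-decoder (second digit 1) or are conditionally independent
given the latent state (second digit 0):

* ``11`` — well-specified: latent codes from three separated cluster
  Gaussians; covariates from a frozen random X-decoder net; pure
  outcomes cluster-linear in the codes; outcomes from a frozen random
  Y-decoder net applied to the whole pure-outcome vector (within-subject
  dependence, nonlinear overall effect).
* ``01`` — covariates as in 11; each outcome is an independent
  cluster-specific nonlinear map of its own latent code.
* ``10`` — covariates drawn directly from a diagonal-covariance Gaussian
  mixture in the P-dimensional space; pure outcomes cluster-linear in
  the informative coordinates; outcomes via the Y-decoder net.
* ``00`` — covariates as in 10; outcomes follow a simple per-cluster
  linear regression on the signal-carrying covariates, independent
  across measurements.

Defaults emulate a regime of well-separated clusters and small
irreducible noise: three equally likely clusters whose means sit at
distance ``separation`` from the origin along random orthogonal
directions (unit component variances), cluster effect vectors with
standard-normal entries, and all noise standard deviations 0.2 on the
scale of a unit-variance signal — every emitted signal (covariate
columns, pure outcomes, outcomes) is standardized before its noise is
added, so noise levels are directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureKind, LongitudinalDataset

__all__ = ["ScenarioConfig", "GeneratingTruth", "generate_scenario"]

SCENARIO_CODES = ("11", "01", "10", "00")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; the defaults are the benchmark conditions."""

    code: str
    n_subjects: int = 2500
    L: int = 4
    P: int = 100
    K_true: int = 3
    D_true: int = 10
    separation: float = 6.0
    x_noise: float = 0.2
    u_noise: float = 0.2
    y_noise: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.code not in SCENARIO_CODES:
            raise ValueError(f"scenario code must be one of {SCENARIO_CODES}")
        if min(self.n_subjects, self.L, self.P, self.K_true, self.D_true) < 1:
            raise ValueError("all counts must be >= 1")
        if self.K_true > self.D_true:
            raise ValueError("need K_true <= D_true for orthogonal cluster directions")


@dataclass
class GeneratingTruth:
    """The parameters actually used to generate a scenario dataset."""

    config: ScenarioConfig
    pi: np.ndarray
    mu: np.ndarray               # (K, D_true) latent (or informative-block) means
    beta0: np.ndarray            # (K,)
    beta: np.ndarray             # (K, D_true) effects on the latent/informative block
    informative: np.ndarray | None   # feature indices carrying cluster signal (10/00)

    @property
    def irreducible_y_variance(self) -> float:
        """Outcome-noise variance on the emitted scale (unit-variance signal)."""
        return self.config.y_noise ** 2

    def irreducible_mse_standardized(self) -> float:
        """Lower bound for prediction MSE after the outcome is re-scaled to
        unit total variance (signal variance 1 + noise variance)."""
        v = self.irreducible_y_variance
        return v / (1.0 + v)


def _standardize_signal(a: np.ndarray, axis) -> np.ndarray:
    m = a.mean(axis=axis, keepdims=True)
    s = a.std(axis=axis, keepdims=True)
    return (a - m) / np.where(s <= 1e-12, 1.0, s)


def _orthogonal_directions(rng, dim: int, k: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q[:, :k].T                      # (k, dim) orthonormal rows


class _RandomMlp:
    """Frozen random one-hidden-layer tanh map, Glorot-initialized."""

    def __init__(self, rng, in_dim: int, hidden: int, out_dim: int):
        def glorot(fi, fo):
            lim = np.sqrt(6.0 / (fi + fo))
            return rng.uniform(-lim, lim, size=(fi, fo))
        self.w1, self.b1 = glorot(in_dim, hidden), np.zeros(hidden)
        self.w2, self.b2 = glorot(hidden, out_dim), np.zeros(out_dim)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.tanh(x @ self.w1 + self.b1) @ self.w2 + self.b2


def generate_scenario(config: ScenarioConfig):
    """Generate one scenario dataset; returns ``(dataset, truth)``.

    Deterministic per seed.  The generating decoder nets share the
    default architecture widths of the model's networks but are frozen
    random draws, never the fitted model's nets.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L, P, K, D = cfg.n_subjects, cfg.L, cfg.P, cfg.K_true, cfg.D_true

    pi = np.full(K, 1.0 / K)
    c = rng.choice(K, size=n, p=pi)
    beta0 = rng.standard_normal(K)
    beta = rng.standard_normal((K, D))

    if cfg.code in ("11", "01"):
        # latent codes from separated cluster Gaussians
        mu = cfg.separation * _orthogonal_directions(rng, D, K)
        Z = mu[c][:, None, :] + rng.standard_normal((n, L, D))
        x_net = _RandomMlp(rng, D, 64, P)
        x_signal = _standardize_signal(x_net(Z), axis=(0, 1))
        X = x_signal + cfg.x_noise * rng.standard_normal((n, L, P))
        informative = None
    else:
        # covariates directly from a diagonal Gaussian mixture in P-space:
        # cluster means live in an informative block of D coordinates
        informative = np.arange(D)
        mu = cfg.separation * _orthogonal_directions(rng, D, K)
        means_full = np.zeros((K, P))
        means_full[:, informative] = mu
        X = means_full[c][:, None, :] + rng.standard_normal((n, L, P))
        Z = X[:, :, informative]

    if cfg.code == "11":
        u_signal = _standardize_signal(
            beta0[c][:, None] + np.einsum("nld,nd->nl", Z, beta[c]), axis=None)
        u = u_signal + cfg.u_noise * rng.standard_normal((n, L))
        y_net = _RandomMlp(rng, L, 16, L)
        y_signal = _standardize_signal(y_net(u), axis=None)
        y = y_signal + cfg.y_noise * rng.standard_normal((n, L))
    elif cfg.code == "01":
        # independent outcomes: per-cluster nonlinear map of each z_l
        maps = [_RandomMlp(rng, D, 16, 1) for _ in range(K)]
        raw = np.empty((n, L))
        for k in range(K):
            idx = c == k
            raw[idx] = maps[k](Z[idx].reshape(-1, D)).reshape(-1, L)
        y_signal = _standardize_signal(raw, axis=None)
        y = y_signal + cfg.y_noise * rng.standard_normal((n, L))
        u = None
    elif cfg.code == "10":
        u_signal = _standardize_signal(
            beta0[c][:, None] + np.einsum("nld,nd->nl", Z, beta[c]), axis=None)
        u = u_signal + cfg.u_noise * rng.standard_normal((n, L))
        y_net = _RandomMlp(rng, L, 16, L)
        y_signal = _standardize_signal(y_net(u), axis=None)
        y = y_signal + cfg.y_noise * rng.standard_normal((n, L))
    else:  # "00": per-cluster linear regression on the informative covariates
        raw = beta0[c][:, None] + np.einsum("nld,nd->nl", Z, beta[c])
        y_signal = _standardize_signal(raw, axis=None)
        y = y_signal + cfg.y_noise * rng.standard_normal((n, L))
        u = None

    kinds = [FeatureKind(f"x{j + 1}") for j in range(P)]
    dataset = LongitudinalDataset(
        subject_ids=np.arange(1, n + 1), X=X, feature_kinds=kinds, y=y,
        c_true=c, Z_true=Z if cfg.code in ("11", "01") else None, u_true=u)
    truth = GeneratingTruth(config=cfg, pi=pi, mu=mu, beta0=beta0, beta=beta,
                            informative=informative)
    return dataset, truth
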