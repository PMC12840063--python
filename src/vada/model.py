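"""Generative core: mixture-prior parameters, densities and forward sampling.

The generative process for one subject is hierarchical:

1. a cluster label ``c ~ Cat(pi)``;
2. per measurement ``l``: a latent code ``z_l ~ N(mu_c, diag sigma2_c)``,
   covariates ``x_l`` from the X-decoder heads applied to ``z_l``, and a
   "pure outcome" ``u_l ~ N(beta0_c + z_l' beta_c, sigma2_u_c)`` — the
   cluster-specific linear marginal model in the latent space;
3. the observed outcome vector ``y`` from the Y-decoder applied to the
   whole vector ``u`` — the step that makes the L measurements of a
   subject dependent.

This module owns the parameter set H = (pi, mu, sigma2, beta, sigma2_u),
the cluster-posterior function h(u, Z, c; H), the complete-data
log-likelihood, and exact forward sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, softmax
from .data import FeatureKind, LongitudinalDataset
from .networks import (NetworkBundle, VAR_FLOOR, apply_x_decoder, apply_y_decoder)

__all__ = [
    "MixtureLatentParams", "TrainableMixture", "cluster_log_joint",
    "responsibilities", "complete_data_loglik", "sample_generative",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureLatentParams:
    """Prior weights, component Gaussians and per-cluster marginal models.

    ``pi`` (K,), ``mu`` (K, D), ``sigma2`` (K, D), ``beta0`` (K,),
    ``beta`` (K, D), ``sigma2_u`` (K,).
    """

    pi: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    beta0: np.ndarray
    beta: np.ndarray
    sigma2_u: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma2 = np.atleast_2d(np.asarray(self.sigma2, dtype=float))
        self.beta0 = np.asarray(self.beta0, dtype=float).reshape(-1)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma2_u = np.asarray(self.sigma2_u, dtype=float).reshape(-1)
        k, d = self.mu.shape
        if self.pi.shape != (k,) or self.sigma2.shape != (k, d) \
                or self.beta0.shape != (k,) or self.beta.shape != (k, d) \
                or self.sigma2_u.shape != (k,):
            raise ValueError("inconsistent mixture parameter shapes")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability simplex (sum 1 within 1e-8)")
        if (self.sigma2 <= 0).any() or (self.sigma2_u <= 0).any():
            raise ValueError("all variances must be strictly positive")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def D(self) -> int:
        return self.mu.shape[1]

    def permute(self, order) -> "MixtureLatentParams":
        """Relabel components; the model it defines is unchanged."""
        o = np.asarray(order)
        return MixtureLatentParams(self.pi[o], self.mu[o], self.sigma2[o],
                                   self.beta0[o], self.beta[o], self.sigma2_u[o])


class TrainableMixture:
    """Unconstrained parameterization of :class:`MixtureLatentParams`.

    pi via softmax over logits; variances via exponentiated logs — so the
    optimizer works on an unconstrained space while the simplex/positivity
    invariants hold by construction.
    """

    def __init__(self, pi_logits, mu, log_sigma2, beta0, beta, log_sigma2_u):
        self.pi_logits = Tensor(pi_logits, requires_grad=True)
        self.mu = Tensor(mu, requires_grad=True)
        self.log_sigma2 = Tensor(log_sigma2, requires_grad=True)
        self.beta0 = Tensor(beta0, requires_grad=True)
        self.beta = Tensor(beta, requires_grad=True)
        self.log_sigma2_u = Tensor(log_sigma2_u, requires_grad=True)

    @classmethod
    def init(cls, K: int, D: int, seed: int) -> "TrainableMixture":
        """No-pretraining initialization: uniform pi, unit variances,
        standard-normal component means, small random marginal effects."""
        rng = np.random.default_rng(seed)
        return cls(np.zeros(K), rng.standard_normal((K, D)), np.zeros((K, D)),
                   rng.normal(0.0, 0.1, K), rng.normal(0.0, 0.1, (K, D)), np.zeros(K))

    @classmethod
    def from_params(cls, p: MixtureLatentParams) -> "TrainableMixture":
        return cls(np.log(np.maximum(p.pi, 1e-300)), p.mu.copy(), np.log(p.sigma2),
                   p.beta0.copy(), p.beta.copy(), np.log(p.sigma2_u))

    # constrained views (Tensors on the tape) ---------------------------------
    def pi(self) -> Tensor:
        return softmax(self.pi_logits, axis=-1)

    def sigma2(self) -> Tensor:
        return self.log_sigma2.exp().clamp_min(VAR_FLOOR)

    def sigma2_u(self) -> Tensor:
        return self.log_sigma2_u.exp().clamp_min(VAR_FLOOR)

    def parameters(self):
        return [self.pi_logits, self.mu, self.log_sigma2,
                self.beta0, self.beta, self.log_sigma2_u]

    def astype(self, dtype) -> None:
        for p in self.parameters():
            p.value = p.value.astype(dtype)

    def to_params(self) -> MixtureLatentParams:
        pi = self.pi().value.astype(float)
        return MixtureLatentParams(pi / pi.sum(), self.mu.value, self.sigma2().value,
                                   self.beta0.value, self.beta.value, self.sigma2_u().value)


def cluster_log_joint(u, Z, mix) -> Tensor:
    """log[p(u|Z,c=k) p(Z|c=k) pi_k] for every k, vectorized over a batch.

    ``u`` has shape (..., L), ``Z`` shape (..., L, D); the result has
    shape (..., K).  ``mix`` may be a :class:`TrainableMixture` (gradients
    flow into H) or a :class:`MixtureLatentParams` (constants).
    """
    if isinstance(mix, TrainableMixture):
        pi, mu, s2, b0, b, s2u = (mix.pi(), mix.mu, mix.sigma2(),
                                  mix.beta0, mix.beta, mix.sigma2_u())
    else:
        pi, mu, s2, b0, b, s2u = map(as_tensor, (mix.pi, mix.mu, mix.sigma2,
                                                 mix.beta0, mix.beta, mix.sigma2_u))
    u, Z = as_tensor(u), as_tensor(Z)
    L = u.shape[-1]
    D = Z.shape[-1]
    # p(u | Z, c): N(u_l; beta0_k + z_l' beta_k, sigma2_u_k), product over l
    u_mean = Z @ b.T + b0                                  # (..., L, K)
    resid2 = (u.reshape(u.shape + (1,)) - u_mean) ** 2     # (..., L, K)
    lp_u = -0.5 * ((resid2 / s2u).sum(axis=-2)
                   + L * (s2u.log() + _LOG2PI))            # (..., K)
    # p(Z | c): N(z_ld; mu_kd, sigma2_kd), product over l, d
    diff2 = (Z.reshape(Z.shape[:-1] + (1, D)) - mu) ** 2   # (..., L, K, D)
    lp_z = -0.5 * ((diff2 / s2).sum(axis=-3).sum(axis=-1)
                   + L * (s2.log().sum(axis=-1) + D * _LOG2PI))
    return lp_u + lp_z + pi.clamp_min(1e-30).log()


def responsibilities(u: np.ndarray, Z: np.ndarray,
                     params: MixtureLatentParams) -> np.ndarray:
    """Cluster posterior h(u, Z, ·; H) for one subject: a K-simplex.

    Computed in log space with max subtraction, so it is invariant to a
    common rescaling of the unnormalized component densities.
    """
    u = np.asarray(u, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not (np.isfinite(u).all() and np.isfinite(Z).all()):
        raise ValueError("responsibilities requires finite inputs")
    log_joint = cluster_log_joint(u, Z, params).value
    if not np.isfinite(log_joint).all():
        bad = int(np.where(~np.isfinite(log_joint))[0][0])
        raise FloatingPointError(f"non-finite component density for cluster {bad}; "
                                 "check the variance floor")
    w = np.exp(log_joint - log_joint.max())
    return w / w.sum()


def _gaussian_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


def complete_data_loglik(y, u, X, Z, c, params: MixtureLatentParams,
                         nets: NetworkBundle) -> float:
    """log p(y, u, X, Z, c) for a single subject.

    Sum of the factor log-densities: p(y|u), p(u_l|z_l,c), p(x_l|z_l),
    p(z_l|c) and p(c).
    """
    y = np.asarray(y)
    u = np.asarray(u, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    c = int(c)
    if not 0 <= c < params.K:
        raise ValueError(f"cluster label {c} out of range 0..{params.K - 1}")
    L = len(u)
    spec = nets.spec

    total = float(np.log(params.pi[c]))
    total += _gaussian_logpdf(Z, params.mu[c], params.sigma2[c]).sum()
    u_mean = params.beta0[c] + Z @ params.beta[c]
    total += _gaussian_logpdf(u, u_mean, params.sigma2_u[c]).sum()

    dec = apply_x_decoder(nets, Z)  # heads over (L, ...) measurements
    col = 0
    if spec.n_continuous:
        total += _gaussian_logpdf(X[:, :spec.n_continuous], dec["mean"],
                                  dec["sigma2"]).sum()
        col = spec.n_continuous
    for i, g in enumerate(spec.categorical_levels):
        onehot = X[:, col:col + g]
        idx = onehot.argmax(axis=1)
        if not np.allclose(onehot.sum(axis=1), 1.0):
            raise ValueError(f"categorical feature block {i} is not one-hot")
        total += np.log(dec["probs"][i][np.arange(L), idx]).sum()
        col += g

    if spec.outcome_kind == "real":
        mean, var = apply_y_decoder(nets, u)
        total += _gaussian_logpdf(y.astype(float), mean, var).sum()
    else:
        yi = y.astype(int)
        if ((yi < 0) | (yi >= spec.outcome_levels)).any():
            raise ValueError("outcome category index out of declared range")
        probs = apply_y_decoder(nets, u)
        total += np.log(probs[np.arange(L), yi]).sum()
    return float(total)


def sample_generative(params: MixtureLatentParams, nets: NetworkBundle,
                      n_subjects: int, seed: int) -> LongitudinalDataset:
    """Draw ``n_subjects`` complete trajectories from the generative process.

    Deterministic given ``seed``; ground-truth labels, latent codes and
    pure outcomes are stored on the returned dataset.
    """
    spec = nets.spec
    if params.D != spec.D:
        raise ValueError(f"params have D={params.D} but networks expect D={spec.D}")
    if n_subjects < 0:
        raise ValueError("n_subjects must be >= 0")
    rng = np.random.default_rng(seed)
    n, L, D, K = n_subjects, spec.L, spec.D, params.K

    c = rng.choice(K, size=n, p=params.pi)
    Z = params.mu[c][:, None, :] + np.sqrt(params.sigma2[c])[:, None, :] \
        * rng.standard_normal((n, L, D))

    dec = apply_x_decoder(nets, Z)
    cols = []
    kinds = []
    if spec.n_continuous:
        x_con = dec["mean"] + np.sqrt(dec["sigma2"]) * rng.standard_normal(
            (n, L, spec.n_continuous))
        cols.append(x_con)
        kinds += [FeatureKind(f"x{j + 1}") for j in range(spec.n_continuous)]
    for i, g in enumerate(spec.categorical_levels):
        p = dec["probs"][i].reshape(n * L, g)
        cum = np.cumsum(p, axis=1)
        draws = (rng.random((n * L, 1)) < cum).argmax(axis=1)
        onehot = np.zeros((n * L, g))
        onehot[np.arange(n * L), draws] = 1.0
        cols.append(onehot.reshape(n, L, g))
        kinds.append(FeatureKind(f"xc{i + 1}", tuple(range(g))))
    X = np.concatenate(cols, axis=2) if cols else np.zeros((n, L, 0))

    u_mean = params.beta0[c][:, None] + np.einsum("nld,nd->nl", Z, params.beta[c])
    u = u_mean + np.sqrt(params.sigma2_u[c])[:, None] * rng.standard_normal((n, L))

    if spec.outcome_kind == "real":
        y_mean, y_var = apply_y_decoder(nets, u)
        y = y_mean + np.sqrt(y_var) * rng.standard_normal((n, L))
        out_kind, out_cats = "real", None
    else:
        probs = apply_y_decoder(nets, u)       # (n, L, G)
        cum = np.cumsum(probs, axis=-1)
        y = (rng.random((n, L, 1)) < cum).argmax(axis=-1)
        out_kind, out_cats = "categorical", tuple(range(spec.outcome_levels))

    return LongitudinalDataset(
        subject_ids=np.arange(1, n + 1), X=X, feature_kinds=kinds, y=y,
        outcome_kind=out_kind, outcome_categories=out_cats,
        c_true=c, Z_true=Z, u_true=u)
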