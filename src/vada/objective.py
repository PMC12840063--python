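"""The variational training objective.

The evidence lower bound for one subject decomposes into an outcome
reconstruction term, a covariate reconstruction term, and a KL
divergence from the mixture prior over (u, Z, c) to the mean-field
posterior.  Reconstruction terms are estimated by Monte Carlo with the
reparameterization trick (u = mu + sigma * eps); the cluster posterior
pi_tilde is the M-sample average of the responsibility function
h(u, Z, ·; H); given pi_tilde, the KL term has a closed form.

The closed-form KL is evaluated exactly as printed in its five-part
form, which equals the true KL divergence plus the constant
(L + L*D)/2 — the per-dimension -1/2 terms are folded out.  The offset
does not affect gradients; callers comparing against an MC estimate of
the true KL must subtract it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, gaussian_logpdf, softmax
from .data import LongitudinalDataset
from .model import TrainableMixture, MixtureLatentParams, cluster_log_joint
from .networks import NetworkBundle, apply_x_encoder, apply_y_encoder, apply_x_decoder, apply_y_decoder

__all__ = ["VariationalState", "ElboBreakdown", "encode_state",
           "reparameterized_samples", "reconstruction_terms",
           "mixture_posterior", "kl_term", "elbo", "kl_offset"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VariationalState:
    """Per-subject posterior summaries.

    ``mu_z``/``sigma2_z``: (N, L, D); ``mu_u``/``sigma2_u_post``: (N, L);
    ``pi_tilde``: (N, K) responsibilities (may be ``None`` before the
    mixture posterior has been formed).
    """

    mu_z: np.ndarray
    sigma2_z: np.ndarray
    mu_u: np.ndarray
    sigma2_u_post: np.ndarray
    pi_tilde: np.ndarray | None = None

    def __post_init__(self):
        if (np.asarray(self.sigma2_z) <= 0).any() or (np.asarray(self.sigma2_u_post) <= 0).any():
            raise ValueError("posterior variances must be positive")
        if self.pi_tilde is not None:
            rows = np.asarray(self.pi_tilde).sum(axis=-1)
            if np.abs(rows - 1.0).max() > 1e-6:
                raise ValueError("pi_tilde rows must sum to 1 within 1e-6")


class _TensorState:
    """Posterior summaries kept on the autodiff tape during training."""

    __slots__ = ("mu_z", "sigma2_z", "mu_u", "sigma2_u")

    def __init__(self, mu_z, sigma2_z, mu_u, sigma2_u):
        self.mu_z, self.sigma2_z = mu_z, sigma2_z
        self.mu_u, self.sigma2_u = mu_u, sigma2_u


@dataclass
class ElboBreakdown:
    """Per-subject batch averages; elbo = recon_y + recon_x - kl."""

    recon_y: float
    recon_x: float
    kl: float
    elbo: float


def kl_offset(L: int, D: int) -> float:
    """Constant by which the closed-form KL exceeds the true divergence."""
    return (L + L * D) / 2.0


def _as_state(state) -> _TensorState:
    if isinstance(state, _TensorState):
        return state
    return _TensorState(as_tensor(state.mu_z), as_tensor(state.sigma2_z),
                        as_tensor(state.mu_u), as_tensor(state.sigma2_u_post))


def encode_state(nets: NetworkBundle, X, y) -> _TensorState:
    """Run both encoders: X (N, L, P) and y (N, L) -> posterior summaries."""
    X = np.asarray(X)
    y = np.asarray(y)
    if y.dtype.kind != "f":
        y = y.astype(X.dtype if X.dtype.kind == "f" else float)
    mu_z, s2_z = apply_x_encoder(nets, as_tensor(X), raw=True)
    mu_u, s2_u = apply_y_encoder(nets, as_tensor(y), raw=True)
    return _TensorState(mu_z, s2_z, mu_u, s2_u)


def reparameterized_samples(state, M: int, seed: int):
    """Draw M reparameterized samples of (u, Z): shapes (M, N, L) / (M, N, L, D).

    Samples are differentiable w.r.t. the posterior means/variances and
    deterministic given ``seed``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    st = _as_state(state)
    rng = np.random.default_rng(seed)
    n, L, D = st.mu_z.shape
    dt = st.mu_z.value.dtype if st.mu_z.value.dtype in (np.float32, np.float64) else np.float64
    eps_u = rng.standard_normal((M, n, L), dtype=dt)
    eps_z = rng.standard_normal((M, n, L, D), dtype=dt)
    u = st.mu_u + st.sigma2_u.sqrt() * Tensor(eps_u)
    Z = st.mu_z + st.sigma2_z.sqrt() * Tensor(eps_z)
    return u, Z


def _log_onehot_prob(probs: Tensor, onehot: np.ndarray) -> Tensor:
    return (Tensor(onehot) * probs.clamp_min(1e-30).log()).sum(axis=-1)


def reconstruction_terms(batch: LongitudinalDataset, nets: NetworkBundle,
                         samples, M: int):
    """MC estimates of E_q log p(y|u) and sum_l E_q log p(x_l|z_l).

    Returns per-subject batch averages as Tensors ``(recon_y, recon_x)``.
    For a real outcome the y-term is the Gaussian log-density under the
    Y-decoder heads; for a categorical outcome it is the negative
    cross-entropy.  The x-term mixes Gaussian log-densities over the
    continuous features and categorical log-probabilities.
    """
    u_s, Z_s = samples
    spec = nets.spec
    n, L = batch.n_subjects, batch.n_measurements

    # ---- outcome branch
    if spec.outcome_kind == "real":
        y = np.asarray(batch.y)
        if y.dtype.kind != "f":
            y = y.astype(batch.X.dtype)
        mean, var = apply_y_decoder(nets, u_s, raw=True)     # (M, N, L)
        ll = gaussian_logpdf(y, mean, var)
        recon_y = ll.sum(axis=-1).mean(axis=0).mean()
    else:
        g = spec.outcome_levels
        onehot = np.eye(g, dtype=batch.X.dtype)[batch.y.astype(int)]   # (N, L, G)
        probs = apply_y_decoder(nets, u_s, raw=True)         # (M, N, L, G)
        recon_y = _log_onehot_prob(probs, onehot).sum(axis=-1).mean(axis=0).mean()

    # ---- covariate branch
    dec = apply_x_decoder(nets, Z_s, raw=True)
    X = batch.X
    total = None
    if spec.n_continuous:
        ll = gaussian_logpdf(X[:, :, :spec.n_continuous], dec["mean"], dec["sigma2"])
        total = ll.sum(axis=-1)                              # (M, N, L)
    col = spec.n_continuous
    for i, g in enumerate(spec.categorical_levels):
        term = _log_onehot_prob(dec["probs"][i], X[:, :, col:col + g])
        total = term if total is None else total + term
        col += g
    recon_x = total.sum(axis=-1).mean(axis=0).mean()
    return recon_y, recon_x


def mixture_posterior(samples, mix, M: int) -> Tensor:
    """pi_tilde: (N, K) — M-sample average of the responsibilities h.

    Gradients flow through h into the mixture parameters (no
    stop-gradient), following the VaDE lineage.
    """
    u_s, Z_s = samples
    log_joint = cluster_log_joint(u_s, Z_s, mix)             # (M, N, K)
    resp = softmax(log_joint, axis=-1)
    return resp.mean(axis=0)


def kl_term(state, pi_tilde, mix) -> Tensor:
    """Closed-form KL term (five-part expression), batch mean per subject.

    Exceeds the true KL divergence by the constant ``kl_offset(L, D)``.
    """
    st = _as_state(state)
    pi_tilde = as_tensor(pi_tilde)
    if isinstance(mix, TrainableMixture):
        pi, mu, s2, b0, b, s2u = (mix.pi(), mix.mu, mix.sigma2(),
                                  mix.beta0, mix.beta, mix.sigma2_u())
    else:
        pi, mu, s2, b0, b, s2u = map(as_tensor, (mix.pi, mix.mu, mix.sigma2,
                                                 mix.beta0, mix.beta, mix.sigma2_u))
    n, L, D = st.mu_z.shape
    K = pi.shape[-1]

    # u part: per (subject, l, k) quadratic around the cluster marginal mean
    u_mean = st.mu_z @ b.T + b0                              # (N, L, K)
    du2 = (st.mu_u.reshape(n, L, 1) - u_mean) ** 2
    bvar = st.sigma2_z @ (b.T ** 2)                          # beta' diag(s2_z) beta
    quad_u = (du2 + st.sigma2_u.reshape(n, L, 1) + bvar) / s2u
    term_u = 0.5 * (pi_tilde * (quad_u + s2u.log()).sum(axis=1)).sum(axis=-1)

    # z part: per (subject, l, k, d)
    dz2 = (st.mu_z.reshape(n, L, 1, D) - mu) ** 2
    quad_z = (dz2 + st.sigma2_z.reshape(n, L, 1, D)) / s2
    inner = quad_z.sum(axis=-1).sum(axis=1) + L * s2.log().sum(axis=-1)  # (N, K)
    term_z = 0.5 * (pi_tilde * inner).sum(axis=-1)

    cross = -(pi_tilde * pi.clamp_min(1e-30).log()).sum(axis=-1)
    ent_u = -0.5 * st.sigma2_u.log().sum(axis=-1)
    ent_z = -0.5 * st.sigma2_z.log().sum(axis=-1).sum(axis=-1)
    ent_c = (pi_tilde * pi_tilde.clamp_min(1e-30).log()).sum(axis=-1)

    per_subject = term_u + term_z + cross + ent_u + ent_z + ent_c
    return per_subject.mean()


def elbo(batch: LongitudinalDataset, nets: NetworkBundle, mix,
         M: int = 1, seed: int = 0, return_tensor: bool = False):
    """Assemble the full objective on a batch of subjects.

    ``mix`` may be a TrainableMixture (training; gradients flow) or
    MixtureLatentParams (evaluation).  Returns an :class:`ElboBreakdown`
    of per-subject batch averages, or ``(breakdown, elbo_tensor)`` when
    ``return_tensor`` is set.
    """
    state = encode_state(nets, batch.X, batch.y)
    samples = reparameterized_samples(state, M, seed)
    recon_y, recon_x = reconstruction_terms(batch, nets, samples, M)
    pi_tilde = mixture_posterior(samples, mix, M)
    kl = kl_term(state, pi_tilde, mix)
    total = recon_y + recon_x - kl
    breakdown = ElboBreakdown(float(recon_y.value), float(recon_x.value),
                              float(kl.value), float(total.value))
    if return_tensor:
        return breakdown, total
    return breakdown
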