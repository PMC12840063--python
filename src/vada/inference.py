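"""Clustering rules, outcome prediction and representation extraction.

Two clustering rules are available after fitting: the complete-data rule
(outcomes observed) assigns each subject to the argmax of the
Monte-Carlo cluster posterior pi_tilde computed from both encoders; the
covariates-only rule uses the latent-code branch alone.  Outcome
prediction follows the three-step pipeline: encode covariates to the
posterior-mean representations, push them through each cluster's linear
marginal model to candidate pure outcomes, decode with the Y-decoder,
and mix the K candidate predictions by the covariates-only cluster
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LongitudinalDataset
from .model import MixtureLatentParams, cluster_log_joint, sample_generative
from .networks import NetworkBundle, apply_x_encoder, apply_y_decoder
from .objective import encode_state, reparameterized_samples, mixture_posterior

__all__ = ["PredictionResult", "encode_features", "cluster_yx", "cluster_x",
           "predict_outcomes", "generate_subjects"]

#: Monte-Carlo samples used at inference time (training uses M=1); a fixed
#: larger M stabilizes reported labels and probabilities.
DEFAULT_INFERENCE_M = 100

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PredictionResult:
    """Predictions plus cluster posteriors under both rules.

    ``cluster_probs_yx`` / ``labels_yx`` are ``None`` when outcomes were
    not supplied.  Hard labels are argmax with lowest-index tie-break.
    """

    y_hat: np.ndarray
    cluster_probs_x: np.ndarray
    labels_x: np.ndarray
    cluster_probs_yx: np.ndarray | None = None
    labels_yx: np.ndarray | None = None
    y_prob: np.ndarray | None = None     # (N, L, G) for categorical outcomes


def _as_X(data) -> np.ndarray:
    if isinstance(data, LongitudinalDataset):
        from .trainer import _reorder_columns
        return _reorder_columns(data).X
    return np.asarray(data, dtype=float)


def encode_features(nets: NetworkBundle, X) -> np.ndarray:
    """Latent representations z_hat = posterior means of the X-encoder."""
    mu_z, _ = apply_x_encoder(nets, _as_X(X))
    return mu_z


def cluster_yx(nets: NetworkBundle, params: MixtureLatentParams,
               dataset: LongitudinalDataset, M: int = DEFAULT_INFERENCE_M,
               seed: int = 0):
    """Complete-data clustering: argmax_k pi_tilde_k from both encoders.

    Returns ``(labels, probs)`` with probs of shape (N, K).
    """
    data = dataset
    X = _as_X(data)
    state = encode_state(nets, X, np.asarray(data.y, dtype=float))
    samples = reparameterized_samples(state, M, seed)
    probs = mixture_posterior(samples, params, M).value
    return probs.argmax(axis=1), probs


def _log_z_prior(Z: np.ndarray, params: MixtureLatentParams) -> np.ndarray:
    """log p(Z|c=k) + log pi_k for Z of shape (..., L, D); returns (..., K)."""
    L, D = Z.shape[-2:]
    diff2 = (Z[..., None, :] - params.mu) ** 2                    # (..., L, K, D)
    quad = (diff2 / params.sigma2).sum(axis=(-3, -1))
    const = L * (np.log(params.sigma2).sum(axis=1) + D * _LOG2PI)
    return -0.5 * (quad + const) + np.log(np.maximum(params.pi, 1e-300))


def cluster_x(nets: NetworkBundle, params: MixtureLatentParams, X,
              M: int = DEFAULT_INFERENCE_M, seed: int = 0):
    """Covariates-only clustering via the z-branch densities.

    q(c=k|X) is approximated by averaging the normalized
    p(Z|c=k) pi_k over M reparameterized samples of Z.
    """
    Xa = _as_X(X)
    mu_z, s2_z = apply_x_encoder(nets, Xa)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((M,) + mu_z.shape)
    Z = mu_z + np.sqrt(s2_z) * eps                                # (M, N, L, D)
    lj = _log_z_prior(Z, params)                                  # (M, N, K)
    lj -= lj.max(axis=-1, keepdims=True)
    w = np.exp(lj)
    probs = (w / w.sum(axis=-1, keepdims=True)).mean(axis=0)
    return probs.argmax(axis=1), probs


def predict_outcomes(nets: NetworkBundle, params: MixtureLatentParams, X,
                     M: int = DEFAULT_INFERENCE_M, seed: int = 0) -> PredictionResult:
    """Predict outcomes from covariates alone.

    z_hat = posterior means; u_hat^k = beta0_k + z_hat' beta_k;
    y_hat^k = Y-decoder mean head of u_hat^k; final prediction mixes the
    K candidates by q(c|X).
    """
    Xa = _as_X(X)
    z_hat = encode_features(nets, Xa)                             # (N, L, D)
    _, probs = cluster_x(nets, params, Xa, M=M, seed=seed)        # (N, K)
    u_k = z_hat @ params.beta.T + params.beta0                    # (N, L, K)
    u_k = np.moveaxis(u_k, -1, 0)                                 # (K, N, L)

    if nets.spec.outcome_kind == "real":
        y_k, _ = apply_y_decoder(nets, u_k)                       # (K, N, L)
        y_hat = np.einsum("nk,knl->nl", probs, y_k)
        return PredictionResult(y_hat=y_hat, cluster_probs_x=probs,
                                labels_x=probs.argmax(axis=1))
    probs_k = apply_y_decoder(nets, u_k)                          # (K, N, L, G)
    y_prob = np.einsum("nk,knlg->nlg", probs, probs_k)
    return PredictionResult(y_hat=y_prob.argmax(axis=-1), cluster_probs_x=probs,
                            labels_x=probs.argmax(axis=1), y_prob=y_prob)


def generate_subjects(nets: NetworkBundle, params: MixtureLatentParams,
                      n: int, seed: int) -> LongitudinalDataset:
    """Out-of-sample generation from the fitted model (delegates to the
    forward sampler)."""
    return sample_generative(params, nets, n, seed)
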