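"""Baseline comparison stack: VaDE, VAE, GMM clustering, PCA, cluster GEEs.

The baselines treat the N*L measurement rows as i.i.d. observations:

* ``VaDE+MM`` — a Gaussian-mixture-prior auto-encoder on the covariate
  rows; its representations and cluster probabilities feed
  cluster-specific marginal models.
* ``VAE+GMM+MM`` — a standard-normal-prior auto-encoder; a Gaussian
  mixture model is fitted to its representations for clustering.
* ``GMM+MM`` — a Gaussian mixture model on the raw standardized
  features.

Per-observation cluster probabilities are merged within subject (summed
over the L rows, argmax) to obtain one label per subject; embeddings are
projected to orthogonal principal components (guarding against rank
deficiency), and one marginal model per cluster is fitted by generalized
estimating equations under an independence, AR(1) or exchangeable
working correlation.  VaDE and VAE share the X-encoder/decoder
architecture of the main model; their KL terms use the exact divergence
convention, so a VaDE with one component and a VAE with a learned
Gaussian prior have identical objectives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Autoregressive, Exchangeable, Independence

from .autodiff import Adam, Tensor, softmax
from .data import LongitudinalDataset
from .model import TrainableMixture
from .networks import (ArchitectureConfig, DataSpec, VAR_FLOOR, build_networks,
                       apply_x_encoder)
from .objective import ElboBreakdown
from .trainer import TrainConfig, _reorder_columns, data_spec_for

__all__ = ["GeeSpec", "fit_vade", "fit_vae", "merge_subject_clusters",
           "pca_project", "PcaRotation", "fit_cluster_gee", "ClusterGeeFit",
           "BaselinePipeline", "baseline_predict", "VadeFit", "VaeFit"]

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# observation-level auto-encoders

def _obs_recon_and_state(nets, x_t: Tensor, seed: int):
    """Encoder state, one reparameterized z sample and the x reconstruction
    log-likelihood for a batch of observation rows."""
    from .networks import apply_x_decoder
    heads = nets.x_encoder.forward(x_t)
    mu, s2 = heads["mean"], heads["logvar"].exp().clamp_min(VAR_FLOOR)
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    z = mu + s2.sqrt() * Tensor(eps.astype(mu.value.dtype))
    dec = apply_x_decoder(nets, z, raw=True)
    spec = nets.spec
    total = None
    if spec.n_continuous:
        from .autodiff import gaussian_logpdf
        ll = gaussian_logpdf(x_t.value[..., :spec.n_continuous],
                             dec["mean"], dec["sigma2"])
        total = ll.sum(axis=-1)
    col = spec.n_continuous
    for i, g in enumerate(spec.categorical_levels):
        onehot = x_t[..., col:col + g]
        term = (onehot * dec["probs"][i].clamp_min(1e-30).log()).sum(axis=-1)
        total = term if total is None else total + term
        col += g
    return mu, s2, z, total


def _z_responsibilities(z: Tensor, pi: Tensor, mu_k: Tensor, s2_k: Tensor) -> Tensor:
    """softmax_k [log N(z; mu_k, s2_k) + log pi_k] for z of shape (..., D)."""
    D = z.shape[-1]
    diff2 = (z.reshape(z.shape[:-1] + (1, D)) - mu_k) ** 2
    lp = -0.5 * ((diff2 / s2_k).sum(axis=-1)
                 + s2_k.log().sum(axis=-1) + D * _LOG2PI)
    return softmax(lp + pi.clamp_min(1e-30).log(), axis=-1)


class VadeFit:
    """Fitted observation-level mixture auto-encoder."""

    def __init__(self, nets, mixture_params, history):
        self.nets = nets
        self.params = mixture_params        # MixtureLatentParams (beta unused)
        self.history = history

    def embed(self, X_obs: np.ndarray) -> np.ndarray:
        mu, _ = apply_x_encoder(self.nets, X_obs)
        return mu

    def obs_probs(self, X_obs: np.ndarray, M: int = 100, seed: int = 0) -> np.ndarray:
        """Per-observation cluster probabilities, averaged over M z-samples."""
        mu, s2 = apply_x_encoder(self.nets, X_obs)
        rng = np.random.default_rng(seed)
        z = mu + np.sqrt(s2) * rng.standard_normal((M,) + mu.shape)
        p = self.params
        diff2 = (z[..., None, :] - p.mu) ** 2
        lp = -0.5 * ((diff2 / p.sigma2).sum(axis=-1)
                     + np.log(p.sigma2).sum(axis=-1) + p.D * _LOG2PI)
        lp = lp + np.log(np.maximum(p.pi, 1e-300))
        lp -= lp.max(axis=-1, keepdims=True)
        w = np.exp(lp)
        return (w / w.sum(axis=-1, keepdims=True)).mean(axis=0)


class VaeFit:
    """Fitted standard-normal-prior auto-encoder."""

    def __init__(self, nets, history, prior_mu=None, prior_sigma2=None):
        self.nets = nets
        self.history = history
        self.prior_mu = prior_mu
        self.prior_sigma2 = prior_sigma2

    def embed(self, X_obs: np.ndarray) -> np.ndarray:
        mu, _ = apply_x_encoder(self.nets, X_obs)
        return mu


def vade_elbo_terms(nets, mix: "TrainableMixture", x_t: Tensor, seed: int):
    """(recon_x, kl) per observation for the mixture-prior auto-encoder.

    KL in the exact-divergence convention (zero when the posterior
    matches a single-component prior exactly).
    """
    mu, s2, z, recon = _obs_recon_and_state(nets, x_t, seed)
    pi, mu_k, s2_k = mix.pi(), mix.mu, mix.sigma2()
    gamma = _z_responsibilities(z, pi, mu_k, s2_k)
    D = mu.shape[-1]
    dz2 = (mu.reshape(mu.shape[:-1] + (1, D)) - mu_k) ** 2
    inner = ((dz2 + s2.reshape(s2.shape[:-1] + (1, D))) / s2_k
             + s2_k.log() - s2.reshape(s2.shape[:-1] + (1, D)).log() - 1.0)
    kl_z = 0.5 * (gamma * inner.sum(axis=-1)).sum(axis=-1)
    kl_c = (gamma * (gamma.clamp_min(1e-30).log()
                     - pi.clamp_min(1e-30).log())).sum(axis=-1)
    return recon.mean(), (kl_z + kl_c).mean()


def vae_elbo_terms(nets, x_t: Tensor, seed: int, prior_mu=None, prior_sigma2=None):
    """(recon_x, kl) per observation for the standard (or learned-prior) VAE."""
    mu, s2, z, recon = _obs_recon_and_state(nets, x_t, seed)
    if prior_mu is None:
        kl = 0.5 * (mu ** 2 + s2 - s2.log() - 1.0).sum(axis=-1)
    else:
        m0 = Tensor(np.asarray(prior_mu, dtype=float))
        v0 = Tensor(np.asarray(prior_sigma2, dtype=float))
        kl = 0.5 * (((mu - m0) ** 2 + s2) / v0 + v0.log() - s2.log() - 1.0).sum(axis=-1)
    return recon.mean(), kl.mean()


def _fit_obs_autoencoder(train_set: LongitudinalDataset, config: TrainConfig,
                         kind: str):
    data = _reorder_columns(train_set)
    n, L = data.n_subjects, data.n_measurements
    X_obs = data.X.reshape(n * L, -1).astype(np.float32)
    spec = data_spec_for(data, config.D, config.K)
    arch = config.arch or ArchitectureConfig(seed=config.seed)
    nets = build_networks(replace(arch, seed=config.seed), spec)
    for net in (nets.x_encoder, nets.x_decoder):
        net.astype(np.float32)
    mix = TrainableMixture.init(config.K, config.D, config.seed + 1)
    mix.astype(np.float32)

    x_params = list(nets.x_encoder.parameters()) + list(nets.x_decoder.parameters())
    if kind == "vade":
        trainable = x_params + [mix.pi_logits, mix.mu, mix.log_sigma2]
    else:
        trainable = x_params
    opt = Adam(trainable, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 2)
    batch = config.batch_subjects * L          # 128 subjects -> 512 observations
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n * L)
        sums = np.zeros(2)
        n_b = 0
        for start in range(0, n * L, batch):
            xb = Tensor(X_obs[order[start:start + batch]])
            seed = int(rng.integers(2 ** 31))
            if kind == "vade":
                recon, kl = vade_elbo_terms(nets, mix, xb, seed)
            else:
                recon, kl = vae_elbo_terms(nets, xb, seed)
            loss = kl - recon
            opt.zero_grad()
            loss.backward()
            opt.step()
            sums += (float(recon.value), float(kl.value))
            n_b += 1
        avg = sums / n_b
        history.append(ElboBreakdown(0.0, avg[0], avg[1], avg[0] - avg[1]))
    return nets, mix, history


def fit_vade(train_set: LongitudinalDataset, config: TrainConfig) -> VadeFit:
    """Train the mixture-prior auto-encoder on i.i.d. observation rows."""
    nets, mix, history = _fit_obs_autoencoder(train_set, config, "vade")
    return VadeFit(nets, mix.to_params(), history)


def fit_vae(train_set: LongitudinalDataset, config: TrainConfig) -> VaeFit:
    """Train the standard-normal-prior auto-encoder on observation rows."""
    nets, _, history = _fit_obs_autoencoder(train_set, config, "vae")
    return VaeFit(nets, history)


# --------------------------------------------------------------------------
# subject merging, PCA, GEE

def merge_subject_clusters(probs: np.ndarray, subject_ids):
    """Merge per-observation cluster probabilities into subject labels.

    Probabilities are summed over each subject's rows; the label is the
    argmax (lowest index on ties).  Returns ``(labels, subjects)`` with
    subjects in order of first appearance.
    """
    probs = np.asarray(probs, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if probs.shape[0] != len(subject_ids):
        raise ValueError("probs rows must align with subject_ids")
    subjects, inverse = np.unique(subject_ids, return_inverse=True)
    order = np.argsort([np.flatnonzero(subject_ids == s)[0] for s in subjects])
    totals = np.zeros((len(subjects), probs.shape[1]))
    np.add.at(totals, inverse, probs)
    subjects, totals = subjects[order], totals[order]
    return totals.argmax(axis=1), subjects


@dataclass
class PcaRotation:
    mean: np.ndarray
    components: np.ndarray      # (m, P) orthonormal rows
    explained_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T


def pca_project(features: np.ndarray, variance_kept: float = 0.9999):
    """Project to orthogonal principal components.

    Keeps the smallest number of components reaching ``variance_kept``
    cumulative variance, then drops components with eigenvalue below
    1e-8 (rank-deficiency guard).  Returns ``(scores, rotation)``.
    """
    X = np.asarray(features, dtype=float)
    pca = PCA(svd_solver="full").fit(X)
    ev = pca.explained_variance_
    cum = np.cumsum(ev) / max(ev.sum(), np.finfo(float).tiny)
    m = int(np.searchsorted(cum, variance_kept) + 1)
    m = min(m, len(ev))
    keep = np.flatnonzero(ev[:m] >= 1e-8)
    if len(keep) == 0:
        keep = np.array([0])
    rot = PcaRotation(pca.mean_, pca.components_[keep], ev[keep])
    return rot.transform(X), rot


@dataclass(frozen=True)
class GeeSpec:
    """Working correlation and link for the cluster-specific marginal models."""

    working: str = "mm2"        # mm0=independence, mm1=ar1, mm2=exchangeable
    link: str = "identity"      # identity | logit
    max_iter: int = 60
    tol: float = 1e-6

    _ALIASES = {"mm0": "independence", "mm1": "ar1", "mm2": "exchangeable",
                "independence": "independence", "ar1": "ar1",
                "exchangeable": "exchangeable"}

    @property
    def structure(self) -> str:
        try:
            return self._ALIASES[self.working.lower()]
        except KeyError:
            raise ValueError(f"unknown working correlation {self.working!r}")

    def cov_struct(self):
        return {"independence": Independence,
                "ar1": lambda: Autoregressive(grid=True),
                "exchangeable": Exchangeable}[self.structure]()

    def family(self):
        if self.link == "identity":
            return sm.families.Gaussian()
        if self.link == "logit":
            return sm.families.Binomial()
        raise ValueError(f"unknown link {self.link!r}")


class ClusterGeeFit:
    """One GEE system per cluster; prediction applies the inverse link."""

    def __init__(self, coefs: dict, spec: GeeSpec, dep_params: dict):
        self.coefs = coefs             # cluster -> coefficient vector (incl. intercept)
        self.spec = spec
        self.dep_params = dep_params   # cluster -> working-correlation estimate

    @property
    def clusters(self):
        return sorted(self.coefs)

    def predict(self, features: np.ndarray, cluster: int) -> np.ndarray:
        beta = self.coefs[cluster]
        eta = beta[0] + np.asarray(features) @ beta[1:]
        if self.spec.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def fit_cluster_gee(train_set: LongitudinalDataset, labels: np.ndarray, K: int,
                    spec: GeeSpec, features: np.ndarray | None = None) -> ClusterGeeFit:
    """Fit one GEE per cluster on that cluster's subjects.

    ``labels`` is one hard label per subject; ``features`` the
    per-observation design (defaults to the flattened covariates).
    Empty clusters are dropped with a warning.
    """
    n, L = train_set.n_subjects, train_set.n_measurements
    labels = np.asarray(labels)
    if features is None:
        features = _reorder_columns(train_set).X.reshape(n * L, -1)
    y = np.asarray(train_set.y, dtype=float).reshape(n * L)
    groups = np.repeat(np.arange(n), L)
    times = np.tile(np.arange(L), n)

    coefs, deps = {}, {}
    for k in range(K):
        subj = np.flatnonzero(labels == k)
        if len(subj) == 0:
            warnings.warn(f"cluster {k} is empty; dropped from prediction mixing")
            continue
        rows = (labels[groups] == k)
        exog = sm.add_constant(features[rows], has_constant="add")
        try:
            res = sm.GEE(y[rows], exog, groups=groups[rows], time=times[rows],
                         family=spec.family(), cov_struct=spec.cov_struct()
                         ).fit(maxiter=spec.max_iter, ctol=spec.tol)
        except (np.linalg.LinAlgError, ValueError) as e:
            raise RuntimeError(f"GEE fit failed for cluster {k}: {e}") from e
        coefs[k] = np.asarray(res.params)
        deps[k] = res.cov_struct.dep_params
    if not coefs:
        raise ValueError("all clusters are empty")
    return ClusterGeeFit(coefs, spec, deps)


# --------------------------------------------------------------------------
# end-to-end baseline pipelines

class BaselinePipeline:
    """One of the three baseline stacks: vade-mm | vae-gmm-mm | gmm-mm."""

    METHODS = ("vade-mm", "vae-gmm-mm", "gmm-mm")

    def __init__(self, method: str, K: int, D: int | None = None,
                 gee: GeeSpec | None = None,
                 train_config: TrainConfig | None = None,
                 variance_kept: float = 0.9999, seed: int = 0):
        if method not in self.METHODS:
            raise ValueError(f"method must be one of {self.METHODS}")
        self.method = method
        self.K = K
        self.D = D
        self.gee_spec = gee or GeeSpec()
        self.train_config = train_config
        self.variance_kept = variance_kept
        self.seed = seed
        self._fitted = False

    # -- stage helpers --------------------------------------------------------
    def _obs_matrix(self, dataset: LongitudinalDataset) -> np.ndarray:
        data = _reorder_columns(dataset)
        return data.X.reshape(data.n_subjects * data.n_measurements, -1)

    def _embed(self, X_obs: np.ndarray) -> np.ndarray:
        if self.method == "gmm-mm":
            return X_obs
        return self._ae.embed(X_obs)

    def _obs_probs(self, X_obs: np.ndarray, emb: np.ndarray) -> np.ndarray:
        if self.method == "vade-mm":
            return self._ae.obs_probs(X_obs, seed=self.seed)
        return self._gmm.predict_proba(emb)

    # -- fitting --------------------------------------------------------------
    def fit(self, train_set: LongitudinalDataset) -> "BaselinePipeline":
        X_obs = self._obs_matrix(train_set)
        cfg = self.train_config
        if cfg is None and self.method != "gmm-mm":
            if self.D is None:
                raise ValueError("D (latent dimension) is required for "
                                 "auto-encoder baselines")
            cfg = TrainConfig(D=self.D, K=self.K, seed=self.seed)
        if self.method == "vade-mm":
            self._ae = fit_vade(train_set, cfg)
        elif self.method == "vae-gmm-mm":
            self._ae = fit_vae(train_set, cfg)
        emb = self._embed(X_obs)
        if self.method in ("vae-gmm-mm", "gmm-mm"):
            # several restarts: a single k-means init lands in poor optima
            # on well-separated high-dimensional mixtures often enough to
            # distort replicate averages
            self._gmm = GaussianMixture(n_components=self.K, covariance_type="full",
                                        n_init=5,
                                        random_state=self.seed).fit(emb)
        probs = self._obs_probs(X_obs, emb)
        n, L = train_set.n_subjects, train_set.n_measurements
        labels, _ = merge_subject_clusters(probs, np.repeat(np.arange(n), L))
        scores, self._rotation = pca_project(emb, self.variance_kept)
        self._gees = fit_cluster_gee(train_set, labels, self.K, self.gee_spec,
                                     features=scores)
        self.train_labels_ = labels
        self._fitted = True
        return self

    # -- prediction -----------------------------------------------------------
    def cluster(self, dataset: LongitudinalDataset) -> np.ndarray:
        """Subject labels for new data via the pipeline's clusterer + merging."""
        if not self._fitted:
            raise RuntimeError("pipeline is not fitted")
        X_obs = self._obs_matrix(dataset)
        emb = self._embed(X_obs)
        probs = self._obs_probs(X_obs, emb)
        n, L = dataset.n_subjects, dataset.n_measurements
        labels, _ = merge_subject_clusters(probs, np.repeat(np.arange(n), L))
        # subjects landing in a dropped (empty-at-fit) cluster fall back to
        # their best fitted cluster
        fitted = np.asarray(self._gees.clusters)
        bad = ~np.isin(labels, fitted)
        if bad.any():
            totals = np.add.reduceat(probs, np.arange(0, n * L, L), axis=0)
            labels[bad] = fitted[totals[np.ix_(bad, fitted)].argmax(axis=1)]
        return labels

    def predict(self, dataset: LongitudinalDataset):
        """Outcome predictions (N, L) plus subject labels for new data."""
        labels = self.cluster(dataset)
        emb = self._embed(self._obs_matrix(dataset))
        scores = self._rotation.transform(emb)
        n, L = dataset.n_subjects, dataset.n_measurements
        y_hat = np.empty(n * L)
        row_labels = np.repeat(labels, L)
        for k in self._gees.clusters:
            rows = row_labels == k
            if rows.any():
                y_hat[rows] = self._gees.predict(scores[rows], k)
        return y_hat.reshape(n, L), labels


def baseline_predict(pipeline: BaselinePipeline, test_set: LongitudinalDataset):
    """Predict outcomes for ``test_set`` with a fitted baseline pipeline."""
    return pipeline.predict(test_set)
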