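"""Standardization, subject-level splitting, and the training loop.

Training follows the stochastic auto-encoding variational Bayes recipe:
Adam at learning rate 1e-3 on the negated ELBO, batches of 128 subjects,
500 epochs, M = 1 Monte-Carlo sample, no pretraining.  Variables are
re-scaled to zero mean and unit variance before training; the
standardization statistics are computed on the training split only and
reused for held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .autodiff import Adam
from .data import LongitudinalDataset
from .model import TrainableMixture, MixtureLatentParams
from .networks import ArchitectureConfig, DataSpec, NetworkBundle, build_networks
from .objective import ElboBreakdown, elbo

__all__ = ["TrainConfig", "StandardizeStats", "standardize", "unstandardize_y",
           "split", "train", "TrainingDivergedError",
           "save_checkpoint", "load_checkpoint", "data_spec_for"]


@dataclass
class StandardizeStats:
    """Per-column means/sds for continuous covariates; scalars for a real outcome."""

    x_mean: np.ndarray           # (n_continuous_expanded_cols,)
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    constant_x: np.ndarray       # bool mask of zero-variance columns (centered only)
    y_standardized: bool


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    D: int
    K: int
    learning_rate: float = 0.001
    batch_subjects: int = 128
    epochs: int = 500
    M: int = 1
    optimizer: str = "adam"
    seed: int = 0
    standardize: bool = True
    arch: ArchitectureConfig | None = None
    dtype: str = "float32"   # training precision; "float64" for gradient studies
    #: epoch after which the latent mixture is warm-started from a k-means
    #: partition of the current embeddings (0 disables).  The networks are
    #: never pretrained; this only re-anchors the mixture parameters, which
    #: otherwise suffer the classic dead-component collapse of
    #: mixture-prior auto-encoders trained from a blind initialization.
    mixture_warmup: int = 50
    #: number of independently initialized candidate runs raced over the
    #: first ``race_epochs`` epochs; the candidate with the best training
    #: ELBO continues for the remaining epochs (multi-start guard against
    #: poor local optima, off by default).
    restarts: int = 1
    race_epochs: int = 100

    def __post_init__(self):
        if self.D < 1 or self.K < 1 or self.batch_subjects < 1 or self.M < 1 \
                or self.epochs < 0 or self.learning_rate <= 0 \
                or self.restarts < 1 or self.race_epochs < 1:
            raise ValueError("invalid training configuration")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the last good state."""

    def __init__(self, message, nets=None, params=None, history=None):
        super().__init__(message)
        self.nets, self.params, self.history = nets, params, history


def standardize(dataset: LongitudinalDataset, stats: StandardizeStats | None = None):
    """Zero-mean/unit-variance rescaling of continuous covariates and real outcomes.

    If ``stats`` is given (fit on a training split) it is applied as-is;
    otherwise statistics are computed from this dataset.  Categorical
    columns are untouched.  Returns ``(dataset', stats)``.
    """
    cont = dataset.continuous_slices
    X = dataset.X.copy()
    y = dataset.y
    if stats is None:
        xm = X[:, :, cont].mean(axis=(0, 1)) if cont else np.zeros(0)
        xs = X[:, :, cont].std(axis=(0, 1)) if cont else np.zeros(0)
        const = xs <= 1e-12
        xs = np.where(const, 1.0, xs)
        y_standardized = dataset.outcome_kind == "real"
        if y_standardized:
            ym, ys = float(y.mean()), float(y.std())
            if ys <= 1e-12:
                ym, ys = ym, 1.0
        else:
            ym, ys = 0.0, 1.0
        stats = StandardizeStats(xm, xs, ym, ys, const, y_standardized)
    if cont:
        X[:, :, cont] = (X[:, :, cont] - stats.x_mean) / stats.x_sd
    if stats.y_standardized:
        y = (np.asarray(y, dtype=float) - stats.y_mean) / stats.y_sd
    return replace(dataset, X=X, y=y), stats


def unstandardize_y(y: np.ndarray, stats: StandardizeStats) -> np.ndarray:
    """Inverse transform for (predicted) outcomes."""
    if not stats.y_standardized:
        return y
    return y * stats.y_sd + stats.y_mean


def unstandardize(dataset: LongitudinalDataset, stats: StandardizeStats) -> LongitudinalDataset:
    """Inverse of :func:`standardize`."""
    cont = dataset.continuous_slices
    X = dataset.X.copy()
    if cont:
        X[:, :, cont] = X[:, :, cont] * stats.x_sd + stats.x_mean
    return replace(dataset, X=X, y=unstandardize_y(dataset.y, stats))


def split(dataset: LongitudinalDataset, ratio: float, seed: int):
    """Uniform random split by subject (all L rows stay together)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = dataset.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    return dataset.subset(np.sort(perm[:n_train])), dataset.subset(np.sort(perm[n_train:]))


def data_spec_for(dataset: LongitudinalDataset, D: int, K: int) -> DataSpec:
    return DataSpec(
        D=D, L=dataset.n_measurements,
        n_continuous=len(dataset.continuous_slices),
        categorical_levels=tuple(g for _, g in dataset.categorical_blocks),
        outcome_kind=dataset.outcome_kind,
        outcome_levels=len(dataset.outcome_categories or ()),
        K=K)


def _reorder_columns(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Put continuous expanded columns first, categorical blocks after.

    The decoders emit one joint Gaussian head over all continuous
    features plus one simplex head per categorical feature, so the
    objective addresses X in that layout.
    """
    order = dataset.continuous_slices + [
        j for start, g in dataset.categorical_blocks for j in range(start, start + g)]
    if order == list(range(dataset.X.shape[2])):
        return dataset
    kinds = ([k for k in dataset.feature_kinds if not k.is_categorical]
             + [k for k in dataset.feature_kinds if k.is_categorical])
    return replace(dataset, X=dataset.X[:, :, order], feature_kinds=kinds)


def _warm_start_mixture(nets, mix, data, K: int, seed: int) -> None:
    """Re-anchor the latent mixture on the current embeddings.

    Subjects are partitioned by k-means on their average latent code;
    component means/variances/weights and the per-cluster marginal models
    are refit from that partition (closed-form least squares).  Network
    weights are untouched.
    """
    from sklearn.cluster import KMeans
    from .networks import apply_x_encoder, apply_y_encoder

    mu_z, _ = apply_x_encoder(nets, data.X)        # (N, L, D)
    mu_u, _ = apply_y_encoder(nets, np.asarray(data.y, dtype=data.X.dtype))
    n, L, D = mu_z.shape
    zbar = mu_z.mean(axis=1).astype(float)
    labels = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(zbar)

    dt = mix.mu.value.dtype
    pi = np.maximum(np.bincount(labels, minlength=K) / n, 1e-3)
    pi = pi / pi.sum()
    mu_k = np.empty((K, D))
    s2_k = np.ones((K, D))
    beta0 = np.zeros(K)
    beta = np.zeros((K, D))
    s2u = np.ones(K)
    for k in range(K):
        idx = labels == k
        if not idx.any():
            mu_k[k] = zbar[labels.argmax()]  # degenerate; keep something finite
            continue
        zk = mu_z[idx].reshape(-1, D).astype(float)
        uk = mu_u[idx].reshape(-1).astype(float)
        mu_k[k] = zk.mean(axis=0)
        s2_k[k] = np.maximum(zk.var(axis=0), 1e-3)
        design = np.column_stack([np.ones(len(zk)), zk])
        coef, *_ = np.linalg.lstsq(design, uk, rcond=None)
        beta0[k], beta[k] = coef[0], coef[1:]
        s2u[k] = max(float(np.mean((uk - design @ coef) ** 2)), 1e-3)
    mix.pi_logits.value = np.log(pi).astype(dt)
    mix.mu.value = mu_k.astype(dt)
    mix.log_sigma2.value = np.log(s2_k).astype(dt)
    mix.beta0.value = beta0.astype(dt)
    mix.beta.value = beta.astype(dt)
    mix.log_sigma2_u.value = np.log(s2u).astype(dt)


class _Run:
    """One training run's full state (networks, mixture, optimizer, rng)."""

    def __init__(self, data, config: TrainConfig, init_seed: int):
        spec = data_spec_for(data, config.D, config.K)
        arch = config.arch or ArchitectureConfig(seed=init_seed)
        if arch.seed != init_seed:
            arch = replace(arch, seed=init_seed)
        self.data = data
        self.config = config
        self.seed = init_seed
        self.nets = build_networks(arch, spec)
        self.mix = TrainableMixture.init(config.K, config.D, init_seed + 1)
        dt = np.float32 if config.dtype == "float32" else np.float64
        if dt is np.float32:
            for net in (self.nets.x_encoder, self.nets.x_decoder,
                        self.nets.y_encoder, self.nets.y_decoder):
                net.astype(dt)
            self.mix.astype(dt)
        self.opt = Adam(list(self.nets.parameters()) + self.mix.parameters(),
                        lr=config.learning_rate)
        self.rng = np.random.default_rng(init_seed + 2)
        self.history: list[ElboBreakdown] = []
        self.last_good = None

    def advance(self, n_epochs: int, total_epochs: int) -> None:
        cfg = self.config
        n = self.data.n_subjects
        for _ in range(n_epochs):
            epoch = len(self.history)
            order = self.rng.permutation(n)
            sums = np.zeros(4)
            n_batches = 0
            for start in range(0, n, cfg.batch_subjects):
                batch = self.data.subset(order[start:start + cfg.batch_subjects])
                step_seed = int(self.rng.integers(2 ** 31))
                breakdown, total = elbo(batch, self.nets, self.mix, M=cfg.M,
                                        seed=step_seed, return_tensor=True)
                if not np.isfinite(breakdown.elbo):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}",
                        nets=self.nets, params=self.last_good, history=self.history)
                self.opt.zero_grad()
                (-total).backward()
                self.opt.step()
                sums += (breakdown.recon_y, breakdown.recon_x,
                         breakdown.kl, breakdown.elbo)
                n_batches += 1
            self.history.append(ElboBreakdown(*(sums / n_batches)))
            self.last_good = self.mix.to_params()
            if cfg.mixture_warmup and epoch + 1 == cfg.mixture_warmup \
                    and total_epochs > epoch + 1:
                _warm_start_mixture(self.nets, self.mix, self.data, cfg.K, self.seed)
                self.opt.reset_state(self.mix.parameters())

    def score(self) -> float:
        tail = [h.elbo for h in self.history[-10:]]
        return float(np.mean(tail)) if tail else -np.inf


def train(train_set: LongitudinalDataset, config: TrainConfig):
    """Fit the model by stochastic gradient ascent on the ELBO.

    Returns ``(nets, params, history)`` where ``history`` is the list of
    per-epoch :class:`ElboBreakdown` averages.  With ``restarts > 1``,
    that many independently initialized runs are raced over the first
    ``race_epochs`` epochs and the best training ELBO continues (a
    multi-start guard against local optima); the whole procedure is
    deterministic per seed.
    """
    data = _reorder_columns(train_set)
    if config.dtype == "float32":
        y = data.y.astype(np.float32) if data.outcome_kind == "real" else data.y
        data = replace(data, X=data.X.astype(np.float32), y=y)

    racing = config.restarts > 1 and config.epochs > config.race_epochs
    if not racing:
        run = _Run(data, config, config.seed)
        run.advance(config.epochs, config.epochs)
        return run.nets, run.mix.to_params(), run.history

    candidates = [_Run(data, config, config.seed + 1009 * j)
                  for j in range(config.restarts)]
    for run in candidates:
        run.advance(config.race_epochs, config.epochs)
    best = max(candidates, key=lambda r: r.score())
    best.advance(config.epochs - config.race_epochs, config.epochs)
    return best.nets, best.mix.to_params(), best.history


# --------------------------------------------------------------------------
# checkpointing: one archive with architecture, weights, mixture parameters
# and standardization constants — enough to resume or predict bit-identically.

def save_checkpoint(path, nets: NetworkBundle, params: MixtureLatentParams,
                    stats: StandardizeStats | None = None) -> None:
    meta = {
        "arch": asdict(nets.config),
        "spec": asdict(nets.spec),
        "has_stats": stats is not None,
    }
    arrays = {"__meta__": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for net_name in ("x_encoder", "x_decoder", "y_encoder", "y_decoder"):
        for i, w in enumerate(getattr(nets, net_name).get_weights()):
            arrays[f"{net_name}__{i}"] = w
    for f in ("pi", "mu", "sigma2", "beta0", "beta", "sigma2_u"):
        arrays[f"mix__{f}"] = getattr(params, f)
    if stats is not None:
        arrays["stats__x_mean"] = stats.x_mean
        arrays["stats__x_sd"] = stats.x_sd
        arrays["stats__scalars"] = np.array([stats.y_mean, stats.y_sd,
                                             float(stats.y_standardized)])
        arrays["stats__const"] = stats.constant_x.astype(float)
    np.savez(path, **arrays)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arch = ArchitectureConfig(
            hidden_x=tuple(meta["arch"]["hidden_x"]),
            hidden_y=tuple(meta["arch"]["hidden_y"]),
            activation=meta["arch"]["activation"],
            init=meta["arch"]["init"], seed=meta["arch"]["seed"])
        sd = dict(meta["spec"])
        sd["categorical_levels"] = tuple(sd["categorical_levels"])
        spec = DataSpec(**sd)
        nets = build_networks(arch, spec)
        for net_name in ("x_encoder", "x_decoder", "y_encoder", "y_decoder"):
            net = getattr(nets, net_name)
            ws = [data[f"{net_name}__{i}"] for i in range(sum(1 for _ in net.parameters()))]
            net.set_weights(ws)
        params = MixtureLatentParams(*(data[f"mix__{f}"] for f in
                                       ("pi", "mu", "sigma2", "beta0", "beta", "sigma2_u")))
        stats = None
        if meta["has_stats"]:
            s = data["stats__scalars"]
            stats = StandardizeStats(data["stats__x_mean"], data["stats__x_sd"],
                                     float(s[0]), float(s[1]),
                                     data["stats__const"].astype(bool), bool(s[2]))
    return nets, params, stats
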