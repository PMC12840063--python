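"""Dense function approximators for the four auto-encoding directions.

The model uses four small networks: the X-encoder g_z (covariates ->
latent posterior), the X-decoder f_x (latent -> covariate distribution
parameters), the Y-encoder g_u (outcome vector -> pure-outcome
posterior) and the Y-decoder f_y (pure outcomes -> outcome distribution
parameters).  The Y-decoder consumes the whole length-L pure-outcome
vector jointly — this is what couples the repeated measurements of a
subject — it is never applied per measurement.

Default shapes: one hidden tanh layer of 64 units on the covariate side
and 16 units on the outcome side, Glorot-uniform initialization,
variance heads parameterized as log-variance and exponentiated (then
floored) at apply time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, softmax

__all__ = [
    "VAR_FLOOR", "ArchitectureConfig", "DataSpec", "DenseNet", "NetworkBundle",
    "build_networks", "apply_x_encoder", "apply_x_decoder",
    "apply_y_encoder", "apply_y_decoder",
]

#: global floor applied to every produced/evaluated variance (post-standardization
#: scale); guards the log-densities against underflow.
VAR_FLOOR = 1e-6


@dataclass(frozen=True)
class ArchitectureConfig:
    """Widths/activations/init for the four networks."""

    hidden_x: tuple = (64,)
    hidden_y: tuple = (16,)
    activation: str = "tanh"
    init: str = "glorot_uniform"
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.hidden_x + self.hidden_y):
            raise ValueError("hidden widths must be >= 1")
        if self.activation not in ("tanh", "relu"):
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.init != "glorot_uniform":
            raise ValueError(f"unsupported init {self.init!r}")


@dataclass(frozen=True)
class DataSpec:
    """Dimensions and variable kinds the bundle is built for."""

    D: int
    L: int
    n_continuous: int
    categorical_levels: tuple = ()   # one entry G_p per categorical feature
    outcome_kind: str = "real"       # "real" | "categorical"
    outcome_levels: int = 0
    K: int = 1

    @property
    def P_expanded(self) -> int:
        return self.n_continuous + sum(self.categorical_levels)


def _glorot(rng, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class DenseNet:
    """Tanh MLP with named affine heads.

    All heads are computed by a single affine map from the last hidden
    layer and split afterwards, which keeps the per-step matmul count low.
    """

    def __init__(self, in_dim: int, hidden: tuple, heads: dict, rng,
                 activation: str = "tanh"):
        self.in_dim = in_dim
        self.hidden_dims = tuple(hidden)
        self.activation = activation
        self.head_slices = {}
        start = 0
        for name, out_dim in heads.items():
            self.head_slices[name] = slice(start, start + out_dim)
            start += out_dim
        self.layers = []
        d = in_dim
        for h in hidden:
            self.layers.append((Tensor(_glorot(rng, d, h), requires_grad=True),
                                Tensor(np.zeros(h), requires_grad=True)))
            d = h
        # per-head Glorot fans (as if each head were its own affine layer)
        w = np.concatenate([_glorot(rng, d, heads[n]) for n in heads], axis=1)
        self.head_w = Tensor(w, requires_grad=True)
        self.head_b = Tensor(np.zeros(start), requires_grad=True)

    def parameters(self):
        for w, b in self.layers:
            yield w
            yield b
        yield self.head_w
        yield self.head_b

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: Tensor) -> dict:
        """Apply to a batch (…, in_dim); returns {head name: Tensor}."""
        h = x
        for li, (w, b) in enumerate(self.layers):
            h = h @ w + b
            h = h.tanh() if self.activation == "tanh" else h.clamp_min(0.0)
            if not np.isfinite(h.value).all():
                raise FloatingPointError(f"non-finite activation in hidden layer {li}")
        out_all = h @ self.head_w + self.head_b
        if not np.isfinite(out_all.value).all():
            raise FloatingPointError("non-finite activation in output heads")
        return {name: out_all[..., s] for name, s in self.head_slices.items()}

    def astype(self, dtype) -> None:
        for p in self.parameters():
            p.value = p.value.astype(dtype)

    # serialization -----------------------------------------------------------
    def get_weights(self) -> list:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p.value = np.asarray(w, dtype=float).copy()


@dataclass
class NetworkBundle:
    """The four function approximators plus the spec they were built for."""

    x_encoder: DenseNet
    x_decoder: DenseNet
    y_encoder: DenseNet
    y_decoder: DenseNet
    config: ArchitectureConfig
    spec: DataSpec

    def parameters(self):
        for net in (self.x_encoder, self.x_decoder, self.y_encoder, self.y_decoder):
            yield from net.parameters()


def build_networks(config: ArchitectureConfig, spec: DataSpec) -> NetworkBundle:
    """Build the four networks with seeded Glorot-uniform weights, no pretraining."""
    rng = np.random.default_rng(config.seed)
    P = spec.P_expanded
    if P < 1 or spec.D < 1 or spec.L < 1:
        raise ValueError("DataSpec dims must be >= 1")

    x_enc = DenseNet(P, config.hidden_x, {"mean": spec.D, "logvar": spec.D},
                     rng, config.activation)

    dec_heads = {}
    if spec.n_continuous:
        dec_heads["mean"] = spec.n_continuous
        dec_heads["logvar"] = spec.n_continuous
    for i, g in enumerate(spec.categorical_levels):
        dec_heads[f"logits{i}"] = g
    if not dec_heads:
        raise ValueError("x_decoder needs at least one feature head")
    x_dec = DenseNet(spec.D, config.hidden_x, dec_heads, rng, config.activation)

    y_enc = DenseNet(spec.L, config.hidden_y, {"mean": spec.L, "logvar": spec.L},
                     rng, config.activation)
    if spec.outcome_kind == "real":
        y_heads = {"mean": spec.L, "logvar": spec.L}
    elif spec.outcome_kind == "categorical":
        if spec.outcome_levels < 2:
            raise ValueError("categorical outcome needs >= 2 levels")
        y_heads = {"logits": spec.L * spec.outcome_levels}
    else:
        raise ValueError(f"unknown outcome kind {spec.outcome_kind!r}")
    y_dec = DenseNet(spec.L, config.hidden_y, y_heads, rng, config.activation)
    return NetworkBundle(x_enc, x_dec, y_enc, y_dec, config, spec)


def _maybe_value(out, raw: bool):
    if raw:
        return out
    if isinstance(out, tuple):
        return tuple(o.value for o in out)
    return {k: (v.value if isinstance(v, Tensor) else [vv.value for vv in v])
            for k, v in out.items()}


def apply_x_encoder(nets: NetworkBundle, x, raw: bool = False):
    """x (…, P) -> (mu_z (…, D), sigma2_z (…, D) floored positive)."""
    heads = nets.x_encoder.forward(as_tensor(x))
    out = (heads["mean"], heads["logvar"].exp().clamp_min(VAR_FLOOR))
    return _maybe_value(out, raw)


def apply_x_decoder(nets: NetworkBundle, z, raw: bool = False):
    """z (…, D) -> per-feature distribution parameters.

    Returns a dict with ``mean``/``sigma2`` arrays over continuous
    features (present only if there are any) and ``probs`` — a list of
    simplex arrays, one per categorical feature.
    """
    heads = nets.x_decoder.forward(as_tensor(z))
    out = {}
    if nets.spec.n_continuous:
        out["mean"] = heads["mean"]
        out["sigma2"] = heads["logvar"].exp().clamp_min(VAR_FLOOR)
    out["probs"] = [softmax(heads[f"logits{i}"], axis=-1)
                    for i in range(len(nets.spec.categorical_levels))]
    return _maybe_value(out, raw)


def apply_y_encoder(nets: NetworkBundle, y, raw: bool = False):
    """y (…, L) -> (mu_u (…, L), sigma2_u (…, L))."""
    heads = nets.y_encoder.forward(as_tensor(y))
    out = (heads["mean"], heads["logvar"].exp().clamp_min(VAR_FLOOR))
    return _maybe_value(out, raw)


def apply_y_decoder(nets: NetworkBundle, u, raw: bool = False):
    """u (…, L) -> outcome heads.

    Real outcome: ``(mean (…, L), sigma2 (…, L))``.  Categorical
    outcome: a single simplex array (…, L, G).
    """
    ut = as_tensor(u)
    heads = nets.y_decoder.forward(ut)
    if nets.spec.outcome_kind == "real":
        out = (heads["mean"], heads["logvar"].exp().clamp_min(VAR_FLOOR))
        return _maybe_value(out, raw)
    g = nets.spec.outcome_levels
    logits = heads["logits"].reshape(ut.shape[:-1] + (nets.spec.L, g))
    probs = softmax(logits, axis=-1)
    return probs if raw else probs.value
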