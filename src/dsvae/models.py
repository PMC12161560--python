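"""Sequence VAEs that factorize window-level context from timestep-level
local structure.

Four variants share one parameterization:

* ``dsvae`` — the dependent model. A context encoder maps the full window
  ``x_{1:W}`` (N components x W timesteps) to a diagonal-Gaussian posterior
  over a context embedding ``z_c``. A sampled ``z_c`` is
  broadcast-concatenated to every timestep's input of the local encoder,
  which outputs one diagonal-Gaussian posterior per timestep over the local
  embeddings ``z_{1:W}``. The local prior is an autoregressive GRU whose
  initial state is conditioned on ``z_c``.
* ``idsvae`` — the independent model: same pieces, but the local encoder
  sees only the window and the local prior is conditioned on a learnable
  vector instead of ``z_c``.
* ``lvae`` — local-only baseline: no context channel at all; its "context
  embedding" is the time-average of the local posterior means.
* ``cvae`` — context-only baseline: a 1-D convolutional encoder/decoder
  over the whole window with a single context latent.

The decoder for dsvae/idsvae/lvae is a per-timestep MLP on
``[z_c; z_t]`` (the same ``z_c`` reused at every timestep of a window).
The training objective is the negative ELBO per window

    recon + beta * (1/W) sum_t KL(q(z_t|.) || p(z_t|z_<t, .))
          + gamma * KL(q(z_c|x_w) || N(0, I))

with a unit-variance Gaussian likelihood (reconstruction = mean over the W
timesteps of the negative log-likelihood), the local KL averaged over
timesteps, and no 1/W on the context term. The local-prior KL is analytic
per timestep along a single sampled latent path (exact marginal KL under an
autoregressive prior is intractable).

Batched array layout throughout: ``(batch, W, N)``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import autograd.numpy as anp
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .io_windows import Window, windows_to_array

VARIANTS = ("dsvae", "idsvae", "lvae", "cvae")


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagonalGaussian:
    """Diagonal Gaussian with mean and log-variance vectors of equal length."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        lv = np.atleast_1d(np.asarray(self.log_variance, dtype=float))
        if mean.shape != lv.shape or mean.ndim != 1:
            raise ValueError(
                f"mean and log_variance must be equal-length vectors, got "
                f"{mean.shape} and {lv.shape}"
            )
        if not np.all(np.isfinite(lv)):
            raise ValueError("log_variance must be finite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "log_variance", lv)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


#: Posterior over z_c: a single DiagonalGaussian of dimension context_size.
ContextPosterior = DiagonalGaussian
#: Posterior over z_{1:W}: a list of W DiagonalGaussians of dimension local_size.
LocalPosterior = list


def kl_diag_gaussian(q: DiagonalGaussian, p: DiagonalGaussian) -> float:
    """Closed-form KL(q || p) between diagonal Gaussians, summed over
    dimensions. Non-negative; zero iff q == p."""
    if q.dim != p.dim:
        raise ValueError(f"dimension mismatch: {q.dim} vs {p.dim}")
    return float(
        np.sum(_kl_terms(q.mean, q.log_variance, p.mean, p.log_variance))
    )


def _kl_terms(mu_q, lv_q, mu_p, lv_p):
    """Elementwise KL between diagonal Gaussians:
    0.5 * (lv_p - lv_q + (var_q + (mu_q - mu_p)^2) / var_p - 1)."""
    return 0.5 * (
        lv_p - lv_q + (anp.exp(lv_q) + (mu_q - mu_p) ** 2) / anp.exp(lv_p) - 1.0
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Full model + training configuration.

    ``local_size`` (LS) and ``context_size`` (CS) are the latent dimensions;
    ``beta`` and ``gamma`` weigh the local and context KL terms. For the
    ``lvae`` variant CS plays no encoding role (its context embedding is the
    time-averaged local mean, dimension LS); for ``cvae`` LS plays none.
    """

    variant: str = "dsvae"
    local_size: int = 4
    context_size: int = 2
    beta: float = 2.0
    gamma: float = 0.01
    context_encoder_arch: str = "rnn"
    hidden_size: int = 32
    prior_hidden_size: int = 32
    conv_channels: int = 32
    conv_kernel: int = 5
    learning_rate: float = 3e-3
    batch_size: int = 128
    max_epochs: int = 20
    patience: int = 10
    input_noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.context_encoder_arch not in ("rnn", "conv"):
            raise ValueError("context_encoder_arch must be 'rnn' or 'conv'")
        for name in ("local_size", "context_size", "hidden_size",
                     "prior_hidden_size", "conv_channels", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("beta", "gamma", "input_noise_std"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_epochs < 0 or self.patience < 0:
            raise ValueError("max_epochs and patience must be >= 0")

    @property
    def embedding_dim(self) -> int:
        """Dimension of the context embedding this variant produces."""
        return self.local_size if self.variant == "lvae" else self.context_size


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _component_rng(seed: int, component_index: int) -> np.random.Generator:
    # each architectural component draws from its own named stream so that
    # shared components (context encoder, decoder) are identical across
    # variants under the same seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(10, component_index))
    )


_CTX, _LOCAL, _PRIOR, _DECODER, _COND = 0, 1, 2, 3, 4


def init_params(config: ModelConfig, n_components: int, width: int) -> dict:
    """Seeded parameter initialization for any variant."""
    N, H, P = n_components, config.hidden_size, config.prior_hidden_size
    LS, CS = config.local_size, config.context_size
    v = config.variant
    params: dict = {}

    if v in ("dsvae", "idsvae", "cvae"):
        rng = _component_rng(config.seed, _CTX)
        arch = "conv" if v == "cvae" else config.context_encoder_arch
        if arch == "rnn":
            ctx = {
                "rnn": {
                    "fw": nn.init_rnn_cell(rng, N, H),
                    "bw": nn.init_rnn_cell(rng, N, H),
                },
                "mu": nn.init_dense(rng, 2 * H, CS),
                "lv": nn.init_dense(rng, 2 * H, CS),
            }
        else:
            C = config.conv_channels
            ctx = {
                "conv1": nn.init_conv1d(rng, N, C, config.conv_kernel),
                "conv2": nn.init_conv1d(rng, C, C, config.conv_kernel),
                "mu": nn.init_dense(rng, C, CS),
                "lv": nn.init_dense(rng, C, CS),
            }
        params["ctx"] = ctx

    if v in ("dsvae", "idsvae", "lvae"):
        rng = _component_rng(config.seed, _LOCAL)
        d_in = N + CS if v == "dsvae" else N
        params["loc"] = {
            "rnn": {
                "fw": nn.init_rnn_cell(rng, d_in, H),
                "bw": nn.init_rnn_cell(rng, d_in, H),
            },
            "mu": nn.init_dense(rng, 2 * H, LS),
            "lv": nn.init_dense(rng, 2 * H, LS),
        }
        rng = _component_rng(config.seed, _PRIOR)
        params["prior"] = {
            "gru": nn.init_gru_cell(rng, LS, P),
            "mu": nn.init_dense(rng, P, LS),
            "lv": nn.init_dense(rng, P, LS),
        }
        rng = _component_rng(config.seed, _COND)
        if v == "dsvae":
            params["prior"]["init"] = nn.init_dense(rng, CS, P)
        else:
            params["prior"]["h0"] = 0.01 * rng.standard_normal(P)

    rng = _component_rng(config.seed, _DECODER)
    if v == "cvae":
        C = config.conv_channels
        params["dec"] = {
            "expand": nn.init_dense(rng, CS, width * (C // 2)),
            "conv1": nn.init_conv1d(rng, C // 2, C, config.conv_kernel),
            "conv2": nn.init_conv1d(rng, C, N, config.conv_kernel),
        }
    else:
        d_in = LS if v == "lvae" else CS + LS
        params["dec"] = {
            "h": nn.init_dense(rng, d_in, H),
            "out": nn.init_dense(rng, H, N),
        }
    return params


# ---------------------------------------------------------------------------
# Batched forward passes (autograd-traceable)
# ---------------------------------------------------------------------------

def context_posterior_batch(params, config, X):
    """(B, W, N) -> context posterior means and log-variances, (B, CS) each."""
    ctx = params["ctx"]
    arch = "conv" if config.variant == "cvae" else config.context_encoder_arch
    if arch == "rnn":
        _, final = nn.birnn(ctx["rnn"], X)
        h = final
    else:
        h = nn.relu(nn.conv1d_same(ctx["conv1"], X))
        h = nn.relu(nn.conv1d_same(ctx["conv2"], h))
        h = anp.mean(h, axis=1)
    mu = nn.dense(ctx["mu"], h)
    lv = nn.clamp_logvar(nn.dense(ctx["lv"], h))
    return mu, lv


def local_posterior_batch(params, config, X, z_c=None):
    """(B, W, N) [+ context sample (B, CS) for dsvae] -> per-timestep local
    posterior means and log-variances, (B, W, LS) each."""
    B, W, N = X.shape
    rnnp = params["loc"]["rnn"]
    if config.variant == "dsvae":
        if z_c is None:
            raise ValueError("dsvae local encoder requires a context sample")
        # input weights cover [x_t; z_c]; the z_c projection is shared by all
        # timesteps of a window, so it is computed once per window
        Wx_full = anp.stack([rnnp["fw"]["Wx"], rnnp["bw"]["Wx"]])  # (2, N+CS, H)
        extra = anp.matmul(z_c, Wx_full[:, N:, :])  # (2, B, H)
        states, _ = nn.birnn(rnnp, X, Wx=Wx_full[:, :N, :], extra_proj=extra)
    else:
        if z_c is not None:
            raise ValueError(
                f"{config.variant} local encoder takes only the window; "
                f"context conditioning is a dsvae-specific mechanism"
            )
        states, _ = nn.birnn(rnnp, X)
    flat = anp.reshape(states, (B * W, -1))
    mu = anp.reshape(nn.dense(params["loc"]["mu"], flat), (B, W, -1))
    lv = anp.reshape(
        nn.clamp_logvar(nn.dense(params["loc"]["lv"], flat)), (B, W, -1)
    )
    return mu, lv


def local_prior_batch(params, config, z_samples, z_c=None):
    """Autoregressive local prior along a sampled path.

    The prior at step t is a function of the GRU state driven by the sampled
    z_{<t}; the step-1 prior depends only on the conditioning (z_c for
    dsvae, a learnable vector otherwise). Returns means and log-variances,
    (B, W, LS) each.
    """
    B, W, _ = z_samples.shape
    prior = params["prior"]
    if config.variant == "dsvae":
        if z_c is None:
            raise ValueError("dsvae local prior requires a context sample")
        s = anp.tanh(nn.dense(prior["init"], z_c))
    else:
        if z_c is not None:
            raise ValueError(
                f"{config.variant} local prior is conditioned on a learnable "
                f"vector, not a context sample"
            )
        s = anp.repeat(anp.reshape(prior["h0"], (1, -1)), B, axis=0)
    gru = prior["gru"]
    P = gru["Wh"].shape[0]
    states = [s]
    for t in range(W - 1):
        # gate math identical to nn.gru_step, with reset/update fused into
        # one sigmoid call to keep the graph small
        gx = z_samples[:, t, :] @ gru["Wx"] + gru["b"]
        gh = s @ gru["Wh"]
        ru = nn.sigmoid(gx[:, : 2 * P] + gh[:, : 2 * P])
        r = ru[:, :P]
        u = ru[:, P:]
        n = anp.tanh(gx[:, 2 * P :] + r * gh[:, 2 * P :])
        s = (1.0 - u) * n + u * s
        states.append(s)
    S = anp.reshape(anp.stack(states, axis=1), (B * W, P))
    mu = anp.reshape(nn.dense(prior["mu"], S), (B, W, -1))
    lv = anp.reshape(nn.clamp_logvar(nn.dense(prior["lv"], S)), (B, W, -1))
    return mu, lv


def decode_batch(params, config, z_c, z_l, width=None):
    """Reconstruction means.

    dsvae/idsvae: per-timestep MLP on [z_c; z_t]; lvae: MLP on z_t alone;
    cvae: convolutional decoder from z_c to the full window. Returns
    (B, W, N).
    """
    if config.variant == "cvae":
        B = z_c.shape[0]
        h = nn.relu(nn.dense(params["dec"]["expand"], z_c))
        h = anp.reshape(h, (B, width, -1))
        h = nn.relu(nn.conv1d_same(params["dec"]["conv1"], h))
        return nn.conv1d_same(params["dec"]["conv2"], h)
    B, W, _ = z_l.shape
    if config.variant == "lvae":
        inp = z_l
    else:
        zc_tiled = anp.repeat(anp.reshape(z_c, (B, 1, -1)), W, axis=1)
        inp = anp.concatenate([zc_tiled, z_l], axis=2)
    flat = anp.reshape(inp, (B * W, -1))
    h = nn.relu(nn.dense(params["dec"]["h"], flat))
    out = nn.dense(params["dec"]["out"], h)
    return anp.reshape(out, (B, W, -1))


_LOG2PI = float(np.log(2.0 * np.pi))


def loss_batch(params, config, X, eps_c, eps_l):
    """Negative-ELBO components for a batch of windows X (B, W, N).

    ``eps_c`` (B, CS) and ``eps_l`` (B, W, LS) are the reparameterization
    draws (one sample per window). Returns a dict with autograd scalars
    ``reconstruction``, ``local_kl``, ``context_kl``, ``total``, each
    averaged over the batch.
    """
    B, W, N = X.shape
    v = config.variant
    zero = anp.sum(anp.zeros(1))

    z_c = None
    context_kl = zero
    if v in ("dsvae", "idsvae", "cvae"):
        mu_c, lv_c = context_posterior_batch(params, config, X)
        z_c = mu_c + anp.exp(0.5 * lv_c) * eps_c
        # context prior is the standard normal
        context_kl = anp.mean(
            anp.sum(_kl_terms(mu_c, lv_c, 0.0, 0.0), axis=1)
        )

    local_kl = zero
    if v in ("dsvae", "idsvae", "lvae"):
        mu_l, lv_l = local_posterior_batch(
            params, config, X, z_c if v == "dsvae" else None
        )
        z_l = mu_l + anp.exp(0.5 * lv_l) * eps_l
        pr_mu, pr_lv = local_prior_batch(
            params, config, z_l, z_c if v == "dsvae" else None
        )
        local_kl = anp.mean(
            anp.mean(anp.sum(_kl_terms(mu_l, lv_l, pr_mu, pr_lv), axis=2), axis=1)
        )
        x_hat = decode_batch(params, config, z_c, z_l)
    else:
        x_hat = decode_batch(params, config, z_c, None, width=W)

    # unit-variance Gaussian likelihood, averaged over the W timesteps
    nll_t = 0.5 * anp.sum((X - x_hat) ** 2, axis=2) + 0.5 * N * _LOG2PI
    recon = anp.mean(anp.mean(nll_t, axis=1))

    total = recon + config.beta * local_kl + config.gamma * context_kl
    return {
        "reconstruction": recon,
        "local_kl": local_kl,
        "context_kl": context_kl,
        "total": total,
    }


# ---------------------------------------------------------------------------
# Loss bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossBreakdown:
    """Negative-ELBO components averaged over a set of M windows.

    ``total = reconstruction + beta * local_kl + gamma * context_kl``.
    """

    reconstruction: float
    local_kl: float
    context_kl: float
    total: float
    window_count: int

    def __post_init__(self):
        if self.local_kl < -1e-9 or self.context_kl < -1e-9:
            raise ValueError("KL terms must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def elbo_loss(
    windows,
    config: ModelConfig,
    params: dict,
    rng: np.random.Generator,
) -> LossBreakdown:
    """Evaluate the loss on one window or a sequence of windows, drawing one
    reparameterized sample per window from ``rng``."""
    if isinstance(windows, Window):
        windows = [windows]
    if isinstance(windows, np.ndarray):
        X = windows if windows.ndim == 3 else windows[None]
        X = np.transpose(X, (0, 2, 1))
    else:
        X = np.transpose(windows_to_array(windows), (0, 2, 1))
    B, W, _ = X.shape
    eps_c = rng.standard_normal((B, config.context_size))
    eps_l = rng.standard_normal((B, W, config.local_size))
    parts = loss_batch(params, config, X, eps_c, eps_l)
    return LossBreakdown(
        reconstruction=float(parts["reconstruction"]),
        local_kl=float(parts["local_kl"]),
        context_kl=float(parts["context_kl"]),
        total=float(parts["total"]),
        window_count=B,
    )


# ---------------------------------------------------------------------------
# Single-window operations (thin wrappers over the batched passes)
# ---------------------------------------------------------------------------

def _window_to_batch(window: Window, width: int | None = None) -> np.ndarray:
    if width is not None and window.width != width:
        raise ValueError(
            f"window width {window.width} does not match model width {width}"
        )
    return window.data.T[None]  # (1, W, N)


def encode_context(
    window: Window, config: ModelConfig, params: dict, width: int | None = None
) -> ContextPosterior:
    """Context posterior for one window (one posterior per window, not per
    timestep). ``width``, when given, asserts the window matches the
    training width. Not defined for the lvae variant, whose context
    embedding is derived by time-averaging local means (see
    :func:`lvae_context`)."""
    if config.variant == "lvae":
        raise ValueError("lvae has no context encoder; use lvae_context instead")
    mu, lv = context_posterior_batch(params, config, _window_to_batch(window, width))
    return DiagonalGaussian(mu[0], lv[0])


def encode_local(
    window: Window,
    context_sample,
    config: ModelConfig,
    params: dict,
    width: int | None = None,
) -> LocalPosterior:
    """Per-timestep local posteriors for one window.

    dsvae requires a CS-dimensional context sample (broadcast-concatenated
    to every timestep's input); idsvae/lvae forbid one — keeping the two
    factorizations structurally distinct is the point of the contrast.
    """
    if config.variant == "cvae":
        raise ValueError("cvae has no local encoder")
    if config.variant != "dsvae" and context_sample is not None:
        raise ValueError(
            f"{config.variant} local encoder takes only the window; "
            f"context conditioning is a dsvae-specific mechanism"
        )
    X = _window_to_batch(window, width)
    if config.variant == "dsvae":
        if context_sample is None:
            raise ValueError("dsvae requires a context sample")
        z_c = np.asarray(context_sample, dtype=float).reshape(1, -1)
        if z_c.shape[1] != config.context_size:
            raise ValueError(
                f"context sample has dimension {z_c.shape[1]}, expected "
                f"{config.context_size}"
            )
    else:
        z_c = None
    mu, lv = local_posterior_batch(params, config, X, z_c)
    return [DiagonalGaussian(mu[0, t], lv[0, t]) for t in range(mu.shape[1])]


def local_prior(
    config: ModelConfig,
    params: dict,
    sampled_locals: Sequence,
    context_sample=None,
) -> list[DiagonalGaussian]:
    """Autoregressive local prior along a sampled latent path.

    ``sampled_locals`` is the sequence of W sampled local embeddings; the
    returned prior at step t depends only on the samples before t and the
    conditioning input (z_c for dsvae, the learnable vector otherwise).
    """
    if config.variant == "cvae":
        raise ValueError("cvae has no local prior")
    z = np.asarray([np.asarray(s, dtype=float) for s in sampled_locals])
    if z.ndim != 2 or z.shape[1] != config.local_size:
        raise ValueError(
            f"sampled locals must be W vectors of dimension {config.local_size}"
        )
    z_c = None
    if config.variant == "dsvae":
        if context_sample is None:
            raise ValueError("dsvae local prior requires a context sample")
        z_c = np.asarray(context_sample, dtype=float).reshape(1, -1)
    elif context_sample is not None:
        raise ValueError(f"{config.variant} local prior takes no context sample")
    mu, lv = local_prior_batch(params, config, z[None], z_c)
    return [DiagonalGaussian(mu[0, t], lv[0, t]) for t in range(mu.shape[1])]


def decode(config: ModelConfig, params: dict, context_sample, local_sample=None,
           width: int | None = None):
    """Decode latents to a reconstruction mean.

    For dsvae/idsvae: per-timestep decoding of [z_c; z_t] -> N-vector; the
    same z_c is reused for every timestep of a window. For lvae: z_t alone.
    For cvae: z_c alone -> the full (N, width) window.
    """
    if config.variant == "cvae":
        if local_sample is not None:
            raise ValueError("cvae decodes from the context sample only")
        if width is None:
            raise ValueError("cvae decoding requires the window width")
        z_c = np.asarray(context_sample, dtype=float).reshape(1, -1)
        out = decode_batch(params, config, z_c, None, width=width)
        return np.asarray(out[0]).T  # (N, W)
    if config.variant == "lvae":
        z_l = np.asarray(local_sample, dtype=float).reshape(1, 1, -1)
        out = decode_batch(params, config, None, z_l)
        return np.asarray(out[0, 0])
    z_c = np.asarray(context_sample, dtype=float).reshape(1, -1)
    z_l = np.asarray(local_sample, dtype=float).reshape(1, 1, -1)
    if z_c.shape[1] != config.context_size or z_l.shape[2] != config.local_size:
        raise ValueError("latent dimensions do not match the model config")
    out = decode_batch(params, config, z_c, z_l)
    return np.asarray(out[0, 0])


def lvae_context(local_posteriors: LocalPosterior) -> np.ndarray:
    """The lvae context embedding: the arithmetic mean over timesteps of the
    per-timestep local posterior means."""
    if not local_posteriors:
        raise ValueError("empty local posterior sequence")
    return np.mean([p.mean for p in local_posteriors], axis=0)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _flatten_tree(tree, prefix=""):
    for k, v in tree.items():
        key = f"{prefix}{k}" if not prefix else f"{prefix}/{k}"
        if isinstance(v, dict):
            yield from _flatten_tree(v, key)
        else:
            yield key, np.asarray(v)


def _unflatten_tree(flat: dict) -> dict:
    tree: dict = {}
    for key, arr in flat.items():
        parts = key.split("/")
        node = tree
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = arr
    return tree


def save_checkpoint(path, config: ModelConfig, params: dict, meta: dict) -> None:
    """Single-file archive (npz) with weights + config + metadata, plus a
    JSON sidecar holding the config for human inspection."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    payload = {k: v for k, v in _flatten_tree(params)}
    header = {"config": dataclasses.asdict(config), "meta": meta}
    payload["__header__"] = np.frombuffer(
        json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)
    path.with_suffix(".json").write_text(json.dumps(header, indent=2, sort_keys=True))


def load_checkpoint(path):
    """Returns (config, params, meta)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path, allow_pickle=False) as f:
        header = json.loads(bytes(f["__header__"]).decode())
        flat = {k: f[k] for k in f.files if k != "__header__"}
    return ModelConfig(**header["config"]), _unflatten_tree(flat), header["meta"]


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------

class BaseSequenceVAE(BaseEstimator, TransformerMixin):
    """Shared estimator machinery; subclasses fix the variant.

    ``fit(X)`` trains on windows (an ``(M, N, W)`` array or a list of
    :class:`~dsvae.io_windows.Window`); ``transform(X)`` returns the
    deterministic context embedding (posterior mean) per window. Training
    is fully seeded from ``random_state`` — two fits with identical inputs
    and config produce identical weights on the same backend.
    """

    variant: str = ""

    def __init__(
        self,
        local_size=4,
        context_size=2,
        beta=2.0,
        gamma=0.01,
        context_encoder_arch="rnn",
        hidden_size=32,
        prior_hidden_size=32,
        conv_channels=32,
        conv_kernel=5,
        learning_rate=3e-3,
        batch_size=128,
        max_epochs=20,
        patience=10,
        input_noise_std=0.0,
        random_state=0,
    ):
        self.local_size = local_size
        self.context_size = context_size
        self.beta = beta
        self.gamma = gamma
        self.context_encoder_arch = context_encoder_arch
        self.hidden_size = hidden_size
        self.prior_hidden_size = prior_hidden_size
        self.conv_channels = conv_channels
        self.conv_kernel = conv_kernel
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.input_noise_std = input_noise_std
        self.random_state = random_state

    # -- config plumbing ---------------------------------------------------

    def make_config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            local_size=self.local_size,
            context_size=self.context_size,
            beta=self.beta,
            gamma=self.gamma,
            context_encoder_arch=self.context_encoder_arch,
            hidden_size=self.hidden_size,
            prior_hidden_size=self.prior_hidden_size,
            conv_channels=self.conv_channels,
            conv_kernel=self.conv_kernel,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            input_noise_std=self.input_noise_std,
            seed=self.random_state,
        )

    @staticmethod
    def _validate_windows(X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            X = windows_to_array(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_windows, n_components, width), got shape {X.shape}"
            )
        if X.shape[0] < 1 or X.shape[2] < 2:
            raise ValueError("need at least one window of width >= 2")
        if not np.all(np.isfinite(X)):
            raise ValueError("windows contain non-finite values")
        return X

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None, X_val=None):
        from .training import fit_loop  # local import: training builds on models

        X = self._validate_windows(X)
        if X_val is not None:
            X_val = self._validate_windows(X_val)
            if X_val.shape[1:] != X.shape[1:]:
                raise ValueError("validation windows must match train shape")
        config = self.make_config()
        params, history = fit_loop(config, X, X_val)
        self.config_ = config
        self.params_ = params
        self.history_ = history
        self.n_components_ = int(X.shape[1])
        self.window_width_ = int(X.shape[2])
        return self

    def _check_fitted_input(self, X) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        X = self._validate_windows(X)
        if X.shape[1] != self.n_components_ or X.shape[2] != self.window_width_:
            raise ValueError(
                f"windows have shape {X.shape[1:]}, model was fitted on "
                f"({self.n_components_}, {self.window_width_})"
            )
        return np.transpose(X, (0, 2, 1))  # (M, W, N)

    def transform(self, X) -> np.ndarray:
        """Deterministic context embeddings: context posterior means, or for
        lvae the time-averaged local posterior means."""
        Xb = self._check_fitted_input(X)
        if self.variant == "lvae":
            mu, _ = local_posterior_batch(self.params_, self.config_, Xb)
            return np.asarray(anp.mean(mu, axis=1))
        mu, _ = context_posterior_batch(self.params_, self.config_, Xb)
        return np.asarray(mu)

    def loss_breakdown(self, X, rng=None) -> LossBreakdown:
        Xb = self._check_fitted_input(X)
        rng = rng or np.random.default_rng(0)
        return elbo_loss(np.transpose(Xb, (0, 2, 1)), self.config_, self.params_, rng)

    def score(self, X, y=None) -> float:
        """Negative total loss with zero reparameterization noise (a
        deterministic ELBO proxy; greater is better)."""
        Xb = self._check_fitted_input(X)
        B, W, _ = Xb.shape
        parts = loss_batch(
            self.params_, self.config_, Xb,
            np.zeros((B, self.config_.context_size)),
            np.zeros((B, W, self.config_.local_size)),
        )
        return -float(parts["total"])

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        save_checkpoint(
            path,
            self.config_,
            self.params_,
            {
                "n_components": self.n_components_,
                "window_width": self.window_width_,
                "history": self.history_,
            },
        )

    @staticmethod
    def load(path) -> "BaseSequenceVAE":
        config, params, meta = load_checkpoint(path)
        est = make_estimator(config)
        est.config_ = config
        est.params_ = params
        est.history_ = meta["history"]
        est.n_components_ = meta["n_components"]
        est.window_width_ = meta["window_width"]
        return est


class DSVAE(BaseSequenceVAE):
    """Dependent disentangled sequence VAE: local encoder and local prior
    are conditioned on the context embedding."""

    variant = "dsvae"


class IDSVAE(BaseSequenceVAE):
    """Independent disentangled sequence VAE: the local channel never sees
    the context embedding."""

    variant = "idsvae"


class LVAE(BaseSequenceVAE):
    """Local-only baseline; context embedding = time-averaged local means."""

    variant = "lvae"


class CVAE(BaseSequenceVAE):
    """Context-only convolutional baseline over the whole window."""

    variant = "cvae"


_ESTIMATORS = {"dsvae": DSVAE, "idsvae": IDSVAE, "lvae": LVAE, "cvae": CVAE}


def make_estimator(config: ModelConfig | dict) -> BaseSequenceVAE:
    """Build the right estimator subclass from a ModelConfig or plain dict."""
    if isinstance(config, dict):
        config = ModelConfig(**config)
    cls = _ESTIMATORS[config.variant]
    kwargs = dataclasses.asdict(config)
    kwargs.pop("variant")
    kwargs["random_state"] = kwargs.pop("seed")
    return cls(**kwargs)
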