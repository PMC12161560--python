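"""Seeded training loop, multi-seed/multi-config grid search, and dataset
embedding.

All randomness (initialization, batch shuffling, reparameterization draws,
optional input-corruption noise) flows from ``config.seed`` through named
sub-streams, so a run is a deterministic function of (data, config) on a
given backend. Model selection follows the protocol of averaging final
validation loss across seeds per configuration and picking the minimizer.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from .io_windows import DatasetSplit, EmbeddingTable, Window, windows_to_array
from .models import (
    BaseSequenceVAE,
    LossBreakdown,
    ModelConfig,
    init_params,
    loss_batch,
    make_estimator,
)
from .nn import Adam

#: Default seed list for multi-seed runs.
DEFAULT_SEEDS = (42, 1337, 1212, 9999)


class TrainingDiverged(RuntimeError):
    """Raised when a loss term becomes non-finite; names epoch and term."""

    def __init__(self, epoch: int, term: str):
        super().__init__(f"non-finite loss at epoch {epoch}: term {term!r}")
        self.epoch = epoch
        self.term = term


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _breakdown(params, config, X, rng) -> LossBreakdown:
    """Loss components on a full set, one reparameterized sample per window."""
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


def fit_loop(config: ModelConfig, X_train: np.ndarray, X_val: np.ndarray | None):
    """Train a model; returns (params, history).

    ``X_train``/``X_val`` are (M, N, W) window arrays. Adam at
    ``config.learning_rate``, minibatches of ``config.batch_size``, up to
    ``config.max_epochs`` epochs with early stopping on the validation total
    (patience ``config.patience``; the best-validation epoch's weights are
    restored, so the returned model is never worse than the best epoch
    seen). ``input_noise_std`` > 0 corrupts training inputs only.

    History is a list of per-epoch dicts with ``train`` and ``val``
    LossBreakdowns (as plain dicts, JSON-ready).
    """
    Xtr = np.transpose(X_train, (0, 2, 1))  # (M, W, N)
    Xva = None if X_val is None else np.transpose(X_val, (0, 2, 1))
    M, W, N = Xtr.shape

    params = init_params(config, N, W)
    if config.max_epochs == 0:
        return params, []

    flat, unflatten = flatten(params)
    opt = Adam(config.learning_rate)
    shuffle_rng = _stream(config.seed, 100)
    eps_rng = _stream(config.seed, 101)
    noise_rng = _stream(config.seed, 102)
    eval_rng = _stream(config.seed, 103)

    def total_fn(p, xb, ec, el):
        return loss_batch(p, config, xb, ec, el)["total"]

    vg = value_and_grad(total_fn)

    history: list[dict] = []
    best_total = np.inf
    best_flat = flat.copy()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(M)
        for lo in range(0, M, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = Xtr[idx]
            if config.input_noise_std > 0:
                xb = xb + config.input_noise_std * noise_rng.standard_normal(xb.shape)
            ec = eps_rng.standard_normal((len(idx), config.context_size))
            el = eps_rng.standard_normal((len(idx), W, config.local_size))
            p = unflatten(flat)
            total, grad = vg(p, xb, ec, el)
            if not np.isfinite(total):
                parts = loss_batch(p, config, xb, ec, el)
                term = next(
                    (k for k, v in parts.items() if not np.isfinite(float(v))),
                    "total",
                )
                raise TrainingDiverged(epoch, term)
            flat = opt.step(flat, flatten(grad)[0])

        p = unflatten(flat)
        train_bd = _breakdown(p, config, Xtr, eval_rng)
        val_bd = train_bd if Xva is None else _breakdown(p, config, Xva, eval_rng)
        history.append(
            {"epoch": epoch, "train": train_bd.to_dict(), "val": val_bd.to_dict()}
        )
        if val_bd.total < best_total:
            best_total = val_bd.total
            best_flat = flat.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break

    return unflatten(best_flat), history


def train_model(train_windows, val_windows, config: ModelConfig | dict) -> BaseSequenceVAE:
    """Train one model from a config; returns the fitted estimator."""
    est = make_estimator(config)
    Xtr = train_windows if isinstance(train_windows, np.ndarray) else windows_to_array(train_windows)
    Xva = None
    if val_windows is not None:
        Xva = val_windows if isinstance(val_windows, np.ndarray) else windows_to_array(val_windows)
    return est.fit(Xtr, X_val=Xva)


@dataclass
class GridResult:
    """Outcome of a (config x seed) grid.

    ``runs[(config_index, seed)]`` is the final (best-epoch) validation
    LossBreakdown; ``mean_val_total[config_index]`` averages it across
    seeds (NaN for configs with any diverged run, which are excluded from
    selection); ``selected_index`` minimizes the mean, ties broken by the
    lowest config index.
    """

    configs: list[ModelConfig]
    seeds: list[int]
    runs: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    mean_val_total: list = field(default_factory=list)
    invalid: list = field(default_factory=list)
    selected_index: int = -1

    @property
    def selected_config(self) -> ModelConfig:
        return self.configs[self.selected_index]

    def selected_models(self) -> dict:
        return {s: self.models[(self.selected_index, s)] for s in self.seeds}


def grid_search(
    train_windows,
    val_windows,
    configs: Sequence[ModelConfig | dict],
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> GridResult:
    """Train every (config, seed) pair and select the config with the best
    mean validation total across seeds.

    A run that diverges marks its config invalid and excludes it from
    selection; the divergence is recorded in ``result.invalid``.
    """
    if not configs or not seeds:
        raise ValueError("need at least one config and one seed")
    cfgs = [c if isinstance(c, ModelConfig) else ModelConfig(**c) for c in configs]
    Xtr = train_windows if isinstance(train_windows, np.ndarray) else windows_to_array(train_windows)
    Xva = val_windows if isinstance(val_windows, np.ndarray) or val_windows is None else windows_to_array(val_windows)

    result = GridResult(configs=cfgs, seeds=list(seeds))
    for ci, cfg in enumerate(cfgs):
        totals = []
        valid = True
        for seed in seeds:
            run_cfg = dataclasses.replace(cfg, seed=int(seed))
            try:
                est = train_model(Xtr, Xva, run_cfg)
            except TrainingDiverged as err:
                result.invalid.append({"config_index": ci, "seed": int(seed),
                                       "error": str(err)})
                valid = False
                continue
            history = est.history_
            if history:
                best = min(history, key=lambda h: h["val"]["total"])
                bd = LossBreakdown(**best["val"])
            else:  # max_epochs == 0: evaluate the initialization
                bd = est.loss_breakdown(Xva if Xva is not None else Xtr)
            result.runs[(ci, int(seed))] = bd
            result.models[(ci, int(seed))] = est
            totals.append(bd.total)
        result.mean_val_total.append(
            float(np.mean(totals)) if valid and totals else float("nan")
        )

    valid_idx = [i for i, m in enumerate(result.mean_val_total) if np.isfinite(m)]
    if not valid_idx:
        raise RuntimeError("every grid configuration diverged")
    # min with ties broken by lowest index (list order is index order)
    result.selected_index = min(valid_idx, key=lambda i: (result.mean_val_total[i], i))
    return result


def embed_dataset(
    model: BaseSequenceVAE,
    windows: Sequence[Window],
    split: DatasetSplit,
    diagnoses: Mapping[str, str],
) -> EmbeddingTable:
    """Embed windows with a trained model into an EmbeddingTable.

    Context embeddings are posterior means (no sampling); the lvae variant
    substitutes time-averaged local posterior means. Each row carries
    (subject_id, window_start, split, diagnosis).
    """
    for w in windows:
        if w.subject_id not in split.assignment:
            raise KeyError(f"subject {w.subject_id!r} has no split assignment")
        if w.subject_id not in diagnoses:
            raise KeyError(f"subject {w.subject_id!r} has no diagnosis")
    Z = model.transform(windows_to_array(windows))
    return EmbeddingTable(
        subject_ids=np.array([w.subject_id for w in windows], dtype=object),
        window_starts=np.array([w.start for w in windows], dtype=int),
        splits=np.array([split[w.subject_id] for w in windows], dtype=object),
        diagnoses=np.array([diagnoses[w.subject_id] for w in windows], dtype=object),
        embeddings=Z,
    )
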