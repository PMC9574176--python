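"""Mini-batch Adam training with patience-based early stopping.

The defining training choice is the mini-batch strategy: every mini-batch is
drawn from the pooled cells of *all* batches (a random permutation of the
whole dataset chopped into blocks), so each mini-batch follows the global
mixture distribution rather than any single batch's. The by-batch ablation
(`sample_by_batch_no_bn`) instead permutes within each batch and emits
single-batch blocks.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from anndata import AnnData

from .network import IntegrationVAE, LossComponents, ModelConfig
from .preprocess import BATCH_KEY


@dataclass
class TrainConfig:
    """Optimizer and stopping settings (Adam, lr 2e-4, weight decay 5e-4,
    mini-batch 64, at most 30,000 iterations, patience 10 epochs)."""

    lr: float = 2e-4
    weight_decay: float = 5e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    minibatch_size: int = 64
    max_iterations: int = 30_000
    patience_epochs: int = 10
    improvement_tol: float = 1e-4
    seed: int = 0
    grad_clip: float | None = None

    def __post_init__(self):
        if self.minibatch_size < 1 or self.patience_epochs < 1 or self.max_iterations < 1:
            raise ValueError("minibatch_size, patience_epochs, max_iterations must be >= 1")


@dataclass
class TrainLog:
    """Per-epoch mean loss trajectory and the stopping outcome."""

    epochs: list[dict] = field(default_factory=list)
    iterations: int = 0
    stop_reason: str = ""
    best_epoch: int = -1
    wall_time: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


class Adam:
    """Adam with torch-style coupled L2 weight decay."""

    def __init__(self, params, lr, betas, weight_decay):
        self.params = params  # list of (name, value, grad)
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self, grad_clip: float | None = None):
        self.t += 1
        if grad_clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for _, _, g in self.params))
            if norm > grad_clip:
                for _, _, g in self.params:
                    g *= grad_clip / norm
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, (_, p, g) in enumerate(self.params):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + 1e-8)


def sample_minibatches(
    n_cells: int,
    size: int,
    rng: np.random.Generator,
    domains: np.ndarray | None = None,
    by_batch: bool = False,
):
    """Yield one epoch of row-index blocks.

    Default: a random permutation of all cells pooled across batches, chopped
    into consecutive blocks of ``size`` (the last block may be smaller).
    ``by_batch=True``: permute within each batch and emit single-batch blocks
    in shuffled order (the ablation sampling scheme).
    """
    if n_cells == 0:
        raise ValueError("empty data")
    if not by_batch:
        perm = rng.permutation(n_cells)
        for start in range(0, n_cells, size):
            yield perm[start : start + size]
        return
    if domains is None:
        raise ValueError("by-batch sampling needs domain labels")
    blocks = []
    for d in np.unique(domains):
        rows = np.flatnonzero(domains == d)
        perm = rows[rng.permutation(rows.size)]
        blocks += [perm[s : s + size] for s in range(0, rows.size, size)]
    for i in rng.permutation(len(blocks)):
        yield blocks[i]


def build_domain_index(batch_labels) -> tuple[np.ndarray, list[str]]:
    """Stable integer encoding of batch labels (sorted label order)."""
    labels = np.asarray(batch_labels).astype(str)
    names = sorted(set(labels))
    lut = {b: i for i, b in enumerate(names)}
    return np.array([lut[b] for b in labels]), names


def fit(
    data: AnnData,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    batch_key: str = BATCH_KEY,
    verbose: bool = False,
) -> tuple[IntegrationVAE, TrainLog]:
    """Train the VAE on a preprocessed (0-1 scaled) matrix.

    The monitored quantity for early stopping is the epoch-mean training
    total loss; training halts at ``max_iterations`` or after
    ``patience_epochs`` epochs without improvement beyond ``improvement_tol``,
    and the parameters from the best-loss epoch are returned.
    """
    train_cfg = train_cfg or TrainConfig()
    from .network import DTYPE

    X = np.asarray(
        data.X.todense() if hasattr(data.X, "todense") else data.X, dtype=DTYPE
    )
    if X.min() < 0 or X.max() > 1 + 1e-9:
        raise ValueError("fit expects [0, 1]-scaled input; run preprocessing first")
    domains, domain_names = build_domain_index(data.obs[batch_key])
    if model_cfg is None:
        model_cfg = ModelConfig(n_features=X.shape[1], n_domains=len(domain_names))
    if model_cfg.n_features != X.shape[1]:
        raise ValueError("model n_features does not match the data width")
    if model_cfg.n_domains != len(domain_names):
        raise ValueError("model n_domains does not match the batch label set")

    by_batch = model_cfg.variant == "sample_by_batch_no_bn"
    plain = model_cfg.variant == "plain_autoencoder"

    model = IntegrationVAE(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), train_cfg.lr, train_cfg.adam_betas, train_cfg.weight_decay)
    rng_batch = np.random.default_rng([train_cfg.seed, 1])
    rng_eps = np.random.default_rng([train_cfg.seed, 2])

    log = TrainLog()
    best_loss = np.inf
    best_state = None
    epochs_since_improvement = 0
    t0 = time.perf_counter()
    iteration = 0
    epoch = 0
    stop = None
    while stop is None:
        epoch += 1
        sums = np.zeros(3)
        n_seen = 0
        for rows in sample_minibatches(
            X.shape[0], train_cfg.minibatch_size, rng_batch, domains, by_batch
        ):
            if rows.size == 1:
                warnings.warn(f"mini-batch of a single cell at iteration {iteration}")
            eps = None if plain else rng_eps.standard_normal((rows.size, model_cfg.latent_dim))
            model.zero_grad()
            try:
                loss = model.forward_backward(X[rows], domains[rows], eps)
            except FloatingPointError as e:
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, iteration {iteration}"
                ) from e
            opt.step(train_cfg.grad_clip)
            sums += np.array([loss.total, loss.reconstruction, loss.kl]) * rows.size
            n_seen += rows.size
            iteration += 1
            if iteration >= train_cfg.max_iterations:
                stop = "max_iter"
                break
        mean = sums / n_seen
        log.epochs.append(
            {
                "epoch": epoch,
                "total": float(mean[0]),
                "reconstruction": float(mean[1]),
                "kl": float(mean[2]),
                "iterations": iteration,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:4d}  total {mean[0]:.4f}  recon {mean[1]:.4f}  "
                f"kl {mean[2]:.4f}",
                flush=True,
            )
        if mean[0] < best_loss - train_cfg.improvement_tol:
            best_loss = mean[0]
            best_state = model.state_dict()
            log.best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
            if stop is None and epochs_since_improvement >= train_cfg.patience_epochs:
                stop = "early_stop"

    if best_state is not None:
        model.load_state_dict(best_state)
    log.iterations = iteration
    log.stop_reason = stop
    log.wall_time = time.perf_counter() - t0
    model._feature_names = list(data.var_names)
    model._domain_names = domain_names
    return model, log


def save_model(model: IntegrationVAE, path) -> None:
    model.save(
        path,
        feature_names=getattr(model, "_feature_names", None),
        domain_names=getattr(model, "_domain_names", None),
    )


def load_model(path) -> IntegrationVAE:
    model, header = IntegrationVAE.load(path)
    model._feature_names = header["feature_names"]
    model._domain_names = header["domain_names"]
    return model
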