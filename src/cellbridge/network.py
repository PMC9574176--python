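"""The integration VAE: batch-free encoder, DSBN decoder, ELBO loss.

The network maps cells from any batch into a shared low-dimensional latent
space. Batch identity is withheld from the encoder entirely — it sees only
the [0, 1]-scaled expression profile — and is re-introduced in the decoder
through domain-specific batch normalization (DSBN), one set of affine
parameters and running statistics per training batch. The encoder therefore
learns batch-invariant structure and generalizes to unseen batches, which is
what makes projection without retraining possible.

Architecture:

    encoder:  fc(n_features -> 1024) - BN - ReLU - fc(1024 -> 10) x 2 (mu, logvar)
    decoder:  fc(10 -> n_features) - DSBN - sigmoid

Loss (per mini-batch): binary cross entropy summed over features and averaged
over cells, plus ``beta`` times the KL divergence of the Gaussian posterior
from the standard-normal prior (default beta = 0.5).

All forward and backward passes are written directly in numpy; gradients are
exact and the module has no deep-learning-framework dependency. Ablation
variants of the architecture are selected through ``ModelConfig.variant``.
"""

from __future__ import annotations

import io
import json
import warnings
import zipfile
from dataclasses import dataclass, asdict, field

import numpy as np

FORMAT_VERSION = 1
DTYPE = np.float32  # network compute dtype; loss helpers follow their input dtype
VARIANTS = (
    "full",
    "encoder_with_batch",
    "no_dsbn",
    "sample_by_batch_no_bn",
    "plain_autoencoder",
)
_BCE_EPS = 1e-8


@dataclass
class ModelConfig:
    """Network topology and loss settings."""

    n_features: int
    n_domains: int
    latent_dim: int = 10
    hidden_dim: int = 1024
    beta: float = 0.5
    variant: str = "full"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.latent_dim < 1 or self.n_domains < 1 or self.n_features < 1:
            raise ValueError("latent_dim, n_domains and n_features must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")

    @property
    def encoder_in_features(self) -> int:
        """Encoder input width; the batch-label ablation appends a one-hot block."""
        if self.variant == "encoder_with_batch":
            return self.n_features + self.n_domains
        return self.n_features

    @property
    def encoder_has_bn(self) -> bool:
        return self.variant != "sample_by_batch_no_bn"

    @property
    def decoder_n_domains(self) -> int:
        """The no-DSBN ablation shares a single BN across all batches."""
        return 1 if self.variant == "no_dsbn" else self.n_domains


@dataclass
class LossComponents:
    total: float
    reconstruction: float
    kl: float


# ---------------------------------------------------------------------------
# layers


class Linear:
    """Affine map with cached input for the backward pass."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Kaiming-uniform fan-in init, zero biases
        bound = np.sqrt(6.0 / n_in) / np.sqrt(2.0)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        self.gW += self._x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.W.T if need_dx else None

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]


class BatchNorm:
    """Batch normalization over features.

    Train mode whitens with mini-batch moments and updates running statistics
    by exponential moving average; eval mode uses the running statistics so
    the map is deterministic per cell.
    """

    def __init__(self, n: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, cache: bool = False) -> np.ndarray:
        if train:
            m = x.shape[0]
            if m == 1:
                warnings.warn("batch norm over a single sample: variance is 0")
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * invstd
            # torch-style running update; unbiased variance when possible
            var_u = var * m / (m - 1) if m > 1 else var
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var_u
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * invstd
        if cache:
            self._cache = (xhat, invstd, train)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self.ggamma += (dy * xhat).sum(axis=0)
        self.gbeta += dy.sum(axis=0)
        if not train:
            return dy * self.gamma * invstd
        m = dy.shape[0]
        dxhat = dy * self.gamma
        return (
            invstd
            / m
            * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def stats(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class DSBN:
    """Domain-specific batch normalization: one BatchNorm branch per domain.

    Rows of a mini-batch are partitioned by their domain (batch) label and
    each partition is normalized by its own branch; outputs are reassembled
    in the input row order.
    """

    def __init__(self, n: int, n_domains: int, eps: float = 1e-5, momentum: float = 0.1):
        self.branches = [BatchNorm(n, eps, momentum) for _ in range(n_domains)]
        self._order = None

    @property
    def n_domains(self) -> int:
        return len(self.branches)

    def forward(
        self, x: np.ndarray, domains: np.ndarray, train: bool, cache: bool = False
    ) -> np.ndarray:
        domains = np.asarray(domains)
        if domains.shape[0] != x.shape[0]:
            raise ValueError("one domain label per row required")
        bad = (domains < 0) | (domains >= self.n_domains)
        if bad.any():
            raise ValueError(f"unknown domain label(s): {np.unique(domains[bad])}")
        y = np.empty_like(x)
        order = []
        for d in range(self.n_domains):
            rows = np.flatnonzero(domains == d)
            if rows.size == 0:
                continue
            y[rows] = self.branches[d].forward(x[rows], train=train, cache=cache)
            order.append((d, rows))
        if cache:
            self._order = order
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.empty_like(dy)
        for d, rows in self._order:
            dx[rows] = self.branches[d].backward(dy[rows])
        return dx

    def params(self):
        out = []
        for d, br in enumerate(self.branches):
            out += [(f"d{d}.{n}", p, g) for n, p, g in br.params()]
        return out

    def stats(self):
        out = []
        for d, br in enumerate(self.branches):
            out += [(f"d{d}.{n}", s) for n, s in br.stats()]
        return out


# ---------------------------------------------------------------------------
# stateless math


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def reparameterize(
    mu: np.ndarray, logvar: np.ndarray, eps: np.ndarray
) -> np.ndarray:
    """z = mu + sigma * eps with sigma = exp(logvar / 2)."""
    if not (mu.shape == logvar.shape == eps.shape):
        raise ValueError("mu, logvar and eps must share a shape")
    return mu + np.exp(0.5 * logvar) * eps


def elbo_loss(
    x: np.ndarray,
    xhat: np.ndarray,
    mu: np.ndarray,
    logvar: np.ndarray,
    beta: float,
) -> LossComponents:
    """Reconstruction BCE (sum over features, mean over cells) plus beta x KL.

    The KL term is the closed-form divergence of N(mu, diag(sigma^2)) from
    N(0, I): 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2), averaged over cells.
    """
    m = x.shape[0]
    xc = np.clip(xhat, _BCE_EPS, 1.0 - _BCE_EPS)
    recon = float(-(x * np.log(xc) + (1 - x) * np.log(1 - xc)).sum() / m)
    kl = float(0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum() / m)
    total = recon + beta * kl
    if not np.isfinite(total):
        raise FloatingPointError("non-finite loss")
    return LossComponents(total=total, reconstruction=recon, kl=kl)


# ---------------------------------------------------------------------------
# the model


class IntegrationVAE:
    """Batch-free encoder + DSBN decoder, trained on [0, 1]-scaled profiles."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.fc1 = Linear(c.encoder_in_features, c.hidden_dim, rng)
        self.enc_bn = BatchNorm(c.hidden_dim, c.bn_eps, c.bn_momentum) if c.encoder_has_bn else None
        self.fc_mu = Linear(c.hidden_dim, c.latent_dim, rng)
        self.fc_logvar = Linear(c.hidden_dim, c.latent_dim, rng)
        self.fc_out = Linear(c.latent_dim, c.n_features, rng)
        self.dsbn = DSBN(c.n_features, c.decoder_n_domains, c.bn_eps, c.bn_momentum)
        self._cache = None

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        layers = [("fc1", self.fc1)]
        if self.enc_bn is not None:
            layers.append(("enc_bn", self.enc_bn))
        layers += [
            ("fc_mu", self.fc_mu),
            ("fc_logvar", self.fc_logvar),
            ("fc_out", self.fc_out),
            ("dsbn", self.dsbn),
        ]
        return layers

    def parameters(self):
        """Learnable parameters as (name, array, grad) triples."""
        out = []
        for lname, layer in self._layers():
            out += [(f"{lname}.{n}", p, g) for n, p, g in layer.params()]
        return out

    def running_stats(self):
        out = []
        for lname, layer in self._layers():
            if hasattr(layer, "stats"):
                out += [(f"{lname}.{n}", s) for n, s in layer.stats()]
        return out

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.copy() for name, p, _ in self.parameters()}
        state.update({f"stats.{name}": s.copy() for name, s in self.running_stats()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            p[...] = state[name]
        for name, s in self.running_stats():
            s[...] = state[f"stats.{name}"]

    def checksum(self) -> int:
        """Order-stable hash of every parameter and running statistic."""
        import hashlib

        h = hashlib.sha256()
        for name, p, _ in self.parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p).tobytes())
        for name, s in self.running_stats():
            h.update(name.encode())
            h.update(np.ascontiguousarray(s).tobytes())
        return int.from_bytes(h.digest()[:8], "big")

    # -- forward -----------------------------------------------------------

    def _encoder_input(self, x: np.ndarray, domains: np.ndarray | None) -> np.ndarray:
        if self.config.variant != "encoder_with_batch":
            return x
        if domains is None:
            raise ValueError(
                "the encoder_with_batch ablation needs domain labels at encode "
                "time and cannot project unseen batches"
            )
        onehot = np.zeros((x.shape[0], self.config.n_domains), dtype=x.dtype)
        onehot[np.arange(x.shape[0]), np.asarray(domains)] = 1.0
        return np.concatenate([x, onehot], axis=1)

    def encode(
        self,
        x: np.ndarray,
        train: bool = False,
        cache: bool = False,
        domains: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for each row of ``x``.

        In eval mode batch norm uses running statistics, so each cell's output
        is independent of whatever else is in the array.
        """
        xin = self._encoder_input(np.asarray(x, dtype=DTYPE), domains)
        if xin.shape[1] != self.config.encoder_in_features:
            raise ValueError(
                f"expected {self.config.encoder_in_features} input features, "
                f"got {xin.shape[1]}"
            )
        h = self.fc1.forward(xin, cache=cache)
        if self.enc_bn is not None:
            h = self.enc_bn.forward(h, train=train, cache=cache)
        a = relu(h)
        if cache:
            self._cache = {"h_pre_relu": h, "a": a}
            self.fc_mu._x = a
            self.fc_logvar._x = a
        mu = self.fc_mu.forward(a, cache=False)
        logvar = self.fc_logvar.forward(a, cache=False)
        return mu, logvar

    def decode(
        self,
        z: np.ndarray,
        domains: np.ndarray,
        train: bool = False,
        cache: bool = False,
    ) -> np.ndarray:
        """Reconstruct [0, 1] profiles from latent coordinates and batch labels."""
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"z must have width {self.config.latent_dim}")
        if self.config.variant == "no_dsbn":
            domains = np.zeros(z.shape[0], dtype=int)
        u = self.fc_out.forward(z, cache=cache)
        v = self.dsbn.forward(u, domains, train=train, cache=cache)
        if cache:
            self._cache["v"] = v
        return sigmoid(v)

    # -- training step -----------------------------------------------------

    def forward_backward(
        self, x: np.ndarray, domains: np.ndarray, eps: np.ndarray | None
    ) -> LossComponents:
        """One train-mode forward pass, loss, and exact gradient accumulation.

        ``eps`` is the standard-normal draw for the reparameterization; the
        plain-autoencoder variant ignores it and uses z = mu with no KL term.
        """
        cfg = self.config
        x = np.asarray(x, dtype=DTYPE)
        m = x.shape[0]
        plain = cfg.variant == "plain_autoencoder"

        mu, logvar = self.encode(x, train=True, cache=True, domains=domains)
        if plain:
            z = mu
        else:
            z = reparameterize(mu, logvar, np.asarray(eps, dtype=DTYPE))
        xhat = self.decode(z, domains, train=True, cache=True)

        beta = 0.0 if plain else cfg.beta
        loss = elbo_loss(x, xhat, mu, logvar, beta)
        if plain:
            loss = LossComponents(loss.reconstruction, loss.reconstruction, 0.0)

        # ---- backward
        # BCE + sigmoid shortcut: dL/dv = (xhat - x) / m
        dv = (xhat - x) / m
        du = self.dsbn.backward(dv)
        dz = self.fc_out.backward(du, need_dx=True)

        if plain:
            dmu = dz
            dlogvar = np.zeros_like(dz)
        else:
            dmu = dz + beta * mu / m
            dlogvar = dz * (z - mu) * 0.5 + beta * 0.5 * (np.exp(logvar) - 1.0) / m

        self.fc_mu._x = self._cache["a"]
        da = self.fc_mu.backward(dmu, need_dx=True)
        self.fc_logvar._x = self._cache["a"]
        da += self.fc_logvar.backward(dlogvar, need_dx=True)
        dh = da * (self._cache["h_pre_relu"] > 0)
        if self.enc_bn is not None:
            dh = self.enc_bn.backward(dh)
        self.fc1.backward(dh, need_dx=False)
        return loss

    # -- serialization -----------------------------------------------------

    def save(
        self,
        path,
        feature_names: list[str] | None = None,
        domain_names: list[str] | None = None,
        extra: dict | None = None,
    ) -> None:
        """Write a single-file archive: config, vocabularies, all arrays."""
        header = {
            "format_version": FORMAT_VERSION,
            "config": asdict(self.config),
            "feature_names": list(feature_names) if feature_names is not None else None,
            "domain_names": list(domain_names) if domain_names is not None else None,
            "extra": extra or {},
        }
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> tuple["IntegrationVAE", dict]:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header["format_version"] != FORMAT_VERSION:
                raise ValueError(
                    f"incompatible model format {header['format_version']} "
                    f"(this build reads {FORMAT_VERSION})"
                )
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            model = cls(ModelConfig(**header["config"]))
            model.load_state_dict({k: arrays[k] for k in arrays.files})
        return model, header


def expected_parameter_count(config: ModelConfig) -> int:
    """Closed-form learnable-parameter count for the declared topology."""
    c = config
    f_in, h, L, f, d = (
        c.encoder_in_features,
        c.hidden_dim,
        c.latent_dim,
        c.n_features,
        c.decoder_n_domains,
    )
    n = f_in * h + h  # encoder affine
    if c.encoder_has_bn:
        n += 2 * h  # encoder BN gamma/beta
    n += 2 * (h * L + L)  # mu and logvar heads
    n += L * f + f  # decoder affine
    n += 2 * d * f  # DSBN affine parameters
    return n
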