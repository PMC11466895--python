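"""Fully connected networks for deformation estimation.

All coordinates handed to the coordinate-based networks are in
normalized box units (the box maps to [-1, 1]); displacements are
returned in the same units.  The networks are parametrized with the
in-package autodiff engine (:mod:`cryodeform.autodiff`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


# ----------------------------------------------------------------------
def positional_encode(x, n_freqs: int = 10):
    """Sin/cos lifting of 3-D coordinates.

    For each coordinate d and octave m = 0..n_freqs-1 the features
    sin(2^m pi x_d) and cos(2^m pi x_d) are emitted; the three raw
    coordinates are appended, giving 6*n_freqs + 3 features (63 for the
    default ten octaves).
    """
    t = ad.as_tensor(x)
    feats = [t]
    for m in range(n_freqs):
        s = ad.mul(t, float(2 ** m) * np.pi)
        feats.append(ad.sin(s))
        feats.append(ad.cos(s))
    return ad.concat(feats, axis=-1)


def posenc_dim(n_freqs: int = 10) -> int:
    return 3 + 6 * n_freqs


# ----------------------------------------------------------------------
class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        if scale is None:
            scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return ad.add(ad.matmul(x, self.W), self.b)

    @property
    def params(self):
        return [self.W, self.b]


def _mlp(dims, rng, zero_last=False):
    layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
    if zero_last:
        layers[-1].W.data[:] = 0.0
        layers[-1].b.data[:] = 0.0
    return layers


def n_parameters(layers) -> int:
    return sum(p.data.size for l in layers for p in l.params)


# ----------------------------------------------------------------------
@dataclass
class LatentCode:
    """Per-image latent posterior: mean, standard deviation, and a sample."""

    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray | None = None


class Encoder:
    """Image -> latent posterior. Three linear layers with ReLU.

    The half-log-variance head starts at zero weight/bias so that
    sigma ~= 1 at initialization.
    """

    def __init__(self, n_pixels: int, latent_dim: int = 10, hidden: int = 128,
                 rng: np.random.Generator | None = None,
                 input_scale: float = 1.0):
        rng = rng or np.random.default_rng(0)
        self.latent_dim = latent_dim
        self.input_scale = float(input_scale)  # images are divided by this
        self.l1 = Linear(n_pixels, hidden, rng)
        self.l2 = Linear(hidden, hidden, rng)
        self.head = Linear(hidden, 2 * latent_dim, rng, scale=1e-3)
        self.head.W.data[:, latent_dim:] = 0.0  # log-sigma head: sigma = 1

    def __call__(self, images):
        """`images`: (B, n_pixels) Tensor or array -> (mu, log_sigma) Tensors."""
        if not isinstance(images, Tensor):
            images = Tensor(np.asarray(images, dtype=np.float64)
                            / self.input_scale)
        h = ad.relu(self.l1(images))
        h = ad.relu(self.l2(h))
        out = self.head(h)
        nl = self.latent_dim
        mu = ad.take(ad.reshape(out, (-1, 2, nl)), np.array([0]), axis=1)
        ls = ad.take(ad.reshape(out, (-1, 2, nl)), np.array([1]), axis=1)
        return ad.reshape(mu, (-1, nl)), ad.reshape(ls, (-1, nl))

    def encode(self, images) -> LatentCode:
        """Numpy convenience wrapper returning a :class:`LatentCode`."""
        with ad.no_grad():
            mu, ls = self(np.atleast_2d(np.asarray(images, dtype=np.float64)))
        return LatentCode(mu=mu.data.copy(), sigma=np.exp(ls.data))

    @property
    def params(self):
        return self.l1.params + self.l2.params + self.head.params


def sample_latent(code: LatentCode, rng: np.random.Generator) -> np.ndarray:
    """Reparametrized sample z = mu + sigma * eps, eps ~ N(0, I)."""
    eps = rng.standard_normal(code.mu.shape)
    code.z = code.mu + code.sigma * eps
    return code.z


class DeformationDecoder:
    """Coordinate-based deformation decoder.

    Takes (positional encoding of a consensus position, latent code) and
    returns the displaced position: D(z, x) = x + delta(z, x).  Eight
    linear layers with ELU activations; the final layer is
    zero-initialized so the deformation starts as the identity.
    """

    def __init__(self, latent_dim: int = 10, hidden: int = 64,
                 n_freqs: int = 10, n_layers: int = 8,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.latent_dim = latent_dim
        self.n_freqs = n_freqs
        dims = [posenc_dim(n_freqs) + latent_dim] + [hidden] * (n_layers - 1) + [3]
        self.layers = _mlp(dims, rng, zero_last=True)

    def displacement(self, z, pos_enc):
        """delta for stacked rows: z (R, nl), pos_enc (R, F) -> (R, 3)."""
        h = ad.concat([ad.as_tensor(pos_enc), ad.as_tensor(z)], axis=-1)
        for layer in self.layers[:-1]:
            h = ad.elu(layer(h))
        return self.layers[-1](h)

    def decode(self, z: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Numpy path: deformed positions (normalized units).

        z: (nl,) or (B, nl); positions: (Ng, 3) normalized.  Returns
        (Ng, 3) or (B, Ng, 3).
        """
        single = np.asarray(z).ndim == 1
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        b, ng = z.shape[0], positions.shape[0]
        with ad.no_grad():
            pe = positional_encode(positions, self.n_freqs)
            pe_t = ad.tile_rows(pe, b)
            z_t = ad.repeat_rows(Tensor(z), ng)
            delta = self.displacement(z_t, pe_t)
        out = positions[None] + delta.data.reshape(b, ng, 3)
        return out[0] if single else out

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]


class InverseDeformationNet:
    """Maps (latent, deformed position) back to the consensus position.

    Six linear layers with ELU and a single additive residual connection
    to the queried position; zero-initialized final layer so the map
    starts as the identity.
    """

    def __init__(self, latent_dim: int = 10, hidden: int = 64,
                 n_freqs: int = 10, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.latent_dim = latent_dim
        self.n_freqs = n_freqs
        dims = [posenc_dim(n_freqs) + latent_dim] + [hidden] * 5 + [3]
        self.layers = _mlp(dims, rng, zero_last=True)

    def residual(self, z, pos_enc):
        h = ad.concat([ad.as_tensor(pos_enc), ad.as_tensor(z)], axis=-1)
        for layer in self.layers[:-1]:
            h = ad.elu(layer(h))
        return self.layers[-1](h)

    def map_back(self, z: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Numpy path: positions (M, 3) normalized, z (nl,) or (M, nl)."""
        positions = np.asarray(positions, dtype=np.float64)
        z = np.asarray(z, dtype=np.float64)
        if z.ndim == 1:
            z = np.broadcast_to(z, (positions.shape[0], z.shape[0]))
        with ad.no_grad():
            pe = positional_encode(positions, self.n_freqs)
            res = self.residual(Tensor(z), pe)
        return positions + res.data

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]


# ----------------------------------------------------------------------
class Adam:
    """ADAM optimizer over a list of autodiff parameters."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
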