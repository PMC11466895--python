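"""Per-half-set variational autoencoder for deformation estimation.

Training follows the schedule used for the half-set deformation VAEs:

* a warm-up phase in which only the Gaussian reference parameters
  (positions, widths, amplitudes, class weights) are optimized;
* joint optimization of encoder, decoder and reference afterwards, with
  ADAM (reference/decoder lr 1e-4, encoder lr 1e-3);
* after every 30 network epochs the networks are frozen for 5 epochs;
* at every 10th unfrozen epoch the reference positions are replaced by
  the predicted conformation with the smallest mean displacement;
* a dynamic regularization weight lambda balances the gradient norms of
  the data and regularization terms to a user ratio r (default 0.9);
* training stops when the data loss has increased a cumulative k times
  (default 40) or the epoch budget is exhausted.

The smoothness regularization graph is rebuilt from the reference after
every epoch, and the repulsion distance tau is set to its mean 2-NN
edge length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import forward_model as fm
from .autodiff import Tensor
from .gaussian_model import GaussianModel, EdgeGraph, build_neighbor_graph
from .io_formats import ParticleStack
from .networks import Adam, DeformationDecoder, Encoder, positional_encode

__all__ = [
    "TrainingConfig", "StopRule", "networks_active", "isometry_regularizer",
    "repulsion_regularizer", "update_lambda", "HalfSetTrainer",
    "train_halfset_vae", "train_two_halfsets",
    "synchronize_halfset_references", "decode_positions",
]


@dataclass
class TrainingConfig:
    n_epochs: int = 200               # post-warm-up epoch budget
    warmup_epochs: int = 10
    batch_size: int = 16
    lr_gaussian: float = 1e-4
    lr_encoder: float = 1e-3
    lr_decoder: float = 1e-4
    lr_gaussian_refine: float | None = None  # reference lr after warm-up
    ratio_target: float = 0.9         # gradient-norm balance r
    stop_count: int = 40              # k: cumulative data-loss increases
    freeze_period: int = 30           # network epochs between freezes
    freeze_length: int = 5
    replace_period: int = 10          # every 10th unfrozen epoch
    kl_weight: float = 1e-3           # relative to the data-loss scale
    latent_dim: int = 10
    n_freqs: int = 10                 # positional-encoding octaves
    encoder_hidden: int = 128
    decoder_hidden: int = 64
    oversample: int = 2
    seed: int = 0
    probe_size: int = 100             # particles for replacement probe

    def __post_init__(self):
        if not 0.0 < self.ratio_target <= 1.0:
            raise ValueError("ratio_target must be in (0, 1]")
        for name in ("warmup_epochs", "batch_size", "freeze_period",
                     "freeze_length", "replace_period", "stop_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_small_problem(cls, n_epochs: int = 120, seed: int = 0,
                          **overrides) -> "TrainingConfig":
        """Optimization settings for desk-scale problems (hundreds to a
        few thousand particles, small boxes).

        The schedule constants (freeze/replacement periods, stop counter,
        balance ratio) are unchanged; only optimizer step sizes, batch
        size and the warm-up length are adapted to the much smaller
        number of ADAM steps per epoch: smaller batches give more steps,
        a longer warm-up converges the reference before the networks
        start, and the network/reference learning rates are raised so
        convergence fits in tens of epochs instead of hundreds of
        thousands of steps.
        """
        defaults = dict(n_epochs=n_epochs, warmup_epochs=40, batch_size=8,
                        lr_gaussian=2e-3, lr_gaussian_refine=2e-4,
                        lr_encoder=2e-3, lr_decoder=5e-4, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


# ----------------------------------------------------------------------
# schedule primitives (unit-testable in isolation)
# ----------------------------------------------------------------------
def networks_active(epoch: int, config: TrainingConfig) -> bool:
    """Whether networks are updated in post-warm-up epoch `epoch` (1-based).

    Pattern: `freeze_period` active epochs followed by `freeze_length`
    frozen ones, repeating (epochs 31-35 and 66-70 frozen by default).
    """
    period = config.freeze_period + config.freeze_length
    return ((epoch - 1) % period) < config.freeze_period


class StopRule:
    """Stop when the data loss has increased a cumulative k times."""

    def __init__(self, k: int):
        self.k = k
        self.increases = 0
        self.prev = None

    def update(self, loss: float) -> bool:
        if self.prev is not None and loss > self.prev:
            self.increases += 1
        self.prev = loss
        return self.increases >= self.k


# ----------------------------------------------------------------------
# regularizers
# ----------------------------------------------------------------------
def _edge_lengths(pos, edges):
    """Edge lengths along the last-but-one axis; pos (.., Ng, 3)."""
    axis = (pos.ndim if isinstance(pos, Tensor) else np.asarray(pos).ndim) - 2
    if isinstance(pos, Tensor):
        pi = ad.take(pos, edges[:, 0], axis=axis)
        pj = ad.take(pos, edges[:, 1], axis=axis)
        return ad.norm_rows(pi - pj)
    pos = np.asarray(pos, dtype=float)
    diff = np.take(pos, edges[:, 0], axis=axis) - np.take(
        pos, edges[:, 1], axis=axis)
    return np.sqrt((diff ** 2).sum(axis=-1))


def isometry_regularizer(positions, deformed, graph: EdgeGraph):
    """Local-isometry penalty: sum over edges of
    (||c_i - c_j|| - ||G(c_i) - G(c_j)||)^2.

    `deformed` may be batched (B, Ng, 3); the batch mean of per-particle
    sums is returned then.  Zero under any global rigid motion.
    """
    if graph.n_edges == 0:
        return (Tensor(0.0) if isinstance(deformed, Tensor) else 0.0)
    d0 = _edge_lengths(positions, graph.edges)
    d1 = _edge_lengths(deformed, graph.edges)
    if isinstance(d1, Tensor) or isinstance(d0, Tensor):
        d0 = d0 if isinstance(d0, Tensor) else Tensor(d0)
        diff = ad.square(d0 - d1)
        total = ad.tsum(diff, axis=-1)
        return ad.tmean(total) if diff.ndim > 1 else total
    diff = (d0 - d1) ** 2
    return float(diff.sum(axis=-1).mean()) if diff.ndim > 1 else float(diff.sum())


def repulsion_regularizer(deformed, graph: EdgeGraph, tau: float):
    """Repulsion penalty: edges closer than tau pay (||.|| - tau)^2."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if graph.n_edges == 0:
        return (Tensor(0.0) if isinstance(deformed, Tensor) else 0.0)
    d1 = _edge_lengths(deformed, graph.edges)
    if isinstance(d1, Tensor):
        mask = (d1.data < tau).astype(float)
        pen = ad.mul(ad.square(d1 - tau), mask)
        total = ad.tsum(pen, axis=-1)
        return ad.tmean(total) if pen.ndim > 1 else total
    pen = np.where(d1 < tau, (d1 - tau) ** 2, 0.0)
    return float(pen.sum(axis=-1).mean()) if pen.ndim > 1 else float(pen.sum())


def update_lambda(grad_norm_data: float, grad_norm_reg: float, r: float,
                  prev_lambda: float = 0.0) -> float:
    """Balance gradient norms: lambda = r * ||grad F|| / ||grad R||."""
    if grad_norm_reg <= 0.0:
        warnings.warn("zero regularizer gradient; keeping previous lambda")
        return prev_lambda
    return r * grad_norm_data / grad_norm_reg


# ----------------------------------------------------------------------
def decode_positions(decoder: DeformationDecoder, z, centers_ang: np.ndarray,
                     half_extent: float) -> np.ndarray:
    """Deformed positions in Angstrom for latent(s) z."""
    out = decoder.decode(z, np.asarray(centers_ang) / half_extent)
    return out * half_extent


# ----------------------------------------------------------------------
class HalfSetTrainer:
    """Trains one half-set VAE; epochs are driven externally."""

    def __init__(self, stack: ParticleStack, train_idx, model: GaussianModel,
                 config: TrainingConfig, val_idx=None, name: str = "half",
                 quiet: bool = True):
        self.stack = stack
        self.cfg = config
        self.name = name
        self.quiet = quiet
        self.train_idx = np.asarray(train_idx)
        self.val_idx = (np.asarray(val_idx) if val_idx is not None
                        else np.empty(0, dtype=int))
        self.rng = np.random.default_rng(config.seed)

        n = stack.box_size
        self.n = n
        self.pixel = stack.pixel_size
        self.half_extent = (n * stack.pixel_size) / 2.0

        used = np.unique(np.concatenate([self.train_idx, self.val_idx]))
        self._ctf = np.zeros((len(stack), n, n))
        self._yfft = np.zeros((len(stack), n, n), dtype=complex)
        for i in used:
            self._ctf[i] = fm.ctf_evaluate(stack.ctfs[i], n, stack.pixel_size)
        self._yfft[used] = fm.image_to_fourier(stack.images[used])
        self._rots = np.stack([fm.rotation_matrix(*e) for e in stack.eulers])

        # reference parameters, normalized coordinates
        self.c0 = Tensor(model.centers / self.half_extent, requires_grad=True)
        self.log_s = Tensor(np.log(model.widths), requires_grad=True)
        self.log_a = Tensor(np.log(model.amplitudes), requires_grad=True)
        with np.errstate(divide="ignore"):
            logits = np.log(np.maximum(model.class_weights, 1e-12))
        self.d_logits = Tensor(logits, requires_grad=True)

        self.encoder = Encoder(n * n, config.latent_dim,
                               config.encoder_hidden, rng=self.rng)
        self.decoder = DeformationDecoder(config.latent_dim,
                                          config.decoder_hidden,
                                          config.n_freqs, rng=self.rng)
        self.opt_gauss = Adam([self.c0, self.log_s, self.log_a,
                               self.d_logits], lr=config.lr_gaussian)
        self.opt_enc = Adam(self.encoder.params, lr=config.lr_encoder)
        self.opt_dec = Adam(self.decoder.params, lr=config.lr_decoder)

        self.graph = build_neighbor_graph(model.centers)
        self.tau = self.graph.c_mean
        self.lambda_ = 0.0
        self.beta = 0.0
        self.noise = fm.estimate_noise_spectrum(
            stack, self.current_model(), subset=self._noise_subset())
        self.stop_rule = StopRule(config.stop_count)
        # encoder inputs are standardized by a single dataset-wide scale
        self._img_scale = float(stack.images[self.train_idx].std()) or 1.0
        self.encoder.input_scale = self._img_scale
        self.epoch = 0              # post-warm-up epochs completed
        self.warmups_done = 0
        self.unfrozen_count = 0
        self.stopped = False
        self.history = {"data": [], "reg": [], "lambda": []}
        self.probe_idx = self.train_idx[:min(config.probe_size,
                                             len(self.train_idx))]

    # -- helpers -------------------------------------------------------
    def _noise_subset(self):
        size = min(len(self.train_idx), 256)
        return self.train_idx[:size]

    def current_model(self) -> GaussianModel:
        d = np.exp(self.d_logits.data)
        d = d / d.sum(axis=0, keepdims=True)
        return GaussianModel(self.c0.data * self.half_extent,
                             np.exp(self.log_s.data),
                             np.exp(self.log_a.data), d)

    def _all_params(self):
        return ([self.c0, self.log_s, self.log_a, self.d_logits]
                + self.encoder.params + self.decoder.params)

    def _zero_grads(self):
        for p in self._all_params():
            p.grad = None

    def _losses(self, idx, use_network: bool, sample: bool = True):
        """Build the loss graph for one batch; returns a dict of Tensors."""
        b = len(idx)
        ng = self.c0.shape[0]
        out = {}
        if use_network:
            imgs = self.stack.images[idx].reshape(b, -1)
            mu, ls = self.encoder(imgs)
            sigma = ad.exp(ls)
            eps = (self.rng.standard_normal((b, self.cfg.latent_dim))
                   if sample else np.zeros((b, self.cfg.latent_dim)))
            z = mu + sigma * eps
            pe = positional_encode(self.c0, self.cfg.n_freqs)
            delta = self.decoder.displacement(
                ad.repeat_rows(z, ng), ad.tile_rows(pe, b))
            # tile_rows stacks the batch blocks; rows are (particle-major)
            delta = ad.reshape(delta, (b, ng, 3))
            pos_norm = ad.reshape(self.c0, (1, ng, 3)) + delta
            kl = ad.tmean(ad.tsum(
                ad.mul(ad.square(mu) + ad.square(sigma)
                       - 2.0 * ls - 1.0, 0.5), axis=-1))
            out["kl"] = kl
            out["mu"] = mu
        else:
            pos_norm = ad.reshape(self.c0, (1, ng, 3)) + np.zeros((b, 1, 1))
            out["kl"] = Tensor(0.0)

        pos_ang = ad.mul(pos_norm, self.half_extent)
        pts = fm.batched_project(pos_ang, self._rots[idx],
                                 self.stack.shifts[idx])
        d = ad.softmax(self.d_logits, axis=0)
        out["data"] = fm.projection_loss(
            pts, d, ad.exp(self.log_a), ad.exp(self.log_s),
            self._yfft[idx], self._ctf[idx], self.noise.per_pixel(),
            self.n, self.pixel, self.cfg.oversample)
        # The regularizers constrain the deformation field: the reference
        # is detached so their gradients act on the decoder only and do
        # not push the consensus model away from the data fit.
        if use_network:
            c_det = Tensor(self.c0.data.reshape(1, ng, 3) * self.half_extent)
            pos_reg = c_det + ad.mul(delta, self.half_extent)
            iso = isometry_regularizer(
                Tensor(self.c0.data * self.half_extent), pos_reg, self.graph)
            rep = repulsion_regularizer(pos_reg, self.graph, self.tau)
            out["reg"] = iso + rep
        else:
            out["reg"] = Tensor(0.0)
        return out

    def _grad_norm(self, params) -> float:
        return float(np.sqrt(sum(
            np.sum(p.grad ** 2) for p in params if p.grad is not None)))

    # -- schedule steps ------------------------------------------------
    def run_warmup_epoch(self):
        """One epoch optimizing only the Gaussian reference parameters."""
        self._run_epoch(use_network=False, step_gauss=True)
        self.warmups_done += 1

    def run_epoch(self):
        """One post-warm-up epoch with the full schedule bookkeeping."""
        if self.stopped:
            return
        if self.epoch == 0 and self.cfg.lr_gaussian_refine is not None:
            self.opt_gauss.lr = self.cfg.lr_gaussian_refine
        if self.beta == 0.0 and self.history["data"]:
            # a unit-Gaussian-scale KL (~latent_dim) contributes a
            # kl_weight fraction of the data loss
            self.beta = (self.cfg.kl_weight * abs(self.history["data"][-1])
                         / self.cfg.latent_dim)
        self.epoch += 1
        active = networks_active(self.epoch, self.cfg)
        mean_data = self._run_epoch(use_network=active, step_gauss=True,
                                    step_networks=active)
        if active:
            self.unfrozen_count += 1
            if self.unfrozen_count % self.cfg.replace_period == 0:
                self.replace_reference()
            self.update_lambda_from_probe()
        self.rebuild_graph()
        if self.stop_rule.update(mean_data):
            self.stopped = True

    def _run_epoch(self, use_network: bool, step_gauss: bool = True,
                   step_networks: bool = False) -> float:
        order = self.rng.permutation(self.train_idx)
        bs = self.cfg.batch_size
        data_sum, nb = 0.0, 0
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            if len(idx) == 0:
                continue
            losses = self._losses(idx, use_network)
            total = losses["data"] + self.lambda_ * losses["reg"]
            if use_network:
                total = total + self.beta * losses["kl"]
            self._zero_grads()
            total.backward()
            if step_gauss:
                self.opt_gauss.step()
            if step_networks:
                self.opt_enc.step()
                self.opt_dec.step()
            self._zero_grads()
            data_sum += losses["data"].item()
            nb += 1
        mean_data = data_sum / max(nb, 1)
        self.history["data"].append(mean_data)
        self.history["lambda"].append(self.lambda_)
        return mean_data

    def run_validation_embedding(self):
        """Encoder-only updates on the held-out validation particles.

        The validation images train their own latent embedding but never
        contribute gradients to the decoder or the reference model.
        """
        if len(self.val_idx) == 0:
            return
        bs = self.cfg.batch_size
        order = self.rng.permutation(self.val_idx)
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            losses = self._losses(idx, use_network=True)
            total = (losses["data"] + self.lambda_ * losses["reg"]
                     + self.beta * losses["kl"])
            self._zero_grads()
            total.backward()
            self.opt_enc.step()
            self._zero_grads()

    def update_lambda_from_probe(self):
        """Recompute lambda from decoder gradient norms on a fixed probe
        subset (larger than a training batch to stabilize the estimate)."""
        idx = self.probe_idx
        losses = self._losses(idx, use_network=True, sample=False)
        self._zero_grads()
        losses["data"].backward()
        gd = self._grad_norm(self.decoder.params)
        self._zero_grads()
        losses = self._losses(idx, use_network=True, sample=False)
        losses["reg"].backward()
        gr = self._grad_norm(self.decoder.params)
        self._zero_grads()
        self.lambda_ = update_lambda(gd, gr, self.cfg.ratio_target,
                                     self.lambda_)

    def measure_balance(self) -> float:
        """Re-measure ||grad(lambda R)|| / ||grad F|| on the probe subset."""
        idx = self.probe_idx
        losses = self._losses(idx, use_network=True, sample=False)
        self._zero_grads()
        losses["data"].backward()
        gd = self._grad_norm(self.decoder.params)
        self._zero_grads()
        losses = self._losses(idx, use_network=True, sample=False)
        (self.lambda_ * losses["reg"]).backward()
        gr = self._grad_norm(self.decoder.params)
        self._zero_grads()
        return gr / gd if gd > 0 else np.inf

    def replace_reference(self):
        """Replace c0 by the predicted conformation with the smallest mean
        displacement over the probe subset."""
        mu = self.encode_mu(self.probe_idx)
        pe = self.c0.data  # normalized consensus positions
        preds = self.decoder.decode(mu, pe)          # (P, Ng, 3) normalized
        disp = np.linalg.norm(preds - pe[None], axis=-1).mean(axis=1)
        best = int(np.argmin(disp))
        self.c0.data = preds[best].copy()

    def rebuild_graph(self):
        self.graph = build_neighbor_graph(self.c0.data * self.half_extent)
        self.tau = self.graph.c_mean

    def encode_mu(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        out = np.zeros((len(idx), self.cfg.latent_dim))
        bs = 256
        for start in range(0, len(idx), bs):
            sl = idx[start:start + bs]
            imgs = self.stack.images[sl].reshape(len(sl), -1)
            out[start:start + len(sl)] = self.encoder.encode(imgs).mu
        return out


# ----------------------------------------------------------------------
def train_halfset_vae(stack: ParticleStack, model: GaussianModel,
                      config: TrainingConfig, train_idx=None, val_idx=None):
    """Train one half-set VAE to completion.

    Returns (encoder, decoder, updated GaussianModel, mu table for the
    trained indices).
    """
    if train_idx is None:
        train_idx = np.arange(len(stack))
    trainer = HalfSetTrainer(stack, train_idx, model, config, val_idx)
    for _ in range(config.warmup_epochs):
        trainer.run_warmup_epoch()
    trainer.noise = fm.estimate_noise_spectrum(
        stack, trainer.current_model(), subset=trainer._noise_subset())
    for _ in range(config.n_epochs):
        trainer.run_epoch()
        if networks_active(trainer.epoch, config):
            trainer.run_validation_embedding()
        if trainer.stopped:
            break
    mu = trainer.encode_mu(trainer.train_idx)
    return trainer.encoder, trainer.decoder, trainer.current_model(), mu


def train_two_halfsets(stack: ParticleStack, model: GaussianModel,
                       config: TrainingConfig, val_idx=None,
                       sync: bool = True, quiet: bool = True):
    """Train the two independent half-set VAEs epoch-synchronously.

    A shared validation subset (if given) is excluded from both decoders'
    training and only embedded by the encoders.  After replacement epochs
    the half-2 reference is re-synchronized to half 1 through the
    Gaussian-mask procedure, so the two references describe the same
    conformation and share indices.
    """
    if val_idx is None:
        val_idx = np.empty(0, dtype=int)
    val_mask = np.zeros(len(stack), dtype=bool)
    val_mask[val_idx] = True
    trainers = []
    for half in (1, 2):
        idx = stack.halfset_indices(half)
        cfg = replace(config, seed=config.seed + half)
        trainers.append(HalfSetTrainer(
            stack, idx[~val_mask[idx]], model.copy(), cfg,
            val_idx=val_idx, name=f"half{half}"))
    t1, t2 = trainers
    for _ in range(config.warmup_epochs):
        t1.run_warmup_epoch()
        t2.run_warmup_epoch()
    for t in trainers:
        t.noise = fm.estimate_noise_spectrum(
            stack, t.current_model(), subset=t._noise_subset())
    for _ in range(config.n_epochs):
        for t in trainers:
            t.run_epoch()
            if not t.stopped and networks_active(max(t.epoch, 1), config):
                t.run_validation_embedding()
        if sync and networks_active(max(t1.epoch, 1), config) and \
                t1.unfrozen_count and \
                t1.unfrozen_count % config.replace_period == 0:
            new_model = synchronize_halfset_references(
                t1.current_model(), t2.current_model(), t2.decoder,
                t2.encode_mu(t2.train_idx[:200]),
                voxel_size=stack.pixel_size, box=stack.box_size)
            t2.c0.data = new_model.centers / t2.half_extent
        if t1.stopped and t2.stopped:
            break
    if sync:
        new_model = synchronize_halfset_references(
            t1.current_model(), t2.current_model(), t2.decoder,
            t2.encode_mu(t2.train_idx[:200]),
            voxel_size=stack.pixel_size, box=stack.box_size)
        t2.c0.data = new_model.centers / t2.half_extent
    return t1, t2


# ----------------------------------------------------------------------
def save_checkpoint(trainer: "HalfSetTrainer", path):
    """Self-describing training checkpoint: network weights, config,
    Gaussian model, and the per-particle latent means."""
    import dataclasses
    import json

    model = trainer.current_model()
    arrays = {
        "centers": model.centers, "widths": model.widths,
        "amplitudes": model.amplitudes, "class_weights": model.class_weights,
        "mu": trainer.encode_mu(trainer.train_idx),
        "train_idx": trainer.train_idx,
        "lambda_": np.array(trainer.lambda_),
        "img_scale": np.array(trainer.encoder.input_scale),
    }
    for i, p in enumerate(trainer.encoder.params):
        arrays[f"enc_{i}"] = p.data
    for i, p in enumerate(trainer.decoder.params):
        arrays[f"dec_{i}"] = p.data
    cfg_json = json.dumps(dataclasses.asdict(trainer.cfg))
    np.savez(path, config=np.array(cfg_json), **arrays)


def load_checkpoint(path, n_pixels: int):
    """Rebuild (encoder, decoder, GaussianModel, mu, config) from a
    checkpoint written by :func:`save_checkpoint`."""
    import json

    data = np.load(path, allow_pickle=False)
    cfg = TrainingConfig(**json.loads(str(data["config"])))
    encoder = Encoder(n_pixels, cfg.latent_dim, cfg.encoder_hidden,
                      rng=np.random.default_rng(0),
                      input_scale=float(data["img_scale"]))
    decoder = DeformationDecoder(cfg.latent_dim, cfg.decoder_hidden,
                                 cfg.n_freqs, rng=np.random.default_rng(0))
    for i, p in enumerate(encoder.params):
        p.data = data[f"enc_{i}"].copy()
    for i, p in enumerate(decoder.params):
        p.data = data[f"dec_{i}"].copy()
    model = GaussianModel(data["centers"], data["widths"],
                          data["amplitudes"], data["class_weights"])
    return encoder, decoder, model, data["mu"].copy(), cfg


# ----------------------------------------------------------------------
def synchronize_halfset_references(model_half1: GaussianModel,
                                   model_half2: GaussianModel,
                                   decoder_half2: DeformationDecoder,
                                   mu_table_half2: np.ndarray,
                                   voxel_size: float, box: int,
                                   mask_radius: float = 6.0,
                                   n_average: int = 100) -> GaussianModel:
    """Pull the half-2 reference into the half-1 conformation.

    A binary mask covers all voxels within `mask_radius` (default 6 A) of
    any half-1 Gaussian; the half-2 reference positions are replaced by
    the average over the `n_average` (default 100) predicted
    conformations with the highest in-mask Gaussian counts.
    """
    half_extent = (box * voxel_size) / 2.0
    mu = np.atleast_2d(mu_table_half2)
    preds = decode_positions(decoder_half2, mu, model_half2.centers,
                             half_extent)                   # (P, Ng, 3)
    mask = build_gaussian_mask(model_half1.centers, box, voxel_size,
                               mask_radius)
    in_mask = count_in_mask(preds, mask, voxel_size)
    top = np.argsort(-in_mask, kind="stable")[:min(n_average, len(in_mask))]
    new_centers = preds[top].mean(axis=0)
    out = model_half2.copy()
    out.centers = new_centers
    return out


def build_gaussian_mask(centers: np.ndarray, box: int, voxel_size: float,
                        radius: float = 6.0) -> np.ndarray:
    """Binary mask of voxels whose centers lie within `radius` of any
    Gaussian center; indexed [z, y, x]."""
    from scipy.spatial import cKDTree

    ax = (np.arange(box) - box // 2) * voxel_size
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    dist, _ = cKDTree(centers).query(pts)
    return (dist.reshape(box, box, box) <= radius)


def count_in_mask(positions: np.ndarray, mask: np.ndarray,
                  voxel_size: float) -> np.ndarray:
    """Per conformation, count Gaussians whose enclosing voxel is masked.

    positions: (P, Ng, 3) Angstrom, world coordinates (x, y, z).
    """
    box = mask.shape[0]
    idx = np.round(positions / voxel_size).astype(int) + box // 2
    inside = np.all((idx >= 0) & (idx < box), axis=-1)
    idx = np.clip(idx, 0, box - 1)
    hit = mask[idx[..., 2], idx[..., 1], idx[..., 0]] & inside
    return hit.sum(axis=1)
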