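"""Inverse deformations and (deformed) weighted backprojection.

The inverse-deformation network is a six-layer coordinate MLP with one
additive residual connection; it regresses the consensus position from
(latent, deformed position) pairs produced by the trained decoder.

Reconstruction: each particle image is CTF-multiplied, backprojected
into the 3-D box in real space (smeared along its viewing direction),
optionally warped by a per-particle sampling field, and accumulated.
The accumulated volume is divided in Fourier space by the accumulated
squared CTFs (central-slice gridding) with a Wiener-style floor.  With
identity fields the deformed path reduces exactly to standard weighted
backprojection because both share the same numerator code.

The sampling (pull-back) convention: the warped volume is sampled at
x + w(x).  For deformation correction w must approximate the forward
displacement D(z, x) - x; :func:`sampling_field_from_inverse` derives it
from the trained inverse network by first-order negation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import autodiff as ad
from . import forward_model as fm
from .autodiff import Tensor
from .io_formats import ParticleStack, VolumeGrid
from .networks import (Adam, DeformationDecoder, InverseDeformationNet,
                       positional_encode)

__all__ = [
    "train_inverse_network", "evaluate_inverse_field",
    "sampling_field_from_inverse", "backproject_standard",
    "backproject_deformed", "compute_fsc", "reconstruct_halfmap",
    "HalfMapPair",
]


# ----------------------------------------------------------------------
# inverse-deformation network
# ----------------------------------------------------------------------
def train_inverse_network(decoder: DeformationDecoder, mu_table: np.ndarray,
                          consensus_ang: np.ndarray, half_extent: float,
                          epochs: int = 200, batch_size: int = 16,
                          lr: float = 1e-3, hidden: int = 64,
                          seed: int = 0) -> InverseDeformationNet:
    """Fit D^-1 so that D^-1(mu_i, D(mu_i, c_j)) = c_j.

    Trained with ADAM for `epochs` epochs (default 200) on the latent
    table of the half set; smoothness is inherited from the bounded
    positional-encoding bandwidth of the network.
    """
    rng = np.random.default_rng(seed)
    mu_table = np.atleast_2d(mu_table)
    c0 = np.asarray(consensus_ang) / half_extent          # normalized
    ng = c0.shape[0]
    net = InverseDeformationNet(mu_table.shape[1], hidden,
                                decoder.n_freqs, rng=rng)
    opt = Adam(net.params, lr=lr)
    # precompute deformed inputs once: the decoder is fixed
    deformed = decoder.decode(mu_table, c0)                # (Nd, ng, 3)
    target = np.broadcast_to(c0, deformed.shape)
    nd = len(mu_table)
    for _ in range(epochs):
        order = rng.permutation(nd)
        for start in range(0, nd, batch_size):
            sel = order[start:start + batch_size]
            b = len(sel)
            x_in = deformed[sel].reshape(-1, 3)
            z = np.repeat(mu_table[sel], ng, axis=0)
            pe = positional_encode(x_in, net.n_freqs)
            res = net.residual(Tensor(z), pe)
            pred_minus_tgt = res + (x_in - target[sel].reshape(-1, 3))
            loss = ad.tmean(ad.tsum(ad.square(pred_minus_tgt), axis=-1))
            if not np.isfinite(loss.item()):
                raise FloatingPointError("inverse-network training diverged")
            for p in net.params:
                p.grad = None
            loss.backward()
            opt.step()
            for p in net.params:
                p.grad = None
    return net


def inverse_roundtrip_error(decoder: DeformationDecoder,
                            net: InverseDeformationNet,
                            mu_table: np.ndarray, consensus_ang: np.ndarray,
                            half_extent: float) -> np.ndarray:
    """Per-(particle, Gaussian) round-trip error ||D^-1(D(c)) - c|| in A."""
    mu_table = np.atleast_2d(mu_table)
    c0 = np.asarray(consensus_ang) / half_extent
    deformed = decoder.decode(mu_table, c0)
    errs = np.zeros(deformed.shape[:2])
    for i, mu in enumerate(mu_table):
        back = net.map_back(mu, deformed[i])
        errs[i] = np.linalg.norm(back - c0, axis=-1) * half_extent
    return errs


def evaluate_inverse_field(net: InverseDeformationNet, mu: np.ndarray,
                           box: int, voxel_size: float, half_extent: float,
                           coarsen: int = 2) -> np.ndarray:
    """Dense displacement field of the inverse map on the full grid (A).

    The network is evaluated on a `coarsen`-times coarser lattice
    (including the boundary) and upsampled trilinearly; exact for affine
    fields.  Returns (n, n, n, 3), indexed [z, y, x], components (x, y, z).
    """
    n = box
    idx = np.unique(np.r_[np.arange(0, n, coarsen), n - 1])
    ax = (idx - n // 2) * voxel_size
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    pts_norm = pts / half_extent
    back = net.map_back(np.asarray(mu, dtype=float), pts_norm)
    disp = (back - pts_norm) * half_extent
    disp = disp.reshape(len(idx), len(idx), len(idx), 3)
    full_ax = (np.arange(n) - n // 2) * voxel_size
    interp = RegularGridInterpolator((ax, ax, ax), disp, method="linear",
                                     bounds_error=False, fill_value=None)
    fz, fy, fx = np.meshgrid(full_ax, full_ax, full_ax, indexing="ij")
    query = np.stack([fz.ravel(), fy.ravel(), fx.ravel()], axis=1)
    return interp(query).reshape(n, n, n, 3)


def sampling_field_from_inverse(net: InverseDeformationNet, mu: np.ndarray,
                                box: int, voxel_size: float,
                                half_extent: float,
                                coarsen: int = 2) -> np.ndarray:
    """Pull-back sampling field w(x) ~= D(z, x) - x, obtained by negating
    the inverse-net displacement (first-order field inversion)."""
    return -evaluate_inverse_field(net, mu, box, voxel_size, half_extent,
                                   coarsen)


# ----------------------------------------------------------------------
# backprojection
# ----------------------------------------------------------------------
def _bilinear_sample(img: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Sample img[y, x] bilinearly; zero outside."""
    n = img.shape[0]
    valid = (x >= 0) & (x <= n - 1) & (y >= 0) & (y <= n - 1)
    xc = np.clip(x, 0, n - 1.000001)
    yc = np.clip(y, 0, n - 1.000001)
    x0 = np.floor(xc).astype(int)
    y0 = np.floor(yc).astype(int)
    fx, fy = xc - x0, yc - y0
    v = (img[y0, x0] * (1 - fx) * (1 - fy)
         + img[y0, x0 + 1] * fx * (1 - fy)
         + img[y0 + 1, x0] * (1 - fx) * fy
         + img[y0 + 1, x0 + 1] * fx * fy)
    return v * valid


@dataclass
class ReconstructionAccumulator:
    """Numerator volume and Fourier-space squared-CTF denominator."""

    numerator: np.ndarray     # (n, n, n) real
    denominator: np.ndarray   # (n, n, n) real, FFT layout

    def __add__(self, other):
        return ReconstructionAccumulator(self.numerator + other.numerator,
                                         self.denominator + other.denominator)

    def finalize(self, voxel_size: float,
                 wiener_floor: float = 1e-3) -> VolumeGrid:
        if np.any(self.denominator < -1e-9):
            raise ValueError("denominator must be nonnegative")
        den = np.maximum(self.denominator,
                         wiener_floor * self.denominator.max())
        f = np.fft.fftn(np.fft.ifftshift(self.numerator), norm="ortho")
        vol = np.fft.fftshift(np.fft.ifftn(f / den, norm="ortho").real)
        return VolumeGrid(vol, voxel_size)


def _accumulate(stack: ParticleStack, idx, field_fn=None):
    """Shared numerator/denominator accumulation for both paths."""
    idx = np.asarray(idx)
    if len(idx) == 0:
        raise ValueError("empty particle set")
    n = stack.box_size
    voxel = stack.pixel_size
    ax = (np.arange(n) - n // 2) * voxel
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    base = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    f1 = np.fft.fftfreq(n) * n          # integer frequency coords
    kv, ku = np.meshgrid(f1, f1, indexing="ij")
    num = np.zeros(n ** 3)
    den = np.zeros((n, n, n))
    for i in idx:
        ctf = fm.ctf_evaluate(stack.ctfs[i], n, voxel)
        yimg = stack.images[i].astype(np.float64)
        cimg = np.fft.fftshift(np.fft.ifft2(
            fm.image_to_fourier(yimg) * ctf, norm="ortho").real)
        r = fm.rotation_matrix(*stack.eulers[i])
        coords = base
        if field_fn is not None:
            w = field_fn(i)
            if w is not None:
                coords = base + w.reshape(-1, 3)
        q = coords @ r[:2].T + stack.shifts[i]
        px = q[:, 0] / voxel + n // 2
        py = q[:, 1] / voxel + n // 2
        num += _bilinear_sample(cimg, px, py)

        # denominator: CTF^2 inserted on the central slice (trilinear)
        plane = ku.ravel()[:, None] * r[0] + kv.ravel()[:, None] * r[1]
        _slice_insert(den, plane, (ctf ** 2).ravel())
    return ReconstructionAccumulator(num.reshape(n, n, n), den)


def _slice_insert(den: np.ndarray, coords: np.ndarray, values: np.ndarray):
    """Trilinear scatter of values at continuous FFT-grid coords (x, y, z)."""
    n = den.shape[0]
    lo = np.floor(coords).astype(int)
    fr = coords - lo
    for dx in (0, 1):
        wx = fr[:, 0] if dx else 1 - fr[:, 0]
        for dy in (0, 1):
            wy = fr[:, 1] if dy else 1 - fr[:, 1]
            for dz in (0, 1):
                wz = fr[:, 2] if dz else 1 - fr[:, 2]
                ix = np.mod(lo[:, 0] + dx, n)
                iy = np.mod(lo[:, 1] + dy, n)
                iz = np.mod(lo[:, 2] + dz, n)
                np.add.at(den, (iz, iy, ix), values * wx * wy * wz)


def backproject_standard(stack: ParticleStack, idx=None,
                         wiener_floor: float = 1e-3) -> VolumeGrid:
    """Standard weighted backprojection (homogeneous case)."""
    if idx is None:
        idx = np.arange(len(stack))
    return _accumulate(stack, idx).finalize(stack.pixel_size, wiener_floor)


def backproject_deformed(stack: ParticleStack, fields, idx=None,
                         wiener_floor: float = 1e-3) -> VolumeGrid:
    """Deformed weighted backprojection.

    `fields` maps a particle index to its (n, n, n, 3) sampling
    displacement field in Angstrom (None = identity); the backprojected
    contribution of voxel x is sampled at x + w(x).
    """
    if idx is None:
        idx = np.arange(len(stack))
    field_fn = fields if callable(fields) else (lambda i: fields[i])
    return _accumulate(stack, idx, field_fn).finalize(stack.pixel_size,
                                                      wiener_floor)


def reconstruct_halfmap(stack: ParticleStack, idx, net: InverseDeformationNet,
                        mu_table: np.ndarray, coarsen: int = 2,
                        wiener_floor: float = 1e-3) -> VolumeGrid:
    """Deformed backprojection of one half set using its inverse network.

    mu_table rows correspond to the entries of `idx`.
    """
    idx = np.asarray(idx)
    n = stack.box_size
    half_extent = n * stack.pixel_size / 2.0
    lookup = {int(p): k for k, p in enumerate(idx)}

    def field_fn(i):
        return sampling_field_from_inverse(
            net, mu_table[lookup[int(i)]], n, stack.pixel_size,
            half_extent, coarsen)

    return backproject_deformed(stack, field_fn, idx, wiener_floor)


# ----------------------------------------------------------------------
# Fourier shell correlation
# ----------------------------------------------------------------------
@dataclass
class HalfMapPair:
    half1: VolumeGrid
    half2: VolumeGrid


def compute_fsc(map_a: VolumeGrid, map_b: VolumeGrid):
    """FSC per shell: Re<A B*> / sqrt(<|A|^2><|B|^2>).

    Returns (spatial_frequency (1/A), fsc).  Shells where either map has
    no power are reported as 0.
    """
    if map_a.data.shape != map_b.data.shape:
        raise ValueError("maps must have the same shape")
    n = map_a.box_size
    fa = np.fft.fftn(np.fft.ifftshift(map_a.data), norm="ortho")
    fb = np.fft.fftn(np.fft.ifftshift(map_b.data), norm="ortho")
    shells = fm.shell_indices_3d(n).ravel()
    nsh = n // 2 + 1
    cross = np.bincount(shells, weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=nsh)
    pa = np.bincount(shells, weights=np.abs(fa.ravel()) ** 2, minlength=nsh)
    pb = np.bincount(shells, weights=np.abs(fb.ravel()) ** 2, minlength=nsh)
    denom = np.sqrt(pa * pb)
    fsc = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    freq = np.arange(nsh) / (n * map_a.voxel_size)
    return freq, fsc


def write_fsc(path, freq: np.ndarray, fsc: np.ndarray):
    """Two-column text: spatial frequency (1/A), correlation."""
    np.savetxt(path, np.column_stack([freq, fsc]), fmt="%.6f",
               header="freq_invA fsc")
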