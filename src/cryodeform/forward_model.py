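"""Differentiable cryo-EM image formation for Gaussian pseudo-atom models.

The projection of a (deformed) Gaussian model is formed in Fourier
space: the 3-D centers are rotated and projected to 2-D points, splatted
onto an oversampled grid with bilinear interpolation, Fourier
transformed, multiplied with the analytic transform of the Gaussian
basis function and with the CTF, and cropped to the output band.

All FFTs in the package use the orthonormal convention, so Parseval's
identity holds without extra constants and white noise of variance v has
per-coefficient spectral power v.

Scaling: a Gaussian a*exp(-||x||^2/s^2) projected along z and sampled in
an orthonormal n-point DFT contributes
``a * pi^{3/2} s^3 / (n * pixel^2) * exp(-pi^2 s^2 |k|^2)`` per 2-D
frequency k (in 1/A), which is the transfer applied here; images formed
this way agree with a real-space render -> project -> FFT oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .io_formats import CTFParams, ParticleStack
from .gaussian_model import GaussianModel


@dataclass
class FourierImage:
    """Full-spectrum complex 2-D image(s), DC at index [..., 0, 0]."""

    data: np.ndarray
    pixel_size: float

    @property
    def box_size(self) -> int:
        return self.data.shape[-1]


@dataclass
class NoiseModel:
    """Radial noise-power weights, one strictly positive value per shell."""

    weights: np.ndarray    # (n//2 + 1,)
    box_size: int
    pixel_size: float

    def __post_init__(self):
        if np.any(self.weights <= 0):
            raise ValueError("noise weights must be positive")

    def per_pixel(self) -> np.ndarray:
        return self.weights[shell_indices(self.box_size)]


# ----------------------------------------------------------------------
# CTF
# ----------------------------------------------------------------------
def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


def ctf_evaluate(ctf: CTFParams, box: int, pixel_size: float) -> np.ndarray:
    """Standard weak-phase CTF on the (box, box) FFT frequency grid.

    CTF(k) = -( sqrt(1 - A^2) sin(chi) + A cos(chi) ), so the value at
    zero frequency is -A.  No envelope.
    """
    freq = np.fft.fftfreq(box, d=pixel_size)
    ky, kx = np.meshgrid(freq, freq, indexing="ij")
    k2 = kx ** 2 + ky ** 2
    ang = np.arctan2(ky, kx)
    lam = electron_wavelength(ctf.voltage)
    z_mean = 0.5 * (ctf.defocus_u + ctf.defocus_v)
    z_diff = 0.5 * (ctf.defocus_u - ctf.defocus_v)
    ast = np.deg2rad(ctf.astig_angle)
    z = z_mean + z_diff * np.cos(2.0 * (ang - ast))
    chi = (np.pi * lam * z * k2
           - 0.5 * np.pi * ctf.cs * 1e7 * lam ** 3 * k2 ** 2
           + np.deg2rad(ctf.phase_shift))
    a = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - a ** 2) * np.sin(chi) + a * np.cos(chi))


# ----------------------------------------------------------------------
# poses
# ----------------------------------------------------------------------
def rotation_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic rotation R = Rz(psi) @ Ry(tilt) @ Rz(rot), degrees."""
    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(np.deg2rad(psi)) @ ry(np.deg2rad(tilt)) @ rz(np.deg2rad(rot))


def project_points(centers: np.ndarray, euler, shift=(0.0, 0.0)) -> np.ndarray:
    """Project 3-D centers under a pose: xi = drop-z(R c) + shift (Angstrom)."""
    r = rotation_matrix(*euler)
    centers = np.asarray(centers, dtype=float)
    return centers @ r[:2].T + np.asarray(shift, dtype=float)


# ----------------------------------------------------------------------
# Fourier helpers
# ----------------------------------------------------------------------
def shell_indices(n: int) -> np.ndarray:
    """Integer Fourier-shell index per pixel of an (n, n) FFT grid."""
    f = np.fft.fftfreq(n) * n
    ky, kx = np.meshgrid(f, f, indexing="ij")
    r = np.sqrt(kx ** 2 + ky ** 2)
    return np.minimum(np.round(r).astype(int), n // 2)


def shell_indices_3d(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n) * n
    kz, ky, kx = np.meshgrid(f, f, f, indexing="ij")
    r = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    return np.minimum(np.round(r).astype(int), n // 2)


def fourier_crop(fimg: np.ndarray, n: int) -> np.ndarray:
    """Keep the central n x n frequencies of a larger FFT-layout image."""
    big = fimg.shape[-1]
    idx = np.r_[0:n // 2, big - n // 2:big]
    return fimg[..., idx[:, None], idx[None, :]]


def fourier_pad(fimg: np.ndarray, big: int) -> np.ndarray:
    """Adjoint of :func:`fourier_crop`: embed into a larger FFT grid."""
    n = fimg.shape[-1]
    out = np.zeros(fimg.shape[:-2] + (big, big), dtype=fimg.dtype)
    idx = np.r_[0:n // 2, big - n // 2:big]
    out[..., idx[:, None], idx[None, :]] = fimg
    return out


def gaussian_transfer(s: float, n: int, pixel_size: float,
                      oversample: int) -> np.ndarray:
    """Fourier transfer of the projected Gaussian basis, incl. DFT scale."""
    freq = np.fft.fftfreq(n, d=pixel_size)
    ky, kx = np.meshgrid(freq, freq, indexing="ij")
    k2 = kx ** 2 + ky ** 2
    return (oversample / pixel_size ** 2 * np.pi ** 1.5 * s ** 3
            * np.exp(-np.pi ** 2 * s ** 2 * k2))


# ----------------------------------------------------------------------
# bilinear splatting
# ----------------------------------------------------------------------
def _splat_prepare(points_px: np.ndarray, big: int):
    """Corner indices and weights for bilinear splatting, with clipping."""
    x = points_px[..., 0]
    y = points_px[..., 1]
    n_clip = int(np.sum((x < 0) | (x > big - 1) | (y < 0) | (y > big - 1)))
    x = np.clip(x, 0.0, big - 1.000001)
    y = np.clip(y, 0.0, big - 1.000001)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    return x0, y0, fx, fy, n_clip


def bilinear_splat(points_px: np.ndarray, weights: np.ndarray,
                   big: int):
    """Splat weighted points into (B, big, big) images; image[y, x] layout.

    Returns (images, cache) where cache is reused for the adjoint.
    """
    b, m = points_px.shape[0], points_px.shape[1]
    x0, y0, fx, fy, n_clip = _splat_prepare(points_px, big)
    w = np.broadcast_to(weights, (b, m))
    img = np.zeros((b, big * big))
    for dx, dy, wcorner in (
            (0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
            (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
        flat = (y0 + dy) * big + (x0 + dx)
        for bi in range(b):
            np.add.at(img[bi], flat[bi], (w * wcorner)[bi])
    return img.reshape(b, big, big), (x0, y0, fx, fy, n_clip)


def bilinear_splat_grads(cache, grad_img: np.ndarray, weights: np.ndarray,
                         big: int):
    """Gradients of sum(grad_img * splat) wrt point positions and weights."""
    x0, y0, fx, fy, _ = cache
    b, m = x0.shape
    g = grad_img.reshape(b, -1)
    vals = {}
    for dx in (0, 1):
        for dy in (0, 1):
            flat = (y0 + dy) * big + (x0 + dx)
            vals[(dx, dy)] = np.take_along_axis(g, flat, axis=1)
    w = np.broadcast_to(weights, (b, m))
    dwx = ((vals[(1, 0)] - vals[(0, 0)]) * (1 - fy)
           + (vals[(1, 1)] - vals[(0, 1)]) * fy)
    dwy = ((vals[(0, 1)] - vals[(0, 0)]) * (1 - fx)
           + (vals[(1, 1)] - vals[(1, 0)]) * fx)
    grad_pts = np.stack([w * dwx, w * dwy], axis=-1)
    grad_w = (vals[(0, 0)] * (1 - fx) * (1 - fy) + vals[(1, 0)] * fx * (1 - fy)
              + vals[(0, 1)] * (1 - fx) * fy + vals[(1, 1)] * fx * fy)
    return grad_pts, grad_w


# ----------------------------------------------------------------------
# image formation
# ----------------------------------------------------------------------
def _form_images(points2d: np.ndarray, class_weights: np.ndarray,
                 amplitudes: np.ndarray, widths: np.ndarray,
                 ctf: np.ndarray, n: int, pixel_size: float,
                 oversample: int = 2):
    """Core Fourier-space projection shared by simulator and training.

    points2d: (B, Ng, 2) Angstrom; ctf: (B, n, n) or (n, n).
    Returns (g (B, n, n) complex, cache for gradients).
    """
    big = oversample * n
    sub_pixel = pixel_size / oversample
    pts_px = points2d / sub_pixel + big // 2
    nc = len(widths)
    g = np.zeros((points2d.shape[0], n, n), dtype=complex)
    per_class = []
    for j in range(nc):
        w_j = class_weights[j] * amplitudes[j]          # (Ng,)
        img, cache = bilinear_splat(pts_px, w_j, big)
        s_big = np.fft.fft2(np.fft.ifftshift(img, axes=(-2, -1)),
                            norm="ortho")
        s_crop = fourier_crop(s_big, n)
        t_j = gaussian_transfer(widths[j], n, pixel_size, oversample)
        g = g + t_j * ctf * s_crop
        per_class.append((w_j, cache, s_crop, t_j))
    return g, (per_class, big, sub_pixel, oversample)


def splat_and_filter(points2d: np.ndarray, model: GaussianModel,
                     ctf: np.ndarray, box: int, pixel_size: float,
                     oversample: int = 2) -> FourierImage:
    """Project deformed Gaussian centers into CTF-filtered Fourier images.

    Raises if every point falls outside the oversampled grid.
    """
    points2d = np.asarray(points2d, dtype=float)
    if points2d.ndim == 2:
        points2d = points2d[None]
    g, (per_class, big, sub, _) = _form_images(
        points2d, model.class_weights, model.amplitudes, model.widths,
        np.asarray(ctf, dtype=float), box, pixel_size, oversample)
    n_clip = per_class[0][1][4]
    if n_clip >= points2d.shape[0] * points2d.shape[1]:
        raise ValueError("all points fall outside the splat grid")
    return FourierImage(g, pixel_size)


def real_image(fimg: FourierImage) -> np.ndarray:
    """Orthonormal inverse FFT, centered real image(s)."""
    img = np.fft.ifft2(fimg.data, norm="ortho").real
    return np.fft.fftshift(img, axes=(-2, -1))


def image_to_fourier(images: np.ndarray) -> np.ndarray:
    """Orthonormal FFT of centered real image(s)."""
    return np.fft.fft2(np.fft.ifftshift(np.asarray(images, dtype=float),
                                        axes=(-2, -1)), norm="ortho")


# ----------------------------------------------------------------------
# autodiff bridge
# ----------------------------------------------------------------------
def batched_project(positions, rot_mats: np.ndarray, shifts: np.ndarray):
    """Autodiff op: positions (B, Ng, 3) [A] -> projected (B, Ng, 2) [A]."""
    pos = ad.as_tensor(positions)
    r2 = rot_mats[:, :2, :]                        # (B, 2, 3)

    data = np.einsum("bij,bkj->bik", pos.data, r2) + shifts[:, None, :]

    def vjp(g):
        return (np.einsum("bik,bkj->bij", g, r2),)

    return ad.custom(data, [pos], vjp)


def projection_loss(points2d, class_weights, amplitudes, widths,
                    y_fft: np.ndarray, ctf: np.ndarray,
                    sigma_pix: np.ndarray, box: int, pixel_size: float,
                    oversample: int = 2):
    """Sigma-weighted Fourier data loss, differentiable wrt the Gaussian
    parameters and the projected 2-D points.

    L = (1/B) sum_i sum_k |g_i(k) - y_i(k)|^2 / Sigma(shell(k))
    """
    pts = ad.as_tensor(points2d)
    d = ad.as_tensor(class_weights)
    a = ad.as_tensor(amplitudes)
    s = ad.as_tensor(widths)
    b = pts.data.shape[0]

    g, (per_class, big, sub, ovs) = _form_images(
        pts.data, d.data, a.data, s.data, ctf, box, pixel_size, oversample)
    resid = g - y_fft
    loss = float(np.sum(np.abs(resid) ** 2 / sigma_pix) / b)

    def vjp(grad_out):
        go = float(grad_out)
        w_res = resid / sigma_pix              # (B, n, n) complex
        grad_pts = np.zeros_like(pts.data)
        grad_d = np.zeros_like(d.data)
        grad_a = np.zeros_like(a.data)
        grad_s = np.zeros_like(s.data)
        for j, (w_j, cache, s_crop, t_j) in enumerate(per_class):
            back = np.fft.ifft2(fourier_pad(w_res * t_j * ctf, big),
                                norm="ortho")
            r_img = (2.0 / b) * np.fft.fftshift(back.real, axes=(-2, -1))
            gp, gw = bilinear_splat_grads(cache, r_img, w_j, big)
            grad_pts += gp / sub
            grad_d[j] = a.data[j] * gw.sum(axis=0)
            grad_a[j] = float(np.sum(gw * d.data[j][None, :]))
            dt_ds = t_j * (3.0 / s.data[j]
                           - 2.0 * np.pi ** 2 * s.data[j]
                           * _freq2(box, pixel_size))
            grad_s[j] = (2.0 / b) * float(
                np.sum((np.conj(w_res) * ctf * s_crop).real * dt_ds))
        return (go * grad_pts, go * grad_d, go * grad_a, go * grad_s)

    return ad.custom(loss, [pts, d, a, s], vjp)


def _freq2(n: int, pixel_size: float) -> np.ndarray:
    f = np.fft.fftfreq(n, d=pixel_size)
    ky, kx = np.meshgrid(f, f, indexing="ij")
    return kx ** 2 + ky ** 2


# ----------------------------------------------------------------------
# noise model and data loss
# ----------------------------------------------------------------------
def model_projections(stack: ParticleStack, model: GaussianModel, idx,
                      positions=None, oversample: int = 2) -> np.ndarray:
    """Fourier projections g_i of (optionally deformed) model positions."""
    idx = np.asarray(idx)
    n = stack.box_size
    ctf = np.stack([ctf_evaluate(stack.ctfs[i], n, stack.pixel_size)
                    for i in idx])
    if positions is None:
        positions = np.broadcast_to(model.centers,
                                    (len(idx),) + model.centers.shape)
    rots = np.stack([rotation_matrix(*stack.eulers[i]) for i in idx])
    pts = (np.einsum("bij,bkj->bik", positions, rots[:, :2, :])
           + stack.shifts[idx][:, None, :])
    fimg = splat_and_filter(pts, model, ctf, n, stack.pixel_size, oversample)
    return fimg.data


def estimate_noise_spectrum(stack: ParticleStack, model: GaussianModel,
                            subset=None, max_subset: int = 256,
                            oversample: int = 2,
                            floor_rel: float = 1e-6) -> NoiseModel:
    """Radially averaged power of the residual g_i - y_i on a subset."""
    n = stack.box_size
    if subset is None:
        rng = np.random.default_rng(0)
        size = min(len(stack), max_subset)
        subset = rng.choice(len(stack), size=size, replace=False)
    subset = np.asarray(subset)
    g = model_projections(stack, model, subset, oversample=oversample)
    y = image_to_fourier(stack.images[subset])
    power = np.abs(g - y) ** 2
    shells = shell_indices(n)
    sums = np.bincount(shells.ravel(),
                       weights=power.sum(axis=0).ravel(),
                       minlength=n // 2 + 1)
    counts = np.bincount(shells.ravel(), minlength=n // 2 + 1) * len(subset)
    weights = sums / np.maximum(counts, 1)
    floor = max(1e-12, floor_rel * float(weights.max()))
    return NoiseModel(np.maximum(weights, floor), n, stack.pixel_size)


def data_loss(g: np.ndarray, y: np.ndarray, noise: NoiseModel) -> float:
    """(1/B) sum_i ||g_i - y_i||^2_Sigma in Fourier space."""
    g = np.asarray(g)
    y = np.asarray(y)
    if g.ndim == 2:
        g, y = g[None], y[None]
    sig = noise.per_pixel()
    return float(np.sum(np.abs(g - y) ** 2 / sig) / g.shape[0])
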