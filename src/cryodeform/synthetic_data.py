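"""Synthetic scenes with known deformations, poses, CTFs and noise.

The generator builds a two-domain Gaussian "hinge" scene: one static
domain and one mobile domain that rotates rigidly about a hinge axis by
a per-particle angle.  Images are formed through the same Fourier-space
code path as training (no train/test model mismatch), corrupted by the
CTF and by white (or optionally colored) noise at a target SNR.

Defaults emulate a desk-scale heterogeneous dataset: 60 Gaussians
(40 static / 20 hinged), angles uniform in [-20, 20] degrees, 1,000
particles, box 48 at 3 A/pixel, defocus 0.8-2.5 um, SNR 0.1 within a
circular mask of radius 0.45 x box.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import json
import os

import numpy as np

from . import forward_model as fm
from .gaussian_model import GaussianModel, render_density
from .io_formats import (CTFParams, ParticleStack, write_particles,
                         write_volume)


@dataclass
class HingeSpec:
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    pivot: np.ndarray = field(default_factory=lambda: np.array([6.0, 0.0, 0.0]))
    angle_range: tuple = (-20.0, 20.0)   # degrees, uniform

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("hinge axis must be nonzero")
        self.axis = self.axis / n
        self.pivot = np.asarray(self.pivot, dtype=float)


@dataclass
class SyntheticScene:
    model: GaussianModel            # ground-truth consensus
    moving: np.ndarray              # (Ng,) bool, True = hinged domain
    hinge: HingeSpec
    n_particles: int = 1000
    box: int = 48
    pixel_size: float = 3.0
    snr: float = 0.1
    noise: str = "white"            # or "colored"
    noise_k0: float = 0.05          # 1/A knee for colored noise
    defocus_range: tuple = (8000.0, 25000.0)   # Angstrom
    shift_max: float = 3.0          # Angstrom
    seed: int = 0

    @property
    def n_gaussians(self) -> int:
        return self.model.n_gaussians


def make_hinge_scene(n_gaussians: int = 60, n_moving: int | None = None,
                     hinge: HingeSpec | None = None, seed: int = 0,
                     **kwargs) -> SyntheticScene:
    """Random two-domain scene; the mobile domain rotates about the hinge.

    By default one third of the Gaussians form the mobile domain (20 of
    the default 60).
    """
    rng = np.random.default_rng(seed)
    hinge = hinge or HingeSpec()
    if n_moving is None:
        n_moving = max(1, n_gaussians // 3)
    n_static = n_gaussians - n_moving
    if n_static <= 0:
        raise ValueError("need at least one static Gaussian")
    static = rng.normal(0.0, 13.0, size=(n_static, 3)) + \
        np.array([-22.0, 0.0, 0.0])
    mobile = rng.normal(0.0, 10.0, size=(n_moving, 3)) + \
        np.array([28.0, 0.0, 0.0])
    centers = np.vstack([static, mobile])
    box = kwargs.get("box", 48)
    pixel = kwargs.get("pixel_size", 3.0)
    limit = 0.42 * box * pixel
    centers = np.clip(centers, -limit, limit)
    model = GaussianModel(centers, [6.0], [1.0],
                          np.ones((1, n_gaussians)))
    moving = np.zeros(n_gaussians, dtype=bool)
    moving[n_static:] = True
    return SyntheticScene(model=model, moving=moving, hinge=hinge,
                          seed=seed, **kwargs)


# ----------------------------------------------------------------------
def _axis_rotation(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    t = np.deg2rad(theta_deg)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)


def deformed_centers(scene: SyntheticScene, theta_deg: float) -> np.ndarray:
    """Ground-truth deformed Gaussian positions for hinge angle theta."""
    c = scene.model.centers.copy()
    r = _axis_rotation(scene.hinge.axis, theta_deg)
    c[scene.moving] = (c[scene.moving] - scene.hinge.pivot) @ r.T \
        + scene.hinge.pivot
    return c


def true_displacements(scene: SyntheticScene,
                       thetas: np.ndarray) -> np.ndarray:
    """(N, Ng, 3) ground-truth displacements from the consensus."""
    return np.stack([deformed_centers(scene, t) for t in thetas]) \
        - scene.model.centers[None]


def true_warp_field(scene: SyntheticScene, theta_deg: float) -> np.ndarray:
    """Dense pull-back sampling field for reconstruction, (n, n, n, 3) A.

    For a voxel x in the mobile region the backprojected density of the
    particle sits at the rotated position, so the correction samples at
    x + w(x) with w(x) = R_theta(x - pivot) + pivot - x; w = 0 in the
    static region.  Region membership is by nearest ground-truth
    Gaussian.
    """
    from scipy.spatial import cKDTree

    n, voxel = scene.box, scene.pixel_size
    ax = (np.arange(n) - n // 2) * voxel
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    _, nearest = cKDTree(scene.model.centers).query(pts)
    mobile = scene.moving[nearest]
    r = _axis_rotation(scene.hinge.axis, theta_deg)
    w = np.zeros_like(pts)
    w[mobile] = (pts[mobile] - scene.hinge.pivot) @ r.T \
        + scene.hinge.pivot - pts[mobile]
    return w.reshape(n, n, n, 3)


# ----------------------------------------------------------------------
def _colored_noise(rng, n_images, box, pixel, k0):
    freq = np.fft.fftfreq(box, d=pixel)
    ky, kx = np.meshgrid(freq, freq, indexing="ij")
    amp = 1.0 / np.sqrt(1.0 + (np.sqrt(kx ** 2 + ky ** 2) / k0) ** 2)
    white = rng.standard_normal((n_images, box, box))
    f = np.fft.fft2(white, norm="ortho") * amp
    return np.fft.ifft2(f, norm="ortho").real


def simulate_particles(scene: SyntheticScene):
    """Simulate the particle stack for a scene.

    Returns (ParticleStack, truth) where truth is a dict with the
    per-particle hinge angles, displacements, noise sigma and the
    ground-truth consensus volume.
    """
    rng = np.random.default_rng(scene.seed)
    nd, n = scene.n_particles, scene.box
    thetas = rng.uniform(*scene.hinge.angle_range, size=nd)
    rot = rng.uniform(0.0, 360.0, size=nd)
    psi = rng.uniform(0.0, 360.0, size=nd)
    tilt = np.rad2deg(np.arccos(rng.uniform(-1.0, 1.0, size=nd)))
    eulers = np.stack([rot, tilt, psi], axis=1)
    shifts = rng.uniform(-scene.shift_max, scene.shift_max, size=(nd, 2))
    ctfs = [CTFParams(defocus_u=rng.uniform(*scene.defocus_range),
                      defocus_v=rng.uniform(*scene.defocus_range),
                      astig_angle=rng.uniform(0.0, 180.0))
            for _ in range(nd)]

    clean = np.zeros((nd, n, n), dtype=np.float32)
    chunk = 64
    for start in range(0, nd, chunk):
        sl = slice(start, min(start + chunk, nd))
        pts = np.stack([
            fm.project_points(deformed_centers(scene, thetas[i]),
                              eulers[i], shifts[i])
            for i in range(sl.start, sl.stop)])
        ctf = np.stack([fm.ctf_evaluate(ctfs[i], n, scene.pixel_size)
                        for i in range(sl.start, sl.stop)])
        fimg = fm.splat_and_filter(pts, scene.model, ctf, n,
                                   scene.pixel_size)
        clean[sl] = fm.real_image(fimg).astype(np.float32)

    # noise scaled to the target SNR inside a circular mask
    yy, xx = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                         indexing="ij")
    mask = (xx ** 2 + yy ** 2) <= (0.45 * n) ** 2
    sig_var = float(np.var(clean[:, mask])) if scene.snr > 0 else 0.0
    if scene.snr > 0 and sig_var > 0:
        target_var = sig_var / scene.snr
        if scene.noise == "colored":
            noise = _colored_noise(rng, nd, n, scene.pixel_size,
                                   scene.noise_k0)
            noise *= np.sqrt(target_var / np.var(noise[:, mask]))
        else:
            noise = rng.normal(0.0, np.sqrt(target_var), size=clean.shape)
        sigma_noise = float(np.sqrt(target_var))
    else:
        noise = np.zeros_like(clean)
        sigma_noise = 0.0

    images = (clean + noise).astype(np.float32)
    halfsets = np.arange(nd) % 2 + 1
    stack = ParticleStack(images, scene.pixel_size, eulers, shifts, ctfs,
                          halfsets)
    truth = {
        "thetas": thetas,
        "displacements": true_displacements(scene, thetas),
        "sigma_noise": sigma_noise,
        "volume": render_density(scene.model, (n, scene.pixel_size)),
    }
    return stack, truth


def write_dataset(directory, stack: ParticleStack, truth: dict,
                  basename: str = "particles"):
    """Persist a simulated dataset: STAR + MRCS + MRC + JSON truth table."""
    os.makedirs(directory, exist_ok=True)
    write_particles(os.path.join(directory, basename + ".star"), stack,
                    stack_name=basename + ".mrcs")
    write_volume(os.path.join(directory, "ground_truth.mrc"),
                 truth["volume"])
    table = {"thetas": np.asarray(truth["thetas"]).tolist(),
             "sigma_noise": truth["sigma_noise"]}
    with open(os.path.join(directory, "ground_truth.json"), "w") as fh:
        json.dump(table, fh)


# ----------------------------------------------------------------------
def _kabsch(p: np.ndarray, q: np.ndarray):
    """Best rigid transform aligning p onto q (rotation + translation)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def deformation_recovery_error(true_disp: np.ndarray, est_disp: np.ndarray,
                               consensus: np.ndarray) -> dict:
    """Per-particle RMS displacement error after removing the best global
    rigid transform (deformations are identifiable only up to the
    consensus gauge).
    """
    true_disp = np.asarray(true_disp)
    est_disp = np.asarray(est_disp)
    if true_disp.ndim == 2:
        true_disp, est_disp = true_disp[None], est_disp[None]
    errors = np.zeros(len(true_disp))
    for i in range(len(true_disp)):
        p = consensus + est_disp[i]
        q = consensus + true_disp[i]
        r, t = _kabsch(p, q)
        resid = (p @ r.T + t) - q
        errors[i] = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return {"per_particle_rms": errors,
            "median": float(np.median(errors)),
            "mean": float(errors.mean()),
            "max": float(errors.max())}
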