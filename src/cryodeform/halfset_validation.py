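"""Deformation-error estimation from two independently trained half sets.

A held-out validation subset (default 10% of the particles) is excluded
from decoder training in both half sets; its images only train the
encoder embeddings.  At evaluation time every validation image is fed
through both encoders and each decoder is evaluated on its own
consensus model, yielding two independent displacement estimates per
Gaussian; the norm of their difference is the per-position deformation
error estimate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaussian_model import GaussianModel
from .io_formats import ParticleStack, VolumeGrid
from .networks import DeformationDecoder, Encoder
from .deformation_vae import decode_positions

__all__ = ["split_for_validation", "estimate_deformation_error",
           "ValidationReport"]


def split_for_validation(n_particles: int, fraction: float = 0.10,
                         seed: int = 0):
    """Deterministic train/validation split of particle indices.

    The validation particles are excluded from decoder training and used
    only for training their latent embedding.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_particles)
    n_val = max(1, int(round(fraction * n_particles)))
    val = np.sort(perm[:n_val])
    train = np.sort(perm[n_val:])
    return train, val


@dataclass
class ValidationReport:
    """Per-validation-particle, per-Gaussian deformation-error norms (A)."""

    error_norms: np.ndarray        # (V, Ng)
    particle_indices: np.ndarray   # (V,)
    matched_by_nn: bool = False    # correspondence fell back to NN matching

    @property
    def per_particle_median(self) -> np.ndarray:
        return np.median(self.error_norms, axis=1)

    @property
    def per_particle_max(self) -> np.ndarray:
        return self.error_norms.max(axis=1)

    @property
    def per_gaussian_median(self) -> np.ndarray:
        return np.median(self.error_norms, axis=0)

    def summary(self) -> dict:
        return {"median": float(np.median(self.error_norms)),
                "mean": float(self.error_norms.mean()),
                "p90": float(np.quantile(self.error_norms, 0.9)),
                "max": float(self.error_norms.max())}

    def to_dataframe(self) -> pd.DataFrame:
        v, ng = self.error_norms.shape
        return pd.DataFrame({
            "particle": np.repeat(self.particle_indices, ng),
            "gaussian": np.tile(np.arange(ng), v),
            "error_A": self.error_norms.ravel()})

    def error_field(self, model: GaussianModel, box: int,
                    voxel_size: float) -> VolumeGrid:
        """Median per-Gaussian error splatted onto the map grid for
        visualization in external viewers."""
        ax = (np.arange(box) - box // 2) * voxel_size
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        out = np.zeros((box, box, box))
        wsum = np.zeros((box, box, box))
        s2 = float(np.mean(model.widths)) ** 2
        med = self.per_gaussian_median
        for i in range(model.n_gaussians):
            cx, cy, cz = model.centers[i]
            w = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2)
                       / s2)
            out += w * med[i]
            wsum += w
        return VolumeGrid(out / np.maximum(wsum, 1e-12), voxel_size)


def estimate_deformation_error(stack: ParticleStack, val_idx,
                               encoder1: Encoder, decoder1: DeformationDecoder,
                               model1: GaussianModel,
                               encoder2: Encoder, decoder2: DeformationDecoder,
                               model2: GaussianModel) -> ValidationReport:
    """Two-decoder disagreement on the validation subset.

    Each decoder is evaluated on its own consensus model with the latent
    obtained from its own encoder; displacements are compared at
    corresponded positions (shared indices after half-set
    synchronization; nearest-neighbor matching after rigid alignment
    when the models have different sizes).
    """
    from scipy.spatial import cKDTree

    val_idx = np.asarray(val_idx)
    n = stack.box_size
    half_extent = n * stack.pixel_size / 2.0
    imgs = stack.images[val_idx].reshape(len(val_idx), -1)
    mu1 = encoder1.encode(imgs).mu
    mu2 = encoder2.encode(imgs).mu

    pos1 = decode_positions(decoder1, mu1, model1.centers, half_extent)
    pos2 = decode_positions(decoder2, mu2, model2.centers, half_extent)
    disp1 = pos1 - model1.centers[None]
    disp2 = pos2 - model2.centers[None]

    matched = False
    if model1.n_gaussians != model2.n_gaussians:
        # centroid alignment, then nearest-neighbor correspondence
        matched = True
        aligned2 = (model2.centers - model2.centers.mean(axis=0)
                    + model1.centers.mean(axis=0))
        _, nn = cKDTree(aligned2).query(model1.centers)
        disp2 = disp2[:, nn]

    errors = np.linalg.norm(disp1 - disp2, axis=-1)
    return ValidationReport(errors, val_idx, matched)
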