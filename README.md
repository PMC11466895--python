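# cryodeform

Continuous conformational heterogeneity estimation for cryo-EM
single-particle data, with deformation-corrected reconstruction.

Single-particle cryo-EM averages tens of thousands of noisy projection
images into one 3-D map. When the imaged complex flexes continuously,
that average blurs the moving parts. `cryodeform` addresses this for
structural biologists by:

1. representing the consensus map as `N_g` Gaussian pseudo-atoms
   `f(x) = Σ_j Σ_i d_{j,i} a_j exp(-||x - c_i||² / s_j²)`;
2. training, independently on each gold-standard half set, a VAE whose
   coordinate-based decoder `D(z, x) = x + δ_θ(z, x)` outputs a
   per-particle 3-D deformation field of those pseudo-atoms, driven by
   a Σ-weighted Fourier-space data loss with local-isometry and
   repulsion regularizers on a nearest-neighbor graph;
3. inverting the learned deformations with a second coordinate network
   and back-projecting every CTF-multiplied image along its corrected
   geometry (deformed weighted backprojection) to obtain improved
   half-maps;
4. estimating per-position deformation errors from the disagreement of
   the two independently trained decoders on a held-out validation
   subset.

Everything runs on plain CPU: networks are small fully connected MLPs
implemented on an in-package numpy autodiff engine. A synthetic-data
module generates ground-truth scenes (two-domain hinge motion, CTF,
noise at a target SNR) so the whole pipeline can be validated without
external data.

## Worked example

Simulate a hinge dataset, train both half-set VAEs, and check how well
the latent space recovers the true hinge angle:

```python
import numpy as np
from scipy.stats import spearmanr
from cryodeform.synthetic_data import make_hinge_scene, simulate_particles
from cryodeform.gaussian_model import initialize_from_map, render_density
from cryodeform.deformation_vae import TrainingConfig, train_two_halfsets
from cryodeform.halfset_validation import split_for_validation

scene = make_hinge_scene(seed=1)          # 60 Gaussians, 1000 particles,
stack, truth = simulate_particles(scene)  # box 48 @ 3 A/px, SNR 0.1
vol = render_density(scene.model, (scene.box, scene.pixel_size))
model0 = initialize_from_map(vol, 0.05 * vol.data.max(), 60, seed=2)
_, val_idx = split_for_validation(len(stack), 0.10, seed=0)

cfg = TrainingConfig.for_small_problem(seed=0)
t1, t2 = train_two_halfsets(stack, model0, cfg, val_idx=val_idx)

for t in (t1, t2):
    mu = t.encode_mu(t.train_idx)
    c = mu - mu.mean(axis=0)
    pc1 = c @ np.linalg.svd(c, full_matrices=False)[2][0]
    rho = spearmanr(pc1, truth["thetas"][t.train_idx]).statistic
    print(f"{t.name}: |Spearman(PC1, theta)| = {abs(rho):.3f}")
```

A run of this script prints:

```
half1: |Spearman(PC1, theta)| = 0.912
half2: |Spearman(PC1, theta)| = 0.901
```

i.e. the first principal component of each half set's 10-dimensional
latent space rank-correlates above 0.9 with the ground-truth hinge
angle, independently in both halves — the per-particle conformational
state has been recovered from images at SNR 0.1.

There is also a thin CLI over the same functions:

```bash
cryodeform simulate --out data/ --n-particles 1000 --seed 1
cryodeform train --star data/particles.star --map data/ground_truth.mrc \
                 --n-gaussians 60 --out run/
cryodeform reconstruct --star data/particles.star --half 1 --out half1.mrc
cryodeform fsc --half1 half1.mrc --half2 half2.mrc --out fsc.txt
```

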