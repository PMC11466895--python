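"""Gaussian pseudo-atom representation of cryo-EM density.

The consensus density is modelled as a sum of isotropic Gaussians

    f(x) = sum_j sum_i d_{j,i} a_j exp(-||x - c_i||^2 / s_j^2)

with centers ``c_i`` (Angstrom), per-class widths ``s_j`` and amplitudes
``a_j``, and a per-Gaussian class-weight vector ``d_{.,i}`` on the
simplex.  With a single width class (the default), every Gaussian shares
one width and one amplitude; heterogeneity of brightness (e.g. from
coarse-graining an atomic model) is represented by multiple one-hot
classes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import AtomicStructure, VolumeGrid


@dataclass
class GaussianModel:
    centers: np.ndarray        # (Ng, 3) Angstrom
    widths: np.ndarray         # (Nc,) Angstrom
    amplitudes: np.ndarray     # (Nc,)
    class_weights: np.ndarray  # (Nc, Ng), columns on the simplex

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.class_weights = np.atleast_2d(
            np.asarray(self.class_weights, dtype=float))
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")
        if np.any(self.class_weights < 0):
            raise ValueError("class weights must be nonnegative")
        colsum = self.class_weights.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-8):
            raise ValueError("class weights must sum to 1 per Gaussian")

    @property
    def n_gaussians(self) -> int:
        return self.centers.shape[0]

    @property
    def n_classes(self) -> int:
        return self.widths.shape[0]

    def per_gaussian_amplitude(self) -> np.ndarray:
        """Effective amplitude of each Gaussian: sum_j d_{j,i} a_j."""
        return self.class_weights.T @ self.amplitudes

    def copy(self) -> "GaussianModel":
        return GaussianModel(self.centers.copy(), self.widths.copy(),
                             self.amplitudes.copy(), self.class_weights.copy())


@dataclass
class EdgeGraph:
    """Regularization connectivity over pseudo-atoms."""

    edges: np.ndarray          # (E, 2) int, i < j, unordered pairs
    c_mean: float              # mean 2-NN edge length (Angstrom); 0 for bonds
    source: str = "knn_heuristic"

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edges = np.sort(self.edges, axis=1)
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        if self.source == "knn_heuristic" and self.c_mean <= 0:
            raise ValueError("c_mean must be positive for the k-NN heuristic")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


# ----------------------------------------------------------------------
def render_density(model: GaussianModel, grid) -> VolumeGrid:
    """Evaluate the Gaussian mixture on a cubic grid.

    `grid` is either a template :class:`VolumeGrid` or a tuple
    ``(box_size, voxel_size)``.
    """
    if isinstance(grid, VolumeGrid):
        n, voxel = grid.box_size, grid.voxel_size
    else:
        n, voxel = grid
    ax = (np.arange(n) - n // 2) * voxel
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    out = np.zeros((n, n, n))
    for i in range(model.n_gaussians):
        cx, cy, cz = model.centers[i]
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        for j in range(model.n_classes):
            w = model.class_weights[j, i]
            if w == 0.0:
                continue
            out += w * model.amplitudes[j] * np.exp(-r2 / model.widths[j] ** 2)
    return VolumeGrid(out, voxel)


def initialize_from_map(volume: VolumeGrid, threshold: float,
                        n_gaussians: int, seed: int,
                        width: float | None = None) -> GaussianModel:
    """Randomly fill the thresholded map with Gaussians.

    Centers are drawn uniformly among voxels whose value exceeds the
    threshold (jittered within the voxel); the shared amplitude is scaled
    so that the L2 norm of the rendered model matches the norm of the map.
    """
    rng = np.random.default_rng(seed)
    mask = volume.data > threshold
    n_avail = int(mask.sum())
    if n_avail < n_gaussians:
        raise ValueError(
            f"only {n_avail} voxels exceed threshold {threshold}, "
            f"need {n_gaussians}")
    vox_idx = np.argwhere(mask)  # (M, 3) in (z, y, x)
    pick = rng.choice(n_avail, size=n_gaussians, replace=False)
    izyx = vox_idx[pick].astype(float)
    izyx += rng.uniform(-0.499, 0.499, size=izyx.shape)
    n = volume.box_size
    centers = (izyx[:, ::-1] - n // 2) * volume.voxel_size  # -> (x, y, z) A

    if width is None:
        width = 2.0 * volume.voxel_size
    model = GaussianModel(centers, [width], [1.0],
                          np.ones((1, n_gaussians)))
    rendered = render_density(model, volume)
    rnorm = np.linalg.norm(rendered.data)
    mnorm = np.linalg.norm(volume.data)
    if rnorm > 0 and mnorm > 0:
        model.amplitudes[:] = mnorm / rnorm
    return model


# ----------------------------------------------------------------------
def build_neighbor_graph(centers: np.ndarray) -> EdgeGraph:
    """Smoothness-regularization graph.

    A 2-nearest-neighbor graph F is built (directed edges deduplicated to
    an undirected set); ``c_mean`` is its mean edge length, and the final
    edge set contains every pair closer than ``1.5 * c_mean``.
    """
    centers = np.asarray(centers, dtype=float)
    ng = centers.shape[0]
    if ng < 2:
        raise ValueError("need at least 2 points")
    k = min(2, ng - 1)
    tree = cKDTree(centers)
    dist, idx = tree.query(centers, k=k + 1)
    pairs = set()
    for i in range(ng):
        for m in range(1, k + 1):
            j = int(idx[i, m])
            pairs.add((min(i, j), max(i, j)))
    f_edges = np.array(sorted(pairs))
    lengths = np.linalg.norm(centers[f_edges[:, 0]] - centers[f_edges[:, 1]],
                             axis=1)
    c_mean = float(lengths.mean())
    if c_mean <= 0:
        # fully degenerate point set: keep the 2-NN edges themselves
        return EdgeGraph(f_edges, max(c_mean, 1e-12))
    cand = tree.query_pairs(1.5 * c_mean * (1 + 1e-12), output_type="ndarray")
    if cand.size:
        d = np.linalg.norm(centers[cand[:, 0]] - centers[cand[:, 1]], axis=1)
        edges = cand[d < 1.5 * c_mean]
    else:
        edges = np.empty((0, 2), dtype=int)
    return EdgeGraph(edges, c_mean)


# ----------------------------------------------------------------------
# coarse-graining of atomic models
# ----------------------------------------------------------------------
_AA3 = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "MSE"}
_NUC = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}
_BETA_ONLY = {"SER", "CYS", "ALA", "GLY", "VAL", "THR"}
_MAIN_CHAIN = {"N", "C", "O", "OXT"}


def _greek(atom_name: str) -> str:
    """Remote-ness indicator letter of a heavy-atom name (CB -> 'B')."""
    return atom_name[1] if len(atom_name) > 1 else ""


def _split_two(names, positions, zs, ref_point):
    """Deterministically split a group into two by distance to a reference."""
    order = np.argsort([np.linalg.norm(positions[i] - ref_point)
                        for i in range(len(names))], kind="stable")
    h = (len(order) + 1) // 2
    return order[:h], order[h:]


def _amino_acid_groups(rname, names, positions, zs):
    """Return a list of (position, z_sum) groups; first is the main chain."""
    amap = {n: i for i, n in enumerate(names)}
    groups = []
    mc_pos_atoms = [amap[a] for a in ("N", "C", "O") if a in amap]
    if not mc_pos_atoms:
        return None
    mc_amp_atoms = [i for i, n in enumerate(names) if n in _MAIN_CHAIN or n == "CA"]
    groups.append((positions[mc_pos_atoms].mean(axis=0),
                   float(zs[mc_amp_atoms].sum())))

    side = [i for i, n in enumerate(names)
            if n not in _MAIN_CHAIN and n != "CA"]
    if rname == "GLY" or not side:
        return groups

    if rname in _BETA_ONLY:
        if "CB" not in amap:
            return groups
        groups.append((positions[amap["CB"]], float(zs[side].sum())))
        return groups

    if rname == "PRO":
        pos_atoms = [amap[a] for a in ("CA", "CB", "CG", "CD") if a in amap]
        groups.append((positions[pos_atoms].mean(axis=0),
                       float(zs[side].sum())))
        return groups

    abg = [amap[n] for n in names
           if n == "CA" or (n not in _MAIN_CHAIN and _greek(n) in ("B", "G"))]
    near = [i for i in side if _greek(names[i]) in ("B", "G")]
    rest = [i for i in side if i not in near]
    if abg:
        groups.append((positions[abg].mean(axis=0), float(zs[near].sum())))
    if rest:
        ref = positions[abg].mean(axis=0) if abg else positions[side].mean(axis=0)
        if rname in ("TYR", "TRP"):
            rest = np.asarray(rest)
            a_idx, b_idx = _split_two([names[i] for i in rest],
                                      positions[rest], zs[rest], ref)
            groups.append((positions[rest[a_idx]].mean(axis=0),
                           float(zs[rest[a_idx]].sum())))
            groups.append((positions[rest[b_idx]].mean(axis=0),
                           float(zs[rest[b_idx]].sum())))
        else:
            rest = np.asarray(rest)
            groups.append((positions[rest].mean(axis=0),
                           float(zs[rest].sum())))
    return groups


def _nucleotide_groups(rname, names, positions, zs):
    amap = {n: i for i, n in enumerate(names)}
    if "P" not in amap:
        return None
    phos = [i for i, n in enumerate(names)
            if n in ("P", "OP1", "OP2", "OP3", "O5'", "O3'")]
    sugar = [i for i, n in enumerate(names)
             if "'" in n and n not in ("O5'", "O3'")]
    base = [i for i, n in enumerate(names)
            if i not in phos and i not in sugar]
    if not sugar or not base:
        return None
    groups = [(positions[amap["P"]], float(zs[phos].sum())),
              (positions[sugar].mean(axis=0), float(zs[sugar].sum()))]
    glyc = amap.get("N9", amap.get("N1", base[0]))
    base = np.asarray(base)
    a_idx, b_idx = _split_two([names[i] for i in base], positions[base],
                              zs[base], positions[glyc])
    groups.append((positions[base[a_idx]].mean(axis=0),
                   float(zs[base[a_idx]].sum())))
    groups.append((positions[base[b_idx]].mean(axis=0),
                   float(zs[base[b_idx]].sum())))
    return groups


def coarse_grain_atomic_model(structure: AtomicStructure,
                              width: float = 1.8):
    """Coarse-grain an atomic model into Gaussians plus a bond graph.

    Amino acids get one main-chain Gaussian at the N/C/O barycenter and
    one to three side-chain Gaussians depending on residue size;
    nucleotides get four (phosphate, sugar, two base groups).  Amplitudes
    are proportional to the summed atomic numbers of each group; distinct
    sums become one-hot width classes so the proportionality is exact
    within the class-weighted model.  Unknown residues are skipped with a
    warning and counted in the returned report.
    """
    centers, amps = [], []
    edges = []
    report = {"skipped": 0, "amino_acids": 0, "nucleotides": 0}
    prev_mc, prev_chain = None, None
    for chain, rid, rname, names, positions, zs in structure.residues():
        if rname in _AA3:
            groups = _amino_acid_groups(rname, names, positions, zs)
            kind = "amino_acids"
        elif rname in _NUC:
            groups = _nucleotide_groups(rname, names, positions, zs)
            kind = "nucleotides"
        else:
            groups = None
            kind = None
        if groups is None:
            if kind is None:
                warnings.warn(f"unknown residue {rname} {chain}:{rid} skipped")
            else:
                warnings.warn(f"incomplete residue {rname} {chain}:{rid} skipped")
            report["skipped"] += 1
            prev_mc, prev_chain = None, None
            continue
        report[kind] += 1
        base_idx = len(centers)
        for pos, z in groups:
            centers.append(pos)
            amps.append(z)
        if kind == "amino_acids":
            mc = base_idx
            # side-chain chain: mc - sc1 - sc2 - ...
            for g in range(1, len(groups)):
                edges.append((base_idx + g - 1, base_idx + g))
        else:
            mc = base_idx  # phosphate continues the main chain
            edges.append((base_idx, base_idx + 1))      # P - sugar
            edges.append((base_idx + 1, base_idx + 2))  # sugar - base1
            edges.append((base_idx + 2, base_idx + 3))  # base1 - base2
        if prev_mc is not None and prev_chain == chain:
            edges.append((prev_mc, mc))
        prev_mc = (base_idx + 1) if kind == "nucleotides" else mc
        prev_chain = chain

    if not centers:
        raise ValueError("no recognized residues in structure")
    centers = np.asarray(centers)
    amps = np.asarray(amps, dtype=float)
    values, inverse = np.unique(amps, return_inverse=True)
    nc, ng = len(values), len(amps)
    weights = np.zeros((nc, ng))
    weights[inverse, np.arange(ng)] = 1.0
    model = GaussianModel(centers, np.full(nc, width), values, weights)
    graph = EdgeGraph(np.asarray(edges, dtype=int).reshape(-1, 2),
                      c_mean=0.0, source="atomic_bonds")
    return model, graph, report
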