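"""Readers and writers for the standard single-particle cryo-EM files.

Coordinate conventions used throughout the package:

* world/model coordinates are in Angstrom, with the box centered at the
  origin: the voxel with index ``n // 2`` on each axis has coordinate 0;
* volumes are numpy arrays indexed ``[z, y, x]`` (MRC section order);
* Euler angles follow the RELION ZYZ intrinsic convention
  (rot, tilt, psi), shifts are in Angstrom and apply in the image plane;
* image stacks are float32 MRCS files, one section per particle.

MRC headers are read and written directly (MRC2014, mode 2); STAR
metadata goes through :mod:`gemmi.cif` (STAR is a superset of CIF) and
atomic models through :func:`gemmi.read_structure`.
"""
from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import gemmi
from gemmi import cif


class FormatError(ValueError):
    """Malformed file content."""


class UnsupportedShapeError(ValueError):
    """Volume is not a cubic box."""


class StarSchemaError(KeyError):
    """A mandatory STAR column is missing."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class VolumeGrid:
    """A cubic scalar volume with voxel size in Angstrom.

    `origin` is the Angstrom coordinate of the center of voxel (0,0,0);
    with the package's centered convention it equals ``-(n//2)*voxel_size``
    on each axis.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise UnsupportedShapeError(
                f"expected a cubic box, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.origin is None:
            n = self.data.shape[0]
            self.origin = np.full(3, -(n // 2) * self.voxel_size)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def box_size(self) -> int:
        return self.data.shape[0]

    def axis_coords(self) -> np.ndarray:
        """World coordinate of each voxel center along one axis (Angstrom)."""
        n = self.box_size
        return (np.arange(n) - n // 2) * self.voxel_size


@dataclass
class CTFParams:
    """Contrast-transfer-function parameters for one particle."""

    defocus_u: float          # Angstrom
    defocus_v: float          # Angstrom
    astig_angle: float = 0.0  # degrees
    voltage: float = 300.0    # kV
    cs: float = 2.7           # mm
    amplitude_contrast: float = 0.1
    phase_shift: float = 0.0  # degrees

    def __post_init__(self):
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class ParticleRecord:
    image_index: int
    euler: np.ndarray        # (rot, tilt, psi) degrees, ZYZ intrinsic
    shift: np.ndarray        # (x, y) Angstrom, image-plane translation
    ctf: CTFParams
    halfset: int             # 1 or 2


class ParticleStack:
    """Particle images plus per-particle metadata (poses, CTF, half set)."""

    def __init__(self, images, pixel_size, eulers, shifts, ctfs, halfsets):
        self.images = None if images is None else np.asarray(images, np.float32)
        self.pixel_size = float(pixel_size)
        self.eulers = np.asarray(eulers, dtype=float)      # (N, 3) degrees
        self.shifts = np.asarray(shifts, dtype=float)      # (N, 2) Angstrom
        self.ctfs = list(ctfs)
        self.halfsets = np.asarray(halfsets, dtype=int)
        n = len(self.eulers)
        if not (len(self.shifts) == len(self.ctfs) == len(self.halfsets) == n):
            raise ValueError("inconsistent metadata lengths")
        if self.images is not None:
            box = self.images.shape[-1] * self.pixel_size
            if np.any(np.abs(self.shifts) >= box):
                raise ValueError("shift magnitude exceeds box extent")
        if not np.all(np.isin(self.halfsets, (1, 2))):
            raise ValueError("half-set labels must be 1 or 2")

    def __len__(self):
        return len(self.eulers)

    @property
    def box_size(self) -> int:
        return self.images.shape[-1]

    def record(self, i: int) -> ParticleRecord:
        return ParticleRecord(i, self.eulers[i], self.shifts[i],
                              self.ctfs[i], int(self.halfsets[i]))

    def subset(self, idx) -> "ParticleStack":
        idx = np.asarray(idx)
        return ParticleStack(
            None if self.images is None else self.images[idx],
            self.pixel_size, self.eulers[idx], self.shifts[idx],
            [self.ctfs[i] for i in idx], self.halfsets[idx])

    def halfset_indices(self, half: int) -> np.ndarray:
        return np.flatnonzero(self.halfsets == half)


@dataclass
class AtomicStructure:
    """Heavy atoms of a PDB/mmCIF model, grouped per residue."""

    elements: list
    atomic_numbers: np.ndarray
    positions: np.ndarray     # (N, 3) Angstrom
    res_names: list
    res_ids: np.ndarray
    chains: list
    atom_names: list

    def __len__(self):
        return len(self.elements)

    def residues(self):
        """Yield (chain, res_id, res_name, atom_names, positions, Z) per residue."""
        order, seen = [], {}
        for i in range(len(self.elements)):
            key = (self.chains[i], int(self.res_ids[i]))
            if key not in seen:
                seen[key] = len(order)
                order.append([key, self.res_names[i], []])
            order[seen[key]][2].append(i)
        for (chain, rid), rname, idx in order:
            idx = np.asarray(idx)
            yield (chain, rid, rname, [self.atom_names[i] for i in idx],
                   self.positions[idx], self.atomic_numbers[idx])


# ----------------------------------------------------------------------
# MRC volumes and stacks
# ----------------------------------------------------------------------
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path):
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise FormatError(f"{path}: truncated MRC header")
        ints = np.frombuffer(header, dtype="<i4")
        floats = np.frombuffer(header, dtype="<f4")
        nx, ny, nz, mode = ints[0], ints[1], ints[2], ints[3]
        if mode not in _MRC_MODES:
            raise FormatError(f"{path}: unsupported MRC mode {mode}")
        if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100000:
            raise FormatError(f"{path}: implausible dimensions {(nx, ny, nz)}")
        mx = ints[7] if ints[7] > 0 else nx
        cella_x = floats[10]
        voxel = float(cella_x) / mx if cella_x > 0 else 1.0
        nsymbt = ints[23]
        fh.seek(1024 + int(nsymbt))
        count = int(nx) * int(ny) * int(nz)
        data = np.fromfile(fh, dtype=_MRC_MODES[int(mode)], count=count)
        if data.size != count:
            raise FormatError(f"{path}: truncated MRC data")
        origin = floats[49:52].astype(float).copy()
    return data.reshape(nz, ny, nx), voxel, origin


def _write_mrc(path, data, voxel_size, origin=None, is_stack=False):
    data = np.ascontiguousarray(data, dtype=np.float32)
    nz, ny, nx = data.shape
    ints = np.zeros(256, dtype="<i4")
    floats = ints.view("<f4")
    ints[0:3] = (nx, ny, nz)
    ints[3] = 2  # float32
    ints[7:10] = (nx, ny, nx if is_stack else nz)
    floats[10:13] = (nx * voxel_size, ny * voxel_size,
                     (nx if is_stack else nz) * voxel_size)
    floats[13:16] = 90.0
    ints[16:19] = (1, 2, 3)
    floats[19] = float(data.min())
    floats[20] = float(data.max())
    floats[21] = float(data.mean())
    ints[22] = 0 if is_stack else 1  # ispg
    if origin is not None:
        floats[49:52] = origin
    ints[52] = int.from_bytes(b"MAP ", "little")
    ints[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")
    floats[54] = float(data.std())
    with open(path, "wb") as fh:
        fh.write(ints.tobytes())
        data.tofile(fh)


def read_volume(path) -> VolumeGrid:
    """Read a cubic MRC volume; raises on non-cubic boxes."""
    data, voxel, origin = _read_mrc(path)
    if len(set(data.shape)) != 1:
        raise UnsupportedShapeError(
            f"{path}: non-cubic volume {data.shape}")
    grid = VolumeGrid(np.asarray(data, np.float32), voxel)
    if np.any(origin != 0):
        grid.origin = origin
    return grid


def write_volume(path, grid: VolumeGrid):
    _write_mrc(path, grid.data, grid.voxel_size, origin=grid.origin)


def read_image_stack(path):
    """Read an MRCS stack -> (images (N, ny, nx), pixel_size)."""
    data, voxel, _ = _read_mrc(path)
    return np.asarray(data, np.float32), voxel


def write_image_stack(path, images, pixel_size):
    _write_mrc(path, images, pixel_size, is_stack=True)


# ----------------------------------------------------------------------
# STAR particle metadata
# ----------------------------------------------------------------------
_POSE_COLS = ["_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi",
              "_rlnOriginXAngst", "_rlnOriginYAngst"]
_CTF_COLS = ["_rlnDefocusU", "_rlnDefocusV", "_rlnDefocusAngle"]
_OPTICS_COLS = ["_rlnVoltage", "_rlnSphericalAberration",
                "_rlnAmplitudeContrast"]


def _column(block, tag, n_rows, optional_value=None):
    col = block.find_loop(tag)
    vals = [x for x in col]
    if not vals:
        if optional_value is not None:
            return [optional_value] * n_rows
        raise StarSchemaError(f"missing mandatory STAR column {tag}")
    return vals


def read_particles(star_path, stack_root=None, load_images=True) -> ParticleStack:
    """Read a RELION-style STAR file (optics-aware or flat single table).

    If the half-set column is absent, labels are assigned by row parity
    (row 0 -> 1, row 1 -> 2, ...).
    """
    doc = cif.read_file(str(star_path))
    pblock = doc.find_block("particles") or doc.sole_block()
    oblock = doc.find_block("optics")

    names = [x for x in pblock.find_loop("_rlnImageName")]
    if not names:
        raise StarSchemaError("missing mandatory STAR column _rlnImageName")
    n = len(names)

    pose = {c: np.array([float(v) for v in _column(pblock, c, n)])
            for c in _POSE_COLS}
    ctf_part = {c: np.array([float(v) for v in _column(pblock, c, n)])
                for c in _CTF_COLS}

    def scalar_from_optics(tag, default):
        if oblock is not None:
            vals = [x for x in oblock.find_loop(tag)]
            if vals:
                return float(vals[0])
        vals = [x for x in pblock.find_loop(tag)]
        if vals:
            return float(vals[0])
        return default

    voltage = scalar_from_optics("_rlnVoltage", 300.0)
    cs = scalar_from_optics("_rlnSphericalAberration", 2.7)
    ac = scalar_from_optics("_rlnAmplitudeContrast", 0.1)
    pixel = scalar_from_optics("_rlnImagePixelSize", 0.0)

    phase = _column(pblock, "_rlnPhaseShift", n, optional_value="0.0")
    half_raw = [x for x in pblock.find_loop("_rlnRandomSubset")]
    if half_raw:
        halfsets = np.array([int(float(x)) for x in half_raw])
    else:
        halfsets = np.arange(n) % 2 + 1

    ctfs = [CTFParams(ctf_part["_rlnDefocusU"][i], ctf_part["_rlnDefocusV"][i],
                      ctf_part["_rlnDefocusAngle"][i], voltage, cs, ac,
                      float(phase[i])) for i in range(n)]
    eulers = np.stack([pose["_rlnAngleRot"], pose["_rlnAngleTilt"],
                       pose["_rlnAnglePsi"]], axis=1)
    shifts = np.stack([pose["_rlnOriginXAngst"],
                       pose["_rlnOriginYAngst"]], axis=1)

    images = None
    if load_images:
        root = stack_root if stack_root is not None else os.path.dirname(
            str(star_path))
        slices, files = [], []
        for nm in names:
            idx, fname = nm.split("@")
            slices.append(int(idx) - 1)
            files.append(fname)
        stacks = {}
        for f in set(files):
            stacks[f], stack_pixel = read_image_stack(os.path.join(root, f))
            if pixel == 0.0:
                pixel = stack_pixel
        images = np.stack([stacks[f][s] for f, s in zip(files, slices)])
    if pixel == 0.0:
        pixel = 1.0
    return ParticleStack(images, pixel, eulers, shifts, ctfs, halfsets)


def write_particles(star_path, stack: ParticleStack, stack_name="particles.mrcs",
                    write_stack=True):
    """Write STAR metadata (optics + particles tables) and the MRCS stack."""
    star_path = str(star_path)
    root = os.path.dirname(star_path)
    if write_stack and stack.images is not None:
        write_image_stack(os.path.join(root, stack_name), stack.images,
                          stack.pixel_size)

    doc = cif.Document()
    ob = doc.add_new_block("optics")
    loop = ob.init_loop("", ["_rlnOpticsGroup", "_rlnVoltage",
                             "_rlnSphericalAberration",
                             "_rlnAmplitudeContrast", "_rlnImagePixelSize",
                             "_rlnImageSize"])
    def fmt(x):
        return f"{float(x):.8f}"

    c0 = stack.ctfs[0]
    loop.add_row(["1", fmt(c0.voltage), fmt(c0.cs),
                  fmt(c0.amplitude_contrast), fmt(stack.pixel_size),
                  str(stack.images.shape[-1] if stack.images is not None else 0)])

    pb = doc.add_new_block("particles")
    cols = ["_rlnImageName", "_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi",
            "_rlnOriginXAngst", "_rlnOriginYAngst", "_rlnDefocusU",
            "_rlnDefocusV", "_rlnDefocusAngle", "_rlnPhaseShift",
            "_rlnRandomSubset", "_rlnOpticsGroup"]
    loop = pb.init_loop("", cols)
    for i in range(len(stack)):
        c = stack.ctfs[i]
        loop.add_row([f"{i + 1:06d}@{stack_name}",
                      fmt(stack.eulers[i, 0]), fmt(stack.eulers[i, 1]),
                      fmt(stack.eulers[i, 2]), fmt(stack.shifts[i, 0]),
                      fmt(stack.shifts[i, 1]), fmt(c.defocus_u),
                      fmt(c.defocus_v), fmt(c.astig_angle),
                      fmt(c.phase_shift), str(int(stack.halfsets[i])), "1"])
    doc.write_file(star_path)


# ----------------------------------------------------------------------
# atomic models
# ----------------------------------------------------------------------
def read_structure(pdb_path) -> AtomicStructure:
    """Read a PDB/mmCIF model: hydrogens dropped, altlocs resolved to the
    highest-occupancy conformer."""
    st = gemmi.read_structure(str(pdb_path))
    if len(st) == 0 or st[0].count_atom_sites() == 0:
        raise FormatError(f"{pdb_path}: empty model")
    model = st[0]
    elements, zs, pos, rnames, rids, chains, anames = [], [], [], [], [], [], []
    for chain in model:
        for res in chain:
            best = {}
            for atom in res:
                if atom.element.atomic_number <= 1:
                    continue  # hydrogen / deuterium
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                elements.append(atom.element.name)
                zs.append(atom.element.atomic_number)
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                rnames.append(res.name)
                rids.append(res.seqid.num)
                chains.append(chain.name)
                anames.append(atom.name)
    if not elements:
        raise FormatError(f"{pdb_path}: no heavy atoms")
    return AtomicStructure(elements, np.array(zs), np.array(pos),
                           rnames, np.array(rids), chains, anames)
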