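"""Density-map and model I/O, map simulation, and synthetic fixtures.

All geometry is in Angstroms. A :class:`DensityGrid` is a point grid: voxel
index ``(i, j, k)`` (0-based) corresponds to the physical position
``origin + (i, j, k) * spacing``, with axes normalized to x, y, z order on
load. Density values are non-negative; negative file values are clamped to
zero, since the tracing method interprets density as (non-negative) mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DensityGrid",
    "Atom",
    "AtomicModel",
    "SeedPoints",
    "MapFormatError",
    "UnsupportedMapError",
    "EmptyThresholdError",
    "read_map",
    "write_map",
    "read_pdb",
    "write_ca_pdb",
    "read_fasta",
    "simulate_map",
    "make_synthetic_chain",
    "make_synthetic_model",
    "threshold_grid",
    "zone_mask",
    "HEAVY_ATOM_COUNTS",
]


class MapFormatError(ValueError):
    """Raised for malformed or unreadable map files."""


class UnsupportedMapError(ValueError):
    """Raised for maps this package does not handle (e.g. non-orthogonal cells)."""


class EmptyThresholdError(ValueError):
    """Raised when no voxel passes a density threshold."""


@dataclass
class DensityGrid:
    """3D scalar density field on a regular orthogonal point grid."""

    origin: np.ndarray          # (3,) Angstrom position of voxel (0,0,0)
    spacing: np.ndarray         # (3,) Angstrom per voxel along x,y,z
    values: np.ndarray          # (nx,ny,nz) non-negative float
    axis_order: tuple = (0, 1, 2)   # file-axis -> xyz permutation (post-normalization)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        """Physical position(s) of voxel index/indices (broadcasts over rows)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def position_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Nearest voxel index of a physical position (may be out of bounds)."""
        return np.rint((np.asarray(pos, dtype=float) - self.origin) / self.spacing).astype(int)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.origin.copy(), self.spacing.copy(),
                           self.values.copy(), self.axis_order)


@dataclass
class Atom:
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray


@dataclass
class AtomicModel:
    """A minimal atomic model: heavy atoms or a Calpha-only trace."""

    atoms: list
    ca_only: bool = False

    def __post_init__(self):
        for a in self.atoms:
            a.position = np.asarray(a.position, dtype=float)
            if not np.all(np.isfinite(a.position)):
                raise ValueError("atom positions must be finite")

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def ca_positions(self) -> np.ndarray:
        """Calpha coordinates ordered by residue index."""
        cas = [a for a in self.atoms if a.element == "CA" or (self.ca_only and a.element == "C")]
        if not cas:
            cas = [a for a in self.atoms]
        cas = sorted(cas, key=lambda a: a.residue_index)
        return np.array([a.position for a in cas], dtype=float)

    def ca_residue_indices(self) -> np.ndarray:
        cas = [a for a in self.atoms if a.element == "CA" or (self.ca_only and a.element == "C")]
        if not cas:
            cas = [a for a in self.atoms]
        return np.array(sorted(a.residue_index for a in cas), dtype=int)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class SeedPoints:
    """Grid points above a density threshold: mean-shift starting seeds."""

    positions: np.ndarray    # (M,3) Angstrom
    indices: np.ndarray      # (M,3) int voxel indices
    phi: np.ndarray          # (M,) density at the seed voxel

    def __len__(self) -> int:
        return len(self.phi)


# ---------------------------------------------------------------------------
# MRC/CCP4 map I/O (via gemmi; MRC2014 dialect, xyz axis order on write)
# ---------------------------------------------------------------------------

def read_map(path: str) -> DensityGrid:
    """Read an MRC/CCP4 density map into a :class:`DensityGrid`.

    Axis order is normalized to x,y,z regardless of the MAPC/MAPR/MAPS
    header. The physical origin honors the ORIGIN header record when any
    component is nonzero, otherwise NXSTART * spacing. Negative densities
    are clamped to zero.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path!r}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise UnsupportedMapError("non-orthogonal unit cells are not supported")
    file_axes = tuple(m.header_i32(i) - 1 for i in (17, 18, 19))  # MAPC/R/S
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)  # normalize data to x,y,z order
    values = np.array(m.grid, copy=True).astype(float)
    nx, ny, nz = values.shape
    spacing = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
    if np.any(origin_rec != 0):
        origin = origin_rec
    else:
        origin = nstart * spacing
    np.maximum(values, 0.0, out=values)
    return DensityGrid(origin=origin, spacing=spacing, values=values,
                       axis_order=file_axes)


def write_map(grid: DensityGrid, path: str) -> None:
    """Write a grid as an MRC2014 map (xyz axis order, ORIGIN record set)."""
    nx, ny, nz = grid.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(gemmi.UnitCell(nx * grid.spacing[0], ny * grid.spacing[1],
                                   nz * grid.spacing[2], 90.0, 90.0, 90.0))
    np.asarray(g)[:] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# PDB / FASTA I/O
# ---------------------------------------------------------------------------

def read_pdb(path: str, ca_only: bool = False) -> AtomicModel:
    """Read heavy atoms (or only Calphas) of the first model of a PDB file."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                if at.element.name == "H":
                    continue
                if ca_only and at.name != "CA":
                    continue
                atoms.append(Atom(element=at.name, residue_index=res.seqid.num,
                                  residue_name=res.name, chain_id=chain.name,
                                  position=np.array([at.pos.x, at.pos.y, at.pos.z])))
    if not atoms:
        raise ValueError(f"no atoms read from {path!r}")
    return AtomicModel(atoms=atoms, ca_only=ca_only)


def write_ca_pdb(path: str, coords: np.ndarray, residue_indices: Sequence[int],
                 residue_names: Sequence[str] | None = None,
                 bfactors: Sequence[float] | None = None,
                 remarks: Sequence[str] = ()) -> None:
    """Write a Calpha-only single-chain PDB file.

    ``bfactors`` (e.g. consensus confidence scaled to 0-100) go to the
    B-factor column.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residue_names is None:
        residue_names = ["ALA"] * n
    if bfactors is None:
        bfactors = [0.0] * n
    with open(path, "w") as fh:
        for r in remarks:
            fh.write(f"REMARK   3 {r}\n")
        for serial, (xyz, ri, rn, b) in enumerate(
                zip(coords, residue_indices, residue_names, bfactors), start=1):
            fh.write(
                "ATOM  {:5d}  CA  {:<3s} A{:4d}    "
                "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}           C\n".format(
                    serial, rn[:3], int(ri), xyz[0], xyz[1], xyz[2], 1.0, float(b)))
        fh.write("TER\nEND\n")


def read_fasta(path: str) -> str:
    """Read the first sequence of a FASTA file as an uppercase string."""
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Map simulation (Gaussian blurring of an atomic model)
# ---------------------------------------------------------------------------

#: Kernel width as a fraction of nominal resolution. With this convention a
#: map "at resolution R" is the atomic model convolved with an isotropic
#: Gaussian of sigma = 0.225 * R (approximately the EMAN pdb2mrc convention,
#: where resolution ~ FWHM * 1.06).
SIGMA_PER_RESOLUTION = 0.225


def simulate_map(model: AtomicModel, resolution: float = 5.0, spacing: float = 1.0,
                 sigma_factor: float = SIGMA_PER_RESOLUTION) -> DensityGrid:
    """Simulate an EM density map by Gaussian blurring of an atomic model.

    Each heavy atom contributes an isotropic Gaussian of standard deviation
    ``sigma_factor * resolution`` with unit amplitude, evaluated on a cubic
    grid padded at least 3 sigma beyond the model's bounding box.
    """
    if len(model) == 0:
        raise ValueError("cannot simulate a map from an empty model")
    if resolution <= 0 or spacing <= 0:
        raise ValueError("resolution and spacing must be positive")
    sigma = sigma_factor * resolution
    pos = model.positions()
    # pad to the full accumulation window (> the 3 sigma minimum) so each
    # atom's kernel mass is complete and maps are exactly additive
    pad = 4.5 * sigma
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    values = np.zeros(shape, dtype=float)
    # accumulate each atom over a local window (4.5 sigma: truncation error
    # is negligible against the 3D Gaussian mass)
    rwin = int(math.ceil(4.5 * sigma / spacing))
    axes = [np.arange(-rwin, rwin + 1)] * 3
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    for p in pos:
        center_idx = np.rint((p - lo) / spacing).astype(int)
        idx = center_idx + offs
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        d2 = np.sum((lo + idx * spacing - p) ** 2, axis=1)
        np.add.at(values, tuple(idx.T), np.exp(-d2 / (2.0 * sigma * sigma)))
    return DensityGrid(origin=lo, spacing=np.full(3, float(spacing)), values=values)


# ---------------------------------------------------------------------------
# Synthetic chain fixtures
# ---------------------------------------------------------------------------

_CA_CA = 3.8          # consecutive Calpha-Calpha distance, Angstrom
_HELIX_RISE = 1.5     # axial rise per residue in an ideal alpha-helix
_HELIX_TWIST = math.radians(100.0)   # rotation per residue

#: Heavy-atom counts of the 20 standard residues (backbone N,CA,C,O plus
#: side-chain heavy atoms). Used both by the synthetic model generator and,
#: normalized, as the default expected-density table for threading.
HEAVY_ATOM_COUNTS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8,
    "Q": 9, "E": 9, "K": 9, "H": 10,
    "F": 11, "R": 11, "Y": 12, "W": 14,
}

_AA3 = {
    "G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "T": "THR", "V": "VAL",
    "P": "PRO", "L": "LEU", "I": "ILE", "N": "ASN", "D": "ASP", "M": "MET",
    "Q": "GLN", "E": "GLU", "K": "LYS", "H": "HIS", "F": "PHE", "R": "ARG",
    "Y": "TYR", "W": "TRP",
}


def _helix_coords(n: int) -> np.ndarray:
    # radius chosen so the chord between consecutive residues is exactly 3.8 A
    chord_sq = _CA_CA ** 2 - _HELIX_RISE ** 2
    radius = math.sqrt(chord_sq) / (2.0 * math.sin(_HELIX_TWIST / 2.0))
    t = np.arange(n)
    return np.column_stack([radius * np.cos(_HELIX_TWIST * t),
                            radius * np.sin(_HELIX_TWIST * t),
                            _HELIX_RISE * t])


def _strand_coords(n: int) -> np.ndarray:
    # near-linear zigzag with exact 3.8 A steps
    wiggle = 0.3
    dz = math.sqrt(_CA_CA ** 2 - (2 * wiggle) ** 2)
    t = np.arange(n)
    return np.column_stack([wiggle * (-1.0) ** t, np.zeros(n), dz * t])


def _random_rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # Haar-random rotation via QR of a Gaussian matrix, plus a small offset
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(0.0, 5.0, size=3)
    centered = coords - coords.mean(axis=0)
    return centered @ q.T + shift


def make_synthetic_chain(kind: str, n_residues: int, seed: int) -> AtomicModel:
    """Generate a synthetic Calpha trace (helix, strand, or mixed).

    Consecutive Calpha distances are 3.8 A by construction. The chain is
    placed with a seeded random rigid transform so distinct seeds give
    distinct poses; coordinates are deterministic given the seed.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if kind == "helix":
        coords = _helix_coords(n_residues)
    elif kind == "strand":
        coords = _strand_coords(n_residues)
    elif kind == "mixed":
        n1 = n_residues // 2
        n2 = n_residues - n1
        h = _helix_coords(n1)
        axis = np.array([0.0, 0.0, 1.0])
        start = h[-1] + _CA_CA * axis
        s = start + np.arange(n2)[:, None] * _CA_CA * axis
        coords = np.vstack([h, s])
    else:
        raise ValueError(f"unknown chain kind {kind!r}")
    rng = np.random.default_rng(seed)
    coords = _random_rigid_transform(coords, rng)
    atoms = [Atom("CA", i + 1, "ALA", "A", coords[i]) for i in range(n_residues)]
    return AtomicModel(atoms=atoms, ca_only=True)


def make_synthetic_model(sequence: str, kind: str = "helix", seed: int = 0,
                         bond_step: float = 1.5) -> AtomicModel:
    """Synthetic all-heavy-atom model for a sequence on an ideal chain.

    Synthetic stand-in for a real deposited structure: the Calpha trace
    comes from :func:`make_synthetic_chain`, and each residue receives
    ``heavy_atoms(aa) - 1`` pseudo atoms laid out as a jittered random walk
    from the Calpha at ``bond_step`` spacing (seeded, persistent outward
    direction), so larger residues extend farther and carry proportionally
    more simulated density -- the signal sequence threading relies on.
    The pseudo side chains are not stereochemical.
    """
    sequence = sequence.upper()
    trace = make_synthetic_chain(kind, len(sequence), seed)
    cas = trace.ca_positions()
    centroid = cas.mean(axis=0)
    rng = np.random.default_rng(seed + 1)
    atoms = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa not in HEAVY_ATOM_COUNTS:
            raise ValueError(f"unknown residue letter {aa!r}")
        resname = _AA3[aa]
        ca = cas[i]
        atoms.append(Atom("CA", i + 1, resname, "A", ca.copy()))
        # backbone N/C analogues: two bridge atoms along the next segment keep
        # the main-chain a continuous dense tube, as in real maps; chain ends
        # get stub atoms instead (amino N / carboxyl C-OXT analogues)
        placed = 1
        if i < n - 1:
            seg = cas[i + 1] - ca
            for f in (1.0 / 3.0, 2.0 / 3.0):
                atoms.append(Atom("X", i + 1, resname, "A", ca + f * seg))
                placed += 1
        else:
            seg = ca - cas[i - 1]
            for f in (1.0 / 3.0, 2.0 / 3.0):
                atoms.append(Atom("X", i + 1, resname, "A", ca + f * seg))
                placed += 1
        if i == 0:
            atoms.append(Atom("X", i + 1, resname, "A",
                              ca - (1.0 / 3.0) * (cas[1] - ca)))
            placed += 1
        # carbonyl-O analogue: perpendicular offset off the chain axis
        axis = (cas[min(i + 1, n - 1)] - cas[max(i - 1, 0)])
        axis /= max(np.linalg.norm(axis), 1e-9)
        perp = np.cross(axis, ca - centroid)
        perp_n = np.linalg.norm(perp)
        perp = perp / perp_n if perp_n > 1e-9 else np.array([0.0, 0.0, 1.0])
        atoms.append(Atom("X", i + 1, resname, "A", ca + 1.3 * perp))
        placed += 1
        # side chain: diffusive outward walk, RMS reach ~ bond_step * sqrt(n)
        outward = ca - centroid
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        pos = ca.copy()
        for _ in range(max(HEAVY_ATOM_COUNTS[aa] - placed, 0)):
            step = 0.35 * outward + rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = pos + bond_step * step
            if np.linalg.norm(cand - ca) > 3.5:
                # rotamers curl: keep side-chain mass within ~3.5 A of the Calpha
                back = ca - pos
                back /= max(np.linalg.norm(back), 1e-9)
                cand = pos + bond_step * (0.7 * back + 0.3 * rng.normal(size=3))
            pos = cand
            atoms.append(Atom("X", i + 1, resname, "A", pos.copy()))
    return AtomicModel(atoms=atoms, ca_only=False)


# ---------------------------------------------------------------------------
# Thresholding and masking
# ---------------------------------------------------------------------------

def threshold_grid(grid: DensityGrid, phi_thr: float) -> SeedPoints:
    """All grid points with density >= ``phi_thr``, as mean-shift seeds."""
    if phi_thr < 0:
        raise ValueError("phi_thr must be non-negative")
    idx = np.argwhere(grid.values >= phi_thr)
    if len(idx) == 0:
        raise EmptyThresholdError(f"no voxel passes threshold {phi_thr}")
    return SeedPoints(positions=grid.index_to_position(idx),
                      indices=idx,
                      phi=grid.values[tuple(idx.T)])


def zone_mask(grid: DensityGrid, model: AtomicModel, radius: float) -> DensityGrid:
    """Zero out voxels farther than ``radius`` from every model atom.

    Plain distance-based segmentation of a subunit from a larger map.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    out = grid.copy()
    tree = cKDTree(model.positions())
    idx = np.argwhere(np.ones(grid.shape, dtype=bool))
    pos = grid.index_to_position(idx)
    d, _ = tree.query(pos, k=1)
    keep = d <= radius
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(idx[keep].T)] = True
    out.values = np.where(mask, out.values, 0.0)
    return out
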