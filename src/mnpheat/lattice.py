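"""Square particle arrays, neighbor tables and concentration diagnostics.

Particles sit on a finite planar square lattice (z = 0) with open
boundaries; positions never move during a simulation, so the neighbor
table and pair geometry are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import WATER_MEAN_FREE_PATH
from .params import ParameterError


class OverlapError(ParameterError):
    """Particles closer than one diameter."""


@dataclass(frozen=True)
class ParticleLattice:
    """A finite set of fixed particle positions.

    Attributes
    ----------
    positions : (N, 3) array, m.  z = 0 for planar arrays.
    n_side : int, lattice side (n_side**2 particles for square arrays).
    spacing : float, nearest-neighbor distance d, m.
    """

    positions: np.ndarray
    n_side: int
    spacing: float

    def __post_init__(self):
        object.__setattr__(self, "positions",
                           np.ascontiguousarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("positions must be an (N, 3) array")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def surface_density(self) -> float:
        """Dipole surface density rho = 1/d^2, m^-2 (0 for a single particle)."""
        if self.n_particles == 1:
            return 0.0
        return 1.0 / self.spacing ** 2

    @property
    def surface_density_nm2(self) -> float:
        """rho in nm^-2, the unit used for density sweeps."""
        return self.surface_density * 1e-18


def build_square_lattice(n_side: int, spacing: float,
                         particle_radius: float | None = None) -> ParticleLattice:
    """Build an n_side x n_side planar square lattice centred at the origin.

    Parameters
    ----------
    n_side : int >= 1
    spacing : float > 0, nearest-neighbor distance, m.
    particle_radius : optional; when given, spacing < 2 R raises
        :class:`OverlapError`.
    """
    if n_side < 1 or int(n_side) != n_side:
        raise ParameterError(f"n_side must be a positive integer, got {n_side!r}")
    if not (spacing > 0):
        raise ParameterError(f"spacing must be > 0, got {spacing!r}")
    if particle_radius is not None and spacing < 2 * particle_radius * (1 - 1e-12):
        raise OverlapError(
            f"spacing {spacing:g} m < particle diameter {2*particle_radius:g} m")
    idx = np.arange(n_side) - (n_side - 1) / 2.0
    xx, yy = np.meshgrid(idx, idx, indexing="ij")
    pos = np.zeros((n_side * n_side, 3))
    pos[:, 0] = xx.ravel() * spacing
    pos[:, 1] = yy.ravel() * spacing
    return ParticleLattice(positions=pos, n_side=int(n_side), spacing=float(spacing))


def neighbor_table(lattice: ParticleLattice, cutoff: float) -> list[np.ndarray]:
    """Per-particle sorted index lists of all j != i with |r_i - r_j| <= cutoff."""
    if not (cutoff > 0):
        raise ParameterError(f"cutoff must be > 0, got {cutoff!r}")
    tree = cKDTree(lattice.positions)
    # small tolerance so pairs exactly at the cutoff distance are kept
    pairs = tree.query_pairs(cutoff * (1 + 1e-12), output_type="ndarray")
    lists: list[list[int]] = [[] for _ in range(lattice.n_particles)]
    for i, j in pairs:
        lists[i].append(j)
        lists[j].append(i)
    return [np.array(sorted(l), dtype=np.int64) for l in lists]


def neighbor_csr(lattice: ParticleLattice, cutoff: float,
                 neighbors: list[np.ndarray] | None = None):
    """Flatten a neighbor table to CSR plus per-pair geometry.

    Returns ``(indptr, indices, rhat, inv_r3)`` where for pair slot p of
    particle i, ``rhat[p]`` is the unit vector from j to i (r_ij = r_i - r_j)
    and ``inv_r3[p] = 1/|r_ij|^3``.  This is the precomputed geometry the
    integration kernel consumes.
    """
    if neighbors is None:
        neighbors = neighbor_table(lattice, cutoff)
    indptr = np.zeros(lattice.n_particles + 1, dtype=np.int64)
    for i, l in enumerate(neighbors):
        indptr[i + 1] = indptr[i] + len(l)
    m = int(indptr[-1])
    indices = np.empty(m, dtype=np.int64)
    rhat = np.empty((m, 3))
    inv_r3 = np.empty(m)
    pos = lattice.positions
    for i, l in enumerate(neighbors):
        s = indptr[i]
        for k, j in enumerate(l):
            d = pos[i] - pos[j]
            r = np.linalg.norm(d)
            indices[s + k] = j
            rhat[s + k] = d / r
            inv_r3[s + k] = r ** -3
    return indptr, indices, rhat, inv_r3


def knudsen_number(lattice: ParticleLattice, particle_radius: float) -> float:
    """K_n = Lambda / l with Lambda the water mean free path (2.5 Angstrom)
    and l = d - 2R the edge-to-edge inter-particle gap.

    K_n >~ 0.1 flags densities where continuum (Stokes) rotational damping
    may break down and hydrodynamic interactions could matter.
    """
    gap = lattice.spacing - 2.0 * particle_radius
    if lattice.n_particles == 1:
        return 0.0
    if gap <= 0:
        raise ParameterError(
            f"particles in contact: spacing {lattice.spacing:g} m <= diameter "
            f"{2*particle_radius:g} m")
    return WATER_MEAN_FREE_PATH / gap


def mass_concentration(spacing: float, radius: float, mass_density: float,
                       convention: str = "cubic") -> float:
    """Nanoparticle mass concentration in g/L for one particle per cell.

    convention = "cubic" uses a cubic cell of side ``spacing`` (isotropic
    3D distribution with the same nearest-neighbor distance); "spherical"
    uses a sphere of diameter ``spacing`` per particle.  1 kg/m^3 == 1 g/L.
    """
    if not (spacing > 0):
        raise ParameterError(f"spacing must be > 0, got {spacing!r}")
    v_particle = (4.0 / 3.0) * np.pi * radius ** 3
    if convention == "cubic":
        v_cell = spacing ** 3
    elif convention == "spherical":
        v_cell = (np.pi / 6.0) * spacing ** 3
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    return mass_density * v_particle / v_cell
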