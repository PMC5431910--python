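"""Dipole-dipole energies, local fields, torques and magnetization.

The pair energy is the point-dipole coupling

    U_ij = (mu0 / 4 pi r^3) [ mu_i . mu_j - 3 (mu_i . rhat)(mu_j . rhat) ]

and the field a dipole j creates at particle i is

    B_ij = (mu0 / 4 pi r^3) [ 3 (mu_j . rhat) rhat - mu_j ],

with rhat the unit vector from j to i.  All interaction sums run over a
precomputed neighbor table (real-space cutoff, open boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MU0_OVER_4PI
from .lattice import ParticleLattice


class SingularityError(ZeroDivisionError):
    """Coinciding dipole positions."""


@dataclass
class DipoleLatticeState:
    """Orientations and angular velocities of every dipole on a lattice.

    orientations : (N, 3) unit vectors e_i.
    angular_velocities : (N, 3) rad/s.
    moment_magnitude : scalar mu shared by all particles, A m^2.
    """

    orientations: np.ndarray
    angular_velocities: np.ndarray
    moment_magnitude: float
    lattice: ParticleLattice

    def __post_init__(self):
        self.orientations = np.ascontiguousarray(self.orientations, dtype=float)
        self.angular_velocities = np.ascontiguousarray(self.angular_velocities,
                                                       dtype=float)
        n = self.lattice.n_particles
        if self.orientations.shape != (n, 3):
            raise ValueError(f"orientations must be ({n}, 3)")
        if self.angular_velocities.shape != (n, 3):
            raise ValueError(f"angular_velocities must be ({n}, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")

    # ---- constructors -------------------------------------------------------

    @classmethod
    def aligned(cls, lattice: ParticleLattice, moment: float,
                direction=(1.0, 0.0, 0.0)) -> "DipoleLatticeState":
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        n = lattice.n_particles
        return cls(np.tile(d, (n, 1)), np.zeros((n, 3)), moment, lattice)

    @classmethod
    def random(cls, lattice: ParticleLattice, moment: float,
               rng: np.random.Generator) -> "DipoleLatticeState":
        """Isotropic orientations, zero angular velocity."""
        n = lattice.n_particles
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return cls(v, np.zeros((n, 3)), moment, lattice)

    @classmethod
    def staggered(cls, lattice: ParticleLattice, moment: float,
                  axis=(0.0, 1.0, 0.0), alternate: str = "col") -> "DipoleLatticeState":
        """Two-sublattice antiparallel state: sign alternates along columns
        (alternate="col") or rows ("row") of the square lattice."""
        n_side = lattice.n_side
        a = np.asarray(axis, dtype=float)
        a /= np.linalg.norm(a)
        e = np.empty((lattice.n_particles, 3))
        for i in range(n_side):
            for j in range(n_side):
                sign = (-1.0) ** (i if alternate == "col" else j)
                e[i * n_side + j] = sign * a
        return cls(e, np.zeros_like(e), moment, lattice)

    def renormalize(self) -> None:
        self.orientations /= np.linalg.norm(self.orientations, axis=1,
                                            keepdims=True)


# ---- pair-level kernels -----------------------------------------------------

def pair_energy(e_i, e_j, r_ij, moment: float) -> float:
    """Dipole-dipole coupling energy of one pair, J.

    ``r_ij = r_i - r_j`` in metres.  Symmetric under i <-> j and odd under
    flipping either orientation.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    r = np.linalg.norm(r_ij)
    if r == 0.0:
        raise SingularityError("zero separation between dipoles")
    rhat = r_ij / r
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    ang = e_i @ e_j - 3.0 * (e_i @ rhat) * (e_j @ rhat)
    return MU0_OVER_4PI * moment * moment * ang / r ** 3


def dipole_field(e_j, r_ij, moment: float) -> np.ndarray:
    """Field at r_i from a dipole mu e_j at r_j (r_ij = r_i - r_j), T."""
    r_ij = np.asarray(r_ij, dtype=float)
    r = np.linalg.norm(r_ij)
    if r == 0.0:
        raise SingularityError("zero separation between dipoles")
    rhat = r_ij / r
    e_j = np.asarray(e_j, dtype=float)
    return MU0_OVER_4PI * moment * (3.0 * (e_j @ rhat) * rhat - e_j) / r ** 3


def local_field(i: int, state: DipoleLatticeState, neighbors,
                external_field=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Total field at particle i: external B1 plus dipolar fields of its
    neighbors, T."""
    pos = state.lattice.positions
    b = np.array(external_field, dtype=float)
    for j in neighbors[i]:
        b += dipole_field(state.orientations[j], pos[i] - pos[j],
                          state.moment_magnitude)
    return b


def local_fields(state: DipoleLatticeState, neighbors,
                 external_field=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(N, 3) array of local fields on every particle, T."""
    return np.array([local_field(i, state, neighbors, external_field)
                     for i in range(state.lattice.n_particles)])


def torques(state: DipoleLatticeState, neighbors,
            external_field=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Magnetic torque mu_i x B_i on every particle, N m."""
    b = local_fields(state, neighbors, external_field)
    mu = state.moment_magnitude * state.orientations
    return np.cross(mu, b)


def total_energy(state: DipoleLatticeState, neighbors,
                 external_field=(0.0, 0.0, 0.0)) -> float:
    """Hamiltonian H = 1/2 sum_ij U_ij - sum_i mu_i . B1, J.

    The 1/2 compensates the double counting of the neighbor table (which is
    symmetric by construction).
    """
    pos = state.lattice.positions
    mu = state.moment_magnitude
    e = state.orientations
    u = 0.0
    for i in range(state.lattice.n_particles):
        for j in neighbors[i]:
            u += pair_energy(e[i], e[j], pos[i] - pos[j], mu)
    b1 = np.asarray(external_field, dtype=float)
    zeeman = -mu * float(np.sum(e @ b1))
    return 0.5 * u + zeeman


def magnetization(state: DipoleLatticeState) -> np.ndarray:
    """Total magnetic moment M = sum_i mu e_i, A m^2."""
    return state.moment_magnitude * state.orientations.sum(axis=0)
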