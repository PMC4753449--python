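"""Cα anisotropic network model (ANM) and normal-mode extraction.

The network joins every bead pair within a distance cutoff by a Hookean
spring of uniform stiffness γ.  The Hessian of the harmonic potential is
assembled from 3×3 superelements

    H_ij = −γ (r_ij ⊗ r_ij) / d_ij²   for contacts i≠j,
    H_ii = −Σ_{j≠i} H_ij,

which makes it symmetric positive semidefinite with exactly six zero
eigenvalues (rigid-body translations and rotations) when the network is a
single connected component.  Eigenvectors are returned sorted by ascending
eigenvalue with the six rigid modes removed; the lowest-frequency modes
approximate the collective motions of the structure.

Defaults: cutoff 13 Å (standard Cα-ANM range), γ = 1 — every overlap
statistic downstream is invariant to the absolute spring constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DisconnectedNetworkError
from .structures import CoordinateSet

__all__ = ["ElasticNetwork", "ModeSet", "build_hessian", "compute_modes", "anm_modes"]

DEFAULT_CUTOFF = 13.0  # Å
RIGID_TOL = 1e-6  # eigenvalues below RIGID_TOL·λ_max count as rigid-body


def _contact_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


@dataclass
class ElasticNetwork:
    coords: CoordinateSet
    cutoff: float = DEFAULT_CUTOFF
    gamma: float = 1.0
    contacts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.contacts = _contact_pairs(self.coords.positions, self.cutoff)

    @property
    def n_components(self) -> int:
        n = len(self.coords)
        adj = csr_matrix(
            (np.ones(len(self.contacts)), (self.contacts[:, 0], self.contacts[:, 1])),
            shape=(n, n),
        )
        ncomp, _ = connected_components(adj, directed=False)
        return int(ncomp)

    def hessian(self) -> np.ndarray:
        return build_hessian(self.coords, self.cutoff, self.gamma)


@dataclass
class ModeSet:
    """Orthonormal internal modes, ascending eigenvalue, rigid modes removed."""

    eigenvalues: np.ndarray  # (k,)
    eigenvectors: np.ndarray  # (3N, k), columns orthonormal
    dof: int  # 3N

    def __post_init__(self) -> None:
        V = self.eigenvectors
        if V.shape[0] != self.dof:
            raise ValueError("eigenvector length disagrees with dof")
        gram = V.T @ V
        if not np.allclose(gram, np.eye(V.shape[1]), atol=1e-9):
            raise ValueError("eigenvectors are not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def degenerate_pairs(self, rtol: float = 1e-6) -> list[tuple[int, int]]:
        """0-based index pairs of adjacent (near-)degenerate eigenvalues."""
        ev = self.eigenvalues
        scale = max(abs(ev).max(), 1e-300)
        return [
            (i, i + 1)
            for i in range(len(ev) - 1)
            if abs(ev[i + 1] - ev[i]) <= rtol * scale
        ]


def build_hessian(
    coords: CoordinateSet | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> np.ndarray:
    """Assemble the dense 3N×3N ANM Hessian.

    Warns (component count) when the contact network is disconnected;
    mode extraction will then find more than six rigid modes and raise.
    """
    pos = coords.positions if isinstance(coords, CoordinateSet) else np.asarray(coords, float)
    n = len(pos)
    if n < 3:
        raise ValueError("need at least three beads for a meaningful network")
    pairs = _contact_pairs(pos, cutoff)
    H = np.zeros((3 * n, 3 * n))
    if len(pairs):
        rij = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        d2 = np.sum(rij**2, axis=1)
        blocks = -gamma * rij[:, :, None] * rij[:, None, :] / d2[:, None, None]
        for (i, j), B in zip(pairs, blocks):
            H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += B
            H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += B.T
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= B
            H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= B.T
    adj = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"elastic network has {ncomp} connected components at cutoff {cutoff} Å",
            stacklevel=2,
        )
    return H


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Largest-magnitude component of each column made positive (for
    reproducible serialisation; squared-overlap statistics are sign-free)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def compute_modes(hessian: np.ndarray, n_modes: int) -> ModeSet:
    """Diagonalise the Hessian, drop the six rigid modes, keep the lowest n."""
    H = np.asarray(hessian, float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3:
        raise ValueError("hessian must be square 3N×3N")
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("hessian must be symmetric")
    dof = H.shape[0]
    if n_modes > dof - 6:
        raise ValueError(f"n_modes={n_modes} exceeds {dof - 6} internal modes")
    evals, evecs = np.linalg.eigh(H)
    lam_max = max(evals[-1], 1e-300)
    near_zero = int(np.sum(evals < RIGID_TOL * lam_max))
    if near_zero > 6:
        raise DisconnectedNetworkError(
            f"{near_zero} near-zero eigenvalues: network not connected"
        )
    if near_zero < 6:
        raise ValueError(
            f"only {near_zero} near-zero eigenvalues found; "
            "Hessian does not look like a free elastic network"
        )
    sel = slice(6, 6 + n_modes)
    return ModeSet(
        eigenvalues=evals[sel].copy(),
        eigenvectors=_fix_signs(evecs[:, sel].copy()),
        dof=dof,
    )


def anm_modes(
    coords: CoordinateSet,
    n_modes: int = 20,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> ModeSet:
    """Convenience path: coordinates → Hessian → lowest internal modes."""
    return compute_modes(build_hessian(coords, cutoff, gamma), n_modes)
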