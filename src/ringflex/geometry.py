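"""Rigid-body superposition and shape descriptors for bead sets.

Superposition is least-squares optimal (Kabsch via SVD, determinant-sign
corrected so reflections are never returned — protein backbones are chiral).
For ring oligomers an additional RMSD variant minimises over the cyclic
relabelings of one ring's protomers, so that two conformers of a Cn ring
are not punished for an arbitrary choice of "first" protomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import SuperpositionError
from .structures import CoordinateSet

__all__ = [
    "RigidTransform",
    "kabsch",
    "superpose",
    "symmetry_rmsd",
    "radius_of_gyration",
    "max_dimension",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``R @ x + t``."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ np.asarray(self.rotation).T + np.asarray(
            self.translation, float
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of paired point arrays.

    Returns the transform taking ``mobile`` onto ``reference`` and the
    residual RMSD.  Raises for <3 points or collinear configurations.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point arrays must be matching (N, 3)")
    if len(P) < 3:
        raise SuperpositionError(f"need >= 3 common beads, got {len(P)}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check on either cloud
    for X in (P0, Q0):
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise SuperpositionError("degenerate (collinear) bead configuration")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def superpose(
    mobile: CoordinateSet, reference: CoordinateSet
) -> tuple[RigidTransform, float]:
    """Kabsch superposition on the (chain, residue) label intersection."""
    common = reference.common_labels(mobile)
    if len(common) < 3:
        raise SuperpositionError(
            f"only {len(common)} common labels between the two sets"
        )
    msub = mobile.subset(common)
    rsub = reference.subset(common)
    order = {lab: i for i, lab in enumerate(rsub.labels)}
    perm = np.array([order[lab] for lab in msub.labels])
    ref_positions = np.empty_like(rsub.positions)
    ref_positions[np.arange(len(perm))] = rsub.positions[perm]
    return kabsch(msub.positions, ref_positions)


def symmetry_rmsd(a: CoordinateSet, b: CoordinateSet, ring_order: int) -> float:
    """Minimum superposed RMSD over cyclic relabelings of b's protomers.

    Both sets must consist of ``ring_order`` protomers with matching bead
    counts; matching within a protomer is positional.  Only cyclic shifts
    are explored (ring topology; the rings are oriented, so no flip).
    """
    if a.n_protomers != ring_order or b.n_protomers != ring_order:
        raise ValueError(
            f"expected {ring_order} protomers, got {a.n_protomers} and {b.n_protomers}"
        )
    a_chains = list(a.protomers)
    b_chains = list(b.protomers)
    counts_a = [a.protomers[c][1] - a.protomers[c][0] for c in a_chains]
    counts_b = [b.protomers[c][1] - b.protomers[c][0] for c in b_chains]
    if counts_a != counts_b:
        raise ValueError("per-protomer bead counts differ between the two rings")
    best = np.inf
    a_pos = np.concatenate([a.protomer_positions(c) for c in a_chains])
    for shift in range(ring_order):
        b_pos = np.concatenate(
            [b.protomer_positions(b_chains[(k + shift) % ring_order]) for k in range(ring_order)]
        )
        _, rmsd = kabsch(b_pos, a_pos)
        best = min(best, rmsd)
    return float(best)


def radius_of_gyration(
    coords: CoordinateSet | np.ndarray, weights: np.ndarray | None = None
) -> float:
    """√(Σ wᵢ‖rᵢ − r̄‖² / Σ wᵢ); uniform weights by default."""
    pos = coords.positions if isinstance(coords, CoordinateSet) else np.asarray(coords, float)
    if len(pos) < 1:
        raise ValueError("need at least one bead")
    if weights is None:
        w = np.ones(len(pos))
    else:
        w = np.asarray(weights, float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    centre = np.average(pos, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((pos - centre) ** 2, axis=1), weights=w)))


def max_dimension(coords: CoordinateSet | np.ndarray) -> float:
    """Maximum pairwise distance (Dmax) of the bead cloud."""
    pos = coords.positions if isinstance(coords, CoordinateSet) else np.asarray(coords, float)
    if len(pos) < 2:
        raise ValueError("need at least two beads")
    if len(pos) > 400:
        try:  # hull vertices suffice for the diameter
            pos = pos[ConvexHull(pos).vertices]
        except Exception:
            pass
    return float(pdist(pos).max())
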