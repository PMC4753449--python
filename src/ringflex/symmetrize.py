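"""Cn-symmetrised ring models built from a single protomer.

A two-domain ring oligomer keeps an (almost) exact Cn inner ring of
oligomerisation domains (OD) while the outer domains adopt protomer-specific
hinge orientations.  A symmetrised model propagates ONE chosen protomer
around the ring: its OD Cα set is superposed in turn onto each of the n OD
positions of the template ring, and each resulting rigid transform is
applied to the protomer as a whole.  The output is an exactly Cn-symmetric
full-length model (up to the asymmetry of the template OD ring itself).

Steric plausibility is scored by counting inter-protomer Cα pairs closer
than a clash threshold (default 3.5 Å).  The count is a proxy for visual
clash inspection; rankings, not absolute counts, are the meaningful output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptySelectionError
from .geometry import RigidTransform, kabsch
from .structures import Atom, CoordinateSet, StructureModel, select_calpha

__all__ = [
    "SymmetrizedModel",
    "build_symmetrized_model",
    "clash_count",
    "enumerate_symmetrized_models",
    "ring_axis",
]

DEFAULT_OD_RANGE = (135, 204)
DEFAULT_CLASH_THRESHOLD = 3.5  # Å


@dataclass
class SymmetrizedModel:
    model: StructureModel
    source_id: str
    protomer_id: str
    order: int
    axis_point: np.ndarray
    axis_direction: np.ndarray
    clash_count: int

    @property
    def label(self) -> str:
        return f"{self.source_id}:{self.protomer_id}"


def ring_axis(od_centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis of a ring of domain centroids: mean point + normal of the
    best-fit plane (principal inertia axis of the centroid cloud)."""
    c = np.asarray(od_centroids, float)
    mean = c.mean(axis=0)
    _, _, Vt = np.linalg.svd(c - mean)
    return mean, Vt[2]  # smallest-variance direction = plane normal


def _od_calpha(model: StructureModel, chain: str, od_range: tuple[int, int]) -> CoordinateSet:
    try:
        return select_calpha(model, residue_range=od_range, chains=[chain])
    except EmptySelectionError as exc:
        raise EmptySelectionError(
            f"no OD Cα in {od_range} for chain {chain} of {model.ident}"
        ) from exc


def build_symmetrized_model(
    hexamer: StructureModel,
    protomer: str,
    od_range: tuple[int, int] = DEFAULT_OD_RANGE,
    n: int | None = None,
    template: StructureModel | None = None,
) -> SymmetrizedModel:
    """Propagate one protomer around the OD ring of a template hexamer.

    ``template`` supplies the n reference OD positions (defaults to the
    protomer's own parent).  Chain ids of the output follow the template.
    """
    template = template if template is not None else hexamer
    ring_chains = list(template.protomers)
    n = n if n is not None else len(ring_chains)
    if len(ring_chains) != n:
        raise ValueError(
            f"template has {len(ring_chains)} protomers, expected ring order {n}"
        )
    mobile_od = _od_calpha(hexamer, protomer, od_range)
    mobile_atoms = [a for a in hexamer.chain_atoms(protomer, het=False)]
    mobile_pos = np.array([a.pos for a in mobile_atoms])

    atoms: list[Atom] = []
    centroids = []
    for chain in ring_chains:
        ref_od = _od_calpha(template, chain, od_range)
        ref_nums = {r for _, r in ref_od.labels}
        mob_nums = {r for _, r in mobile_od.labels}
        shared = sorted(ref_nums & mob_nums)
        if len(shared) < 3:
            raise ValueError(
                f"fewer than 3 shared OD residues between {protomer} and {chain}"
            )
        m_idx = {r: i for i, (_, r) in enumerate(mobile_od.labels)}
        r_idx = {r: i for i, (_, r) in enumerate(ref_od.labels)}
        P = mobile_od.positions[[m_idx[r] for r in shared]]
        Q = ref_od.positions[[r_idx[r] for r in shared]]
        transform, _ = kabsch(P, Q)
        moved = transform.apply(mobile_pos)
        centroids.append(transform.apply(mobile_od.positions).mean(axis=0))
        for a, xyz in zip(mobile_atoms, moved):
            atoms.append(
                Atom(a.element, a.name, chain, a.res_num, a.res_name, tuple(map(float, xyz)))
            )
    point, direction = ring_axis(np.array(centroids))
    model = StructureModel(
        atoms=atoms,
        protomers=ring_chains,
        ident=f"{hexamer.ident}_C{n}{protomer}",
    )
    clashes = clash_count(model)
    return SymmetrizedModel(
        model=model,
        source_id=hexamer.ident,
        protomer_id=protomer,
        order=n,
        axis_point=point,
        axis_direction=direction,
        clash_count=clashes,
    )


def clash_count(
    model: StructureModel, threshold: float = DEFAULT_CLASH_THRESHOLD
) -> int:
    """Number of inter-protomer Cα pairs closer than ``threshold`` Å."""
    if len(model.protomers) < 2:
        raise ValueError("clash counting needs at least two protomers")
    coords = select_calpha(model)
    chain_of = np.array([hash(c) for c, _ in coords.labels])
    tree = cKDTree(coords.positions)
    pairs = tree.query_pairs(threshold, output_type="ndarray").reshape(-1, 2)
    if not len(pairs):
        return 0
    return int(np.sum(chain_of[pairs[:, 0]] != chain_of[pairs[:, 1]]))


def enumerate_symmetrized_models(
    structures: list[StructureModel],
    od_range: tuple[int, int] = DEFAULT_OD_RANGE,
    n: int = 6,
    template: StructureModel | None = None,
) -> list[SymmetrizedModel]:
    """One symmetrised model per protomer per structure, ranked by clash
    count (ties broken by structure id then chain id — stable under input
    reordering)."""
    models = []
    for st in structures:
        for chain in st.protomers:
            models.append(
                build_symmetrized_model(
                    st, chain, od_range=od_range, n=n, template=template
                )
            )
    models.sort(key=lambda m: (m.clash_count, m.source_id, m.protomer_id))
    return models
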