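"""Macromolecular coordinate I/O and Cα bead selection.

The two working containers are :class:`StructureModel` — a thin, fully
in-memory image of a (multi-chain) PDB entry — and :class:`CoordinateSet`,
the ordered, labelled Cα bead cloud that every geometric and elastic-network
operation downstream consumes.  Residue numbering is taken verbatim from the
source file (1-based author numbering); residues absent from the model are
omitted, never imputed, and paired operations work on label intersections.

PDB parsing and writing go through gemmi; alternate locations are resolved
to the first conformer and zero-occupancy atoms are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptySelectionError, ParseError

__all__ = [
    "Atom",
    "StructureModel",
    "CoordinateSet",
    "read_structure",
    "write_structure",
    "select_calpha",
    "coordinates_to_model",
]


@dataclass(frozen=True)
class Atom:
    element: str
    name: str
    chain_id: str
    res_num: int
    res_name: str
    pos: tuple[float, float, float]
    het: bool = False


@dataclass
class StructureModel:
    """All ATOM/HETATM records of one model, plus the protomer chain order."""

    atoms: list[Atom]
    protomers: list[str]
    ident: str = ""

    def __post_init__(self) -> None:
        if not self.protomers:
            raise ValueError("protomer chain list must be non-empty")
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            if not all(np.isfinite(a.pos)):
                raise ValueError(f"non-finite position for atom {a}")
            key = (a.chain_id, a.res_num, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def chain_atoms(self, chain_id: str, het: bool | None = False) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and (het is None or a.het == het)
        ]

    def residue_numbers(self, chain_id: str) -> list[int]:
        return sorted({a.res_num for a in self.chain_atoms(chain_id)})


@dataclass
class CoordinateSet:
    """Ordered Cα (or generic bead) positions with (chain, residue) labels.

    ``protomers`` maps each chain id to the half-open index range of its
    beads; the ranges partition ``[0, N)`` in chain order.
    """

    positions: np.ndarray  # (N, 3) Å
    labels: list[tuple[str, int]]
    protomers: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions disagree in length")
        if not self.protomers:
            # single implicit protomer per chain id, in order of appearance
            self.protomers = {}
            start = 0
            for i, (chain, _) in enumerate(self.labels):
                if i + 1 == len(self.labels) or self.labels[i + 1][0] != chain:
                    self.protomers[chain] = (start, i + 1)
                    start = i + 1
        cursor = 0
        for chain, (lo, hi) in self.protomers.items():
            if lo != cursor or hi <= lo:
                raise ValueError("protomer ranges must partition [0, N)")
            nums = [r for c, r in self.labels[lo:hi]]
            if any(c != chain for c, _ in self.labels[lo:hi]):
                raise ValueError(f"labels in range of {chain} carry other chains")
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(f"residue numbers not increasing in chain {chain}")
            cursor = hi
        if cursor != len(self.labels):
            raise ValueError("protomer ranges must cover all beads")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_protomers(self) -> int:
        return len(self.protomers)

    def protomer_positions(self, chain_id: str) -> np.ndarray:
        lo, hi = self.protomers[chain_id]
        return self.positions[lo:hi]

    def subset(self, labels: Sequence[tuple[str, int]]) -> "CoordinateSet":
        """Beads with the given labels, kept in this set's own order."""
        want = set(labels)
        idx = [i for i, lab in enumerate(self.labels) if lab in want]
        if not idx:
            raise EmptySelectionError("subset selection matched no beads")
        new_labels = [self.labels[i] for i in idx]
        protomers: dict[str, tuple[int, int]] = {}
        start = 0
        for k, (chain, _) in enumerate(new_labels):
            if k + 1 == len(new_labels) or new_labels[k + 1][0] != chain:
                protomers[chain] = (start, k + 1)
                start = k + 1
        return CoordinateSet(self.positions[idx], new_labels, protomers)

    def with_positions(self, positions: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            np.asarray(positions, float), list(self.labels), dict(self.protomers)
        )

    def common_labels(self, other: "CoordinateSet") -> list[tuple[str, int]]:
        mine = set(self.labels)
        return [lab for lab in other.labels if lab in mine]


_WATER = {"HOH", "WAT", "DOD"}


def read_structure(path: str | Path, expand_assembly: bool = False) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations collapse to the first conformer, zero-occupancy
    atoms are dropped, chains keep file order.  HETATM records (ions,
    waters, ligands) are retained on the model but flagged, and are never
    selected into a :class:`CoordinateSet`.

    ``expand_assembly`` applies the file's first biological-assembly
    (BIOMT) definition, so that e.g. a half-ring asymmetric unit becomes
    the full oligomer; copied chains get numeric suffixes.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ParseError(f"no models in {path}")
    model = st[0]
    if expand_assembly and len(st.assemblies) > 0:
        model = gemmi.make_assembly(
            st.assemblies[0], model, gemmi.HowToNameCopiedChain.AddNumber
        )
    atoms: list[Atom] = []
    protomers: list[str] = []
    for chain in model:
        has_polymer = False
        for res in chain:
            het = res.het_flag == "H" or res.name in _WATER
            for at in res:
                if at.occ <= 0:
                    continue
                atoms.append(
                    Atom(
                        element=at.element.name,
                        name=at.name,
                        chain_id=chain.name,
                        res_num=res.seqid.num,
                        res_name=res.name,
                        pos=(at.pos.x, at.pos.y, at.pos.z),
                        het=het,
                    )
                )
                if not het:
                    has_polymer = True
        if has_polymer and chain.name not in protomers:
            protomers.append(chain.name)
    if not atoms:
        raise ParseError(f"no ATOM records in {path}")
    if not protomers:
        raise ParseError(f"no polymer (non-HETATM) chains in {path}")
    return StructureModel(atoms=atoms, protomers=protomers, ident=path.stem)


def write_structure(
    model: StructureModel | Iterable[StructureModel], path: str | Path
) -> None:
    """Write one StructureModel, or several as consecutive MODEL blocks."""
    models = [model] if isinstance(model, StructureModel) else list(model)
    st = gemmi.Structure()
    st.name = models[0].ident or "ringflex"
    for k, m in enumerate(models, start=1):
        gm = gemmi.Model(k)
        by_chain: dict[str, list[Atom]] = {}
        for a in m.atoms:
            by_chain.setdefault(a.chain_id, []).append(a)
        for chain_id, chain_atoms in by_chain.items():
            gc = gemmi.Chain(chain_id)
            current: gemmi.Residue | None = None
            for a in chain_atoms:
                if (
                    current is None
                    or current.seqid.num != a.res_num
                    or current.name != a.res_name
                ):
                    current = gemmi.Residue()
                    current.name = a.res_name
                    current.seqid = gemmi.SeqId(a.res_num, " ")
                    current.het_flag = "H" if a.het else "A"
                    gc.add_residue(current)
                    current = gc[-1]
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = 1.0
                current.add_atom(ga)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


def select_calpha(
    model: StructureModel,
    residue_range: tuple[int, int] | None = None,
    chains: Sequence[str] | None = None,
) -> CoordinateSet:
    """Cα beads within an inclusive residue range, ordered by chain then residue.

    Residues missing from the model are simply absent from the output; no
    imputation is attempted.
    """
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"empty residue range {residue_range}")
    chain_order = list(chains) if chains is not None else list(model.protomers)
    positions: list[tuple[float, float, float]] = []
    labels: list[tuple[str, int]] = []
    protomers: dict[str, tuple[int, int]] = {}
    for chain in chain_order:
        start = len(labels)
        cas = [
            a
            for a in model.chain_atoms(chain)
            if a.name == "CA"
            and (
                residue_range is None
                or residue_range[0] <= a.res_num <= residue_range[1]
            )
        ]
        cas.sort(key=lambda a: a.res_num)
        for a in cas:
            positions.append(a.pos)
            labels.append((chain, a.res_num))
        if len(labels) > start:
            protomers[chain] = (start, len(labels))
    if not labels:
        raise EmptySelectionError(
            f"no CA atoms in range {residue_range} for chains {chain_order}"
        )
    return CoordinateSet(np.array(positions, float), labels, protomers)


def coordinates_to_model(
    coords: CoordinateSet, ident: str = "beads", res_name: str = "ALA"
) -> StructureModel:
    """Promote a bead set to a Cα-only StructureModel (for writing to PDB)."""
    atoms = [
        Atom("C", "CA", chain, num, res_name, tuple(map(float, xyz)))
        for (chain, num), xyz in zip(coords.labels, coords.positions)
    ]
    return StructureModel(atoms=atoms, protomers=list(coords.protomers), ident=ident)
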