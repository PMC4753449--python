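"""Conformational-transition vectors and their overlap with normal modes.

A transition vector T is the unit-normalised 3N displacement from one
conformer to another, taken after rigid superposition (so no rigid-body
component survives) on the label intersection of the two bead sets.

The cumulative overlap of T with the first j normal modes is the sum of
SQUARED projections

    dot_j = Σ_{i=1..j} (v_i · T)²  ∈ [0, 1],

the fraction of the transition's variance captured by the j-mode essential
subspace.  Under a null of uniformly random unit T in dof dimensions the
expectation of dot_j is exactly j/dof, which makes excess overlap easy to
standardise as a Z-score against a seeded Monte-Carlo null.

Convention note: ``dof`` is taken as 3N.  With N = 1206 beads this gives
chance levels 2/3618 ≈ 0.00055, 5/3618 ≈ 0.0014, 10/3618 ≈ 0.0028;
3N−6 is indistinguishable at two significant figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTransitionError
from .enm import ModeSet
from .geometry import superpose
from .structures import CoordinateSet

__all__ = [
    "TransitionVector",
    "OverlapResult",
    "transition_vector",
    "cumulative_overlap",
    "chance_overlap",
    "overlap_zscore",
    "transition_dot",
    "linear_morph",
]

DEGENERATE_NORM = 1e-6  # Å: below this the conformers are "the same"


@dataclass
class TransitionVector:
    t: np.ndarray  # (3N,), unit norm
    start_id: str
    end_id: str
    labels: list[tuple[str, int]]  # label intersection actually used
    frame: str = ""  # conformer whose frame T lives in (= start)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if not np.isclose(np.linalg.norm(self.t), 1.0, atol=1e-9):
            raise ValueError("transition vector must be unit norm")
        if not self.frame:
            self.frame = self.start_id

    @property
    def dof(self) -> int:
        return self.t.size


@dataclass
class OverlapResult:
    j: int
    dot_j: float
    chance: float
    zscore: float | None = None
    n_random: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.dot_j <= 1.0 + 1e-9):
            raise ValueError("cumulative overlap must lie in [0, 1]")


def transition_vector(
    start: CoordinateSet,
    end: CoordinateSet,
    start_id: str = "start",
    end_id: str = "end",
) -> TransitionVector:
    """Unit displacement start→end after superposing end onto start."""
    common = start.common_labels(end)
    transform, _ = superpose(end, start)  # maps end into start's frame
    s_sub = start.subset(common)
    e_sub = end.subset(common)
    order = {lab: i for i, lab in enumerate(e_sub.labels)}
    e_pos = transform.apply(e_sub.positions)[[order[lab] for lab in s_sub.labels]]
    disp = (e_pos - s_sub.positions).ravel()
    norm = np.linalg.norm(disp)
    if norm <= DEGENERATE_NORM:
        raise DegenerateTransitionError(
            f"{start_id} and {end_id} coincide after superposition "
            f"(|displacement| = {norm:.2e} Å)"
        )
    return TransitionVector(disp / norm, start_id, end_id, list(s_sub.labels))


def cumulative_overlap(modes: ModeSet, T: TransitionVector | np.ndarray, j: int) -> float:
    """Σ_{i≤j} (v_i · T)² — fraction of T inside the first-j-mode subspace."""
    t = T.t if isinstance(T, TransitionVector) else np.asarray(T, float)
    if t.size != modes.dof:
        raise ValueError(f"dimension mismatch: T has {t.size}, modes {modes.dof}")
    if not (1 <= j <= modes.n_modes):
        raise ValueError(f"j={j} outside available modes (1..{modes.n_modes})")
    proj = modes.eigenvectors[:, :j].T @ t
    return float(np.sum(proj**2))


def chance_overlap(dof: int, j: int) -> float:
    """Expected dot_j for a uniformly random unit vector: exactly j/dof."""
    if not (1 <= j <= dof):
        raise ValueError(f"need 1 <= j <= dof, got j={j}, dof={dof}")
    return j / dof


def _random_unit_vectors(n: int, dof: int, rng: np.random.Generator) -> np.ndarray:
    g = rng.standard_normal((n, dof))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def overlap_zscore(
    modes: ModeSet,
    T: TransitionVector | np.ndarray,
    j: int,
    n_random: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """Standardised excess of dot_j over a random-unit-vector null.

    The null draws ``n_random`` uniformly random unit vectors (normalised
    Gaussians) in dof dimensions and computes their dot_j against the same
    modes; Z = (observed − null mean) / null sd.  Reproducible given seed.
    """
    if n_random < 100:
        raise ValueError("n_random must be at least 100")
    observed = cumulative_overlap(modes, T, j)
    rng = np.random.default_rng(seed)
    V = modes.eigenvectors[:, :j]
    # project in manageable batches to bound memory at large dof
    null = np.empty(n_random)
    batch = max(1, int(5e7 // max(modes.dof, 1)))
    done = 0
    while done < n_random:
        m = min(batch, n_random - done)
        U = _random_unit_vectors(m, modes.dof, rng)
        null[done : done + m] = np.sum((U @ V) ** 2, axis=1)
        done += m
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("null distribution has zero variance")
    z = (observed - float(null.mean())) / sd
    return OverlapResult(
        j=j,
        dot_j=observed,
        chance=chance_overlap(modes.dof, j),
        zscore=float(z),
        n_random=n_random,
        seed=seed,
    )


def transition_vector_in_frame(
    start: CoordinateSet,
    end: CoordinateSet,
    frame_coords: CoordinateSet,
    start_id: str = "start",
    end_id: str = "end",
    frame_id: str = "frame",
) -> TransitionVector:
    """Transition vector expressed in a third conformer's frame.

    Both endpoints are superposed onto ``frame_coords`` (on the triple
    label intersection) before differencing; use this to compare two
    transitions that share a conformer, e.g. T(a→b)·T(b→c) in b's frame.
    """
    common = [
        lab
        for lab in start.common_labels(end)
        if lab in set(frame_coords.labels)
    ]
    s_sub, e_sub = start.subset(common), end.subset(common)
    f_sub = frame_coords.subset(common)
    ts, _ = superpose(s_sub, f_sub)
    te, _ = superpose(e_sub, f_sub)
    order_s = {lab: i for i, lab in enumerate(s_sub.labels)}
    order_e = {lab: i for i, lab in enumerate(e_sub.labels)}
    idx_s = [order_s[lab] for lab in f_sub.labels]
    idx_e = [order_e[lab] for lab in f_sub.labels]
    disp = (
        te.apply(e_sub.positions)[idx_e] - ts.apply(s_sub.positions)[idx_s]
    ).ravel()
    norm = np.linalg.norm(disp)
    if norm <= DEGENERATE_NORM:
        raise DegenerateTransitionError(
            f"{start_id} and {end_id} coincide after superposition"
        )
    return TransitionVector(
        disp / norm, start_id, end_id, list(f_sub.labels), frame=frame_id
    )


def transition_dot(T1: TransitionVector, T2: TransitionVector) -> float:
    """Plain dot product of two transition vectors sharing labels and frame."""
    if T1.labels != T2.labels:
        raise ValueError("transition vectors are built on different label sets")
    if T1.frame != T2.frame:
        raise ValueError(
            f"transition vectors live in different frames ({T1.frame} vs {T2.frame})"
        )
    return float(np.dot(T1.t, T2.t))


def linear_morph(
    start: CoordinateSet, end: CoordinateSet, n_frames: int
) -> list[CoordinateSet]:
    """Straight-line interpolation between superposed conformers."""
    if n_frames < 2:
        raise ValueError("need at least two frames")
    common = start.common_labels(end)
    transform, _ = superpose(end, start)
    s_sub = start.subset(common)
    e_sub = end.subset(common)
    order = {lab: i for i, lab in enumerate(e_sub.labels)}
    e_pos = transform.apply(e_sub.positions)[[order[lab] for lab in s_sub.labels]]
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1)
        frames.append(s_sub.with_positions((1 - f) * s_sub.positions + f * e_pos))
    return frames
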