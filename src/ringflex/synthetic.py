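"""Synthetic two-domain ring oligomers, conformer pools, and noisy curves.

The toy emulates the architecture of a hexameric replication initiator:
each protomer is an N-terminal outer domain (OBD-like) joined through a
hinge to a C-terminal inner domain (OD-like); the inner domains form an
exactly Cn-symmetric ring while each outer domain is rigidly rotated about
its own hinge axis, tilted (default 45°) to the ring axis.  Per-protomer
hinge angles select the overall symmetry class:

    equal angles             → Cn
    period-2 pattern a,b,... → C3-like (for n = 6)
    period-3 pattern a,a,b.. → C2-like (for n = 6)

Domains are compact helix bundles of Cα-like beads with ~3.8 Å virtual
bonding, sized and spaced so the assembly stays a single connected elastic
network at the default 13 Å ANM cutoff.  Residue numbering runs outer
domain first (1..n_outer) then inner domain — the biological N→C order.

Conformer pools stand in for MD snapshots: frames are drawn by displacing
the reference along normal modes with independent Gaussian amplitudes.
Noisy scattering curves apply relative Gaussian noise with an s-dependent
error inflation, mimicking counting statistics at higher angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enm import ModeSet
from .structures import Atom, CoordinateSet, StructureModel
from .saxs import ScatteringProfile

__all__ = [
    "ToyRingSpec",
    "NoiseModel",
    "make_toy_ring",
    "toy_calpha",
    "perturb_along_modes",
    "simulate_sas_curve",
]

_CHAINS = "ABCDEFGHIJKLMNOP"


@dataclass
class ToyRingSpec:
    n: int = 6
    inner_beads: int = 40  # OD-like domain
    outer_beads: int = 60  # OBD-like domain
    ring_radius: float = 14.0  # Å, OD centroid distance from the axis
    hinge_tilt_deg: float = 45.0  # hinge axis tilt relative to the ring axis
    angles_deg: tuple[float, ...] | list[float] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("ring order must be at least 2")
        if min(self.inner_beads, self.outer_beads) < 3:
            raise ValueError("domains need at least 3 beads")
        if not self.angles_deg:
            self.angles_deg = tuple(0.0 for _ in range(self.n))
        if len(self.angles_deg) != self.n:
            raise ValueError("need one hinge angle per protomer")

    @property
    def beads_per_protomer(self) -> int:
        return self.inner_beads + self.outer_beads

    @property
    def hinge_residue(self) -> int:
        """First inner-domain residue; the hinge pivot sits on its bead."""
        return self.outer_beads + 1


def _helix_bundle(n_beads: int, n_helices: int) -> np.ndarray:
    """Connected chain of Cα-like beads folded into an antiparallel bundle.

    Ideal α-helix geometry (2.3 Å radius, 1.5 Å rise, 100°/residue) gives
    ~3.8 Å consecutive-bead spacing; helices alternate direction on a 5 Å
    grid so the chain stays covalently plausible at the turns.
    """
    per = int(np.ceil(n_beads / n_helices))
    pts = []
    k = 0
    for h in range(n_helices):
        m = min(per, n_beads - k)
        t = np.arange(m)
        z = 1.5 * t if h % 2 == 0 else 1.5 * (per - 1) - 1.5 * t
        ang = np.deg2rad(100.0) * t
        x = h * 5.0 + 2.3 * np.cos(ang)
        y = 2.3 * np.sin(ang)
        pts.append(np.column_stack([x, y, z]))
        k += m
        if k >= n_beads:
            break
    return np.concatenate(pts)[:n_beads]


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _protomer_template(spec: ToyRingSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One protomer at ring position 0: (positions, hinge point, hinge axis).

    Inner domain (2-helix bundle) centred at radius R with its bundle axis
    along the ring axis z; outer domain (3-helix bundle) attached radially
    outward at the inner domain's top, chain order outer→inner.
    """
    inner = _helix_bundle(spec.inner_beads, 2)
    inner -= inner.mean(axis=0)
    inner += np.array([spec.ring_radius, 0.0, 0.0])
    hinge_point = inner[0]  # first inner bead = residue outer_beads + 1

    outer = _helix_bundle(spec.outer_beads, 3)
    # re-express so the chain END (residue outer_beads) sits at the origin,
    # then point the bundle outward along +x and up a little
    outer = outer - outer[-1]
    tilt = _rotation(np.array([0.0, 1.0, 0.0]), np.deg2rad(-60.0))
    outer = outer @ tilt.T
    attach = hinge_point + np.array([3.8, 0.0, 1.0]) - np.array([0.0, 0.0, 0.0])
    outer = outer + attach

    radial = np.array([1.0, 0.0, 0.0])
    zaxis = np.array([0.0, 0.0, 1.0])
    tiltr = np.deg2rad(spec.hinge_tilt_deg)
    hinge_axis = np.cos(tiltr) * zaxis + np.sin(tiltr) * radial
    return np.concatenate([outer, inner]), hinge_point, hinge_axis


def make_toy_ring(spec: ToyRingSpec) -> StructureModel:
    """Assemble the ring: hinge-rotate each protomer's outer domain, then
    place the protomer at its Cn position.  Equal hinge angles give an
    exactly Cn-symmetric model."""
    template, hinge_point, hinge_axis = _protomer_template(spec)
    n_out = spec.outer_beads
    atoms: list[Atom] = []
    clash_warned = False
    placed: list[np.ndarray] = []
    for k in range(spec.n):
        pos = template.copy()
        Rh = _rotation(hinge_axis, np.deg2rad(spec.angles_deg[k]))
        pos[:n_out] = (pos[:n_out] - hinge_point) @ Rh.T + hinge_point
        Rz = _rotation(np.array([0.0, 0.0, 1.0]), 2 * np.pi * k / spec.n)
        pos = pos @ Rz.T
        placed.append(pos)
        chain = _CHAINS[k]
        for i, xyz in enumerate(pos):
            atoms.append(
                Atom("C", "CA", chain, i + 1, "ALA", tuple(map(float, xyz)))
            )
    model = StructureModel(
        atoms=atoms, protomers=[_CHAINS[k] for k in range(spec.n)], ident="toy_ring"
    )
    return model


def toy_calpha(spec: ToyRingSpec) -> CoordinateSet:
    """Shortcut: build the ring and return its full Cα bead set."""
    from .structures import select_calpha

    return select_calpha(make_toy_ring(spec))


def perturb_along_modes(
    coords: CoordinateSet,
    modes: ModeSet,
    amplitudes: np.ndarray | list[float],
    n_frames: int,
    seed: int = 0,
) -> list[CoordinateSet]:
    """Gaussian mode-space conformer pool (MD-snapshot stand-in).

    Frame = coords + Σ_i a_i·g_i·v_i with g_i ~ N(0, 1) i.i.d. per frame,
    so the ensemble RMS displacement along mode i equals a_i·‖v_i‖ = a_i.
    """
    amps = np.asarray(amplitudes, float)
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    if len(amps) > modes.n_modes:
        raise ValueError("more amplitudes than available modes")
    if modes.dof != 3 * len(coords):
        raise ValueError("modes and coordinates disagree in dimension")
    rng = np.random.default_rng(seed)
    V = modes.eigenvectors[:, : len(amps)]
    frames = []
    for _ in range(n_frames):
        g = rng.standard_normal(len(amps))
        disp = (V @ (amps * g)).reshape(-1, 3)
        frames.append(coords.with_positions(coords.positions + disp))
    return frames


@dataclass
class NoiseModel:
    rel_floor: float = 0.01  # relative error at low angle
    s_inflation: float = 2.0  # extra relative error at the top of the s range
    seed: int = 0

    def sigma_rel(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        top = s[-1] if s[-1] > 0 else 1.0
        out = self.rel_floor * (1.0 + self.s_inflation * (s / top) ** 2)
        return out


def simulate_sas_curve(
    true_profile: ScatteringProfile, noise: NoiseModel | None = None
) -> ScatteringProfile:
    """Noisy synthetic measurement: I_obs = I_true·(1 + ε), ε ~ N(0, σ_rel),
    with the σ column set to I_true·σ_rel.  Seeded via the noise model."""
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    srel = noise.sigma_rel(true_profile.s)
    eps = rng.standard_normal(len(true_profile)) * srel
    sigma = np.abs(true_profile.intensity) * srel
    sigma = np.maximum(sigma, 1e-12 * np.max(np.abs(true_profile.intensity)))
    return ScatteringProfile(
        true_profile.s,
        true_profile.intensity * (1.0 + eps),
        sigma,
        unit=true_profile.unit,
    )
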