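"""Shared fixtures: small toy rings, their modes, and a sphere bead cloud.

Everything is generated programmatically (no stored data); session scope
keeps the eigendecompositions from being repeated across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import ringflex as rf

SMALL = dict(inner_beads=20, outer_beads=30)  # 300-bead hexamer, fast NMA
MEDIUM = dict(inner_beads=30, outer_beads=45)  # 450 beads, SAXS-scale


@pytest.fixture(scope="session")
def ring_c6() -> rf.CoordinateSet:
    """Closed ring: all hinge angles zero — exact C6 symmetry."""
    return rf.toy_calpha(rf.ToyRingSpec(**SMALL))


@pytest.fixture(scope="session")
def ring_c2_like() -> rf.CoordinateSet:
    """Two opposite outer domains rotated — period-3 pattern, C2 symmetry."""
    return rf.toy_calpha(rf.ToyRingSpec(**SMALL, angles_deg=(0, 0, 55, 0, 0, 55)))


@pytest.fixture(scope="session")
def ring_c3_like() -> rf.CoordinateSet:
    """Alternating outer domains rotated — period-2 pattern, C3 symmetry."""
    return rf.toy_calpha(rf.ToyRingSpec(**SMALL, angles_deg=(0, 100, 0, 100, 0, 100)))


@pytest.fixture(scope="session")
def modes_c6(ring_c6: rf.CoordinateSet) -> rf.ModeSet:
    return rf.anm_modes(ring_c6, n_modes=12)


@pytest.fixture(scope="session")
def sphere_cloud() -> tuple[np.ndarray, float]:
    """Deterministic quasi-uniform bead filling of a 30 Å sphere.

    Equal-volume radial shells, Fibonacci angular points de-phased per
    shell; ~6000 beads.  Returned with the sphere radius.
    """
    return _ball_beads(30.0, n_shells=40, per_shell=150), 30.0


def _ball_beads(radius: float, n_shells: int, per_shell: int) -> np.ndarray:
    pts = []
    golden = np.pi * (3 - np.sqrt(5))
    for k in range(n_shells):
        r = radius * (((k + 0.5) / n_shells) ** (1 / 3))
        i = np.arange(per_shell)
        z = 1 - 2 * (i + 0.5) / per_shell
        rho = np.sqrt(1 - z**2)
        th = golden * i + k * 0.7
        pts.append(np.column_stack([r * rho * np.cos(th), r * rho * np.sin(th), r * z]))
    return np.concatenate(pts)
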