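"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from loopstate.kinetics import RateConstants
from loopstate.structures import AtomSelection

RING1 = "ABCDE"
RING2 = "FGHIJ"


def ring_selection(chains: str, first: int = 1, last: int = 24) -> AtomSelection:
    """Calpha selection covering the given chains of a synthetic ring."""
    return AtomSelection.parse(",".join(f"{c}:{first}-{last}" for c in chains))


def numeric_v0(k: RateConstants, s: float) -> float:
    """Enzyme-normalised steady-state velocity at fixed substrate, computed
    numerically from the species balance (independent of the closed-form
    steady-state algebra).

    At fixed S the occupancies solve the linear system
        0 = k1*S*(E0-ES-EP) - (k-1+k2)*ES + k-2*EP
        0 = k2*ES - (k-2+k3)*EP
    and v0 = k3*EP/E0.
    """
    e0 = 1.0
    A = np.array(
        [
            [-(k.k1 * s + k.k_minus1 + k.k2), -k.k1 * s + k.k_minus2],
            [k.k2, -(k.k_minus2 + k.k3)],
        ]
    )
    b = np.array([-k.k1 * s * e0, 0.0])
    es, ep = np.linalg.solve(A, b)
    return k.k3 * ep / e0


def random_rates(rng: np.random.Generator) -> RateConstants:
    """Valid rate constants log-uniform over 6 decades."""
    k1 = 10.0 ** rng.uniform(3, 9)
    others = 10.0 ** rng.uniform(-2, 4, size=4)
    return RateConstants(k1, others[0], others[1], others[2], others[3])


def rotation_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
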