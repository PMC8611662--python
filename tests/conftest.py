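import sys
from pathlib import Path

import numpy as np
import pytest

from triospin.hamiltonian import SpinSystemSpec, TrioGeometry, HyperfineCoupling
from triospin.kinetics_yields import ReactionScheme
from triospin.spin_core import SpinSystemLayout

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def trio_layout():
    return SpinSystemLayout((1, 2, 3))


@pytest.fixture
def pair_layout():
    return SpinSystemLayout((1, 2))


def random_spin_system(rng, max_nuclei=1, n_electrons=3):
    """Small random layout + Hermitian Hamiltonian scaled near the rates."""
    n_nuc = int(rng.integers(0, max_nuclei + 1))
    nuclei = tuple((1, 0.5) for _ in range(n_nuc))
    layout = SpinSystemLayout(tuple(range(1, n_electrons + 1)), nuclei)
    dim = layout.total_dim
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    k_f = 10.0 ** rng.uniform(4, 7)
    h = (a + a.conj().T) * k_f  # couplings comparable to the rates
    k_x = k_f * 10.0 ** rng.uniform(-1.5, 1.5)
    scavenged = (int(rng.integers(1, 3)), 3) if n_electrons == 3 else (2, 3)
    if n_electrons == 3:
        scheme = ReactionScheme(k_f=k_f, k_x=k_x, scavenged_pair=scavenged)
    else:
        scheme = ReactionScheme(k_f=k_f, k_b=k_x, kind="RPM")
    return layout, h, scheme


def collinear_axial_system(separation=12.0, scavenger_height=8.0, azz=40.0):
    """Trio on the z axis, single axial hyperfine tensor along z on radical 1.

    The whole Hamiltonian is then invariant under rotations about z, so the
    yield map must be constant on circles of fixed polar angle.
    """
    geometry = TrioGeometry({
        1: np.array([0.0, 0.0, 0.0]),
        2: np.array([0.0, 0.0, separation]),
        3: np.array([0.0, 0.0, -scavenger_height]),
    })
    hf = HyperfineCoupling(1, 0.5, np.diag([0.0, 0.0, azz]), label="axial")
    return SpinSystemSpec(geometry=geometry, hyperfines=(hf,))


def zero_coupling_trio(separation_scale=1e5):
    """Trio with no nuclei and EED suppressed by enormous separations."""
    geometry = TrioGeometry({
        1: np.array([0.0, 0.0, 0.0]),
        2: np.array([separation_scale, 0.0, 0.0]),
        3: np.array([0.0, separation_scale, 0.0]),
    })
    return SpinSystemSpec(geometry=geometry)
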