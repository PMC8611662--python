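"""Spin-operator algebra on the composite Hilbert space of a radical trio.

A system is two or three electron spins-1/2 plus any number of nuclear spins
(I = 1/2, 1 or 3/2), each nucleus hyperfine-coupled to one electron site.
The tensor-product ordering is fixed: electrons first, in site-label order,
then nuclei in declaration order.  All operators are dense complex matrices
on the full composite space; at the dimensions relevant here (<= a few
hundred) dense algebra is both simplest and fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache, reduce

import numpy as np

__all__ = [
    "SpinSystemLayout",
    "spin_matrices",
    "spin_operators",
    "nuclear_spin_operators",
    "singlet_projector",
    "triplet_projector",
]

_ALLOWED_I = (0.5, 1.0, 1.5)


@dataclass(frozen=True)
class SpinSystemLayout:
    """Composite Hilbert-space layout of a 2- or 3-radical spin system.

    Parameters
    ----------
    electron_sites
        Ordered labels of the electron spin-1/2 sites.  Conventionally
        1 and 2 are the primary radical pair and 3 the scavenger.
    nuclei
        Ordered ``(host_site, I)`` pairs; each nucleus is attached to an
        existing electron site and has spin quantum number I in
        {1/2, 1, 3/2}.
    """

    electron_sites: tuple[int, ...]
    nuclei: tuple[tuple[int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        sites = tuple(self.electron_sites)
        nuclei = tuple((int(h), float(i)) for h, i in self.nuclei)
        object.__setattr__(self, "electron_sites", sites)
        object.__setattr__(self, "nuclei", nuclei)
        if not 2 <= len(sites) <= 3:
            raise ValueError(f"need 2 or 3 electron sites, got {len(sites)}")
        if len(set(sites)) != len(sites):
            raise ValueError(f"duplicate electron site labels: {sites}")
        for host, i_qn in nuclei:
            if host not in sites:
                raise ValueError(f"nucleus references unknown electron site {host}")
            if i_qn not in _ALLOWED_I:
                raise ValueError(f"unsupported nuclear spin I={i_qn}; allowed: {_ALLOWED_I}")

    @property
    def n_electrons(self) -> int:
        return len(self.electron_sites)

    @property
    def dims(self) -> tuple[int, ...]:
        """Multiplicity of every tensor factor, electrons first."""
        return tuple([2] * self.n_electrons + [int(round(2 * i + 1)) for _, i in self.nuclei])

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.dims))

    def electron_slot(self, site: int) -> int:
        try:
            return self.electron_sites.index(site)
        except ValueError:
            raise KeyError(
                f"unknown electron site {site!r}; layout has {self.electron_sites}"
            ) from None

    def nucleus_slot(self, index: int) -> int:
        if not 0 <= index < len(self.nuclei):
            raise KeyError(f"nucleus index {index} out of range (have {len(self.nuclei)})")
        return self.n_electrons + index


@lru_cache(maxsize=None)
def spin_matrices(multiplicity: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Sx, Sy, Sz) for a single spin of given multiplicity 2S+1.

    Built from the ladder operators; basis ordered m = S, S-1, ..., -S.
    """
    if multiplicity < 2:
        raise ValueError("multiplicity must be >= 2")
    s = (multiplicity - 1) / 2.0
    m = s - np.arange(multiplicity)
    sz = np.diag(m).astype(complex)
    # <m+1| S+ |m> = sqrt(S(S+1) - m(m+1))
    sp = np.zeros((multiplicity, multiplicity), dtype=complex)
    for k in range(1, multiplicity):
        sp[k - 1, k] = np.sqrt(s * (s + 1) - m[k] * (m[k] + 1))
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    return sx, sy, sz


def _embed(layout: SpinSystemLayout, slot: int, op: np.ndarray) -> np.ndarray:
    factors = [np.eye(d, dtype=complex) for d in layout.dims]
    factors[slot] = op
    return reduce(np.kron, factors)


def spin_operators(layout: SpinSystemLayout, site: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Electron spin operators (Sx, Sy, Sz) embedded in the full space."""
    slot = layout.electron_slot(site)
    return tuple(_embed(layout, slot, op) for op in spin_matrices(2))


def nuclear_spin_operators(layout: SpinSystemLayout, index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spin operators (Ix, Iy, Iz) of the index-th declared nucleus."""
    slot = layout.nucleus_slot(index)
    mult = layout.dims[slot]
    return tuple(_embed(layout, slot, op) for op in spin_matrices(mult))


def _check_pair(layout: SpinSystemLayout, pair: tuple[int, int]) -> tuple[int, int]:
    a, b = pair
    if a == b:
        raise ValueError(f"projector pair must be two distinct electron sites, got {pair}")
    layout.electron_slot(a)
    layout.electron_slot(b)
    return a, b


def singlet_projector(layout: SpinSystemLayout, pair: tuple[int, int]) -> np.ndarray:
    """Projector onto the singlet state of electron pair (a, b).

    Satisfies P = I/4 - S_a . S_b, hence Tr P = total_dim / 4.
    """
    a, b = _check_pair(layout, pair)
    sa = spin_operators(layout, a)
    sb = spin_operators(layout, b)
    dim = layout.total_dim
    p = 0.25 * np.eye(dim, dtype=complex)
    for ka, kb in zip(sa, sb):
        p -= ka @ kb
    return p


def triplet_projector(layout: SpinSystemLayout, pair: tuple[int, int]) -> np.ndarray:
    """Projector onto the triplet manifold of electron pair (a, b): I - P_S."""
    return np.eye(layout.total_dim, dtype=complex) - singlet_projector(layout, pair)
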