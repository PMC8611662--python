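"""Assembly of the spin Hamiltonian H = H_Zee + H_EED + H_hf + H_ex.

Radical positions are point dipoles (angstroms).  The electron-electron
dipolar (EED) tensor for a pair at separation r is the traceless symmetric

    T(r) = d(r) (1 - 3 rhat rhat^T),   d(r) = (mu0/4pi) g_a g_b mu_B^2 / (h r^3)

in frequency units, with coupling Hamiltonian S_a . T . S_b.  The
conventional zero-field-splitting parameter |D| = (3/2) d(r) is exposed as a
diagnostic: at a pair separation of 18 A (the distal tryptophan distance in
cryptochrome) it evaluates to ~14 MHz, the scale that competes with the
~1.4 MHz electron Larmor frequency in the geomagnetic field (50 uT).

Hyperfine terms are S_i . A_ik . I_k with 3x3 tensors in MHz; the exchange
term uses the convention H_ex = -J_ab (2 S_a . S_b + 1/2).  The nuclear
Zeeman interaction is omitted (three orders of magnitude below the electron
Zeeman term at 50 uT).  All assembled operators are in rad s^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    G_ELECTRON,
    H_PLANCK,
    HBAR,
    M_PER_ANGSTROM,
    MU_0,
    MU_B,
    RAD_PER_MHZ,
    mt_to_mhz,
)
from .spin_core import (
    SpinSystemLayout,
    nuclear_spin_operators,
    spin_operators,
)

__all__ = [
    "FieldSpec",
    "TrioGeometry",
    "HyperfineCoupling",
    "ExchangeSpec",
    "GTensorSpec",
    "SpinSystemSpec",
    "zeeman_term",
    "zeeman_generators",
    "eed_tensor",
    "eed_d_parameter",
    "assemble_hamiltonian",
]


@dataclass(frozen=True)
class FieldSpec:
    """Static magnetic field: flux density (tesla) and unit direction."""

    b0: float = 50e-6
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    strict: bool = False

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError("B0 must be >= 0")
        n = np.asarray(self.orientation, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm == 0.0:
            raise ValueError("field orientation must be a nonzero vector")
        if abs(norm - 1.0) > 1e-9:
            if self.strict:
                raise ValueError(f"field orientation not unit length (|n|={norm:.6g})")
            warnings.warn("normalizing non-unit field orientation", stacklevel=2)
        object.__setattr__(self, "orientation", tuple(n / norm))

    @property
    def vector(self) -> np.ndarray:
        return self.b0 * np.asarray(self.orientation)


@dataclass(frozen=True)
class TrioGeometry:
    """Point-dipole positions (angstrom) of the radical electrons, by site."""

    positions: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        pos = {int(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.positions.items()}
        object.__setattr__(self, "positions", pos)
        labels = sorted(pos)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if np.linalg.norm(pos[a] - pos[b]) <= 0.0:
                    raise ValueError(f"sites {a} and {b} are coincident")

    def separation(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.positions[a] - self.positions[b]))

    def vector(self, a: int, b: int) -> np.ndarray:
        """Displacement from site a to site b (angstrom)."""
        return self.positions[b] - self.positions[a]

    def pairs(self) -> list[tuple[int, int]]:
        labels = sorted(self.positions)
        return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]


@dataclass(frozen=True)
class HyperfineCoupling:
    """One nucleus: host electron site, spin I, 3x3 tensor (MHz)."""

    host_site: int
    spin: float
    tensor_mhz: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor_mhz, dtype=float)
        if t.shape != (3, 3):
            raise ValueError(
                f"hyperfine tensor for nucleus {self.label or self.host_site} "
                f"must be 3x3, got {t.shape}"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("hyperfine tensor entries must be finite")
        object.__setattr__(self, "tensor_mhz", t)

    @classmethod
    def from_mt(cls, host_site: int, spin: float, tensor_mt, label: str = "") -> "HyperfineCoupling":
        return cls(host_site, spin, mt_to_mhz(1.0) * np.asarray(tensor_mt, float), label)


@dataclass(frozen=True)
class ExchangeSpec:
    """Scalar exchange coupling J_ab (MHz) per electron pair; default 0.

    Electronic exchange beyond ~1 nm is negligible for these systems, hence
    the zero default; the sign convention H_ex = -J(2 S_a.S_b + 1/2) is fixed
    so that user-set J values are reproducible.
    """

    j_mhz: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), v in self.j_mhz.items():
            key = (min(a, b), max(a, b))
            if key in canon and canon[key] != float(v):
                raise ValueError(f"conflicting J values for pair {key}")
            canon[key] = float(v)
        object.__setattr__(self, "j_mhz", canon)

    def get(self, a: int, b: int) -> float:
        return self.j_mhz.get((min(a, b), max(a, b)), 0.0)


@dataclass(frozen=True)
class GTensorSpec:
    """Isotropic g-value per electron site (default free-electron-like)."""

    g: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, val in self.g.items():
            if val <= 0:
                raise ValueError(f"g-value for site {site} must be positive")

    def get(self, site: int) -> float:
        return self.g.get(site, G_ELECTRON)


def zeeman_term(layout: SpinSystemLayout, fieldspec: FieldSpec, g: GTensorSpec | None = None) -> np.ndarray:
    """Electron Zeeman Hamiltonian sum_i (g_i mu_B / hbar) B . S_i (rad/s)."""
    g = g or GTensorSpec()
    b_vec = fieldspec.vector
    dim = layout.total_dim
    h = np.zeros((dim, dim), dtype=complex)
    for site in layout.electron_sites:
        omega = g.get(site) * MU_B / HBAR
        sx, sy, sz = spin_operators(layout, site)
        h += omega * (b_vec[0] * sx + b_vec[1] * sy + b_vec[2] * sz)
    return h


def zeeman_generators(layout: SpinSystemLayout, b0: float, g: GTensorSpec | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Gx, Gy, Gz) with H_Zee(n) = n . G for unit field direction n.

    Precomputing these makes orientation scans cheap: only the Zeeman term
    changes between field directions.
    """
    g = g or GTensorSpec()
    dim = layout.total_dim
    gens = [np.zeros((dim, dim), dtype=complex) for _ in range(3)]
    for site in layout.electron_sites:
        omega = g.get(site) * MU_B * b0 / HBAR
        for gen, s in zip(gens, spin_operators(layout, site)):
            gen += omega * s
    return tuple(gens)


def eed_tensor(r_vec: np.ndarray, g_a: float = G_ELECTRON, g_b: float = G_ELECTRON) -> np.ndarray:
    """Point-dipole coupling tensor (MHz) for separation vector r_vec (angstrom).

    T = d(r) (1 - 3 rhat rhat^T), traceless and symmetric; the pair coupling
    Hamiltonian is S_a . T . S_b.
    """
    r_vec = np.asarray(r_vec, dtype=float).reshape(3)
    r = float(np.linalg.norm(r_vec))
    if r <= 0.0:
        raise ValueError("coincident dipoles: EED tensor undefined at zero separation")
    rhat = r_vec / r
    d_hz = (MU_0 / (4.0 * np.pi)) * g_a * g_b * MU_B**2 / (H_PLANCK * (r * M_PER_ANGSTROM) ** 3)
    return (d_hz / 1e6) * (np.eye(3) - 3.0 * np.outer(rhat, rhat))


def eed_d_parameter(r: float, g_a: float = G_ELECTRON, g_b: float = G_ELECTRON) -> float:
    """Conventional |D| = (3/2) d(r) in MHz at separation r (angstrom)."""
    d_hz = (MU_0 / (4.0 * np.pi)) * g_a * g_b * MU_B**2 / (H_PLANCK * (r * M_PER_ANGSTROM) ** 3)
    return 1.5 * d_hz / 1e6


def _pair_coupling(layout, a, b, tensor_mhz) -> np.ndarray:
    sa = spin_operators(layout, a)
    sb = spin_operators(layout, b)
    dim = layout.total_dim
    h = np.zeros((dim, dim), dtype=complex)
    for i in range(3):
        for j in range(3):
            if tensor_mhz[i, j] != 0.0:
                h += (tensor_mhz[i, j] * RAD_PER_MHZ) * (sa[i] @ sb[j])
    return h


def assemble_hamiltonian(
    layout: SpinSystemLayout,
    geometry: TrioGeometry | None,
    fieldspec: FieldSpec,
    hyperfines: list[HyperfineCoupling] = (),
    exchange: ExchangeSpec | None = None,
    g: GTensorSpec | None = None,
) -> np.ndarray:
    """Full spin Hamiltonian H = H_Zee + H_EED + H_hf + H_ex in rad s^-1.

    The EED term includes every electron pair present in the geometry;
    passing ``geometry=None`` omits dipolar coupling entirely.
    """
    g = g or GTensorSpec()
    exchange = exchange or ExchangeSpec()
    h = zeeman_term(layout, fieldspec, g)

    if geometry is not None:
        missing = [s for s in layout.electron_sites if s not in geometry.positions]
        if missing:
            raise ValueError(f"geometry lacks positions for electron sites {missing}")
        for a, b in geometry.pairs():
            if a not in layout.electron_sites or b not in layout.electron_sites:
                continue
            t = eed_tensor(geometry.vector(a, b), g.get(a), g.get(b))
            h += _pair_coupling(layout, a, b, t)

    nuclei = list(layout.nuclei)
    hyperfines = list(hyperfines)
    if len(hyperfines) != len(nuclei):
        raise ValueError(
            f"{len(hyperfines)} hyperfine tensors supplied for {len(nuclei)} declared nuclei"
        )
    for k, hf in enumerate(hyperfines):
        host, i_qn = nuclei[k]
        if hf.host_site != host or float(hf.spin) != i_qn:
            raise ValueError(f"hyperfine entry {k} does not match layout nucleus {k}")
        si = spin_operators(layout, host)
        ik = nuclear_spin_operators(layout, k)
        for i in range(3):
            for j in range(3):
                if hf.tensor_mhz[i, j] != 0.0:
                    h += (hf.tensor_mhz[i, j] * RAD_PER_MHZ) * (si[i] @ ik[j])

    for a, b in [(x, y) for i, x in enumerate(layout.electron_sites) for y in layout.electron_sites[i + 1:]]:
        j_ab = exchange.get(a, b)
        if j_ab != 0.0:
            sa = spin_operators(layout, a)
            sb = spin_operators(layout, b)
            dot = sum(ka @ kb for ka, kb in zip(sa, sb))
            h += (-j_ab * RAD_PER_MHZ) * (2.0 * dot + 0.5 * np.eye(layout.total_dim))
    return h


@dataclass(frozen=True)
class SpinSystemSpec:
    """Full declarative description of a 2- or 3-radical spin system.

    Bundles layout, point-dipole geometry, hyperfine tensors, exchange,
    g-values and the applied field; the kinetics and scan layers consume
    this object.
    """

    geometry: TrioGeometry
    hyperfines: tuple[HyperfineCoupling, ...] = ()
    exchange: ExchangeSpec = field(default_factory=ExchangeSpec)
    g: GTensorSpec = field(default_factory=GTensorSpec)
    field_spec: FieldSpec = field(default_factory=FieldSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hyperfines", tuple(self.hyperfines))

    @property
    def electron_sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.geometry.positions))

    @property
    def layout(self) -> SpinSystemLayout:
        return SpinSystemLayout(
            electron_sites=self.electron_sites,
            nuclei=tuple((hf.host_site, float(hf.spin)) for hf in self.hyperfines),
        )

    def static_hamiltonian(self) -> np.ndarray:
        """EED + hyperfine + exchange terms (field-independent part), rad/s."""
        zero_field = FieldSpec(b0=0.0, orientation=self.field_spec.orientation)
        return assemble_hamiltonian(
            self.layout, self.geometry, zero_field, list(self.hyperfines), self.exchange, self.g
        )

    def hamiltonian(self, orientation=None) -> np.ndarray:
        """Full Hamiltonian for the given unit field direction (rad/s)."""
        fs = self.field_spec
        if orientation is not None:
            fs = FieldSpec(b0=fs.b0, orientation=tuple(np.asarray(orientation, float)))
        return self.static_hamiltonian() + zeeman_term(self.layout, fs, self.g)

    def with_scavenger_at(self, position, site: int = 3) -> "SpinSystemSpec":
        """Copy of this system with electron site ``site`` moved to ``position``."""
        pos = dict(self.geometry.positions)
        pos[site] = np.asarray(position, dtype=float)
        return SpinSystemSpec(
            geometry=TrioGeometry(pos),
            hyperfines=self.hyperfines,
            exchange=self.exchange,
            g=self.g,
            field_spec=self.field_spec,
        )

    def drop_site(self, site: int) -> "SpinSystemSpec":
        """Copy with one (hyperfine-free) electron site removed."""
        if any(hf.host_site == site for hf in self.hyperfines):
            raise ValueError(f"cannot drop site {site}: it hosts hyperfine-coupled nuclei")
        pos = {k: v for k, v in self.geometry.positions.items() if k != site}
        return SpinSystemSpec(
            geometry=TrioGeometry(pos),
            hyperfines=self.hyperfines,
            exchange=ExchangeSpec({k: v for k, v in self.exchange.j_mhz.items() if site not in k}),
            g=GTensorSpec({k: v for k, v in self.g.g.items() if k != site}),
            field_spec=self.field_spec,
        )
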