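"""Field-orientation sampling and the relative anisotropy statistic.

A compass based on a spin-selective reaction reads the *direction* of the
geomagnetic field from the orientation dependence of a reaction yield.  The
yield is sampled over near-uniform unit vectors from a geodesic subdivision
of the icosahedron (10 f^2 + 2 vertices at subdivision frequency f; the
default f = 16 gives 2562 orientations, i.e. 1281 antipodal axes).  Because
yields are invariant under field inversion (B -> -B), one orientation per
axis suffices; that polarity symmetry is verified on a random subsample each
run rather than silently assumed.

The anisotropy of a yield channel over the axes is summarized by

    Gamma = (max - min) / mean        (reported in percent)

with max, min and mean taken over the sampled axes with uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hamiltonian import SpinSystemSpec, zeeman_generators
from .kinetics_yields import (
    InitialState,
    ReactionScheme,
    YieldResult,
    initial_density,
    yields_by_resolvent,
)

__all__ = [
    "OrientationGrid",
    "YieldMap",
    "AnisotropyResult",
    "build_orientation_grid",
    "yield_map",
    "gamma",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Vertices (12, 3) and faces (20, 3) of a unit icosahedron."""
    verts = []
    for a in (-1.0, 1.0):
        for b in (-_GOLDEN, _GOLDEN):
            verts += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.asarray(verts)
    verts /= np.linalg.norm(verts[0])
    # faces: triples of mutually nearest vertices (edge length 2/|v|)
    edge2 = 4.0 / (1.0 + _GOLDEN**2)
    faces = []
    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(np.sum((verts[i] - verts[j]) ** 2) - edge2) > 1e-9:
                continue
            for k in range(j + 1, n):
                if (
                    abs(np.sum((verts[i] - verts[k]) ** 2) - edge2) < 1e-9
                    and abs(np.sum((verts[j] - verts[k]) ** 2) - edge2) < 1e-9
                ):
                    faces.append((i, j, k))
    return verts, np.asarray(faces)


@dataclass(frozen=True)
class OrientationGrid:
    """Unit field directions with antipodal pairing.

    ``axis_representatives`` indexes one member of each antipodal pair, so
    yields need only be computed for half the vertices.
    """

    vertices: np.ndarray
    antipode_index: np.ndarray
    axis_representatives: np.ndarray
    frequency: int

    @property
    def n_orientations(self) -> int:
        return len(self.vertices)

    @property
    def n_axes(self) -> int:
        return len(self.axis_representatives)


def build_orientation_grid(frequency: int = 16) -> OrientationGrid:
    """Geodesic icosahedral grid with 10 f^2 + 2 unit vectors.

    Each icosahedral face is barycentrically subdivided at frequency f and
    the points are projected to the sphere.  The icosahedron is centrally
    symmetric, so the grid closes under inversion and splits into exactly
    (10 f^2 + 2) / 2 antipodal axes.
    """
    if frequency < 1:
        raise ValueError("subdivision frequency must be >= 1")
    verts, faces = _icosahedron()
    f = int(frequency)
    points: dict[tuple[int, int, int], np.ndarray] = {}
    for ia, ib, ic in faces:
        va, vb, vc = verts[ia], verts[ib], verts[ic]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * va + j * vb + k * vc) / f
                p /= np.linalg.norm(p)
                key = tuple(np.round(p * 1e7).astype(np.int64))
                points.setdefault(key, p)
    vertices = np.array(list(points.values()))
    # antipode lookup via the same rounding key
    key_of = {tuple(np.round(v * 1e7).astype(np.int64)): i for i, v in enumerate(vertices)}
    antipode = np.empty(len(vertices), dtype=np.int64)
    for i, v in enumerate(vertices):
        j = key_of.get(tuple(np.round(-v * 1e7).astype(np.int64)))
        if j is None:
            raise RuntimeError("orientation grid not antipodally closed")
        antipode[i] = j
    reps = np.array([i for i in range(len(vertices)) if i < antipode[i]], dtype=np.int64)
    return OrientationGrid(vertices, antipode, reps, f)


@dataclass(frozen=True)
class YieldMap:
    """Per-axis channel yields over an orientation grid."""

    axes: np.ndarray           # (n_axes, 3) representative unit vectors
    phi_f: np.ndarray
    phi_x: np.ndarray
    phi_b: np.ndarray
    polarity_deviation: float  # max |Phi(+B) - Phi(-B)| over the checked subsample

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"forward": self.phi_f, "scavenging": self.phi_x,
                    "recombination": self.phi_b}[name]
        except KeyError:
            raise ValueError(f"unknown yield channel {name!r}") from None


@dataclass(frozen=True)
class AnisotropyResult:
    """Relative anisotropy of one yield channel over the field axes."""

    channel: str
    y_max: float
    y_min: float
    y_mean: float
    gamma_percent: float
    yields_per_axis: np.ndarray = field(repr=False, default=None)


def _solve_orientation(h_static, gens, n, layout, scheme, rho0) -> YieldResult:
    h = h_static + n[0] * gens[0] + n[1] * gens[1] + n[2] * gens[2]
    return yields_by_resolvent(h, layout, scheme, rho0)


def yield_map(
    system: SpinSystemSpec,
    scheme: ReactionScheme,
    init: InitialState,
    grid: OrientationGrid,
    polarity_check_fraction: float = 0.05,
    rng: np.random.Generator | None = None,
) -> YieldMap:
    """Channel yields for one representative orientation of every grid axis.

    Only the Zeeman term is rebuilt between orientations.  Polarity symmetry
    (equal yields at +B and -B) is validated on a random fraction of the
    axes; the largest observed deviation is reported on the result.
    """
    layout = system.layout
    h_static = system.static_hamiltonian()
    gens = zeeman_generators(layout, system.field_spec.b0, system.g)
    rho0 = initial_density(layout, init)
    reps = grid.axis_representatives
    axes = grid.vertices[reps]
    phis = {"forward": [], "scavenging": [], "recombination": []}
    results: list[YieldResult] = []
    for n in axes:
        res = _solve_orientation(h_static, gens, n, layout, scheme, rho0)
        results.append(res)
        phis["forward"].append(res.phi_f)
        phis["scavenging"].append(res.phi_x)
        phis["recombination"].append(res.phi_b)

    rng = rng or np.random.default_rng(0)
    n_check = max(1, int(round(polarity_check_fraction * len(axes))))
    check_idx = rng.choice(len(axes), size=min(n_check, len(axes)), replace=False)
    deviation = 0.0
    for i in check_idx:
        res_neg = _solve_orientation(h_static, gens, -axes[i], layout, scheme, rho0)
        res_pos = results[i]
        deviation = max(
            deviation,
            abs(res_neg.phi_f - res_pos.phi_f),
            abs(res_neg.phi_x - res_pos.phi_x),
            abs(res_neg.phi_b - res_pos.phi_b),
        )
    return YieldMap(
        axes=axes,
        phi_f=np.asarray(phis["forward"]),
        phi_x=np.asarray(phis["scavenging"]),
        phi_b=np.asarray(phis["recombination"]),
        polarity_deviation=deviation,
    )


def gamma(yields_per_axis: np.ndarray, channel: str = "forward") -> AnisotropyResult:
    """Relative anisotropy Gamma = (max - min)/mean over axes, in percent."""
    y = np.asarray(yields_per_axis, dtype=float)
    if y.size < 2:
        raise ValueError("need yields for at least 2 axes")
    y_max, y_min = float(y.max()), float(y.min())
    # clamp against rounding so y_min <= y_mean <= y_max holds exactly
    y_mean = float(np.clip(y.mean(), y_min, y_max))
    if y_mean == 0.0:
        raise ValueError(f"degenerate yield channel {channel!r}: zero mean")
    return AnisotropyResult(
        channel=channel,
        y_max=y_max,
        y_min=y_min,
        y_mean=y_mean,
        gamma_percent=100.0 * (y_max - y_min) / y_mean,
        yields_per_axis=y,
    )


def gamma_of_map(ymap: YieldMap, channel: str = "forward") -> AnisotropyResult:
    """Convenience: anisotropy of a named channel of a computed yield map."""
    return gamma(ymap.channel(channel), channel=channel)
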