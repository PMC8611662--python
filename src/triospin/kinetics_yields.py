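"""Reaction kinetics and yields of the scavenged radical trio.

The spin density matrix obeys a Liouville-von Neumann master equation with
Haberkorn (anticommutator) reaction terms:

    drho/dt = -i[H, rho] - k_f rho - (k_X/2){P_S^a3, rho} - (k_b/2){P_S^12, rho}

Escape (k_f) acts spin-independently on the whole trio; scavenging (k_X)
removes population through the singlet channel of the scavenged pair (a, 3),
forming a diamagnetic product; primary-pair recombination (k_b) is the
singlet channel of pair (1, 2), used by the RPM / R3M comparison schemes and
purposefully zero in the scavenging scheme.  The observables are the channel
yields

    Phi_f = k_f  Int_0^inf Tr[rho(t)] dt
    Phi_X = k_X  Int_0^inf Tr[P_S^a3 rho(t)] dt
    Phi_b = k_b  Int_0^inf Tr[P_S^12 rho(t)] dt

which sum to one when every decay channel is accounted for.

Two solvers are provided.  The default "resolvent" path rewrites the master
equation with the non-Hermitian effective Hamiltonian

    H_eff = H - i(k_f/2) I - i(k_X/2) P_S^a3 - i(k_b/2) P_S^12

so that rho(t) = exp(-i H_eff t) rho0 exp(+i H_eff^dag t), and evaluates the
time integrals in closed form from the eigendecomposition of H_eff -- the
fast path needed by orientation scans (thousands of solves per map).  The
"integration" path propagates the master equation itself with an adaptive
ODE solver and quadratures the channel fluxes; it is slower but makes no
diagonalizability assumption and serves as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .spin_core import SpinSystemLayout, singlet_projector, triplet_projector

__all__ = [
    "ReactionScheme",
    "InitialState",
    "YieldResult",
    "KineticsError",
    "initial_density",
    "reaction_channels",
    "effective_hamiltonian",
    "yields_by_resolvent",
    "yields_by_integration",
]

#: default escape rate, 1/(3 us): the primary pair's escape to the
#: signalling state on its established ~3 microsecond lifetime.
DEFAULT_K_F = 1.0 / 3e-6


class KineticsError(RuntimeError):
    """Raised when a yield computation cannot be completed reliably."""


@dataclass(frozen=True)
class ReactionScheme:
    """Reaction channels and rates (s^-1).

    kind 'scavenging' is the three-radical scheme (k_b forced 0);
    'RPM' is the bare pair with singlet recombination k_b;
    'R3M' keeps the third radical as an inert bystander (k_X = 0) with
    recombination re-engaged.
    """

    k_f: float = DEFAULT_K_F
    k_x: float = 0.0
    k_b: float = 0.0
    scavenged_pair: tuple[int, int] = (2, 3)
    kind: str = "scavenging"

    def __post_init__(self) -> None:
        for name in ("k_f", "k_x", "k_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kind not in ("scavenging", "RPM", "R3M"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        a, b = self.scavenged_pair
        if b != 3 or a not in (1, 2):
            raise ValueError("scavenged_pair must be (1, 3) or (2, 3)")
        if self.kind == "scavenging" and self.k_b != 0.0:
            raise ValueError("scavenging scheme neglects primary-pair recombination (k_b = 0)")
        if self.kind == "R3M" and self.k_x != 0.0:
            raise ValueError("R3M bystander is inert (k_X = 0)")


@dataclass(frozen=True)
class InitialState:
    """Initial spin state of the primary pair (1, 2).

    'singlet_born' and 'triplet_born' are the geminate pair projectors;
    'F_pair' is a pair formed with random spin configuration (maximally
    mixed).  The scavenger and all nuclei start maximally mixed and
    uncorrelated in every case.
    """

    kind: str = "singlet_born"

    def __post_init__(self) -> None:
        if self.kind not in ("singlet_born", "triplet_born", "F_pair"):
            raise ValueError(
                f"unknown initial state {self.kind!r}; "
                "expected singlet_born, triplet_born or F_pair"
            )


@dataclass(frozen=True)
class YieldResult:
    """Channel yields for one field orientation; phi_f + phi_x + phi_b ~ 1."""

    phi_f: float
    phi_x: float = 0.0
    phi_b: float = 0.0
    residual: float = 0.0

    @property
    def total(self) -> float:
        return self.phi_f + self.phi_x + self.phi_b


def initial_density(layout: SpinSystemLayout, init: InitialState) -> np.ndarray:
    """Unit-trace density matrix for the given initial-state kind."""
    if init.kind == "singlet_born":
        p = singlet_projector(layout, (1, 2))
    elif init.kind == "triplet_born":
        p = triplet_projector(layout, (1, 2))
    else:  # F_pair: maximally mixed primary pair (and everything else)
        p = np.eye(layout.total_dim, dtype=complex)
    return p / np.trace(p).real


def reaction_channels(layout: SpinSystemLayout, scheme: ReactionScheme) -> list[tuple[str, float, np.ndarray | None]]:
    """(name, rate, projector) per active channel; projector None = identity."""
    channels: list[tuple[str, float, np.ndarray | None]] = [("forward", scheme.k_f, None)]
    if scheme.k_x > 0.0:
        channels.append(("scavenging", scheme.k_x, singlet_projector(layout, scheme.scavenged_pair)))
    if scheme.k_b > 0.0:
        channels.append(("recombination", scheme.k_b, singlet_projector(layout, (1, 2))))
    return channels


def effective_hamiltonian(h: np.ndarray, layout: SpinSystemLayout, scheme: ReactionScheme) -> np.ndarray:
    """Non-Hermitian H_eff whose two-sided propagator solves the master equation."""
    h_eff = h.astype(complex).copy()
    dim = layout.total_dim
    for _, rate, proj in reaction_channels(layout, scheme):
        if rate == 0.0:
            continue
        p = np.eye(dim, dtype=complex) if proj is None else proj
        h_eff -= 0.5j * rate * p
    return h_eff


def _channel_yield_fields(scheme: ReactionScheme, values: dict[str, float], residual: float = 0.0) -> YieldResult:
    return YieldResult(
        phi_f=values.get("forward", 0.0),
        phi_x=values.get("scavenging", 0.0),
        phi_b=values.get("recombination", 0.0),
        residual=residual,
    )


def yields_by_resolvent(
    h: np.ndarray,
    layout: SpinSystemLayout,
    scheme: ReactionScheme,
    rho0: np.ndarray,
    cond_limit: float = 1e8,
) -> YieldResult:
    """Exact steady yields from the eigendecomposition of H_eff.

    With H_eff = V diag(lam) V^-1 the time integral of Tr[P rho(t)] is

        sum_jk (V^dag P V)_kj (V^-1 rho0 V^-dag)_jk / (i (lam_j - conj(lam_k)))

    valid whenever every eigenvalue decays (Im lam < 0), which k_f > 0
    guarantees.  Falls back with an error if V is too ill-conditioned
    (near-defective H_eff); callers may then use the integration path.
    """
    if scheme.k_f <= 0.0:
        raise KineticsError("resolvent path requires k_f > 0 for guaranteed decay")
    h_eff = effective_hamiltonian(h, layout, scheme)
    lam, v = np.linalg.eig(h_eff)
    cond = np.linalg.cond(v)
    if not np.isfinite(cond) or cond > cond_limit:
        raise KineticsError(
            f"defective effective Hamiltonian (eigenvector condition {cond:.3g}); "
            "use yields_by_integration"
        )
    v_inv = np.linalg.inv(v)
    m = v_inv @ rho0 @ v_inv.conj().T
    denom = 1.0j * (lam[:, None] - lam.conj()[None, :])
    kernel = m / denom
    values: dict[str, float] = {}
    for name, rate, proj in reaction_channels(layout, scheme):
        if rate == 0.0:
            values[name] = 0.0
            continue
        p = np.eye(layout.total_dim, dtype=complex) if proj is None else proj
        a = v.conj().T @ p @ v
        values[name] = float(np.real(rate * np.sum(kernel * a.T)))
    return _channel_yield_fields(scheme, values)


def yields_by_integration(
    h: np.ndarray,
    layout: SpinSystemLayout,
    scheme: ReactionScheme,
    rho0: np.ndarray,
    t_max: float | None = None,
    tol: float = 1e-10,
    residual_limit: float = 1e-4,
) -> YieldResult:
    """Yields by direct numerical propagation of the master equation.

    Integrates rho(t) together with the accumulated channel fluxes over
    [0, t_max] (default 25 / k_f).  The population remaining at t_max is an
    exact bound on the unaccounted yield (conservation); it is returned as
    ``residual`` and triggers an error if above ``residual_limit``.
    """
    if scheme.k_f <= 0.0 and t_max is None:
        raise KineticsError("t_max must be given when k_f = 0")
    if t_max is None:
        t_max = 25.0 / scheme.k_f
    dim = layout.total_dim
    channels = reaction_channels(layout, scheme)
    projs = [np.eye(dim, dtype=complex) if p is None else p for _, _, p in channels]
    rates = [r for _, r, _ in channels]
    n2 = dim * dim

    def rhs(_t, y):
        rho = (y[:n2] + 1j * y[n2:2 * n2]).reshape(dim, dim)
        drho = -1j * (h @ rho - rho @ h)
        for rate, p in zip(rates, projs):
            if rate:
                drho -= 0.5 * rate * (p @ rho + rho @ p)
        flux = [rate * np.trace(p @ rho).real for rate, p in zip(rates, projs)]
        return np.concatenate([drho.real.ravel(), drho.imag.ravel(), flux])

    y0 = np.concatenate([rho0.real.ravel(), rho0.imag.ravel(), np.zeros(len(channels))])
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="DOP853", rtol=tol, atol=tol)
    if not sol.success:
        raise KineticsError(f"master-equation integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    rho_end = (y_end[:n2] + 1j * y_end[n2:2 * n2]).reshape(dim, dim)
    residual = float(np.trace(rho_end).real)
    if residual > residual_limit:
        raise KineticsError(
            f"yields not converged within t_max={t_max:.3g} s: residual trace {residual:.3g}"
        )
    values = {name: float(y_end[2 * n2 + i]) for i, (name, _, _) in enumerate(channels)}
    return _channel_yield_fields(scheme, values, residual=residual)
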