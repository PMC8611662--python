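"""Moser-Dutton distance ruler for biological electron-transfer rates.

Long-range nonadiabatic ET through a biological medium decays exponentially
with donor-acceptor separation.  The activationless bound used here is

    k(R) = kappa * exp(-beta (R - sigma)) * exp(-G)

with kappa = 1e13 s^-1 the van der Waals contact rate, sigma = 3.6 A the
contact distance, beta the tunneling decay constant (0.9 A^-1 for a covalent
bridge, 1.4 A^-1 for typical protein, 2.8 / 4.0 A^-1 for weakly coupled,
vacuum-like media) and G an optional activation free energy in units of
k_B*T (default 0, i.e. activationless).

A large effective beta is mathematically interchangeable with protein-like
tunneling over a modest barrier: the barrier making the beta_ref rate equal
the activationless beta_eff rate at distance R is

    G = (beta_eff - beta_ref) (R - sigma)   [k_B*T].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["ETParams", "moser_dutton_rate", "equivalent_barrier", "STANDARD_BETAS"]

#: conventional tunneling decay constants (A^-1): covalent bridge, typical
#: protein, weakly coupled medium, vacuum-like.
STANDARD_BETAS = (0.9, 1.4, 2.8, 4.0)


@dataclass(frozen=True)
class ETParams:
    """Parameters of the exponential distance law (rates in s^-1, lengths in A)."""

    kappa: float = 1e13
    sigma: float = 3.6
    beta: float = 1.4
    barrier: float = 0.0  # activation free energy, units of k_B*T

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.barrier < 0:
            raise ValueError("barrier must be >= 0")


def moser_dutton_rate(r: float, params: ETParams | None = None, **overrides) -> float:
    """ET rate (s^-1) at donor-acceptor distance r (angstrom).

    Distances below the contact distance sigma clamp to the contact rate
    kappa * exp(-barrier): the expression is a tunneling bound and
    super-contact rates would be unphysical.
    """
    params = params or ETParams()
    if overrides:
        params = ETParams(**{**params.__dict__, **overrides})
    if r < 0:
        raise ValueError(f"negative donor-acceptor distance: {r}")
    if r < params.sigma:
        warnings.warn(
            f"distance {r} A below contact distance {params.sigma} A; "
            "clamping to the contact rate",
            stacklevel=2,
        )
        r = params.sigma
    return params.kappa * math.exp(-params.beta * (r - params.sigma) - params.barrier)


def equivalent_barrier(beta_eff: float, beta_ref: float, r: float, sigma: float = 3.6) -> float:
    """Barrier (k_B*T) equating the beta_ref rate to the activationless beta_eff rate at r."""
    if beta_eff < beta_ref:
        raise ValueError(
            f"beta_eff ({beta_eff}) < beta_ref ({beta_ref}): no nonnegative barrier exists"
        )
    if r < sigma:
        warnings.warn("distance below contact; barrier evaluated at contact (0)", stacklevel=2)
        r = sigma
    return (beta_eff - beta_ref) * (r - sigma)
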