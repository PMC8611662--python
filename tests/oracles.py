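"""Independent oracles for cross-checking the kinetics solvers.

Everything here is built from first principles with Kronecker identities --
never by calling the package's propagation paths -- so agreement between a
package solver and these functions is a genuine dual-route check.
"""

import numpy as np
from scipy.linalg import expm

from triospin.kinetics_yields import ReactionScheme, reaction_channels
from triospin.spin_core import SpinSystemLayout


def liouvillian(h: np.ndarray, layout: SpinSystemLayout, scheme: ReactionScheme) -> np.ndarray:
    """Superoperator L with vec(drho/dt) = L vec(rho), row-major vec.

    Built directly from the master equation
    drho/dt = -i[H, rho] - k_f rho - (k_X/2){P_X, rho} - (k_b/2){P_b, rho}
    using vec(A rho B) = (A kron B^T) vec(rho).
    """
    dim = h.shape[0]
    eye = np.eye(dim)
    lv = -1j * (np.kron(h, eye) - np.kron(eye, h.T))
    for _, rate, proj in reaction_channels(layout, scheme):
        if rate == 0.0:
            continue
        p = eye if proj is None else proj
        lv -= 0.5 * rate * (np.kron(p, eye) + np.kron(eye, p.T))
    return lv


def superoperator_yields(h, layout, scheme, rho0):
    """Exact channel yields from the steady integral -L^{-1} vec(rho0)."""
    lv = liouvillian(h, layout, scheme)
    integral = np.linalg.solve(-lv, rho0.ravel()).reshape(h.shape)
    out = {}
    for name, rate, proj in reaction_channels(layout, scheme):
        p = np.eye(h.shape[0]) if proj is None else proj
        out[name] = float(np.real(rate * np.trace(p @ integral)))
    return out


def superoperator_propagate(h, layout, scheme, rho0, t):
    """rho(t) by exponentiating the full Liouvillian."""
    lv = liouvillian(h, layout, scheme)
    return (expm(lv * t) @ rho0.ravel()).reshape(h.shape)
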