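"""Constrained scavenger placement scan Gamma_beta(R).

For each radius R around the scavenged radical the scavenger position is
optimized over a sphere, with the scavenging rate pinned to the
Moser-Dutton value at that distance.  Weakly coupled media (large beta)
force small optimal distances; covalent-bridge coupling allows remote
scavengers.
"""

import numpy as np

from triospin import (
    FixtureSpec,
    ScanSpec,
    build_orientation_grid,
    make_fixture,
    profile_gamma_beta,
)

bundle = make_fixture(FixtureSpec(kind="reference_probe"))
grid = build_orientation_grid(2)  # preview resolution (21 axes)

print("beta (/A)   Gamma_max (%)   R_max (A)   k_X(R_max) (ns^-1)")
for beta in (0.9, 1.4, 2.8, 4.0):
    spec = ScanSpec(
        target_site=2, beta=beta,
        r_grid=tuple(np.arange(4.0, 21.0, 1.0)),
        sphere_points=12, refinement_rounds=1,
    )
    res = profile_gamma_beta(bundle.system, bundle.scheme, bundle.init, spec, grid=grid)
    k_x = res.profile.set_index("R").loc[res.r_max, "k_x"]
    print(f"  {beta:4.1f}      {res.gamma_max:8.1f}      {res.r_max:6.1f}      "
          f"{k_x * 1e-9:8.2f}")

print("\nAs beta grows the optimum moves inward: faster coupling decay is")
print("compensated by a faster reaction at a shorter scavenger-target distance.")
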