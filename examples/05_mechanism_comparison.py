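"""Scavenging versus recombination-based compasses under matched conditions.

Compares three mechanisms on the flavin/tryptophan-like trio with identical
couplings and distance-law rates: the bare radical pair (RPM), the trio with
an inert bystander (R3M), and the scavenged trio.
"""

from triospin import FixtureSpec, build_orientation_grid, compare_mechanisms, make_fixture

bundle = make_fixture(FixtureSpec(kind="flavin_trp_like"))
table = compare_mechanisms(
    bundle.system, bundle.init, beta=1.4, scavenged_site=2,
    grid=build_orientation_grid(2),
)
print(table[["mechanism", "gamma_percent", "k_b_per_s", "k_x_per_s",
             "rate_distance_angstrom"]].to_string(index=False))

print("\nAt the 18 A primary separation the distance-law recombination rate is")
print("far below the escape rate, so RPM and R3M barely discriminate spin")
print("states; the scavenging channel, running at the much shorter")
print("scavenger-target distance, retains a directional signal.")
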