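# Methods

## Model

A system is two or three electron spins-1/2 (labels 1, 2 = primary radical
pair, 3 = scavenger/bystander) plus nuclear spins I ∈ {1/2, 1, 3/2}, each
hyperfine-coupled to one electron.  The composite space is ordered electrons
first (in site-label order), then nuclei in declaration order; all operators
are dense complex matrices (dimensions here stay ≤ a few hundred, where
dense eigendecompositions beat any sparse machinery).

The Hamiltonian is Ĥ = Ĥ_Zee + Ĥ_EED + Ĥ_hf + Ĥ_ex, held internally in
angular frequency (rad s⁻¹); user-facing couplings are MHz or mT, converted
once at construction (mT × 28.0249514242 MHz/mT, pinned in `constants`).

* **Zeeman**: isotropic g per site (default 2.0023).  g-tensor anisotropy is
  not supported — organic radical g-anisotropies shift level positions by
  far less than the hyperfine scales of interest at 50 µT.  The nuclear
  Zeeman term is omitted: it is ~3 orders of magnitude below the electron
  term at geomagnetic intensity and commutes with nothing that matters on
  the microsecond reaction time scale.
* **EED**: point dipoles at the radical positions (Å).  For separation
  vector r, T(r) = d(r)(𝟙 − 3r̂r̂ᵀ) with d(r) = (µ0/4π) g_a g_b µ_B²/(h r³),
  coupling S_a·T·S_b, applied to *all* pairs present.  The conventional
  |D| = (3/2)d(r) is exposed as a diagnostic; it gives 13.4 MHz at 18.0 Å
  (14 MHz at 17.7 Å).  No spin-density distribution: one point per radical.
* **Hyperfine**: S_i·A_ik·I_k with arbitrary (not necessarily symmetric)
  real 3×3 tensors in MHz.
* **Exchange**: Ĥ_ex = −J_ab(2S_a·S_b + ½), J in MHz, default 0 for every
  pair (exchange is negligible at the ≥1 nm separations of interest); the
  sign/form convention is fixed so that nonzero user values are reproducible.

## Kinetics and yields

Reactions are Haberkorn terms: spin-independent escape k_f on the full
trace, singlet-channel scavenging k_X on pair (a,3), optional
singlet-channel primary recombination k_b on pair (1,2).  Scheme kinds:
`scavenging` (k_b ≡ 0 — recombination deliberately disengaged to isolate
the scavenging pathway), `RPM` (pair only, k_b > 0), `R3M` (trio with inert
bystander, k_X ≡ 0, k_b > 0).  Initial states: singlet-born or triplet-born
primary pair, or F-pair (maximally mixed); scavenger and nuclei always
start maximally mixed and uncorrelated, which fixes the initial
scavenger-pair singlet probability at 1/4.

Two solvers compute the channel yields Φ = k ∫₀^∞ Tr[P ρ(t)] dt:

1. **Resolvent (default)**: the master equation is exactly equivalent to
   two-sided propagation with H_eff = Ĥ − i(k_f/2)𝟙 − i(k_X/2)P̂_S^a3 −
   i(k_b/2)P̂_S^12; with H_eff = VΛV⁻¹ the time integral is a closed-form
   double sum over eigenpairs.  Cost is one dim-N eigendecomposition per
   field orientation — the reason orientation scans are feasible.  A
   condition-number guard (default 10⁸) raises rather than silently using a
   near-defective eigenbasis.
2. **Integration**: direct adaptive propagation (DOP853) of ρ(t) together
   with accumulated channel fluxes over [0, t_max] (default 25/k_f, leaving
   e⁻²⁵ unaccounted).  The trace remaining at t_max bounds the unaccounted
   yield exactly (conservation) and is returned as `residual`, erroring
   above 10⁻⁴ instead of being dropped.

The tests additionally hold both paths against a third, independently coded
oracle that builds the full Liouvillian from Kronecker identities and
computes Φ from −L⁻¹ρ0.

## Orientation sampling and Γ

Field directions come from geodesic subdivision of the icosahedron
(10f² + 2 vertices; default f = 16 → 2562 orientations).  The icosahedron
is centrally symmetric, so the grid splits into exactly 1281 antipodal
axes; yields are computed for one representative per axis.  Γ is
(max − min)/mean of the chosen channel over axes with uniform weights — the
grid is near-uniform (nearest-neighbour spacing CV < 0.2), making
quadrature weights a second-order refinement not worth the asymmetry they
introduce.  The default channel is the forward (signalling) yield; the
scavenging channel is available by flag and, with k_b = 0, mirrors it
through Φ_f + Φ_X = 1.

**Polarity symmetry is not exactly exact.**  The usual time-reversal
argument for Φ(+B) = Φ(−B) goes through unchanged only when the initial
density and the measured projector effectively commute.  That holds for
F-pair initial states, for recombination schemes (where ρ0 and the reaction
projector are both functions of P̂_S^12), and for EED-free trios — in all
of these the package measures deviations < 10⁻¹³.  For a singlet- or
triplet-born pair scavenged through P̂_S^a3 in the presence of EED coupling
the symmetry is weakly broken by the absorptive dynamics: measured
deviations reach ~2×10⁻⁴ in per-axis yields at strong scavenging rates
(k_X ~ 10⁹ s⁻¹) and ~10⁻⁵ at moderate ones.  Axis-halving is retained —
the error in Γ is orders below the effects of interest — but it is treated
as a controlled approximation: every yield map verifies Φ(+B) vs Φ(−B) on
a random 5 % subsample and reports the largest deviation
(`YieldMap.polarity_deviation`) rather than assuming the symmetry silently.

## Electron-transfer constraint

Scavenging (and recombination) rates are bounded by the activationless
tunneling law k(R) = κ e^(−β(R−σ)−ΔG‡/k_BT), κ = 10¹³ s⁻¹, σ = 3.6 Å,
β conventionally one of {0.9, 1.4, 2.8, 4.0} Å⁻¹ (any positive value
accepted), ΔG‡ default 0.  Distances below σ clamp to the contact rate —
the law is an upper bound and super-contact rates would be unphysical.  The
barrier equivalence ΔG‡ = (β_eff − β_ref)(R − σ) converts a large effective
β into protein-like tunneling over a modest barrier; the round trip is
exact by construction.  Rates are s⁻¹ internally, ns⁻¹ only in
presentation.

## Scans

`gamma_at_position` places the scavenger, recomputes *both* scavenger EED
tensors from the actual inter-radical vectors (orientation as well as
distance matters), sets k_X from the distance law at the scavenger–target
separation, and evaluates Γ.  `profile_gamma_beta` maximizes Γ over sphere
directions at each radius: a coarse icosahedral direction set (default 42)
followed by deterministic local refinement — rings of 8 azimuthal
candidates around the running best at a halving angular radius (default 2
rounds).  Ties across radii resolve to the smaller R (the stronger-coupling
solution).  A 1 Å exclusion zone around the primary radicals avoids the
point-dipole singularity.  `unconstrained_scan` frees (k_X, position) and
flags any record whose rate exceeds the β = 0.9 Å⁻¹ activationless bound at
its own distance as `unphysical_rate`.  Per-position evaluations are
independent and reduced in sorted order, so outputs are deterministic and
order-independent.

## Synthetic systems

The fixtures emulate the structural classes of the cryptochrome problem
without shipping external data; all hyperfine magnitudes are *illustrative
placeholders* at realistic scales (axial 47 MHz flavin-N5-like, ~10 MHz
proton-like, ~18 MHz indole-nitrogen-like), clearly labelled as such.
Defaults: primary separation 18 Å (the distal-tryptophan class, chosen so
the pair |D| reproduces the ~14 MHz scale), scavenger on the perpendicular
bisector of the primary pair (the maximally symmetric default; scans
override it) at 10 Å from its target, escape 1/(3 µs), k_X from the
β = 1.4 Å⁻¹ distance law.  `reference_probe` (hyperfine-free partner and
scavenger, triplet-born) mirrors the superoxide-like maximal-contrast
limit; `flavin_trp_like` (singlet-born, spin-1 nitrogens on both partners,
dim 144) the photoreduction pair; `rpm_pair` the bare-pair control;
`random_trio` seeded random property-test systems.  What the fixtures do
*not* emulate: real per-nucleus tensor sets (tens of nuclei per radical),
spin-density-distributed dipolar tensors, spin relaxation, or protein
sterics — passing tests demonstrate correct model mechanics, not
quantitative predictions for any particular protein.  Real structures enter
through the versioned YAML config schema and, for coordinates, the PDB
centroid helper (first model, first altloc, heavy atoms only, 1-based
residue numbering).

## Numerical choices and problem sizes

Eigendecomposition is the single propagation path used inside scans (fixed
solver ⇒ bit-reproducible results under identical config + seed).  The test
and example scans run at reduced resolution — f = 1–2 orientation grids
(12–42 orientations), dim-16/144 fixtures, 1 Å radius grids, one refinement
round — which resolves the qualitative structure (optimum location to the
grid step, monotonicity of R_max in β); the library default remains the
full f = 16 survey grid.  Spin relaxation and time-dependent
(radio-frequency) fields are outside the package's scope.
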