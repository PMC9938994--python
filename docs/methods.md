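# Methods

## Model and units

All simulations use reduced DPD units: the pair-interaction cutoff is the
unit of length, bead mass is 1, and one energy unit corresponds to
k_B·300 K. The temperature convention is the single source of truth for
kelvin↔DPD conversion (`mesodpd.parameters.TemperatureConvention`); it is
what reconciles the Flory–Huggins repulsion mapping

    a_ij(T) = 75 k_BT / ρ + 3.4965 k_BT χ_ij,     χ_ii = 0

with a diagonal of 24.83 at 298 K and ρ = 3. Common parameter settings are
the defaults everywhere: ρ = 3, σ = 3, k_bond = 4, r_bond = 1. The friction
coefficient is never an independent input; it is always γ = σ²/(2 k_BT)
(fluctuation–dissipation), with ω_D = ω_R² = (1 − r)² below the cutoff.

Bonded neighbours also feel the nonbonded soft repulsion (no exclusions),
which is standard practice for Groot–Warren-type models.

## Repulsion-matrix transformations

*Range-x scaling* multiplies every off-diagonal χ entry by one common
positive factor chosen so that the smallest a_ij sits exactly x DPD units
below the diagonal. Because the most negative χ entry produces that
minimum, the minimum is also the largest absolute deviation in the matrix —
"range x" bounds every |a_ij − a_ii| by x. The transformation preserves the
sign pattern and relative ordering of all deviations.

*Morphing* interpolates the repulsion row of a source bead type linearly
toward a target type's row; the mutual source–target entry runs toward the
diagonal value, so at 100 % the two types repel every partner identically.
Morphs compose: f₁ then f₂ equals a single morph at f₁ + f₂(1 − f₁).

## Integrators

All four schemes share the same conservative force kernel and differ in how
the dissipative/random pair forces enter the update:

- **gwmvv** — Groot–Warren modified velocity-Verlet. Implemented in
  half-kick arithmetic: `v½ = v + ½Δt f`, drift, force recomputation with
  the λ-predicted velocity `ṽ = v + λΔt f`, then `v = v½ + ½Δt f_new`.
  With σ = 0 the velocity prediction is irrelevant and the scheme is
  bitwise plain velocity-Verlet (λ default 0.65).
- **scmvv / dpdmvv** — after the drift, conservative + random forces are
  computed once and the dissipative force is re-evaluated against the
  updated velocity estimate n times (fixed-point iteration; n = 1 is the
  DPDMVV variant). The iteration contracts with factor ~γω_DΔt.
- **s1mvv** — Shardlow S1 splitting. For each pair within the cutoff, in a
  fixed ascending (i, j) sweep order, an explicit half step followed by an
  implicit half step of the pair's relative-velocity Ornstein–Uhlenbeck
  dynamics (one shared noise draw), composed with a velocity-Verlet
  conservative step. The pair update's stationary relative-velocity
  variance is exactly 2 k_BT for any Δt; residual temperature drift comes
  from the conservative part.
- **pnhln** — pairwise Nosé–Hoover–Langevin. The friction coefficient is an
  auxiliary variable ξ applied in a single semi-implicit kick per pair
  (noise amplitude σ fixed), driven by integral feedback
  dξ/dt = G/μ with G = Σ_pairs ω_D(r)(|v_ij|² − 6 k_BT) evaluated on the
  incoming velocities, plus a weak Ornstein–Uhlenbeck relaxation of ξ
  toward γ (rate 1/μ², stationary spread √(k_BT/μ)) that supplies
  ergodicity noise without moving the working point. The control signal
  uses the full relative velocity rather than only its longitudinal
  projection: discretization heating accumulates partly in transverse pair
  modes, and a longitudinal-only signal is blind to it. With coupling
  μ = 500 this holds the box temperature within ~1 K of the set point at
  Δt = 0.04–0.08 where the S1 scheme drifts by several kelvin to tens of
  kelvin. μ is the thermal mass of ξ: smaller values adapt faster but
  noisier.

Random numbers are counter-based: each (step, pair) maps through a
splitmix64-style hash to one standard normal draw, so ζ_ij = ζ_ji by
construction and results are bit-reproducible for a given seed regardless
of pair enumeration order. Coincident beads (r = 0, legal under soft
potentials) receive a deterministic fallback force direction chosen by
index parity, with a warning.

Boundaries: periodic axes wrap into [0, L); reflective z-walls fold the
coordinate and flip v_z (specular). Walls break z-momentum conservation by
construction and produce density oscillations in their vicinity. A bead
displaced by more than one box length in a single step aborts the run with
a divergence error.

The pressure tensor combines the kinetic term with the conservative pair
virial (soft repulsion + bonds); dissipative/random forces are excluded, so
an ideal fluid (a = 0) measures P = ρ k_BT exactly up to sampling. The z
surface tension is the instantaneous global anisotropy
γ_z = Lz (P_zz − (P_xx + P_yy)/2), used as a relative formation signal,
not an interface-normalized tension.

## System building

Composition → molecule counts is volume-scaled: with physical mole numbers
n_k ∝ w_k/M_k (true molecular molar masses — fragment sums double-count
capping hydrogens, so `MoleculeSpec` can carry the molecule's real molar
mass) and molecular volumes V_k from fragment volumes, counts follow
N_k ∝ n_k V_k / beads_k, which equates bead-count shares with physical
volume fractions. Disabling volume scaling gives plain molar ratios and
over-represents water. Fractional counts are rounded to nearest (the
reference species stays exact).

Random starts grow each molecule as a unit-step random walk from a uniform
anchor; layered starts stratify chains into n z-slabs of two opposing
leaflets with head beads at the slab faces and water filling the gaps.
"Force-step" minimization is steepest descent on the conservative forces
with per-bead displacement capped at 0.1 cutoff lengths and backtracking,
so the potential energy never increases and velocities are untouched.

## Analysis definitions

- *Bilayer detection*: contiguous runs of the surfactant z-density above
  the midpoint of its extreme levels; profiles whose peak-to-trough
  contrast is below 25 % of the maximum count as non-bimodal (mixed), and
  runs narrower than 1 DPD length are discarded as noise.
- *Bilayer thickness*: per detected slab, the distance between the two
  flanking headgroup density maxima plus one mean headgroup FWHM,
  converted to Å by r_c. This is a deliberate, testable definition (the
  envelope-style band it emulates is not uniquely specified by any
  standard); it is exact on synthetic twin-Gaussian profiles by
  construction.
- *Temperature drift*: mean kinetic temperature over the final 50 % of a
  series minus the set point. Kinetic temperature uses 3N degrees of
  freedom without centre-of-mass subtraction.
- *Convergence step*: first index from which every sliding-window
  least-squares slope of the γ_z series stays below tolerance.
- *Unit conversions*: r_c = (V_min ρ ⟨V_i/V_min⟩_N)^{1/3} (number-weighted
  over all beads; permutation invariant, scales as ρ^{1/3});
  t_phys = t_DPD f_soft r_c √(⟨M⟩_N/(R T)) with f_soft = 1000 by default.

## Synthetic demo data and what it does (not) show

The bundled 5-type particle set (Me, Et, Me2O, MeOH, H2O) is synthetic.
Its χ contrast pattern encodes the qualitative chemistry — hydrophobes
repel water strongly, ether oxygen mildly hydrophilic, terminal hydroxyl
most hydrophilic — with the hydroxyl–water entry carrying the largest
magnitude so that range scaling makes it both the matrix minimum and the
maximum absolute deviation. Fragment volumes are stand-ins: water is fixed
at 30 Å³ (the smallest particle), Me and MeOH are fixed at chemically
plausible 38 / 45 Å³, and the Me2O / Et volumes are calibrated so that the
volume-scaled composition mapping reproduces the two published full-scale
box compositions (79,174 and 65,337 water molecules per 18,500
surfactants). Two published counts cannot constrain four volumes, so
Å-valued outputs (r_c ≈ 4.94 Å for the scheme-A box, thicknesses, the
~61–63 µs production-run duration) are consistency checks of the pipeline,
not recoveries of the study's exact inputs.

Scaled-down tests use ≈2,000–4,100 beads and 10⁴–5·10⁴ steps (full scale
is 338k beads and 10⁶ steps):

- The S1 drift sweep runs the 0.75 mass-fraction mixture in a *fully
  periodic* box. At these box heights (Lz ≈ 18) reflective walls add an
  O(1/Lz) heating artifact of ~2 K that is negligible at full scale
  (Lz = 48); periodic boundaries remove it, leaving the integrator's own
  drift, which reproduces the full-scale values at Δt = 0.04 and 0.12
  within tens of percent and their monotone growth with Δt.
- Bilayer formation runs use a tall narrow box (≈7×7×26) with reflective
  z-walls at Δt = 0.12, where formation is fastest; ≥2 lamellae and a
  strong γ_z rise appear within 5·10⁴ steps, while a 0.30 mass-fraction
  control shows no sustained rise. Small boxes cannot show the slow
  coarsening or seed-to-seed convergence-time statistics of full-scale
  runs.
- Thickness is measured on a single tension-free bilayer (periodic box,
  layered start, surfactant load chosen near γ_z ≈ 0, brief relaxation).
  Membranes at imposed nonzero tension are thinner/thicker accordingly, so
  the zero-tension state is the well-defined reference. With the synthetic
  repulsions the scheme-A bilayer measures ≈55–62 Å (published reference
  ≈50 Å) and scheme B ≈45–49 Å (reference ≈35 Å); the ordering and
  relative thinning of the ethane-based fragmentation are reproduced, the
  absolute scheme-B value is not — chain packing depends on repulsion
  details the synthetic set cannot recover.

## Numerical choices and limitations

- Cell lists require every box length ≥ 3 cutoffs; pair enumeration is
  verified against the O(N²) reference to 1e-12.
- The S1/PNHLN sweep order is fixed ascending (i, j) for reproducibility;
  other orders give statistically equivalent but not bitwise-identical
  trajectories.
- Single-threaded execution; determinism is bitwise for a given seed.
- No electrostatics, variable bead masses, barostats, or GPU execution.
- Wall reflection is purely specular (no soft wall potential); wall-contact
  density oscillations are therefore slightly sharper than with a soft
  wall.
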