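"""Synthetic fixtures: demo particle sets, scaled-down lamellar systems and
reference fluids, so the whole pipeline is testable without external data.

The 5-type demo set (Me, Et, Me2O, MeOH, H2O) mirrors the qualitative
chemistry of a C10E4/water mixture: hydrophobe–water repulsions above the
diagonal, hydrophile–water below, with the MeOH–water entry the matrix
minimum.  Off-diagonal magnitudes are anchored only through the "range x"
definition (min a_ij = a_ii − x); the published range-10/15/20 matrices
themselves live in external repositories and are not reproduced here.

Fragment volumes are synthetic stand-ins: water is fixed at 30 Å³ (the
smallest particle) and the remaining volumes are calibrated so that the
volume-scaled composition mapping reproduces the two published box
compositions for the 0.75 mass-fraction mixture (79,174 water molecules
per 18,500 surfactants for fragmentation scheme A, 65,337 for scheme B).
Two printed counts cannot pin down four volumes, so Me and MeOH are fixed
at chemically plausible values and Me2O/Et absorb the two constraints.
Å-valued outputs computed from these volumes are therefore *consistent
stand-ins*, not the study's exact numbers.
"""

from __future__ import annotations

import numpy as np

from .builder import Composition, box_for_counts, random_start, volume_scaled_counts
from .chem import MoleculeSpec, ParticleSet, ParticleType, parse_spices
from .engine import BoxSpec, BoxState, SimulationConfig, thermal_velocities
from .parameters import ChiMatrix, kelvin_to_dpd, scale_to_range

__all__ = [
    "demo_particle_set",
    "scheme_a",
    "scheme_b",
    "water",
    "small_lamellar_system",
    "pure_fluid_box",
    "DEMO_TOKENS",
]

DEMO_TOKENS = ("Me", "Et", "Me2O", "MeOH", "H2O")

# fragment molar masses, g/mol (methane, ethane, dimethyl ether, methanol, water)
_MASSES = {"Me": 16.04, "Et": 30.07, "Me2O": 46.07, "MeOH": 32.04, "H2O": 18.02}

# true molecular molar masses used for composition mapping (fragment sums
# double-count capping hydrogens)
M_C10E4 = 334.50   # CH3(CH2)9(OC2H4)4OH, g/mol
M_H2O = 18.02

# published box compositions for 18,500 surfactants at mass fraction 0.75
_N_REF = 18_500
_N_WATER_A = 79_174
_N_WATER_B = 65_337

# base Flory–Huggins contrast pattern (dimensionless, before range scaling):
# hydrophobes repel water, ether oxygen is mildly hydrophilic, the terminal
# hydroxyl most hydrophilic.  The hydroxyl–water entry carries the largest
# magnitude, so after range scaling the smallest a_ij is also the maximum
# absolute deviation from the diagonal — the "range x" definition.
_BASE_CHI = np.array([
    #  Me    Et    Me2O  MeOH  H2O
    [0.0,  0.1,  0.6,  1.0,  2.0],   # Me
    [0.1,  0.0,  0.7,  1.1,  2.2],   # Et
    [0.6,  0.7,  0.0, -0.2, -1.2],   # Me2O
    [1.0,  1.1, -0.2,  0.0, -2.5],   # MeOH
    [2.0,  2.2, -1.2, -2.5,  0.0],   # H2O
])


def _calibrated_volumes() -> dict[str, float]:
    """Fragment volumes (Å³) reproducing the two published water counts."""
    ratio = _N_REF * (0.25 / 0.75) * (M_C10E4 / M_H2O)   # unscaled water count
    v_a = 30.0 * 14 * ratio / _N_WATER_A                 # scheme A molecule
    v_b = 30.0 * 10 * ratio / _N_WATER_B                 # scheme B molecule
    v_me, v_meoh = 38.0, 45.0
    v_me2o = (v_a - 9 * v_me - v_meoh) / 4.0
    v_et = (v_b - v_me - 4 * v_me2o - v_meoh) / 4.0
    return {"Me": v_me, "Et": v_et, "Me2O": v_me2o, "MeOH": v_meoh,
            "H2O": 30.0}


VOLUMES = _calibrated_volumes()


def demo_particle_set(range_x: float = 20.0, T: float = 298.0,
                      rho: float = 3.0) -> ParticleSet:
    """Amphiphile/water demo set whose smallest a_ij is a_ii − range_x."""
    if range_x > 0:
        a = scale_to_range(ChiMatrix(_BASE_CHI), range_x, T, rho)
    else:
        a = scale_to_range(ChiMatrix(_BASE_CHI), 0.0, T, rho)
    types = [ParticleType(t, VOLUMES[t], _MASSES[t]) for t in DEMO_TOKENS]
    return ParticleSet(types=types, repulsion=a, reference_temperature=T,
                       rho=rho,
                       comment=f"synthetic demo set, range {range_x:g}, {T} K")


def scheme_a() -> MoleculeSpec:
    """C10E4 fragmentation scheme A: 9 methane, 4 dimethyl ether, 1 methanol."""
    return parse_spices("9Me-4Me2O-MeOH", name="C10E4", molar_mass=M_C10E4)


def scheme_b() -> MoleculeSpec:
    """C10E4 fragmentation scheme B: ethane-based alkyl tail."""
    return parse_spices("4Et-Me-4Me2O-MeOH", name="C10E4", molar_mass=M_C10E4)


def water() -> MoleculeSpec:
    return parse_spices("H2O", name="water", molar_mass=M_H2O)


def surfactant_water_counts(n_surfactant: int, scheme: str = "A",
                            mass_fraction: float = 0.75,
                            pset: ParticleSet | None = None,
                            volume_scaling: bool = True) -> dict[str, int]:
    """Volume-scaled molecule counts for a surfactant/water mixture."""
    pset = pset or demo_particle_set()
    surf = scheme_a() if scheme.upper() == "A" else scheme_b()
    comp = Composition([(surf, mass_fraction), (water(), 1.0 - mass_fraction)])
    return volume_scaled_counts(comp, n_surfactant, pset,
                                volume_scaling=volume_scaling)


def small_lamellar_system(scale: float, scheme: str = "A",
                          box: BoxSpec | None = None, seed: int = 0,
                          range_x: float = 20.0,
                          mass_fraction: float = 0.75,
                          T: float = 298.0,
                          boundary_mode: str = "periodic_xy_reflective_z",
                          **config_kw) -> tuple[SimulationConfig, BoxState]:
    """Scaled-down surfactant/water box preserving the volume-scaled
    surfactant : water molecule ratio of the full-scale system.

    ``scale`` ∈ (0, 1] multiplies the reference surfactant count (18,500).
    If no box is given, one is derived so the bead total equals ρ·V
    (Lz = 2 Lx).  Extra keyword arguments go into the SimulationConfig.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    pset = demo_particle_set(range_x=range_x, T=T)
    n_surf = max(1, round(_N_REF * scale))
    counts = surfactant_water_counts(n_surf, scheme, mass_fraction, pset)
    surf = scheme_a() if scheme.upper() == "A" else scheme_b()
    mols = [surf, water()]
    if box is None:
        box = box_for_counts(counts, mols, rho=3.0, aspect_z=2.0,
                             boundary_mode=boundary_mode)
    else:
        # keep the surfactant count, let water fill the box to rho V
        n_beads_surf = counts[surf.name] * surf.n_beads
        counts[water().name] = max(0, round(3.0 * box.volume) - n_beads_surf)
    state = random_start(counts, box, pset, mols, seed=seed, temperature=T)
    cfg = SimulationConfig(temperature=T, seed=seed, **config_kw)
    return cfg, state


class _UniformSet:
    """Minimal stand-in for a ParticleSet: a bare repulsion matrix for
    single-type reference fluids whose a need not equal 75 k_BT/ρ."""

    def __init__(self, a: float, name: str = "W"):
        self.repulsion = np.array([[float(a)]])
        self.types = [ParticleType(name, 30.0, 18.02)]
        self.names = [name]

    def index(self, token: str) -> int:
        return 0


def pure_fluid_box(n_beads: int, a: float, T: float, box: BoxSpec,
                   seed: int = 0, rho: float = 3.0):
    """Single-type unbonded fluid for thermostat / equation-of-state checks.

    Returns (config, state, particle_set_like).  ``n_beads`` must match
    ρ·V within 1 %.
    """
    target = rho * box.volume
    if abs(n_beads - target) > max(1.0, 0.01 * target):
        raise ValueError(
            f"n_beads {n_beads} inconsistent with rho*V = {target:.1f}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    pos = rng.random((n_beads, 3)) * box.array
    vel = thermal_velocities(n_beads, kelvin_to_dpd(T),
                             seed=(seed ^ 0x5EED) & 0x7FFFFFFF)
    state = BoxState(pos, vel, np.zeros(n_beads, dtype=np.int64),
                     np.arange(n_beads, dtype=np.int64),
                     np.empty((0, 2), dtype=np.int64), box,
                     type_names=["W"])
    cfg = SimulationConfig(temperature=T, seed=seed)
    return cfg, state, _UniformSet(a)
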